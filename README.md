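# cttwas — cell-type-resolved TWAS from bulk tissue

`cttwas` is a pipeline for transcriptome-wide association studies (TWAS) of a
binary phenotype in bulk blood when the signal of interest may live in a
single cell type. Case–control differences that affect only one or a few cell
types are diluted — or cancel — in whole-tissue measurements, so the package
combines:

1. **Reference-based deconvolution** — cell-type proportions estimated per
   sample from bulk DNA methylation against a panel of per-cell-type mean
   beta profiles (non-negative least squares on the simplex).
2. **Cell-type-specific TWAS** — for each transcript, bulk abundance is
   regressed, *with no intercept*, on the proportions and their interactions
   with case status:

   Y<sup>bulk</sup> = Σ<sub>c</sub> m<sub>c</sub> P<sub>c</sub> +
   Σ<sub>c</sub> m<sub>c</sub><sup>case</sup> (case × P<sub>c</sub>) + covariates + E

   Because Σ<sub>c</sub> P<sub>c</sub> = 1 the model needs no constant. The
   interaction coefficient m<sub>c</sub><sup>case</sup> estimates the
   case–control difference of the cell-type-c mean and is tested per cell
   type, with Benjamini–Hochberg q-values (q < 0.1 significance) computed
   within each cell type, and genomic-inflation lambdas plus permuted-label
   TWAS runs as calibration checks.
3. **Pathway enrichment by circular permutation** — markers are ordered along
   the genome; a gene is "top" if any of its markers is (genes extended by a
   10 kb upstream promoter flank, a marker may hit several overlapping
   genes). Per pathway the 2×2 association between top-gene status and
   membership is summarized by Cramér's V, with the null obtained by rotating
   the top-marker indicator around the genome-wide circle — preserving the
   number of top markers, their local correlation, and gene size. Family-wise
   error is controlled by the Westfall–Young max-V adjustment over the same
   rotations; enriched pathways are clustered by gene-set Jaccard similarity
   with Louvain communities.
4. **Mediation (deQTL) scans** — a SNP (or CpG, or hormone) is tested as a
   regulator acting on case status *through* a transcript, H₀: a×b = 0, with
   a linear mediator model, a logistic outcome model, and a quasi-Bayesian
   Monte-Carlo approximation of the average causal mediation effect (ACME).
   Draw counts escalate tenfold from 1,000 up to 1,000,000 until the p-value
   is resolvable. Markers are pre-selected by nominal case association
   (p < 0.05) within a 10 kb cis window of the tested genes.
5. **Cross-study concordance** — top-fraction gene overlap between result
   sets, an exact one-sided binomial sign test of directional agreement
   (null: 50%), and Fisher 2×2 gene-set enrichment with odds ratios.

A synthetic multi-omics cohort generator with full ground truth (Dirichlet
cell proportions, planted cell-type effects, cis-eQTLs, mediated disease
paths, methylation reference mixtures, hormone shifts) makes every stage
testable end to end without access to any restricted data.

## Worked example

Plant a 1.5-SD case effect on transcript `T00000` in B cells (mean proportion
5.6%), deconvolve the proportions from methylation, and run the cell-type
TWAS:

```python
import cttwas as ct

cfg = ct.SimulationConfig(
    n_samples=600, n_cases=300, n_transcripts=500,
    effect_map=[(0, 2, 1.5)],   # transcript T00000, B cells, +1.5 SD in cases
    seed=7,
)
ds = ct.simulate_cohort(cfg)
P = ct.estimate_proportions(ds.methylation, ds.reference_panel)
res = ct.fit_celltype_twas(ds.expression, ds.phenotypes, P)
print(res[res.index == "T00000"][["context", "effect", "se", "p", "q"]].round(4))
```

```
              context  effect      se       p       q
transcript_id
T00000           CD8T  0.1690  0.1402  0.2284  0.9101
T00000           CD4T -0.0537  0.1024  0.6006  0.9438
T00000              B  1.5645  0.1708  0.0000  0.0000
T00000           Mono  0.1645  0.1960  0.4017  0.9652
T00000           Gran -0.0127  0.0366  0.7296  0.9818
T00000             NK -0.4519  0.2412  0.0615  0.8852
```

The planted effect is recovered in the correct cell type (estimate 1.56 vs
truth 1.5, q ≈ 0) while the five off-target cell types stay null. The B-cell
p-value column has genomic inflation λ = 0.936, i.e. calibrated tests.

The whole pipeline — simulate → QC → deconvolve → TWAS → pathways →
mediation scan → concordance — runs as one command on a bundled demo
configuration:

```bash
cttwas run-all --seed 1 --out demo_output
```

Each stage is also its own subcommand (`simulate`, `qc`, `deconvolve`,
`twas`, `pathways`, `regulate`, `overlap`) operating on TSV/GMT/VCF files;
outputs carry the package version, config hash and seed in their headers and
a manifest with checksums is written for reproducibility.

## Layout

- `src/cttwas/synthetic.py` — cohort generator and ground truth
- `src/cttwas/io.py` — TSV/GMT/VCF readers and writers, transcript QC
- `src/cttwas/deconvolution.py` — proportion estimation and group comparison
- `src/cttwas/twas.py` — bulk and interaction-model TWAS, lambda, FDR
- `src/cttwas/enrichment.py` — circular-permutation enrichment, clustering
- `src/cttwas/mediation.py` — quasi-Bayesian mediation scans
- `src/cttwas/overlap.py` — sign tests and 2×2 enrichment
- `src/cttwas/pipeline.py`, `cli.py` — orchestration and the `cttwas` CLI

See `docs/methods.md` for the statistical details, parameter defaults and
known limitations.
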