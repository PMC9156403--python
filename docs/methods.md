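# Methods

## The deconvolution TWAS model

Bulk expression of a transcript is modelled as a proportion-weighted mixture
of latent cell-type means. With case status coded 0/1 and per-sample
cell-type proportions P_c (estimated from methylation, below), the
association model is ordinary least squares with **no intercept**:

    Y_bulk = sum_c m_c * P_c + sum_c m_c_case * (case * P_c) + covariates + E

Since the proportions sum to one, the P_c block spans the constant and an
intercept would be collinear; the equivalent parameterization with an
intercept and one proportion dropped gives identical fits (and is what the
bulk TWAS uses, where case status enters as a main effect). The interaction
coefficient m_c_case is the case–control difference of the cell-type-c mean;
its two-sided p-value uses the t distribution on the residual degrees of
freedom. Covariates enter as plain additive columns, not interacted with
proportions: the model asks whether *case status* shifts cell-type means,
and covariate-by-proportion interactions would cost 6 degrees of freedom per
covariate for a hypothesis the design does not test.

Multiple testing is controlled by Benjamini–Hochberg q-values computed
**within each cell type** (and separately for bulk), significance at
q < 0.1. A Storey-type pi0-smoothed variant is available
(`fdr_qvalues(..., method="storey")`) but BH is the default because it is
deterministic and assumption-light. Calibration is monitored two ways: the
genomic-inflation factor lambda = median(chi2(p)) / 0.4549, and full TWAS
reruns under permuted case labels (proportions and covariates stay attached
to their samples), whose lambdas should average ≈ 1.

Cell types whose interaction column is numerically constant (e.g. a cell
type absent from every case) are reported with p = NaN and flagged
untestable rather than silently dropped.

## Proportion estimation

Per sample, the bulk methylation vector over the reference CpGs is fit by
non-negative least squares against the panel of per-cell-type mean betas and
the weights renormalized onto the simplex. On well-conditioned panels this
coincides with the equality-constrained quadratic program (available as
`method="qp"`); NNLS-plus-renormalization is the default for its simplicity
and numerical robustness. All CpGs shared between the data and the panel are
used; curation of an optimal reference CpG subset is upstream of this
package. Case–control differences in proportions are tested per cell type by
OLS of the proportion on case status plus covariates; constant proportion
columns are flagged degenerate.

## Circular-permutation pathway enrichment

Markers (transcripts, for TWAS results) are sorted by chromosome and
position and conceptually joined into one genome-wide circle
(per-chromosome rotation is available behind a flag; the genome-wide circle
is the default because a single rotation domain maximizes the number of
distinct null configurations). The top-marker indicator (default rule:
q < 0.1) is rotated by a uniformly random offset in 0..M-1; each rotation
preserves the number of top markers and their spacing, which makes the null
robust to local correlation among neighboring markers and accounts for gene
size, since genes with more markers are hit more often in rotations too.

Genes are intervals extended by a 10 kb upstream (promoter) flank on the
strand-appropriate side; a marker maps to every gene whose extended interval
contains it, and a gene counts once no matter how many of its markers are
top. The gene universe is the set of genes that received at least one
marker: genes with no marker can never be top and would only pad the
contingency table. Per pathway with at least 3 genes in the universe, the
2×2 table (top gene yes/no × in pathway yes/no) is summarized by Cramér's V
= |ad−bc| / sqrt((a+b)(c+d)(a+c)(b+d)), which equals sqrt(chi2/n) for a 2×2
table and is 0 when a margin is empty.

The permutation p-value is the proportion of rotations with V at least the
observed value (ties count toward the tail) floored at 1/n_perm — a plain
proportion can be zero, which is unreportable. Family-wise error is
controlled at alpha = 0.05 with the Westfall–Young single-step adjustment:
the adjusted p is the proportion of rotations whose *maximum* V across all
tested pathways reaches the observed V (Bonferroni is available as an
alternative). Significant pathways are clustered on a graph with edges
weighted by gene-set Jaccard similarity (threshold 0.25) using Louvain
communities at resolution 1 with a fixed seed; none of these three values
has a principled external referent, they are conventional defaults.

Because the permutation distribution has only M distinct rotations, null
p-values are discrete and conservative (super-uniform), which the test suite
checks directly; under marker exchangeability the circular p agrees with a
gene-label permutation p up to Monte-Carlo and rotation-population error.

## Mediation (regulation / deQTL) scans

A marker regulates a transcript's contribution to disease if the indirect
path a×b is nonzero: mediator model `transcript ~ marker` (OLS, path a),
outcome model `case ~ transcript + marker` (logistic regression, path b and
direct path c'). The binary outcome makes the logistic link the natural
choice for the quasi-Bayesian potential-outcome machinery. Covariates are
regressed out of markers and mediators *before* the scan. For SNPs the
marker is an instrument: the code only ever regresses mediator and outcome
on the marker, never the reverse, so the inferred direction cannot be
flipped by the scan.

The ACME is approximated by simulation: K parameter vectors are drawn from
each fitted model's asymptotic normal distribution; per draw, potential
mediator values under the treat/control marker contrast (default dosage 1
vs 0) are simulated with independent residual draws at the fitted residual
SD (the residual SD itself is held at its estimate rather than drawn — its
sampling variability is second-order for the ACME), pushed through the
outcome model at both marker arms, and the potential-outcome differences
averaged over the sample and the two arms. The point estimate is the mean
of draws; the Monte-Carlo p-value is 2·min(fraction ≤ 0, fraction ≥ 0).
When no draw crosses zero the draw count escalates tenfold through the
schedule 1,000 → 10,000 → 100,000 → 1,000,000 until the p-value is
resolvable or the schedule is exhausted. Logistic separation or non-finite
standard errors mark the pair non-converged (NaN estimates) rather than
contaminating the scan.

Candidate pairs are formed by pre-selection: markers with a nominal
case-status association (two-sided p < 0.05, equal-variance two-group test,
equivalent to the OLS slope test) lying within the gene body ± 10 kb
(strand-agnostic; the strand-aware flank is a promoter notion specific to
pathway mapping). Hormones skip the positional filter and pair with every
tested gene. For each gene with a differentially expressed transcript, all
of that gene's transcripts with expression data are tested; BH q-values are
computed over the whole scan, significance at q < 0.1.

## Concordance statistics

Two result sets are compared by ranking genes within each set by the best
(minimum) transcript-level p-value, intersecting the top fraction (default
5%), and recording effect-direction agreement. Under independence the
expected agreement is 50%; the sign test reports the exact one-sided upper
binomial tail P(X ≥ k | n, 1/2). One-sided is the correct tail here because
the alternative of interest is *excess* concordance. Gene-set enrichment
crosses a query set against a target set over a shared universe with the
odds ratio ad/bc (infinite OR flagged rather than encoded numerically) and
the two-sided Fisher exact test.

## The synthetic cohort generator

The generator emulates the data structure the pipeline consumes, with full
ground truth:

- **Proportions**: Dirichlet with alpha = (9.7, 16.3, 5.6, 4.7, 59.4, 3.0)
  for (CD8T, CD4T, B, Mono, Gran, NK) — means equal to typical adult blood
  composition and concentration ≈ 99, i.e. granulocyte SD ≈ 0.05 between
  subjects. Case-specific composition shifts are applied on the Dirichlet
  *means* (renormalized, same concentration), keeping draws on the simplex.
- **Expression**: simulated on a log2(TPM+1)-like Gaussian scale. Baseline
  cell-type means are drawn in [2, 8] (so values stay positive without
  clipping, which would break the exact mixture identity); eQTL slopes add
  dosage effects to specific cell types (or all, for a bulk-level eQTL);
  planted case effects add multiples of `effect_scale` (default 1.0, the
  "within-cell-type SD" unit) to specific cell-type means in cases. Latent
  cell-type profiles are deterministic given the design; all stochastic
  per-sample variation enters through a single bulk residual
  (`bulk_noise_sd`, default 0.05), mirroring the error structure of the
  mixture regression. The default residual is deliberately small — it
  represents measurement noise on well-expressed transcripts, not
  between-subject biological variability (which the deterministic profiles
  omit) — so that effects planted in rare cell types (B cells at 5.6%) are
  detectable at bundled sample sizes. Configurations that exercise the
  mediation machinery raise it (0.3) so the mediator retains variance beyond
  its eQTL, keeping marker and mediator distinguishable in the outcome model.
- **Case labels**: a deterministic split (first `n_cases` samples) unless a
  mediation map is present, in which case labels are Bernoulli draws from a
  logistic model on the *observed* (noise-included) bulk abundance of the
  mediator transcripts plus any direct dosage effects, centered to an
  expected prevalence of `n_cases/n_samples`. Using the observed mediator
  makes the scanned outcome model correctly specified; using the latent one
  would attenuate path b by the measurement-error reliability ratio.
- **Methylation**: a reference panel of per-cell-type betas ~ Beta(0.4, 0.4)
  (bimodal, as methylation is), mixed by the true proportions plus Gaussian
  noise (`ref_noise_sd`, default 0.02 — array-scale technical noise) and
  clipped to [0, 1].
- **Genotypes**: dosages ~ Binomial(2, MAF), MAF uniform in (0.1, 0.5).
  SNPs named in eQTL/mediation maps are placed mid-gene of their target so
  cis-window logic finds them; remaining SNPs cycle through gene bodies.
- **Coordinates**: two synthetic chromosomes, genes of 10 kb spaced 60 kb
  apart, 0-based half-open internally.
- **Hormones**: Gaussian with configurable per-hormone mean, SD and case
  shift (defaults have no shift).

What the generator does **not** emulate: between-subject biological
expression variance within a cell type, linkage disequilibrium and
population structure, count-level sequencing noise, batch effects, and
correlated methylation neighborhoods. Passing tests therefore demonstrate
the statistical machinery is correct under its stated model, not that real
cohorts at these sample sizes would yield similar power.

## Numerical and design choices

- TWAS fits are vectorized across transcripts (one shared (X'X)^-1, per-
  transcript residual variances); rank deficiency raises an error naming the
  problem rather than silently pseudo-inverting.
- Transcript QC removes, sequentially and attributing each transcript to the
  first rule that fires: library-prep depletion targets (rRNA biotype and
  the globins HBA1/HBA2/HBB/HBD), unannotated transcripts, presence in
  strictly fewer than 1% of samples (presence = abundance > 0), mean
  abundance < 1 or > 20,000.
- Permutation and simulation seeds are explicit arguments everywhere and
  recorded in outputs; identical configuration and seed reproduce results
  byte-for-byte.
- Scan problem sizes in the test suite and acceptance script (cohorts of
  200–600 samples, 40–2,000 transcripts, 10–20 seeds per suite,
  1,000–10,000 permutation/Monte-Carlo draws) were chosen so the full
  validation runs comfortably on a laptop-class single CPU while keeping
  binomial/Monte-Carlo error well below the tested margins.

## Known limitations

- Per-sample cell-type expression is never observed: the mediation scan uses
  covariate-residualized **bulk** abundance as the mediator even when the
  differential expression was detected in one cell type.
- The deconvolution estimator assumes the reference panel matches the
  assayed tissue; panel mis-specification biases proportions and everything
  downstream.
- The quasi-Bayesian ACME test is conservative under H0: a×b = 0 when only
  one path is null (a known property of the product-of-paths null), and
  permutation p-values are discrete, hence also conservative at small
  n_perm.
- The Fisher-exact 2×2 enrichment treats genes as exchangeable units and
  ignores gene length and marker density; within this package it is used
  for cross-set comparisons, not genomic enrichment (the circular
  permutation handles that).
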