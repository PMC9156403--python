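"""Synthetic multi-omics cohort generator with known ground truth.

Emulates the data structure of a whole-blood case-control transcriptomic
study: Dirichlet-distributed proportions of six blood cell types,
cell-type-specific case effects on transcript abundance, bulk expression as
the proportion-weighted mixture of latent cell-type profiles plus residual
noise, cis-SNPs with eQTL effects optionally mediated to case status through
a transcript, bulk methylation as a mixture of a reference panel, and
hormone levels with optional case shifts.

Expression is simulated on a log2(TPM+1)-like Gaussian scale.  Latent
cell-type profiles are deterministic given the design (case status, dosage);
all per-sample stochastic variation enters through the single bulk residual,
mirroring the error structure of the mixture regression the pipeline fits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .deconvolution import CellProportions, ReferencePanel
from .io import (
    ExpressionMatrix,
    GenotypeMatrix,
    MethylationMatrix,
    write_tsv,
)

DEFAULT_CELLTYPES = ("CD8T", "CD4T", "B", "Mono", "Gran", "NK")
# Mean blood proportions (CD8 T, CD4 T, B, monocytes, granulocytes, NK);
# using them directly as Dirichlet alpha gives concentration ~99 and hence
# realistic between-subject variability (granulocyte SD ~ 0.05).
DEFAULT_ALPHA = (9.7, 16.3, 5.6, 4.7, 59.4, 3.0)
DEFAULT_HORMONES = {
    "estradiol": (50.0, 15.0, 0.0),
    "progesterone": (5.0, 2.0, 0.0),
    "oxytocin": (20.0, 5.0, 0.0),
    "bdnf": (25.0, 8.0, 0.0),
}

GENE_LENGTH = 10_000
GENE_SPACING = 60_000


class ConfigurationError(ValueError):
    """A SimulationConfig field is inconsistent; the message names it."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    ``effect_map`` entries are ``(transcript_idx, celltype_idx, effect_size)``
    with the effect expressed in units of ``effect_scale``.  ``eqtl_map``
    entries are ``(snp_idx, transcript_idx, celltype_idx_or_None, slope)``;
    a ``None`` cell type applies the slope in every cell type (a bulk-level
    eQTL).  ``mediation_map`` entries are ``(snp_idx, transcript_idx,
    b_logit_slope, direct_logit_slope)``; the ``a`` path must be planted with
    a matching ``eqtl_map`` entry.  When ``mediation_map`` is non-empty, case
    labels are drawn from the logistic model (expected prevalence
    ``n_cases / n_samples``); otherwise the first ``n_cases`` samples are
    cases.
    """

    n_samples: int = 400
    n_cases: int = 200
    celltype_names: tuple[str, ...] = DEFAULT_CELLTYPES
    dirichlet_alpha: tuple[float, ...] = DEFAULT_ALPHA
    prop_case_shift: tuple[float, ...] | None = None
    n_transcripts: int = 1000
    n_effect_transcripts: int = 0
    effect_map: list[tuple[int, int, float]] = field(default_factory=list)
    effect_scale: float = 1.0
    bulk_noise_sd: float = 0.05
    n_snps: int = 100
    maf_range: tuple[float, float] = (0.1, 0.5)
    eqtl_map: list[tuple[int, int, int | None, float]] = field(default_factory=list)
    mediation_map: list[tuple[int, int, float, float]] = field(default_factory=list)
    n_cpgs: int = 300
    ref_noise_sd: float = 0.02
    hormone_spec: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_HORMONES)
    )
    genome_layout: str = "two_chromosomes"
    seed: int = 0

    @property
    def n_celltypes(self) -> int:
        return len(self.celltype_names)

    def validate(self) -> None:
        if len(self.dirichlet_alpha) != self.n_celltypes:
            raise ConfigurationError(
                "dirichlet_alpha: expected one entry per cell type "
                f"({self.n_celltypes}), got {len(self.dirichlet_alpha)}"
            )
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ConfigurationError("dirichlet_alpha: entries must be > 0")
        if self.prop_case_shift is not None and len(self.prop_case_shift) != self.n_celltypes:
            raise ConfigurationError("prop_case_shift: one entry per cell type required")
        if not (0 <= self.n_cases <= self.n_samples):
            raise ConfigurationError("n_cases: must be between 0 and n_samples")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range: must satisfy 0 < low <= high <= 0.5")
        if self.bulk_noise_sd < 0:
            raise ConfigurationError("bulk_noise_sd: must be >= 0")
        if self.ref_noise_sd < 0:
            raise ConfigurationError("ref_noise_sd: must be >= 0")
        for name, trip in (("effect_map", self.effect_map),):
            for t, c, _ in trip:
                if not 0 <= t < self.n_transcripts:
                    raise ConfigurationError(f"{name}: transcript index {t} out of range")
                if not 0 <= c < self.n_celltypes:
                    raise ConfigurationError(f"{name}: cell-type index {c} out of range")
        for s, t, c, _ in self.eqtl_map:
            if not 0 <= s < self.n_snps:
                raise ConfigurationError(f"eqtl_map: snp index {s} out of range")
            if not 0 <= t < self.n_transcripts:
                raise ConfigurationError(f"eqtl_map: transcript index {t} out of range")
            if c is not None and not 0 <= c < self.n_celltypes:
                raise ConfigurationError(f"eqtl_map: cell-type index {c} out of range")
        for s, t, _, _ in self.mediation_map:
            if not 0 <= s < self.n_snps:
                raise ConfigurationError(f"mediation_map: snp index {s} out of range")
            if not 0 <= t < self.n_transcripts:
                raise ConfigurationError(f"mediation_map: transcript index {t} out of range")


@dataclass
class SyntheticDataset:
    """One simulated cohort with its ground truth."""

    expression: ExpressionMatrix
    celltype_expression: dict[str, pd.DataFrame]  # latent truth; not pipeline input
    methylation: MethylationMatrix
    reference_panel: ReferencePanel
    genotypes: GenotypeMatrix
    proportions_true: CellProportions
    phenotypes: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# Layout helpers
# ---------------------------------------------------------------------------


def _transcript_layout(n_transcripts: int) -> pd.DataFrame:
    half = (n_transcripts + 1) // 2
    chroms, starts, strands = [], [], []
    for i in range(n_transcripts):
        on_first = i < half
        j = i if on_first else i - half
        chroms.append("chr1" if on_first else "chr2")
        starts.append(GENE_SPACING * j + 20_000)
        strands.append("+" if i % 2 == 0 else "-")
    ids = [f"T{i:05d}" for i in range(n_transcripts)]
    return pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(n_transcripts)],
            "chrom": chroms,
            "start": starts,
            "end": [s + GENE_LENGTH for s in starts],
            "strand": strands,
            "biotype": "protein_coding",
        },
        index=pd.Index(ids, name="transcript_id"),
    )


def _point_layout(
    n: int, prefix: str, anchored: dict[int, int], genes: pd.DataFrame, salt: int
) -> pd.DataFrame:
    """Place point features inside gene bodies, cycling through genes.

    Indices in ``anchored`` map feature index -> transcript index; those
    features sit mid-gene of their anchor so that cis-window logic finds
    them.  Others cycle through genes with distinct offsets.
    """
    chroms, poss = [], []
    per_gene_counter: dict[int, int] = {}
    for i in range(n):
        t = anchored.get(i, i % len(genes))
        k = per_gene_counter.get(t, 0)
        per_gene_counter[t] = k + 1
        row = genes.iloc[t]
        if i in anchored:
            pos = row["start"] + GENE_LENGTH // 2 + k
        else:
            pos = row["start"] + 100 + salt + 17 * k
        chroms.append(row["chrom"])
        poss.append(int(pos))
    return pd.DataFrame(
        {"chrom": chroms, "pos": poss},
        index=pd.Index([f"{prefix}{i:05d}" for i in range(n)], name="id"),
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full synthetic cohort from ``config`` (deterministic in seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, T, C, S = (
        config.n_samples,
        config.n_transcripts,
        config.n_celltypes,
        config.n_snps,
    )
    # matrices get plain (unnamed) sample columns so TSV round-trips exactly;
    # the phenotype table's row index keeps the name
    sample_ids = pd.Index([f"S{i:04d}" for i in range(n)])
    celltypes = list(config.celltype_names)

    effect_map = list(config.effect_map)
    if not effect_map and config.n_effect_transcripts > 0:
        effect_map = [
            (t, t % C, 1.5) for t in range(config.n_effect_transcripts)
        ]

    # --- genotypes -------------------------------------------------------
    maf = rng.uniform(*config.maf_range, size=S)
    dosage = rng.binomial(2, maf[:, None], size=(S, n)).astype(float)

    # --- latent cell-type expression (baseline + eQTL) --------------------
    base = rng.uniform(2.0, 8.0, size=T)
    mu = base[None, :] + rng.normal(0.0, config.effect_scale, size=(C, T))
    # Y0[c]: T x n latent profile before case effects
    Y0 = np.broadcast_to(mu.T[:, :, None], (T, C, n)).copy()  # T x C x n
    for s, t, c, slope in config.eqtl_map:
        if c is None:
            Y0[t, :, :] += slope * dosage[s][None, :]
        else:
            Y0[t, c, :] += slope * dosage[s]

    # --- proportions (controls' alpha) and case labels --------------------
    alpha = np.asarray(config.dirichlet_alpha, dtype=float)
    P = rng.dirichlet(alpha, size=n)  # n x C

    # bulk measurement noise is drawn up front so that, under the mediation
    # model, case status can depend on the *observed* mediator abundance
    bulk_noise = (
        rng.normal(0.0, config.bulk_noise_sd, size=(T, n))
        if config.bulk_noise_sd > 0
        else np.zeros((T, n))
    )

    if config.mediation_map:
        base_rate = config.n_cases / config.n_samples
        eta = np.full(n, logit(base_rate))
        bulk0 = np.einsum("tcn,nc->tn", Y0, P) + bulk_noise
        for s, t, b, c_direct in config.mediation_map:
            m = bulk0[t]
            eta += b * (m - m.mean()) + c_direct * (dosage[s] - dosage[s].mean())
        case = rng.binomial(1, expit(eta)).astype(int)
    else:
        case = np.zeros(n, dtype=int)
        case[: config.n_cases] = 1

    if config.prop_case_shift is not None and any(config.prop_case_shift):
        shift = np.asarray(config.prop_case_shift, dtype=float)
        mean = alpha / alpha.sum()
        mean_case = mean + shift
        if (mean_case <= 0).any():
            raise ConfigurationError("prop_case_shift: shifted means must stay > 0")
        alpha_case = mean_case / mean_case.sum() * alpha.sum()
        idx = np.flatnonzero(case == 1)
        P[idx] = rng.dirichlet(alpha_case, size=len(idx))

    # --- case effects on cell-type profiles -------------------------------
    Y = Y0
    for t, c, eff in effect_map:
        Y[t, c, :] += eff * config.effect_scale * case

    # --- bulk expression ---------------------------------------------------
    bulk = np.einsum("tcn,nc->tn", Y, P) + bulk_noise

    annotation = _transcript_layout(T)
    expression = ExpressionMatrix(
        pd.DataFrame(bulk, index=annotation.index, columns=sample_ids), annotation
    )

    # --- methylation: reference panel mixture ------------------------------
    ref_betas = rng.beta(0.4, 0.4, size=(config.n_cpgs, C))
    cpg_coords = _point_layout(config.n_cpgs, "cg", {}, annotation, salt=29)
    ref = ReferencePanel(
        pd.DataFrame(ref_betas, index=cpg_coords.index, columns=celltypes)
    )
    meth = ref_betas @ P.T
    if config.ref_noise_sd > 0:
        meth = meth + rng.normal(0.0, config.ref_noise_sd, size=meth.shape)
    meth = np.clip(meth, 0.0, 1.0)
    methylation = MethylationMatrix(
        pd.DataFrame(meth, index=cpg_coords.index, columns=sample_ids), cpg_coords
    )

    # --- genotype coordinates (cis-anchor mediated/eQTL SNPs) --------------
    anchored = {s: t for s, t, _, _ in config.eqtl_map}
    anchored.update({s: t for s, t, _, _ in config.mediation_map})
    snp_coords = _point_layout(S, "rs", anchored, annotation, salt=11)
    genotypes = GenotypeMatrix(
        pd.DataFrame(dosage, index=snp_coords.index, columns=sample_ids),
        snp_coords,
        maf=pd.Series(maf, index=snp_coords.index),
    )

    # --- phenotypes ---------------------------------------------------------
    pheno = pd.DataFrame(
        {"case_status": case}, index=sample_ids.rename("sample_id")
    )
    pheno["age"] = rng.normal(30.0, 5.0, size=n).round(1)
    for name, (mean, sd, shift) in config.hormone_spec.items():
        pheno[name] = rng.normal(mean + shift * case, sd)

    proportions = CellProportions(
        pd.DataFrame(P, index=sample_ids, columns=celltypes)
    )
    truth = {
        "seed": config.seed,
        "effect_map": [list(e) for e in effect_map],
        "eqtl_map": [list(e) for e in config.eqtl_map],
        "mediation_map": [list(e) for e in config.mediation_map],
        "effect_scale": config.effect_scale,
        "case_ids": [sample_ids[i] for i in np.flatnonzero(case == 1)],
    }
    celltype_expression = {
        ct: pd.DataFrame(Y[:, c, :], index=annotation.index, columns=sample_ids)
        for c, ct in enumerate(celltypes)
    }
    return SyntheticDataset(
        expression=expression,
        celltype_expression=celltype_expression,
        methylation=methylation,
        reference_panel=ref,
        genotypes=genotypes,
        proportions_true=proportions,
        phenotypes=pheno,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_dataset(
    ds: SyntheticDataset, directory, write_vcf: bool = False
) -> dict[str, str]:
    """Write all cohort tables as TSV (+ truth JSON); returns a file manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def _emit(name: str, df: pd.DataFrame, fname: str) -> None:
        path = directory / fname
        write_tsv(df, path)
        manifest[name] = str(path)

    _emit("expression", ds.expression.abundance, "expression.tsv")
    _emit("annotation", ds.expression.annotation, "annotation.tsv")
    _emit("methylation", ds.methylation.betas, "methylation.tsv")
    _emit("cpg_coords", ds.methylation.coords, "cpg_coords.tsv")
    _emit("reference", ds.reference_panel.betas, "reference.tsv")
    _emit("genotypes", ds.genotypes.dosages, "genotypes.tsv")
    _emit("snp_coords", ds.genotypes.coords, "snp_coords.tsv")
    _emit("phenotypes", ds.phenotypes, "phenotypes.tsv")
    _emit("proportions_true", ds.proportions_true.values, "proportions_true.tsv")

    truth_path = directory / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(ds.truth, fh, indent=1)
    manifest["truth"] = str(truth_path)

    if write_vcf:
        vcf_path = directory / "genotypes.vcf"
        _write_minimal_vcf(ds.genotypes, vcf_path)
        manifest["vcf"] = str(vcf_path)
    return manifest


def _write_minimal_vcf(gt: GenotypeMatrix, path) -> None:
    """Emit a minimal VCF 4.2 with GT fields (dosages rounded to 0/1/2)."""
    samples = list(gt.dosages.columns)
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = pd.unique(gt.coords["chrom"])
        for ch in chroms:
            fh.write(f"##contig=<ID={ch}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        order = gt.coords.sort_values(["chrom", "pos"]).index
        for snp in order:
            ch = gt.coords.loc[snp, "chrom"]
            pos = int(gt.coords.loc[snp, "pos"]) + 1  # VCF is 1-based
            calls = [
                gt_strings[int(round(v))] for v in gt.dosages.loc[snp].to_numpy()
            ]
            fh.write(
                f"{ch}\t{pos}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_dataset(directory) -> SyntheticDataset:
    """Round-trip loader for :func:`write_dataset` output (truth included)."""
    from .io import read_expression, read_genotypes, read_methylation, read_phenotypes

    directory = Path(directory)
    expression = read_expression(
        directory / "expression.tsv", directory / "annotation.tsv"
    )
    methylation = read_methylation(
        directory / "methylation.tsv", directory / "cpg_coords.tsv"
    )
    ref = ReferencePanel(
        pd.read_csv(directory / "reference.tsv", sep="\t", index_col=0, comment="#")
    )
    genotypes = read_genotypes(
        directory / "genotypes.tsv", directory / "snp_coords.tsv"
    )
    pheno = read_phenotypes(directory / "phenotypes.tsv")
    props = CellProportions(
        pd.read_csv(
            directory / "proportions_true.tsv", sep="\t", index_col=0, comment="#"
        )
    )
    with open(directory / "truth.json") as fh:
        truth = json.load(fh)
    return SyntheticDataset(
        expression=expression,
        celltype_expression={},
        methylation=methylation,
        reference_panel=ref,
        genotypes=genotypes,
        proportions_true=props,
        phenotypes=pheno,
        truth=truth,
    )
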