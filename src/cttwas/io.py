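"""Readers, writers and transcript quality control.

All tabular formats are plain TSV with the feature identifier in the first
column and sample identifiers in the header.  Genomic coordinates are held
0-based half-open internally; BED-like annotation files written by this
package use the same convention and say so in their header comment.  Lines
starting with ``#`` are treated as comments in every reader.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("cttwas")

#: Default library-prep depletion targets: ribosomal RNA biotype plus the
#: globin genes removed by the blood RNA-seq prep.
DEPLETION_BIOTYPES = ("rRNA",)
DEPLETION_GENES = ("HBA1", "HBA2", "HBB", "HBD")


class ValidationError(ValueError):
    """A typed container failed one of its invariants."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Transcript x sample abundance with per-transcript annotation.

    ``abundance`` is indexed by transcript id with sample ids as columns.
    ``annotation`` is indexed identically and carries ``gene_id``, ``chrom``,
    ``start``, ``end``, ``strand`` and ``biotype`` columns.  Missing gene
    annotation is encoded as an empty string or NaN in ``gene_id``.
    """

    abundance: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if self.abundance.index.duplicated().any():
            dupes = self.abundance.index[self.abundance.index.duplicated()]
            raise ValidationError(f"duplicate transcript ids: {list(dupes[:5])}")
        if not np.isfinite(self.abundance.to_numpy(dtype=float)).all():
            raise ValidationError("abundance contains non-finite values")
        if not self.annotation.index.equals(self.abundance.index):
            self.annotation = self.annotation.reindex(self.abundance.index)

    @property
    def transcript_ids(self) -> pd.Index:
        return self.abundance.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.abundance.columns

    @property
    def gene_ids(self) -> pd.Series:
        return self.annotation["gene_id"]

    def subset(self, transcript_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.abundance.loc[transcript_ids], self.annotation.loc[transcript_ids]
        )


@dataclass
class MethylationMatrix:
    """CpG x sample beta values in [0, 1] with CpG coordinates."""

    betas: pd.DataFrame
    coords: pd.DataFrame  # index cpg ids; columns chrom, pos

    def __post_init__(self) -> None:
        vals = self.betas.to_numpy(dtype=float)
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            bad = np.argwhere((vals < 0) | (vals > 1))[0]
            raise ValidationError(
                f"beta outside [0, 1] at cpg {self.betas.index[bad[0]]!r}, "
                f"sample {self.betas.columns[bad[1]]!r}"
            )

    @property
    def cpg_ids(self) -> pd.Index:
        return self.betas.index


@dataclass
class GenotypeMatrix:
    """SNP x sample allele dosages in [0, 2]."""

    dosages: pd.DataFrame
    coords: pd.DataFrame  # index snp ids; columns chrom, pos
    maf: pd.Series | None = None

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(dtype=float)
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 2:
            raise ValidationError("dosage outside [0, 2]")
        if self.maf is None:
            freq = self.dosages.mean(axis=1) / 2.0
            self.maf = np.minimum(freq, 1 - freq)

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.index


@dataclass
class PathwayDB:
    """Named gene sets, e.g. parsed from a GMT file."""

    gene_sets: dict[str, set[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for pid, genes in self.gene_sets.items():
            if not genes:
                raise ValidationError(f"pathway {pid!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.gene_sets)

    def __getitem__(self, pid: str) -> set[str]:
        return self.gene_sets[pid]

    def items(self):
        return self.gene_sets.items()


# The sample table is a plain DataFrame indexed by sample id with a binary
# ``case_status`` column; covariate and hormone columns are free-form numeric.


def validate_sample_table(pheno: pd.DataFrame) -> pd.DataFrame:
    if "case_status" not in pheno.columns:
        raise ValidationError("sample table lacks a case_status column")
    cs = pheno["case_status"]
    if cs.isna().any():
        raise ValidationError("case_status contains missing values")
    if not set(np.unique(cs)) <= {0, 1}:
        raise ValidationError("case_status must be coded 0/1")
    return pheno


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    logger.info("read %s: %d rows x %d cols", path, df.shape[0], df.shape[1])
    return df


def write_tsv(df: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t")


def read_expression(path, annotation_path) -> ExpressionMatrix:
    """Read a transcript x sample TSV plus a BED-like annotation TSV."""
    abundance = _read_tsv(path)
    annotation = pd.read_csv(annotation_path, sep="\t", index_col=0, comment="#")
    return ExpressionMatrix(abundance, annotation)


def read_methylation(path, coords_path=None) -> MethylationMatrix:
    betas = _read_tsv(path)
    if coords_path is not None:
        coords = pd.read_csv(coords_path, sep="\t", index_col=0, comment="#")
    else:
        coords = pd.DataFrame(index=betas.index, columns=["chrom", "pos"])
    return MethylationMatrix(betas, coords)


def read_genotypes(path, coords_path=None) -> GenotypeMatrix:
    dosages = _read_tsv(path)
    if coords_path is not None:
        coords = pd.read_csv(coords_path, sep="\t", index_col=0, comment="#")
    else:
        coords = pd.DataFrame(index=dosages.index, columns=["chrom", "pos"])
    return GenotypeMatrix(dosages, coords)


def read_phenotypes(path) -> pd.DataFrame:
    return validate_sample_table(_read_tsv(path))


def read_vcf(path) -> GenotypeMatrix:
    """Read genotype dosages from a VCF (GT field; allele count per sample).

    Missing genotypes are imputed with the per-SNP sample mean and logged.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, rows, chroms, poss = [], [], [], []
    n_imputed = 0
    for var in vcf:
        # cyvcf2 gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        codes = var.gt_types.astype(float)
        dosage = np.select(
            [codes == 0, codes == 1, codes == 3], [0.0, 1.0, 2.0], default=np.nan
        )
        if np.isnan(dosage).any():
            n_imputed += int(np.isnan(dosage).sum())
            dosage = np.where(np.isnan(dosage), np.nanmean(dosage), dosage)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        rows.append(dosage)
        chroms.append(var.CHROM)
        poss.append(var.POS - 1)  # VCF is 1-based
    if n_imputed:
        logger.info("VCF read: mean-imputed %d missing genotypes", n_imputed)
    dosages = pd.DataFrame(rows, index=ids, columns=samples)
    coords = pd.DataFrame({"chrom": chroms, "pos": poss}, index=ids)
    return GenotypeMatrix(dosages, coords)


def read_gmt(path, source: str | None = None) -> PathwayDB:
    """Parse a Broad-dialect GMT file: name, description, tab-separated genes."""
    gene_sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "GMT requires name, description and >=1 gene"
                )
            name = fields[0]
            if name in gene_sets:
                raise ValueError(f"{path}: duplicate pathway id {name!r}")
            gene_sets[name] = {g for g in fields[2:] if g}
    if not gene_sets:
        warnings.warn(f"{path}: empty GMT file", stacklevel=2)
        logger.warning("%s: empty GMT file", path)
    return PathwayDB(gene_sets, source=source or str(path))


# ---------------------------------------------------------------------------
# Transcript QC
# ---------------------------------------------------------------------------


def transcript_qc_filter(
    expr: ExpressionMatrix,
    depletion_biotypes=DEPLETION_BIOTYPES,
    depletion_genes=DEPLETION_GENES,
    min_presence_frac: float = 0.01,
    tpm_low: float = 1.0,
    tpm_high: float = 20_000.0,
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Apply transcript-level quality filters, sequentially.

    Rules fire in order; a transcript is counted against the first rule that
    removes it:

    1. library-prep depletion targets (biotype in ``depletion_biotypes`` or
       gene in ``depletion_genes``)
    2. unannotated (missing/empty gene id)
    3. present (abundance > 0) in fewer than ``min_presence_frac`` of samples
       (strict ``<``)
    4. mean abundance below ``tpm_low``
    5. mean abundance above ``tpm_high``

    Returns the filtered matrix and a report of removal counts per rule.
    """
    ann = expr.annotation
    ab = expr.abundance
    n_samples = ab.shape[1]

    gene = ann["gene_id"].fillna("").astype(str)
    biotype = ann.get("biotype", pd.Series("", index=ann.index)).fillna("").astype(str)

    removed = pd.Series("", index=ab.index, dtype=object)

    is_depletion = biotype.isin(depletion_biotypes) | gene.isin(depletion_genes)
    removed[is_depletion & (removed == "")] = "depletion_target"

    is_unannotated = gene == ""
    removed[is_unannotated & (removed == "")] = "unannotated"

    presence_frac = (ab > 0).sum(axis=1) / n_samples
    removed[(presence_frac < min_presence_frac) & (removed == "")] = "low_presence"

    mean_ab = ab.mean(axis=1)
    removed[(mean_ab < tpm_low) & (removed == "")] = "low_expression"
    removed[(mean_ab > tpm_high) & (removed == "")] = "high_expression"

    report = {
        rule: int((removed == rule).sum())
        for rule in (
            "depletion_target",
            "unannotated",
            "low_presence",
            "low_expression",
            "high_expression",
        )
    }
    keep = removed == ""
    report["input"] = int(len(ab))
    report["retained"] = int(keep.sum())
    if report["retained"] == 0:
        warnings.warn("transcript QC removed every transcript", stacklevel=2)
    logger.info("transcript QC: %s", report)
    return expr.subset(ab.index[keep]), report
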