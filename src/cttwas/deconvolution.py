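"""Reference-based cell-type deconvolution from bulk DNA methylation.

Bulk beta values at reference CpGs are modelled as a convex mixture of the
per-cell-type mean methylation profiles.  Proportions are recovered per
sample by non-negative least squares followed by renormalization onto the
simplex; an equality-constrained quadratic solve is available behind a flag
for ill-conditioned panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from .io import MethylationMatrix, ValidationError, validate_sample_table


@dataclass
class ReferencePanel:
    """Per-cell-type mean beta profiles over a set of reference CpGs."""

    betas: pd.DataFrame  # index cpg ids; one column per cell type

    def __post_init__(self) -> None:
        if self.betas.shape[1] < 2:
            raise ValidationError("reference panel needs >= 2 cell types")
        if self.betas.index.duplicated().any():
            raise ValidationError("reference panel has duplicate CpGs")
        if self.betas.columns.duplicated().any():
            raise ValidationError("reference panel cell-type labels not unique")

    @property
    def cpg_ids(self) -> pd.Index:
        return self.betas.index

    @property
    def celltypes(self) -> pd.Index:
        return self.betas.columns


@dataclass
class CellProportions:
    """Sample x cell-type proportion matrix on the simplex."""

    values: pd.DataFrame  # index sample ids; columns cell types

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if (arr < -1e-12).any():
            raise ValidationError("negative cell proportion")
        rowsums = arr.sum(axis=1)
        if np.abs(rowsums - 1).max() > 1e-8:
            raise ValidationError("cell proportions must sum to 1 per sample")

    @property
    def celltypes(self) -> pd.Index:
        return self.values.columns

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index


class InsufficientReferenceError(ValueError):
    """Too few CpGs shared between the bulk data and the reference panel."""


def estimate_proportions(
    meth: MethylationMatrix,
    ref: ReferencePanel,
    method: str = "nnls",
) -> CellProportions:
    """Estimate cell-type proportions from bulk methylation.

    Per sample, solves ``min ||m - R w||^2`` subject to ``w >= 0`` and, for
    ``method='qp'``, ``sum w = 1``.  The default ``'nnls'`` method drops the
    equality constraint and renormalizes the non-negative solution onto the
    simplex, which coincides with the constrained solution on
    well-conditioned references.
    """
    shared = ref.cpg_ids.intersection(meth.cpg_ids)
    k = ref.betas.shape[1]
    if len(shared) < k:
        raise InsufficientReferenceError(
            f"only {len(shared)} CpGs shared between bulk data and reference; "
            f"need at least {k}"
        )
    R = ref.betas.loc[shared].to_numpy(dtype=float)
    M = meth.betas.loc[shared].to_numpy(dtype=float)

    out = np.empty((M.shape[1], k))
    for j in range(M.shape[1]):
        if method == "nnls":
            w, _ = scipy.optimize.nnls(R, M[:, j])
        elif method == "qp":
            res = scipy.optimize.lsq_linear(
                np.vstack([R, np.full((1, k), 1e3)]),
                np.append(M[:, j], 1e3),
                bounds=(0, np.inf),
            )
            w = res.x
        else:
            raise ValueError(f"unknown method {method!r}")
        total = w.sum()
        out[j] = w / total if total > 0 else np.full(k, 1.0 / k)
    values = pd.DataFrame(out, index=meth.betas.columns, columns=ref.celltypes)
    return CellProportions(values)


def compare_proportions(
    P: CellProportions,
    pheno: pd.DataFrame,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cell-type OLS of proportion on case status (+ covariates).

    Returns a DataFrame indexed by cell type with columns ``beta``, ``se``,
    ``p`` and ``degenerate`` (True when the proportion column is constant and
    no inference is possible).
    """
    validate_sample_table(pheno)
    pheno = pheno.loc[P.sample_ids]
    X = pd.DataFrame({"case_status": pheno["case_status"].astype(float)})
    for c in covariates or []:
        X[c] = pheno[c].astype(float)
    X = sm.add_constant(X)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0)
        pairs = corr.stack().sort_values(ascending=False).head(1)
        raise ValidationError(f"rank-deficient design; most collinear: {pairs.index[0]}")

    rows = []
    for ct in P.celltypes:
        y = P.values[ct].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            rows.append({"beta": 0.0, "se": np.nan, "p": np.nan, "degenerate": True})
            continue
        fit = sm.OLS(y, X).fit()
        rows.append(
            {
                "beta": fit.params["case_status"],
                "se": fit.bse["case_status"],
                "p": fit.pvalues["case_status"],
                "degenerate": False,
            }
        )
    return pd.DataFrame(rows, index=P.celltypes)


def validate_proportions(
    P_est: CellProportions, P_truth: CellProportions | pd.DataFrame
) -> pd.DataFrame:
    """Pearson and Spearman correlation of estimates against truth or counts."""
    truth = P_truth.values if isinstance(P_truth, CellProportions) else P_truth
    shared = P_est.sample_ids.intersection(truth.index)
    if len(shared) < 3:
        raise ValidationError(f"only {len(shared)} shared samples; need >= 3")
    rows = []
    for ct in P_est.celltypes:
        a = P_est.values.loc[shared, ct]
        b = truth.loc[shared, ct]
        rows.append(
            {
                "pearson": scipy.stats.pearsonr(a, b)[0],
                "spearman": scipy.stats.spearmanr(a, b)[0],
            }
        )
    return pd.DataFrame(rows, index=P_est.celltypes)
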