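"""Bulk and cell-type-specific transcriptome-wide association.

The cell-type model regresses bulk abundance, with no intercept, on the cell
proportions and their interactions with case status::

    Y_bulk = sum_c m_c P_c + sum_c m_c^case (case x P_c) + covariates + E

Because the proportions sum to one the model needs no constant.  The
interaction coefficient ``m_c^case`` estimates the case-control difference
of the cell-type-c mean and is the per-cell-type test statistic.  All fits
are ordinary least squares, vectorized across transcripts, with
t-distribution inference on the residual degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .deconvolution import CellProportions
from .io import ExpressionMatrix, ValidationError, validate_sample_table


@dataclass
class TwasModelSpec:
    """Model configuration shared by the bulk and cell-type TWAS."""

    covariates: list[str] = field(default_factory=list)
    include_proportions_in_bulk: bool = True
    fdr_threshold: float = 0.1
    fdr_method: str = "bh"  # or "storey"

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold < 1:
            raise ValidationError("fdr_threshold must be in (0, 1)")


# ---------------------------------------------------------------------------
# Vectorized OLS machinery
# ---------------------------------------------------------------------------


def _ols_many(X: np.ndarray, Y: np.ndarray):
    """OLS of every column of ``Y`` (n x T) on ``X`` (n x k).

    Returns (beta: k x T, se: k x T, t: k x T, p: k x T, dof).
    """
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        raise ValidationError(
            f"rank-deficient design matrix (rank {rank} < {k} columns)"
        )
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2 * scipy.stats.t.sf(np.abs(t), dof)
    return beta, se, t, p, dof


def _align(expr: ExpressionMatrix, pheno: pd.DataFrame, P: CellProportions | None):
    validate_sample_table(pheno)
    samples = expr.sample_ids
    pheno = pheno.loc[samples]
    if P is not None:
        P = CellProportions(P.values.loc[samples])
    return pheno, P


def _covariate_block(pheno: pd.DataFrame, names: list[str]) -> np.ndarray:
    if not names:
        return np.empty((len(pheno), 0))
    return pheno[list(names)].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Bulk TWAS
# ---------------------------------------------------------------------------


def fit_bulk_twas(
    expr: ExpressionMatrix,
    pheno: pd.DataFrame,
    P: CellProportions | None,
    spec: TwasModelSpec | None = None,
) -> pd.DataFrame:
    """Per-transcript OLS of abundance on case status, covariates and proportions.

    One proportion column is dropped to avoid collinearity with the
    intercept.  Returns a DataFrame with one row per transcript: ``gene``,
    ``context`` (``"bulk"``), ``effect``, ``se``, ``t``, ``p``, ``q``.
    """
    spec = spec or TwasModelSpec()
    pheno, P = _align(expr, pheno, P)
    n = len(pheno)
    case = pheno["case_status"].to_numpy(dtype=float)
    blocks = [np.ones((n, 1)), case[:, None], _covariate_block(pheno, spec.covariates)]
    if P is not None and spec.include_proportions_in_bulk:
        blocks.append(P.values.to_numpy(dtype=float)[:, :-1])  # drop last column
    X = np.hstack(blocks)
    Y = expr.abundance.to_numpy(dtype=float).T  # n x T
    beta, se, t, p, _ = _ols_many(X, Y)
    out = pd.DataFrame(
        {
            "gene": expr.gene_ids.to_numpy(),
            "context": "bulk",
            "effect": beta[1],
            "se": se[1],
            "t": t[1],
            "p": p[1],
        },
        index=expr.transcript_ids,
    )
    out["q"] = fdr_qvalues(out["p"].to_numpy(), method=spec.fdr_method)
    return out


# ---------------------------------------------------------------------------
# Cell-type TWAS
# ---------------------------------------------------------------------------


def fit_celltype_twas(
    expr: ExpressionMatrix,
    pheno: pd.DataFrame,
    P: CellProportions,
    spec: TwasModelSpec | None = None,
) -> pd.DataFrame:
    """No-intercept interaction TWAS; one row per transcript x cell type.

    Cell types whose interaction column is (nearly) constant — e.g. a cell
    type absent from all cases — are flagged untestable with ``p = NaN``.
    Q-values are computed within each cell type separately.
    """
    spec = spec or TwasModelSpec()
    pheno, P = _align(expr, pheno, P)
    n = len(pheno)
    C = len(P.celltypes)
    cov = _covariate_block(pheno, spec.covariates)
    if n <= 2 * C + cov.shape[1]:
        raise ValidationError(
            f"need more than {2 * C + cov.shape[1]} samples for {C} cell types "
            f"and {cov.shape[1]} covariates; got {n}"
        )
    case = pheno["case_status"].to_numpy(dtype=float)
    Pm = P.values.to_numpy(dtype=float)
    inter = case[:, None] * Pm

    # near-constant interaction columns are untestable, not errors
    testable = inter.std(axis=0) > 1e-10
    X = np.hstack([Pm, inter[:, testable], cov])
    Y = expr.abundance.to_numpy(dtype=float).T
    beta, se, t, p, _ = _ols_many(X, Y)

    frames = []
    j = 0
    for c, ct in enumerate(P.celltypes):
        if testable[c]:
            row = C + j
            eff, s_, t_, p_ = beta[row], se[row], t[row], p[row]
            j += 1
        else:
            nanvec = np.full(Y.shape[1], np.nan)
            eff, s_, t_, p_ = nanvec, nanvec, nanvec, nanvec
        df = pd.DataFrame(
            {
                "gene": expr.gene_ids.to_numpy(),
                "context": ct,
                "effect": eff,
                "se": s_,
                "t": t_,
                "p": p_,
            },
            index=expr.transcript_ids,
        )
        df["q"] = fdr_qvalues(df["p"].to_numpy(), method=spec.fdr_method)
        frames.append(df)
    return pd.concat(frames)


# ---------------------------------------------------------------------------
# Calibration statistics
# ---------------------------------------------------------------------------

_CHI2_MEDIAN = scipy.stats.chi2.ppf(0.5, 1)  # 0.45493...


def compute_lambda(pvalues) -> float:
    """Genomic inflation factor: median association chi2 over the null median."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) < 100:
        raise ValidationError(f"need >= 100 finite p-values, got {len(p)}")
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    chi2 = scipy.stats.chi2.isf(p, 1)
    return float(np.median(chi2) / _CHI2_MEDIAN)


def fdr_qvalues(pvalues, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN p-values propagate NaN.

    ``method='storey'`` scales the BH values by a pi0 estimate from the
    smoothed lambda-spectrum of the p-value distribution.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum() == 0:
        return q
    _, q_ok, _, _ = multipletests(p[ok], method="fdr_bh")
    if method == "storey":
        q_ok = np.minimum(q_ok * _storey_pi0(p[ok]), 1.0)
    elif method != "bh":
        raise ValueError(f"unknown FDR method {method!r}")
    q[ok] = q_ok
    return q


def _storey_pi0(p: np.ndarray) -> float:
    """Smoother-based estimate of the null proportion pi0."""
    lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_raw = np.array([(p > lam).mean() / (1 - lam) for lam in lambdas])
    coef = np.polynomial.polynomial.polyfit(lambdas, pi0_raw, 3)
    pi0 = float(np.polynomial.polynomial.polyval(lambdas[-1], coef))
    return min(max(pi0, 1e-3), 1.0)


def permutation_calibration(
    expr: ExpressionMatrix,
    pheno: pd.DataFrame,
    P: CellProportions,
    spec: TwasModelSpec | None = None,
    n_perm: int = 10,
    seed: int = 0,
    context: str = "celltype",
) -> dict:
    """TWAS under permuted case labels; returns per-permutation lambdas.

    Only the case labels are shuffled; covariates and proportions stay
    attached to their samples, so the permuted runs estimate the empirical
    null of the case terms.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    fit = fit_celltype_twas if context == "celltype" else fit_bulk_twas
    lambdas = []
    for _ in range(n_perm):
        shuffled = pheno.copy()
        shuffled["case_status"] = rng.permutation(
            pheno["case_status"].to_numpy()
        )
        res = fit(expr, shuffled, P, spec)
        lambdas.append(compute_lambda(res["p"].dropna()))
    return {
        "lambdas": lambdas,
        "mean_lambda": float(np.mean(lambdas)),
        "seed": seed,
        "n_perm": n_perm,
        "context": context,
    }
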