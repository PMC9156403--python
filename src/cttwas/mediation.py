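"""Quasi-Bayesian mediation scans for regulators of case-associated transcripts.

A marker (SNP dosage, CpG beta, or hormone level) is tested as a regulator
acting on case status *through* a transcript: the mediator model is linear
(``mediator ~ marker``, path ``a``), the outcome model logistic
(``case ~ mediator + marker``, paths ``b`` and direct ``c'``); the null
hypothesis is no indirect effect, ``H0: a x b = 0``.  The average causal
mediation effect (ACME) and its Monte-Carlo p-value are approximated by
drawing parameter vectors from each fitted model's asymptotic normal
distribution, simulating potential mediator values under the treat/control
marker contrast, and averaging potential-outcome differences over the
observed sample.  When no draw crosses zero the draw count escalates through
a 10-fold schedule (1,000 up to 1,000,000) until the p-value is resolvable.

For a SNP the marker is an instrument: the code only ever regresses the
mediator and the outcome on the marker, never the reverse, so the causal
direction cannot be flipped by the scan.

Covariates must be regressed out of marker and mediator values before the
scan (the pipeline residualizes the QC-passed bulk abundance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .io import validate_sample_table
from .twas import fdr_qvalues

DEFAULT_SIMS_SCHEDULE = (1_000, 10_000, 100_000, 1_000_000)


@dataclass
class MediationSpec:
    """Settings for a regulation scan."""

    marker_type: str = "snp"  # snp | cpg | hormone
    cis_window: int = 10_000
    preselect_alpha: float = 0.05
    sims_schedule: tuple[int, ...] = DEFAULT_SIMS_SCHEDULE
    treat_value: float = 1.0
    control_value: float = 0.0
    q_threshold: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.preselect_alpha < 1:
            raise ValueError("preselect_alpha must be in (0, 1)")
        for lo, hi in zip(self.sims_schedule, self.sims_schedule[1:]):
            if hi != lo * 10:
                raise ValueError("sims_schedule must increase 10-fold per step")


# ---------------------------------------------------------------------------
# Pre-selection
# ---------------------------------------------------------------------------


def _case_assoc_p(values: np.ndarray, case: np.ndarray) -> float:
    """Two-sided p for marker ~ case status (OLS slope == two-sample t-test)."""
    a, b = values[case == 1], values[case == 0]
    if len(a) < 2 or len(b) < 2 or values.std() == 0:
        return 1.0
    return float(scipy.stats.ttest_ind(a, b, equal_var=True).pvalue)


def preselect_markers(
    marker_values: pd.DataFrame,
    marker_coords: pd.DataFrame | None,
    pheno: pd.DataFrame,
    gene_annotations: pd.DataFrame,
    spec: MediationSpec,
) -> pd.DataFrame:
    """Select (marker, gene) candidate pairs for mediation testing.

    A marker passes if its case-status association is nominally significant
    (``p < preselect_alpha``) and — for SNP/CpG markers — it lies within the
    gene body extended by ``cis_window`` on both sides (strand-agnostic).
    Hormones pass on the association criterion alone and are paired with
    every gene in ``gene_annotations``.

    ``marker_values`` is markers x samples; ``gene_annotations`` holds the
    genes of interest (typically genes with a differentially expressed
    transcript) with ``gene_id``, ``chrom``, ``start``, ``end`` columns.
    """
    validate_sample_table(pheno)
    case = pheno.loc[marker_values.columns, "case_status"].to_numpy()
    rows = []
    for mid in marker_values.index:
        vals = marker_values.loc[mid].to_numpy(dtype=float)
        p = _case_assoc_p(vals, case)
        if p >= spec.preselect_alpha:
            continue
        if spec.marker_type == "hormone":
            for gid in gene_annotations["gene_id"]:
                rows.append({"marker": mid, "gene": gid, "assoc_p": p})
            continue
        if marker_coords is None:
            raise ValueError(f"{spec.marker_type} markers require coordinates")
        chrom = marker_coords.loc[mid, "chrom"]
        pos = int(marker_coords.loc[mid, "pos"])
        g = gene_annotations
        hit = g[
            (g["chrom"] == chrom)
            & (pos >= g["start"] - spec.cis_window)
            & (pos <= g["end"] + spec.cis_window)
        ]
        for gid in hit["gene_id"]:
            rows.append({"marker": mid, "gene": gid, "assoc_p": p})
    return pd.DataFrame(rows, columns=["marker", "gene", "assoc_p"])


# ---------------------------------------------------------------------------
# Quasi-Bayesian mediation test
# ---------------------------------------------------------------------------


def _acme_draws(
    rng,
    med_mean,
    med_cov,
    med_sigma,
    out_mean,
    out_cov,
    marker: np.ndarray,
    treat: float,
    control: float,
    n_sims: int,
) -> np.ndarray:
    """Simulate per-draw ACME values averaged over the two treatment arms.

    Per draw: sample coefficient vectors from each model's asymptotic normal,
    simulate n potential mediator values under the treat and control marker
    settings (independent error draws, the fitted residual SD), push them
    through the outcome model at both marker arms, and average the
    potential-outcome differences.  Heavy arrays are float32: the averaging
    over draws and samples dwarfs single-precision rounding.
    """
    from scipy.special import expit

    n = len(marker)
    chunk = max(1, min(n_sims, 5_000_000 // n))
    acme = np.empty(n_sims)
    done = 0
    while done < n_sims:
        b = min(chunk, n_sims - done)
        mp = rng.multivariate_normal(med_mean, med_cov, size=b)  # a0, a1
        op = rng.multivariate_normal(out_mean, out_cov, size=b)  # g0, gm, gt
        g0 = op[:, [0]].astype(np.float32)
        gm = op[:, [1]].astype(np.float32)
        gt = op[:, 2].astype(np.float32)
        # potential mediators under treat/control (independent error draws)
        e1 = rng.standard_normal((b, n), dtype=np.float32)
        e0 = rng.standard_normal((b, n), dtype=np.float32)
        sig = np.float32(med_sigma)
        m1 = (mp[:, [0]] + mp[:, [1]] * treat).astype(np.float32) + sig * e1
        m0 = (mp[:, [0]] + mp[:, [1]] * control).astype(np.float32) + sig * e0
        u1 = g0 + gm * m1  # linear predictor minus the marker term
        u0 = g0 + gm * m0
        delta = np.zeros(b, dtype=np.float64)
        for arm_t in (treat, control):
            shift = (gt * np.float32(arm_t))[:, None]
            delta += (expit(u1 + shift) - expit(u0 + shift)).mean(
                axis=1, dtype=np.float64
            )
        acme[done : done + b] = delta / 2.0
        done += b
    return acme


def mediation_test(
    marker: np.ndarray,
    mediator: np.ndarray,
    outcome: np.ndarray,
    spec: MediationSpec | None = None,
    seed: int | None = None,
) -> dict:
    """Quasi-Bayesian test of the indirect (mediated) effect of one marker.

    Inputs are aligned 1-D arrays: marker values (covariate-residualized),
    mediator values (residualized transcript abundance), and the binary
    outcome.  Returns a dict with paths ``a``, ``b``, ``c_prime``, the
    ``acme`` point estimate (mean of draws), the Monte-Carlo ``p``
    (``2 * min(frac <= 0, frac >= 0)``), ``n_sims`` used, and a
    ``converged`` flag (False on logistic separation; estimates are NaN).
    """
    spec = spec or MediationSpec()
    marker = np.asarray(marker, dtype=float)
    mediator = np.asarray(mediator, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if mediator.std() == 0:
        raise ValueError("mediator is constant")

    na = dict(a=np.nan, b=np.nan, c_prime=np.nan, acme=np.nan, p=np.nan,
              n_sims=0, converged=False)

    Xm = sm.add_constant(marker)
    med_fit = sm.OLS(mediator, Xm).fit()
    Xo = sm.add_constant(np.column_stack([mediator, marker]))
    try:
        with np.errstate(all="ignore"):
            out_fit = sm.Logit(outcome, Xo).fit(disp=0, maxiter=100)
        if not np.isfinite(out_fit.bse).all() or np.abs(out_fit.params).max() > 50:
            return na
    except Exception:
        return na

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_sims = 0
    for n_sims in spec.sims_schedule:
        acme = _acme_draws(
            rng,
            med_fit.params,
            med_fit.cov_params(),
            np.sqrt(med_fit.scale),
            out_fit.params,
            np.asarray(out_fit.cov_params()),
            marker,
            spec.treat_value,
            spec.control_value,
            n_sims,
        )
        frac_le = (acme <= 0).mean()
        frac_ge = (acme >= 0).mean()
        p = 2.0 * min(frac_le, frac_ge)
        if p > 0:
            break
    return {
        "a": float(med_fit.params[1]),
        "b": float(out_fit.params[1]),
        "c_prime": float(out_fit.params[2]),
        "acme": float(acme.mean()),
        "p": min(float(p), 1.0),
        "n_sims": int(n_sims),
        "converged": True,
    }


def run_regulation_scan(
    marker_values: pd.DataFrame,
    marker_coords: pd.DataFrame | None,
    expr_residuals: pd.DataFrame,
    transcript_annotations: pd.DataFrame,
    pheno: pd.DataFrame,
    de_genes: list[str],
    spec: MediationSpec | None = None,
) -> pd.DataFrame:
    """Mediation scan over all candidate (marker, transcript) pairs.

    ``expr_residuals`` is transcripts x samples covariate-residualized
    abundance; ``transcript_annotations`` carries ``gene_id`` plus
    coordinates per transcript.  For every gene in ``de_genes`` (genes with a
    differentially expressed transcript), all of its transcripts with
    expression data are tested against every pre-selected cis marker.
    Benjamini-Hochberg q-values are computed over the whole scan.
    """
    spec = spec or MediationSpec()
    ann = transcript_annotations[transcript_annotations["gene_id"].isin(de_genes)]
    gene_ann = (
        ann.groupby("gene_id")
        .agg(chrom=("chrom", "first"), start=("start", "min"), end=("end", "max"))
        .reset_index()
    )
    candidates = preselect_markers(marker_values, marker_coords, pheno, gene_ann, spec)
    if candidates.empty:
        return pd.DataFrame(
            columns=["marker", "transcript", "gene", "a", "b", "c_prime",
                     "acme", "p", "n_sims", "q", "converged"]
        )
    outcome = pheno.loc[expr_residuals.columns, "case_status"].to_numpy(dtype=float)
    gene_to_tx = ann.reset_index().groupby("gene_id")[ann.index.name or "index"]
    tx_by_gene = {g: list(v) for g, v in gene_to_tx}

    rng = np.random.default_rng(spec.seed)
    rows = []
    for _, cand in candidates.iterrows():
        mvals = marker_values.loc[cand["marker"], expr_residuals.columns].to_numpy(
            dtype=float
        )
        for tx in tx_by_gene.get(cand["gene"], []):
            mediator = expr_residuals.loc[tx].to_numpy(dtype=float)
            res = mediation_test(
                mvals, mediator, outcome, spec, seed=int(rng.integers(2**31 - 1))
            )
            rows.append({"marker": cand["marker"], "transcript": tx,
                         "gene": cand["gene"], **res})
    out = pd.DataFrame(rows)
    out["q"] = fdr_qvalues(out["p"].to_numpy())
    return out
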