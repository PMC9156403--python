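"""Cross-study concordance: top-fraction overlap, sign tests, 2x2 enrichment.

The sign test asks whether genes found by two independent studies agree in
effect direction more often than the 50% expected under independence; the
p-value is the exact one-sided upper binomial tail.  The 2x2 enrichment
crosses membership in a query gene set against a target set over a common
universe, with the odds ratio and Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats


@dataclass
class SignTestResult:
    n: int
    k: int
    p: float


@dataclass
class TwoByTwoEnrichment:
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    or_infinite: bool
    p: float


def _best_p_per_gene(results: pd.DataFrame) -> pd.DataFrame:
    """Summarize transcript-level results per gene: minimum p, its effect sign."""
    df = results.dropna(subset=["p"]).sort_values("p", kind="mergesort")
    first = df.groupby("gene", sort=False).head(1)
    return pd.DataFrame(
        {"p": first["p"].to_numpy(), "sign": np.sign(first["effect"]).to_numpy()},
        index=first["gene"],
    )


def top_fraction_overlap(
    results_a: pd.DataFrame, results_b: pd.DataFrame, frac: float = 0.05
) -> pd.DataFrame:
    """Intersect the top fraction of two result sets, ranked by p per gene.

    Both inputs need ``gene``, ``p`` and ``effect`` columns (transcript-level
    results are collapsed to the best transcript per gene).  Returns one row
    per overlapping gene with the effect sign in each study and whether the
    signs agree.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    ga = _best_p_per_gene(results_a)
    gb = _best_p_per_gene(results_b)
    n_a = max(1, int(np.ceil(frac * len(ga))))
    n_b = max(1, int(np.ceil(frac * len(gb))))
    top_a = ga.nsmallest(n_a, "p")
    top_b = gb.nsmallest(n_b, "p")
    shared = top_a.index.intersection(top_b.index)
    return pd.DataFrame(
        {
            "sign_a": top_a.loc[shared, "sign"],
            "sign_b": top_b.loc[shared, "sign"],
            "concordant": (
                top_a.loc[shared, "sign"] == top_b.loc[shared, "sign"]
            ),
        },
        index=shared,
    )


def sign_test(n: int, k: int) -> SignTestResult:
    """Exact one-sided binomial test of directional concordance.

    ``n`` overlapping genes, ``k`` sharing direction; p = P(X >= k) for
    X ~ Binomial(n, 1/2).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    p = float(scipy.stats.binom.sf(k - 1, n, 0.5))
    return SignTestResult(n=n, k=k, p=min(p, 1.0))


def gene_set_enrichment_2x2(
    query: set[str], target: set[str], universe: set[str]
) -> TwoByTwoEnrichment:
    """Fisher 2x2 enrichment of a query gene set against a target set."""
    if not universe:
        raise ValueError("universe is empty")
    query, target, universe = set(query), set(target), set(universe)
    if not query <= universe or not target <= universe:
        raise ValueError("query and target must be subsets of the universe")
    a = len(query & target)
    b = len(query - target)
    c = len(target - query)
    d = len(universe) - a - b - c
    or_inf = b * c == 0 and a * d > 0
    odds = np.inf if or_inf else (a * d / (b * c) if b * c else np.nan)
    _, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return TwoByTwoEnrichment(
        a=a, b=b, c=c, d=d,
        odds_ratio=float(odds), or_infinite=bool(or_inf), p=float(p),
    )
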