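"""Gene-set enrichment by circular permutation of the marker vector.

Markers (here: transcripts, ordered along the genome) carry a binary
"top finding" flag.  A gene is a top gene when at least one of its markers
is top; each gene counts once.  Per pathway, association between top-gene
status and pathway membership over the gene universe is summarized by
Cramér's V of the 2x2 table.  The null distribution rotates the top-marker
flags around the genome-wide circle of marker positions, which preserves the
number of top markers and their local correlation structure, and hence
accounts for gene size (genes with more markers are more often hit in the
rotations too).  Family-wise error is controlled with the Westfall-Young
single-step max-V adjustment over the same rotations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import PathwayDB


@dataclass
class MarkerGeneMap:
    """Genomically ordered markers and their marker -> gene multimap."""

    markers: pd.DataFrame  # ordered by (chrom, pos); index marker ids
    mapping: dict[str, set[str]]  # marker id -> gene ids (possibly empty)
    universe: list[str]  # genes receiving >= 1 marker

    @property
    def n_markers(self) -> int:
        return len(self.markers)


def map_markers_to_genes(
    marker_coords: pd.DataFrame,
    gene_annotations: pd.DataFrame,
    upstream_flank: int = 10_000,
) -> MarkerGeneMap:
    """Map point markers to genes extended by an upstream (promoter) flank.

    ``marker_coords`` needs ``chrom`` and ``pos`` columns; gene annotations
    need ``gene_id``, ``chrom``, ``start``, ``end``, ``strand``.  The gene
    interval is extended by ``upstream_flank`` on the strand-appropriate
    side; a marker maps to every gene whose extended interval contains it.
    Markers mapping to no gene are retained — they still occupy positions on
    the permutation circle.
    """
    bad = set(gene_annotations["strand"].unique()) - {"+", "-"}
    if bad:
        raise ValueError(f"unknown strand symbol(s): {sorted(bad)}")

    ordered = marker_coords.sort_values(["chrom", "pos"], kind="mergesort")
    genes = gene_annotations.copy()
    on_plus = genes["strand"] == "+"
    genes["ext_start"] = np.where(on_plus, genes["start"] - upstream_flank, genes["start"])
    genes["ext_end"] = np.where(on_plus, genes["end"], genes["end"] + upstream_flank)

    mapping: dict[str, set[str]] = {}
    hit_genes: list[str] = []
    seen: set[str] = set()
    for chrom, sub in ordered.groupby("chrom", sort=False):
        g = genes[genes["chrom"] == chrom]
        starts = g["ext_start"].to_numpy()
        ends = g["ext_end"].to_numpy()
        gids = g["gene_id"].to_numpy()
        pos = sub["pos"].to_numpy()
        # half-open [ext_start, ext_end)
        contains = (pos[:, None] >= starts[None, :]) & (pos[:, None] < ends[None, :])
        for i, mid in enumerate(sub.index):
            hits = gids[contains[i]]
            mapping[mid] = set(hits)
            for gid in hits:
                if gid not in seen:
                    seen.add(gid)
                    hit_genes.append(gid)
    return MarkerGeneMap(markers=ordered, mapping=mapping, universe=hit_genes)


def cramers_v_2x2(a: float, b: float, c: float, d: float) -> float:
    """Cramér's V (phi) of a 2x2 table; 0 when any margin is empty."""
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d < 1:
        raise ValueError("table must contain at least one observation")
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return abs(a * d - b * c) / np.sqrt(denom)


def _v_from_counts(overlap, n_top, set_sizes, n_universe):
    """Vectorized Cramér's V for 2x2 tables sharing the gene universe.

    ``overlap`` (..., n_pathways): top genes inside each pathway; ``n_top``
    (...,): total top genes; ``set_sizes`` (n_pathways,): pathway sizes.
    """
    a = overlap
    k = np.asarray(n_top, dtype=float)[..., None]
    s = np.asarray(set_sizes, dtype=float)
    N = float(n_universe)
    denom = k * (N - k) * s * (N - s)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.abs(a * N - k * s) / np.sqrt(denom)
    return np.where(denom > 0, v, 0.0)


def circular_permutation_enrichment(
    twas_results: pd.DataFrame,
    marker_map: MarkerGeneMap,
    pathways: PathwayDB,
    top_rule=None,
    n_perm: int = 10_000,
    min_genes: int = 3,
    seed: int = 0,
    fwer_method: str = "westfall-young",
    per_chromosome: bool = False,
) -> pd.DataFrame:
    """Circular-permutation pathway enrichment for one TWAS context.

    ``twas_results`` is indexed by marker (transcript) id with ``p`` and
    ``q`` columns; ``top_rule`` is a callable mapping the results frame to a
    boolean Series (default: ``q < 0.1``).  Rotations use one genome-wide
    circle over the genomically ordered markers by default; set
    ``per_chromosome`` to rotate each chromosome independently.

    Returns one row per tested pathway: ``n_genes``, ``n_overlap``, ``v``,
    ``p`` (floored at ``1/n_perm``), ``p_adj``, ``significant``.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very low for permutation p-values",
                      stacklevel=2)
    missing = [m for m in twas_results.index if m not in marker_map.mapping]
    if missing:
        raise ValueError(
            f"{len(missing)} markers in results are absent from the marker map "
            f"(first: {missing[0]!r})"
        )
    rng = np.random.default_rng(seed)

    order = [m for m in marker_map.markers.index if m in twas_results.index]
    res = twas_results.loc[order]
    if top_rule is None:
        top = (res["q"] < 0.1).to_numpy()
    else:
        top = np.asarray(top_rule(res), dtype=bool)
    M = len(order)

    universe = marker_map.universe
    gene_idx = {g: i for i, g in enumerate(universe)}
    N = len(universe)

    # marker x gene incidence (integer: matmul must count, not OR)
    G = np.zeros((M, N), dtype=np.int32)
    for i, mid in enumerate(order):
        for g in marker_map.mapping[mid]:
            G[i, gene_idx[g]] = 1

    # pathway incidence over the universe
    kept, set_cols = [], []
    for pid, genes in pathways.items():
        in_univ = [gene_idx[g] for g in genes if g in gene_idx]
        if len(genes & set(gene_idx)) == 0 and len(genes) > 0 and not in_univ:
            warnings.warn(f"pathway {pid!r} disjoint from gene universe; skipped",
                          stacklevel=2)
            continue
        if len(in_univ) < min_genes:
            continue
        col = np.zeros(N, dtype=np.int32)
        col[in_univ] = 1
        kept.append(pid)
        set_cols.append(col)
    if not kept:
        return pd.DataFrame(
            columns=["n_genes", "n_overlap", "v", "p", "p_adj", "significant"]
        )
    Pmat = np.column_stack(set_cols)  # N x n_pathways
    set_sizes = Pmat.sum(axis=0)

    obs_genes = (top[None, :].astype(np.int32) @ G) > 0
    obs_overlap = (obs_genes.astype(np.int32) @ Pmat).astype(float)
    obs_v = _v_from_counts(obs_overlap, obs_genes.sum(axis=1), set_sizes, N)[0]

    chrom_of = marker_map.markers.loc[order, "chrom"].to_numpy()
    exceed = np.zeros(len(kept))
    max_exceed = np.zeros(len(kept))
    block = 500
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        if per_chromosome:
            rot = np.empty((b, M), dtype=bool)
            for ch in pd.unique(chrom_of):
                idx = np.flatnonzero(chrom_of == ch)
                offs = rng.integers(0, len(idx), size=b)
                sub = top[idx]
                for r in range(b):
                    rot[r, idx] = np.roll(sub, offs[r])
        else:
            offs = rng.integers(0, M, size=b)
            rot = np.stack([np.roll(top, off) for off in offs])
        g = (rot.astype(np.int32) @ G) > 0  # b x N
        overlap = (g.astype(np.int32) @ Pmat).astype(float)  # b x n_pathways
        v = _v_from_counts(overlap, g.sum(axis=1), set_sizes, N)
        exceed += (v >= obs_v[None, :] - 1e-15).sum(axis=0)
        max_exceed += (v.max(axis=1)[:, None] >= obs_v[None, :] - 1e-15).sum(axis=0)
        done += b

    p = np.maximum(exceed / n_perm, 1.0 / n_perm)
    if fwer_method == "westfall-young":
        p_adj = np.maximum(max_exceed / n_perm, p)
    elif fwer_method == "bonferroni":
        p_adj = np.minimum(p * len(kept), 1.0)
        p_adj = np.maximum(p_adj, p)
    else:
        raise ValueError(f"unknown fwer_method {fwer_method!r}")

    out = pd.DataFrame(
        {
            "n_genes": set_sizes,
            "n_overlap": obs_overlap[0].astype(int),
            "v": obs_v,
            "p": p,
            "p_adj": p_adj,
            "significant": p_adj <= 0.05,
        },
        index=pd.Index(kept, name="pathway"),
    )
    out["cluster"] = pd.NA
    return out


def cluster_pathways(
    results: pd.DataFrame,
    pathways: PathwayDB,
    similarity_threshold: float = 0.25,
    seed: int = 0,
) -> pd.Series:
    """Louvain clustering of significant pathways by gene-set Jaccard similarity.

    Nodes are the pathways in ``results`` (pass the significant subset);
    edges connect pathways whose Jaccard index meets the threshold, weighted
    by that index.  Returns a cluster id per pathway.
    """
    if len(results) < 1:
        raise ValueError("need at least one pathway to cluster")
    ids = list(results.index)
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            ga, gb = pathways[a], pathways[b]
            jac = len(ga & gb) / len(ga | gb)
            if jac >= similarity_threshold:
                graph.add_edge(a, b, weight=jac)
    communities = nx.community.louvain_communities(graph, weight="weight", seed=seed)
    assignment = {}
    for cid, members in enumerate(sorted(communities, key=lambda s: sorted(s)[0])):
        for pid in members:
            assignment[pid] = cid
    return pd.Series(assignment, name="cluster").loc[ids]
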