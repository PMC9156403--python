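"""Cramér's V, marker-gene mapping, circular permutations, Louvain clusters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cttwas import (
    PathwayDB,
    circular_permutation_enrichment,
    cluster_pathways,
    cramers_v_2x2,
    map_markers_to_genes,
)


def _chi2_oracle(a, b, c, d):
    """Brute-force Pearson chi-square from observed/expected cell counts."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    return ((obs - expected) ** 2 / expected).sum(), n


class TestCramersV:
    def test_perfect_association(self):
        assert cramers_v_2x2(10, 0, 0, 10) == 1.0

    def test_independence(self):
        assert cramers_v_2x2(5, 5, 5, 5) == 0.0

    def test_worked_value(self):
        assert cramers_v_2x2(8, 2, 4, 6) == pytest.approx(0.40825, abs=1e-5)

    def test_zero_margin_returns_zero(self):
        assert cramers_v_2x2(0, 0, 3, 7) == 0.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            cramers_v_2x2(-1, 2, 3, 4)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(*(st.integers(min_value=1, max_value=200) for _ in range(4)))
    def test_matches_sqrt_chi2_over_n(self, a, b, c, d):
        chi2, n = _chi2_oracle(a, b, c, d)
        assert cramers_v_2x2(a, b, c, d) == pytest.approx(
            np.sqrt(chi2 / n), abs=1e-12
        )


@pytest.fixture()
def gene_annotation():
    return pd.DataFrame(
        {
            "gene_id": ["plus_gene", "minus_gene", "inner_a", "inner_b"],
            "chrom": ["chr1", "chr1", "chr2", "chr2"],
            "start": [50_000, 50_000, 10_000, 15_000],
            "end": [60_000, 60_000, 30_000, 35_000],
            "strand": ["+", "-", "+", "+"],
        }
    )


class TestMarkerGeneMapping:
    def test_upstream_flank_is_strand_aware(self, gene_annotation):
        coords = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [45_000, 65_000]},
            index=["m_before", "m_after"],
        )
        mm = map_markers_to_genes(coords, gene_annotation, upstream_flank=10_000)
        # 5 kb before the start: upstream of the + gene only
        assert mm.mapping["m_before"] == {"plus_gene"}
        # 5 kb after the end: upstream of the - gene only
        assert mm.mapping["m_after"] == {"minus_gene"}

    def test_marker_beyond_flank_unmapped(self, gene_annotation):
        coords = pd.DataFrame({"chrom": ["chr1"], "pos": [35_000]}, index=["m_far"])
        mm = map_markers_to_genes(coords, gene_annotation, upstream_flank=10_000)
        assert mm.mapping["m_far"] == set()
        assert mm.n_markers == 1  # still occupies a circle position

    def test_marker_in_overlapping_genes_maps_to_both(self, gene_annotation):
        coords = pd.DataFrame({"chrom": ["chr2"], "pos": [20_000]}, index=["m_in"])
        mm = map_markers_to_genes(coords, gene_annotation, upstream_flank=0)
        assert mm.mapping["m_in"] == {"inner_a", "inner_b"}

    def test_unknown_strand_rejected(self, gene_annotation):
        bad = gene_annotation.copy()
        bad.loc[0, "strand"] = "."
        coords = pd.DataFrame({"chrom": ["chr1"], "pos": [0]}, index=["m"])
        with pytest.raises(ValueError, match="strand"):
            map_markers_to_genes(coords, bad)


def _grid_fixture(n_markers=400, seed=0, n_pathways=30, genes_per_path=25):
    """Markers on a regular two-chromosome grid, one gene per marker."""
    rng = np.random.default_rng(seed)
    half = n_markers // 2
    coords = pd.DataFrame(
        {"chrom": ["chr1"] * half + ["chr2"] * half,
         "pos": list(range(0, half * 1000, 1000)) * 2},
        index=[f"M{i}" for i in range(n_markers)],
    )
    genes = pd.DataFrame(
        {"gene_id": [f"G{i}" for i in range(n_markers)],
         "chrom": coords["chrom"].to_numpy(),
         "start": coords["pos"].to_numpy(),
         "end": coords["pos"].to_numpy() + 400,
         "strand": "+"},
    )
    mm = map_markers_to_genes(coords, genes, upstream_flank=100)
    ids = [f"G{i}" for i in range(n_markers)]
    paths = PathwayDB(
        {f"P{j}": set(rng.choice(ids, genes_per_path, replace=False))
         for j in range(n_pathways)}
    )
    return coords, mm, paths


def _results(coords, top_idx):
    q = np.full(len(coords), 0.5)
    q[np.asarray(top_idx, dtype=int)] = 0.01
    return pd.DataFrame({"p": 0.5, "q": q}, index=coords.index)


class TestCircularPermutation:
    def test_no_top_markers_gives_v_zero_p_one(self):
        coords, mm, paths = _grid_fixture()
        res = _results(coords, [])
        enr = circular_permutation_enrichment(res, mm, paths, n_perm=200, seed=0)
        assert (enr["v"] == 0).all()
        assert (enr["p"] == 1.0).all()

    def test_small_pathway_excluded(self):
        coords, mm, _ = _grid_fixture()
        paths = PathwayDB({"tiny": {"G0", "G1"}, "ok": {"G0", "G1", "G2", "G3"}})
        res = _results(coords, [0, 1, 2])
        enr = circular_permutation_enrichment(res, mm, paths, n_perm=200, seed=0)
        assert "tiny" not in enr.index and "ok" in enr.index

    def test_planted_clustered_block_detected(self):
        coords, mm, paths = _grid_fixture()
        block = PathwayDB({**dict(paths.items()),
                           "HIT": {f"G{i}" for i in range(25)}})
        res = _results(coords, range(25))
        enr = circular_permutation_enrichment(res, mm, block, n_perm=1000, seed=1)
        assert enr.loc["HIT", "v"] == 1.0
        assert enr.loc["HIT", "p"] == 1.0 / 1000  # floored at 1/n_perm
        assert bool(enr.loc["HIT", "significant"])

    def test_null_pvalues_valid(self):
        """Random (exchangeable) top markers: P(p <= a) <= a + MC error."""
        coords, mm, paths = _grid_fixture()
        all_p = []
        fwer_hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            res = _results(coords, rng.choice(len(coords), 30, replace=False))
            enr = circular_permutation_enrichment(res, mm, paths, n_perm=500,
                                                  seed=seed)
            all_p.extend(enr["p"])
            fwer_hits += int(enr["significant"].sum() > 0)
        all_p = np.asarray(all_p)
        for alpha in (0.05, 0.1):
            se = np.sqrt(alpha * (1 - alpha) / len(all_p))
            assert (all_p <= alpha).mean() <= alpha + 3 * se
        # FWER is controlled at 0.05 per run; one alarm in five runs is
        # within expectation for a valid procedure
        assert fwer_hits <= 1

    def test_marker_renaming_preserves_pvalues(self):
        coords, mm, paths = _grid_fixture()
        res = _results(coords, range(10, 40))
        enr1 = circular_permutation_enrichment(res, mm, paths, n_perm=300, seed=3)
        renamed = coords.rename(index=lambda m: f"X_{m}")
        genes = pd.DataFrame(
            {"gene_id": [f"G{i}" for i in range(len(coords))],
             "chrom": coords["chrom"].to_numpy(),
             "start": coords["pos"].to_numpy(),
             "end": coords["pos"].to_numpy() + 400, "strand": "+"},
        )
        mm2 = map_markers_to_genes(renamed, genes, upstream_flank=100)
        res2 = res.rename(index=lambda m: f"X_{m}")
        enr2 = circular_permutation_enrichment(res2, mm2, paths, n_perm=300, seed=3)
        pd.testing.assert_series_equal(enr1["p"], enr2["p"])

    def test_agrees_with_gene_label_permutation_under_exchangeability(self):
        """With i.i.d. top markers and a 1:1 marker-gene map, rotating the
        marker circle and shuffling gene labels give the same null."""
        coords, mm, _ = _grid_fixture(n_markers=400)
        ids = [f"G{i}" for i in range(400)]
        rng = np.random.default_rng(9)
        paths = PathwayDB({"ONE": set(rng.choice(ids, 40, replace=False))})
        top_idx = rng.choice(400, 40, replace=False)
        res = _results(coords, top_idx)
        n_perm = 3000
        enr = circular_permutation_enrichment(res, mm, paths, n_perm=n_perm, seed=4)
        p_circ = enr.loc["ONE", "p"]

        # oracle: permute which genes are top, recompute V
        from cttwas.enrichment import cramers_v_2x2

        in_path = np.isin(np.arange(400), [ids.index(g) for g in paths["ONE"]])
        top = np.zeros(400, dtype=bool)
        top[top_idx] = True

        def v_of(topvec):
            a = int((topvec & in_path).sum())
            b = int((topvec & ~in_path).sum())
            c = int((~topvec & in_path).sum())
            d = int((~topvec & ~in_path).sum())
            return cramers_v_2x2(a, b, c, d)

        obs = v_of(top)
        count = 0
        for _ in range(n_perm):
            count += v_of(rng.permutation(top)) >= obs - 1e-15
        p_label = max(count / n_perm, 1 / n_perm)
        # the rotation null has only n_markers distinct outcomes, so the two
        # estimates differ by rotation-population noise ~ sqrt(p(1-p)/M) on
        # top of the Monte-Carlo error of each estimate
        var = p_label * (1 - p_label) * (1 / 400 + 2 / n_perm)
        assert abs(p_circ - p_label) <= 2 * np.sqrt(var) + 2 / n_perm


class TestClusterPathways:
    def test_identical_gene_sets_share_cluster(self):
        db = PathwayDB({"a": {"g1", "g2", "g3"}, "b": {"g1", "g2", "g3"}})
        cl = cluster_pathways(pd.DataFrame(index=["a", "b"]), db, seed=0)
        assert cl["a"] == cl["b"]

    def test_disjoint_gene_sets_split(self):
        db = PathwayDB({"a": {"g1", "g2"}, "b": {"g3", "g4"}})
        cl = cluster_pathways(pd.DataFrame(index=["a", "b"]), db, seed=0)
        assert cl["a"] != cl["b"]

    def test_three_planted_blocks_recovered(self):
        gsets = {}
        for blk in range(3):
            core = [f"B{blk}_g{i}" for i in range(16)]
            for j in range(4):
                gsets[f"blk{blk}_p{j}"] = set(core) | {f"B{blk}_x{j}{i}" for i in range(4)}
        db = PathwayDB(gsets)
        cl = cluster_pathways(pd.DataFrame(index=list(gsets)), db,
                              similarity_threshold=0.25, seed=0)
        assert cl.nunique() == 3
        for blk in range(3):
            members = {cl[f"blk{blk}_p{j}"] for j in range(4)}
            assert len(members) == 1
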