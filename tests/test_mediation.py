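"""Mediation scan: pre-selection windows, quasi-Bayesian ACME, escalation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from cttwas import (
    MediationSpec,
    SimulationConfig,
    mediation_test,
    preselect_markers,
    run_regulation_scan,
    simulate_cohort,
)


def _pheno(case):
    return pd.DataFrame({"case_status": case},
                        index=[f"S{i}" for i in range(len(case))])


def _marker_frame(rows: dict, n):
    return pd.DataFrame(rows, index=[f"S{i}" for i in range(n)]).T


class TestPreselection:
    def _setup(self):
        rng = np.random.default_rng(0)
        n = 200
        case = np.repeat([1, 0], n // 2)
        associated = rng.normal(0, 1, n) + 0.8 * case  # strongly associated
        unassociated = rng.normal(0, 1, n)
        markers = _marker_frame(
            {"m_assoc": associated, "m_null": unassociated}, n
        )
        genes = pd.DataFrame(
            {"gene_id": ["g1"], "chrom": ["chr1"], "start": [100_000],
             "end": [110_000]}
        )
        return markers, genes, _pheno(case)

    def test_unassociated_marker_excluded(self):
        markers, genes, pheno = self._setup()
        coords = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [105_000, 105_000]},
            index=["m_assoc", "m_null"],
        )
        cand = preselect_markers(markers, coords, pheno, genes, MediationSpec())
        assert set(cand["marker"]) == {"m_assoc"}

    @pytest.mark.parametrize(
        "pos,included",
        [(119_999, True), (120_001, False), (90_001, True), (89_999, False)],
    )
    def test_cis_window_boundary(self, pos, included):
        markers, genes, pheno = self._setup()
        coords = pd.DataFrame({"chrom": ["chr1"], "pos": [pos]}, index=["m_assoc"])
        cand = preselect_markers(
            markers.loc[["m_assoc"]], coords, pheno, genes, MediationSpec()
        )
        assert (len(cand) == 1) is included

    def test_hormone_paired_with_every_gene_no_window(self):
        markers, genes, pheno = self._setup()
        genes = pd.DataFrame(
            {"gene_id": ["g1", "g2", "g3"], "chrom": "chr1",
             "start": [0, 1_000_000, 2_000_000],
             "end": [100, 1_000_100, 2_000_100]}
        )
        spec = MediationSpec(marker_type="hormone")
        cand = preselect_markers(markers.loc[["m_assoc"]], None, pheno, genes, spec)
        assert set(cand["gene"]) == {"g1", "g2", "g3"}


def _simulate_triplet(seed, a=0.5, b=0.8, n=500):
    rng = np.random.default_rng(seed)
    marker = rng.binomial(2, 0.3, n).astype(float)
    mediator = a * marker + rng.normal(0, 1, n)
    eta = b * (mediator - mediator.mean())
    outcome = rng.binomial(1, expit(eta)).astype(float)
    return marker, mediator, outcome


class TestMediationTest:
    def test_type_one_error_controlled_under_null(self):
        """a = 0: rejection rate at 0.05 stays within 3 binomial SEs."""
        n_seeds, rejections = 100, 0
        for seed in range(n_seeds):
            marker, mediator, outcome = _simulate_triplet(seed, a=0.0)
            res = mediation_test(marker, mediator, outcome, seed=seed)
            rejections += res["p"] < 0.05
        se = np.sqrt(0.05 * 0.95 / n_seeds)
        assert rejections / n_seeds <= 0.05 + 3 * se

    def test_recovery_sign_and_magnitude_vs_plugin_oracle(self):
        spec = MediationSpec(sims_schedule=(1_000, 10_000))
        estimates = []
        for seed in range(20):
            marker, mediator, outcome = _simulate_triplet(100 + seed, n=1000)
            res = mediation_test(marker, mediator, outcome, spec, seed=seed)
            assert res["acme"] > 0
            estimates.append(res["acme"])
        # large-sample plug-in oracle at the generating parameters
        rng = np.random.default_rng(999)
        eps = rng.standard_normal(2_000_000)
        EM = 0.5 * 0.6  # E[mediator]: slope x E[dosage] at MAF 0.3
        oracle = (expit(0.8 * (0.5 + eps - EM)) - expit(0.8 * (eps - EM))).mean()
        assert abs(np.mean(estimates) - oracle) / oracle < 0.2

    def test_unresolvable_pvalue_escalates_tenfold(self):
        marker, mediator, outcome = _simulate_triplet(7, a=0.9, b=1.5, n=2000)
        spec = MediationSpec(sims_schedule=(1_000, 10_000))
        res = mediation_test(marker, mediator, outcome, spec, seed=0)
        assert res["n_sims"] == 10_000  # p was 0 at 1,000 draws

    def test_acme_zero_when_b_is_zero(self):
        rng = np.random.default_rng(8)
        n = 2000
        marker = rng.binomial(2, 0.3, n).astype(float)
        mediator = 0.8 * marker + rng.normal(0, 1, n)
        outcome = rng.binomial(1, 0.5, n).astype(float)  # independent of mediator
        res = mediation_test(marker, mediator, outcome, seed=1)
        assert abs(res["acme"]) < 0.02

    def test_deterministic_given_seed(self):
        marker, mediator, outcome = _simulate_triplet(3)
        a = mediation_test(marker, mediator, outcome, seed=5)
        b = mediation_test(marker, mediator, outcome, seed=5)
        assert a == b

    def test_constant_mediator_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            mediation_test(np.arange(10.0), np.ones(10), np.repeat([0.0, 1.0], 5))

    def test_separation_flagged_not_converged(self):
        rng = np.random.default_rng(4)
        marker = rng.normal(0, 1, 100)
        mediator = rng.normal(0, 1, 100)
        outcome = (mediator > np.median(mediator)).astype(float)  # separable
        res = mediation_test(marker, mediator, outcome, seed=0)
        assert res["converged"] is False
        assert np.isnan(res["acme"])

    def test_monte_carlo_se_shrinks_with_draws(self):
        """Tenfold more draws shrinks the p-value's MC spread roughly 10**0.5-fold."""
        marker, mediator, outcome = _simulate_triplet(11, a=0.25, b=0.4)
        p_small, p_big = [], []
        for rep in range(25):
            p_small.append(
                mediation_test(marker, mediator, outcome,
                               MediationSpec(sims_schedule=(1_000,)), seed=rep)["p"]
            )
            p_big.append(
                mediation_test(marker, mediator, outcome,
                               MediationSpec(sims_schedule=(10_000,)), seed=rep)["p"]
            )
        ratio = np.std(p_small, ddof=1) / np.std(p_big, ddof=1)
        assert 1.5 < ratio < 7.0  # sqrt(10) ~ 3.2, generous MC tolerance


class TestRegulationScan:
    @staticmethod
    def _scan(seed, planted=True):
        med = ([(0, 0, 2.0, 0.0), (1, 1, 2.0, 0.0), (2, 2, 2.0, 0.0)]
               if planted else [])
        med += [(s, s, 0.0, 0.5) for s in range(3, 9)]  # direct-only bait
        eq = ([(0, 0, None, 0.5), (1, 1, None, 0.5), (2, 2, None, 0.5)]
              if planted else [])
        cfg = SimulationConfig(
            n_samples=400, n_cases=200, n_transcripts=40, n_snps=80,
            bulk_noise_sd=0.3, eqtl_map=eq, mediation_map=med, seed=seed,
        )
        ds = simulate_cohort(cfg)
        de = [f"G{i:05d}" for i in range(15)]
        return run_regulation_scan(
            ds.genotypes.dosages, ds.genotypes.coords, ds.expression.abundance,
            ds.expression.annotation, ds.phenotypes, de,
            MediationSpec(sims_schedule=(1_000, 10_000), seed=seed),
        )

    def test_recovers_planted_deqtl_paths(self):
        planted = {("rs00000", "T00000"), ("rs00001", "T00001"),
                   ("rs00002", "T00002")}
        good = 0
        for seed in range(6):
            scan = self._scan(seed)
            sig = scan[scan["q"] < 0.1]
            found = {(r.marker, r.transcript) for r in sig.itertuples()}
            tp, fp = len(found & planted), len(found - planted)
            good += tp >= 2 and fp <= 1
        assert good >= 4  # majority of seeds

    def test_null_scan_mostly_empty(self):
        empty = 0
        for seed in range(5):
            scan = self._scan(50 + seed, planted=False)
            if len(scan) == 0 or (scan["q"] >= 0.1).all():
                empty += 1
        assert empty >= 4

    def test_case_associated_hormone_without_b_path_not_significant(self):
        rng = np.random.default_rng(2)
        n = 400
        case = np.repeat([1, 0], n // 2)
        hormone = rng.normal(0, 1, n) + 0.6 * case  # associated, but no b path
        pheno = _pheno(case)
        markers = _marker_frame({"oxytocin": hormone}, n)
        resid = pd.DataFrame(
            rng.normal(0, 1, (3, n)), index=["T0", "T1", "T2"],
            columns=pheno.index,
        )
        ann = pd.DataFrame(
            {"gene_id": ["g0", "g1", "g2"], "chrom": "chr1",
             "start": [0, 100, 200], "end": [50, 150, 250], "strand": "+"},
            index=resid.index,
        )
        scan = run_regulation_scan(
            markers, None, resid, ann, pheno, ["g0", "g1", "g2"],
            MediationSpec(marker_type="hormone", sims_schedule=(1_000,), seed=0),
        )
        assert len(scan) == 3  # tested against every gene
        assert (scan["q"] >= 0.1).all()
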