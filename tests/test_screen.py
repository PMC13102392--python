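"""Screening statistics: KS, Fisher, LMMs, FDR, classification, power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import ldmorph as lm
from ldmorph.reference import load_reference_screen
from ldmorph.simulate import simulate_gene_dataset


def ks_oracle(a, b):
    """O(n*m) ECDF sweep: sup |ECDF_a - ECDF_b| over all sample points."""
    grid = np.concatenate([a, b])
    fa = np.array([(a <= g).mean() for g in grid])
    fb = np.array([(b <= g).mean() for g in grid])
    return np.abs(fa - fb).max()


def bh_oracle(p):
    """Hand step-up: p_(i) * n/i with cumulative minimum from the largest."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p)
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestKsTwoSample:
    def test_identical_samples(self):
        d, p = lm.ks_two_sample([1.0, 2, 3], [1.0, 2, 3])
        assert d == 0 and p == 1

    def test_disjoint_supports(self):
        d, _ = lm.ks_two_sample([1, 2, 3], [4, 5, 6])
        assert d == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lm.ks_two_sample([], [1.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_d_matches_ecdf_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=37), rng.normal(0.3, 1.2, size=25)
        d, _ = lm.ks_two_sample(a, b)
        assert d == pytest.approx(ks_oracle(a, b), abs=1e-12)


class TestFisherCombine:
    def test_all_ones(self):
        chi2, df, p = lm.fisher_combine([1.0, 1.0, 1.0])
        assert chi2 == 0 and df == 6 and p == 1

    def test_two_p05_closed_form(self):
        chi2, df, p = lm.fisher_combine([0.05, 0.05])
        x = -4 * np.log(0.05)
        assert chi2 == pytest.approx(x)
        assert df == 4
        # chi2_4 upper tail closed form: exp(-x/2) * (1 + x/2)
        assert p == pytest.approx(np.exp(-x / 2) * (1 + x / 2), abs=1e-12)
        assert p == pytest.approx(0.0175, abs=5e-4)

    def test_single_p_is_identity(self):
        for pv in (0.5, 0.01, 0.999):
            assert lm.fisher_combine([pv])[2] == pytest.approx(pv, abs=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            lm.fisher_combine([0.0, 0.5])

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_chi2_tail_of_brute_sum(self, seed):
        rng = np.random.default_rng(seed)
        ps = rng.uniform(0.001, 1, size=rng.integers(2, 8))
        chi2, df, p = lm.fisher_combine(ps)
        assert p == pytest.approx(stats.chi2.sf((-2 * np.log(ps)).sum(), 2 * len(ps)),
                                  abs=1e-14)


class TestAdjustFdr:
    def test_hand_example(self):
        np.testing.assert_allclose(lm.adjust_fdr([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_unchanged(self):
        assert lm.adjust_fdr([0.2])[0] == pytest.approx(0.2)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_step_up_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 30))
        np.testing.assert_allclose(lm.adjust_fdr(p), bh_oracle(p), atol=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=25))
    def test_adjusted_at_least_raw_and_order_preserving(self, p):
        adj = lm.adjust_fdr(p)
        assert (adj >= np.asarray(p) - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestPowerAndSampleSize:
    def test_null_effect_power_is_alpha(self):
        assert lm.power_two_sample(20, 20, 0.0) == pytest.approx(0.05, abs=1e-9)

    def test_printed_power_rows(self):
        assert round(100 * lm.power_two_sample(45, 30, 0.8)) == 92
        assert round(100 * lm.power_two_sample(42, 45, 0.8)) == 96

    def test_monotone_in_n_and_d(self):
        base = lm.power_two_sample(20, 20, 0.5)
        assert lm.power_two_sample(40, 20, 0.5) > base
        assert lm.power_two_sample(20, 40, 0.5) > base
        assert lm.power_two_sample(20, 20, 0.8) > base

    def test_huge_effect_needs_minimum_n(self):
        # df = 2 makes the t critical value heavy, so the floor of n = 2
        # is only reached for extreme standardized effects
        assert lm.sample_size_for_power(20.0) == 2

    @pytest.mark.parametrize("d,n_control", [(0.8, None), (1.06, 19), (0.6, None)])
    def test_search_invariant(self, d, n_control):
        n = lm.sample_size_for_power(d, n_control=n_control)
        n1 = n if n_control is None else n_control
        assert lm.power_two_sample(n1, n, d) >= 0.8
        if n > 2:
            n1m = n - 1 if n_control is None else n_control
            assert lm.power_two_sample(n1m, n - 1, d) < 0.8

    def test_unreachable_power(self):
        with pytest.raises(ValueError):
            lm.sample_size_for_power(0.5, power=0.999999, max_n=50)


class TestCohensD:
    def test_identical_means(self):
        assert lm.cohens_d([1, 2, 3], [3, 2, 1]) == 0

    def test_unit_shift_unit_sd(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 2000)
        b = a + 1.0  # identical spread, shifted by exactly 1 SD
        assert lm.cohens_d(b, a) == pytest.approx(1.0, abs=1e-9 + 1 / a.std())

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=17), rng.normal(0.4, 2.0, size=23)
        sp = np.sqrt((16 * a.var(ddof=1) + 22 * b.var(ddof=1)) / 38)
        assert lm.cohens_d(a, b) == pytest.approx((a.mean() - b.mean()) / sp,
                                                  abs=1e-12)


class TestClassifyHits:
    def test_published_table_dual_criterion(self):
        ref = load_reference_screen()
        cls = lm.classify_hits(ref.set_index("gene"))
        robust = set(cls[cls == "robust"].index)
        assert robust == {"txnipa", "mmp14b", "foxp1b"}
        assert set(cls[cls == "distributional-only"].index) == {"tbx15", "tmem115"}

    def test_all_ns_when_p_one(self):
        df = pd.DataFrame({"ks_stratified_adj_p": [1.0], "lmm_adj_p": [1.0],
                           "ks_pooled_p": [1.0]})
        assert lm.classify_hits(df).tolist() == ["ns"]

    def test_criterion_boundary(self):
        df = pd.DataFrame({"ks_stratified_adj_p": [0.04], "lmm_adj_p": [0.06]})
        assert lm.classify_hits(df).tolist() == ["distributional-only"]


class TestLmm:
    def test_pct_change_beta_inverse(self):
        from ldmorph.screen import pct_change_from_beta

        assert pct_change_from_beta(np.log(1.2)) == pytest.approx(20.0)
        assert pct_change_from_beta(0.0) == 0.0
        for pct in (-30.0, 5.0, 19.9):
            assert pct_change_from_beta(np.log(1 + pct / 100)) == pytest.approx(pct)

    def test_shift_effect_detected(self):
        gd = simulate_gene_dataset(lm.SimulationConfig(),
                                   lm.GeneEffect(beta=np.log(1.2)), seed=21)
        r = lm.fit_lmm_intercept(gd)
        assert r.p < 1e-6
        assert r.pct_change == pytest.approx(20, abs=6)
        assert r.ci_low < r.pct_change < r.ci_high

    def test_identical_genotypes_zero_interaction(self):
        # identical log-linear size scaling for both genotypes: the
        # interaction coefficient vanishes exactly
        rng = np.random.default_rng(22)
        rows = []
        for exp, b in (("e1", 0.02), ("e2", -0.05)):
            area = np.exp(rng.uniform(12, 15, 40))
            for genotype in ("control", "mutant"):
                rows.append(pd.DataFrame({
                    "fish_id": [f"{exp}{genotype}{i}" for i in range(40)],
                    "gene": "g", "genotype": genotype, "experiment": exp,
                    "standard_length": 10.0, "sat_area": area,
                    "total_lipid_area": 0.6 * area,
                    "mean_feret": np.exp(1.0 + 0.2 * np.log(area) + b),
                    "n_droplets": 100}))
        r = lm.fit_lmm_interaction(pd.concat(rows, ignore_index=True))
        assert abs(r.beta) < 1e-6

    def test_single_experiment_routed(self):
        gd = simulate_gene_dataset(lm.SimulationConfig(n_experiments=1),
                                   lm.GeneEffect(), seed=23)
        with pytest.raises(ValueError):
            lm.fit_lmm_intercept(gd)

    def test_trait_lmm_null_near_zero(self):
        gd = simulate_gene_dataset(lm.SimulationConfig(), lm.GeneEffect(), seed=24)
        r = lm.fit_trait_lmm(gd, "standard_length")
        assert abs(r.pct_change) < 10
        r2 = lm.fit_trait_lmm(gd, "total_adiposity")
        assert r2.p > 0.001  # no adiposity effect simulated


class TestSingleExperimentAnalysis:
    def test_equals_lmm_in_zero_batch_limit(self):
        gd = simulate_gene_dataset(
            lm.SimulationConfig(n_experiments=1, sigma_batch=0.0),
            lm.GeneEffect(beta=0.1), seed=31)
        ols = lm.single_experiment_analysis(gd)
        # duplicate the experiment into two identical batches: the LMM's
        # batch variance goes to zero and beta matches OLS
        gd2 = pd.concat([gd, gd.assign(experiment="exp2",
                                       fish_id=gd.fish_id + "b")])
        mixed = lm.fit_lmm_intercept(gd2)
        assert mixed.beta == pytest.approx(ols.beta, abs=1e-6)
        assert ols.preliminary

    def test_requires_single_experiment_and_both_genotypes(self):
        gd = simulate_gene_dataset(lm.SimulationConfig(), lm.GeneEffect(), seed=32)
        with pytest.raises(ValueError):
            lm.single_experiment_analysis(gd)
        solo = gd[(gd.experiment == "exp1") & (gd.genotype == "control")]
        with pytest.raises(ValueError):
            lm.single_experiment_analysis(solo)


class TestConsistency:
    def test_identical_effects_score_one(self):
        assert lm.compute_consistency([4.2, 4.2, 4.2]) == pytest.approx(1.0)

    def test_opposite_signs_score_zero(self):
        assert lm.compute_consistency([5.0, -5.0]) == 0.0

    def test_direct_arithmetic(self):
        assert lm.compute_consistency([5.0, 10.0]) == pytest.approx(0.6796, abs=2e-3)

    def test_needs_two_effects(self):
        with pytest.raises(ValueError):
            lm.compute_consistency([1.0])


class TestStratifiedKs:
    def test_single_experiment_equals_single_p(self):
        gd = simulate_gene_dataset(lm.SimulationConfig(n_experiments=1),
                                   lm.GeneEffect(), seed=41)
        r = lm.stratified_ks_test(gd)
        assert r.n_experiments == 1
        single_p = list(r.per_experiment_p.values())[0]
        assert r.p == pytest.approx(single_p, abs=1e-12)

    def test_weighted_effect_sign_matches_shift(self):
        gd = simulate_gene_dataset(lm.SimulationConfig(),
                                   lm.GeneEffect(beta=np.log(1.25)), seed=42)
        r = lm.stratified_ks_test(gd)
        assert r.effect > 0
        assert r.p < 0.01

    def test_no_eligible_experiment(self):
        gd = simulate_gene_dataset(lm.SimulationConfig(), lm.GeneEffect(),
                                   seed=43, allocation=[(4, 4), (4, 4)])
        with pytest.raises(ValueError):
            lm.stratified_ks_test(gd)
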