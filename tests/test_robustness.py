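"""Sensitivity suite: variance tests, moments, hetero-LMM, permutation, Welch."""

import numpy as np
import pytest
from scipy import stats

import ldmorph as lm
from ldmorph.robustness import HeteroLmmResult, _profile_loglik
from ldmorph.simulate import simulate_gene_dataset


class TestVarianceFTest:
    def test_equal_variances_ratio_near_one(self):
        rng = np.random.default_rng(0)
        c, m = rng.normal(size=200), rng.normal(size=200)
        r = lm.variance_f_test(c, m)
        assert r.variance_ratio == pytest.approx(1.0, abs=0.3)
        assert r.f_p > 0.05

    def test_swap_inverts_ratio_preserves_p(self):
        rng = np.random.default_rng(1)
        c, m = rng.normal(size=30), rng.normal(0, 2, size=40)
        r1 = lm.variance_f_test(c, m)
        r2 = lm.variance_f_test(m, c)
        assert r1.variance_ratio == pytest.approx(1 / r2.variance_ratio)
        assert r1.f_p == pytest.approx(r2.f_p, abs=1e-10)

    def test_power_at_sd_ratio_two(self):
        rng = np.random.default_rng(2)
        rej = sum(
            lm.variance_f_test(rng.normal(size=50), rng.normal(0, 2, 50)).f_p < 0.05
            for _ in range(200))
        assert rej / 200 > 0.8

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            lm.variance_f_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestDistributionMoments:
    def test_symmetric_sample_zero_skew(self):
        g1, _, _ = lm.distribution_moments([-2, -1, 0, 1, 2])
        assert g1 == pytest.approx(0, abs=1e-12)

    def test_large_normal_sample_near_zero_excess_kurtosis(self):
        x = np.random.default_rng(3).normal(size=100_000)
        g1, g2, tail = lm.distribution_moments(x)
        # Monte-Carlo SEs: sqrt(6/n), sqrt(24/n)
        assert abs(g1) < 3 * np.sqrt(6 / len(x))
        assert abs(g2) < 3 * np.sqrt(24 / len(x))
        assert tail == pytest.approx(100 * 2 * stats.norm.sf(2), abs=0.5)

    def test_tail_percentage_counting(self):
        x = np.zeros(50)
        x[:25] = 1.0
        x[0] = 25.0  # lone extreme point: exactly 1 of 50 beyond 2 SD
        _, _, tail = lm.distribution_moments(x)
        assert tail == pytest.approx(2.0)

    def test_small_or_degenerate_rejected(self):
        with pytest.raises(ValueError):
            lm.distribution_moments([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            lm.distribution_moments([1.0, 1.0, 1.0, 1.0])


class TestHeteroscedasticLmm:
    def test_equal_variance_matches_homoscedastic(self):
        gd = simulate_gene_dataset(lm.SimulationConfig(),
                                   lm.GeneEffect(beta=0.1), seed=50)
        het = lm.heteroscedastic_lmm(gd)
        hom = lm.fit_lmm_intercept(gd)
        assert het.sigma_mutant / het.sigma_control == pytest.approx(1.0, abs=0.35)
        assert abs(het.beta - hom.beta) < hom.se

    def test_variance_inflation_recovered(self):
        ratios = []
        for rep in range(30):
            gd = simulate_gene_dataset(
                lm.SimulationConfig(),
                lm.GeneEffect(variance_inflation=2.0), seed=600 + rep)
            h = lm.heteroscedastic_lmm(gd)
            ratios.append(h.sigma_mutant / h.sigma_control)
        assert np.mean(ratios) == pytest.approx(2.0, abs=0.3)

    def test_single_experiment_equals_wls_oracle(self):
        gd = simulate_gene_dataset(
            lm.SimulationConfig(n_experiments=1, sigma_batch=0.0),
            lm.GeneEffect(beta=0.15, variance_inflation=2.0), seed=51)
        het = lm.heteroscedastic_lmm(gd)
        assert het.sigma_batch == 0.0
        # GLS closed form at the fitted variances
        d = gd.copy()
        X = np.column_stack([np.ones(len(d)), np.log(d.sat_area),
                             (d.genotype == "mutant").astype(float)])
        y = np.log(d.mean_feret.to_numpy())
        w = np.where(d.genotype == "mutant", het.sigma_mutant**-2,
                     het.sigma_control**-2)
        beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
        assert het.beta == pytest.approx(beta[2], abs=1e-6)

    def test_equal_variance_constraint_recovers_loglik(self):
        gd = simulate_gene_dataset(lm.SimulationConfig(n_experiments=1,
                                                       sigma_batch=0.0),
                                   lm.GeneEffect(), seed=52)
        d = gd.copy()
        X = np.column_stack([np.ones(len(d)), np.log(d.sat_area),
                             (d.genotype == "mutant").astype(float)])
        y = np.log(d.mean_feret.to_numpy())
        mut = (d.genotype == "mutant").to_numpy()
        groups = [(X, y, mut)]
        # profile the common-sigma likelihood directly
        from scipy.optimize import minimize_scalar

        def nll_common(log_s):
            return _profile_loglik([log_s, log_s], groups, True)[0]

        opt = minimize_scalar(nll_common, bounds=(-6, 2), method="bounded")
        # ML normal loglik of OLS with sigma^2 = RSS/n
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        s2 = np.mean((y - X @ beta) ** 2)
        ll = -0.5 * len(y) * (np.log(2 * np.pi * s2) + 1)
        assert -opt.fun == pytest.approx(ll, abs=1e-6)


class TestPermutationTest:
    def test_bounds_and_determinism(self):
        gd = simulate_gene_dataset(lm.SimulationConfig(),
                                   lm.GeneEffect(beta=np.log(1.3)), seed=60)
        r1 = lm.permutation_test(gd, B=99, seed=7)
        r2 = lm.permutation_test(gd, B=99, seed=7)
        assert r1.perm_p == r2.perm_p
        assert 1 / 100 <= r1.perm_p <= 1
        # strong effect: observed beats every permutation
        assert r1.perm_p == pytest.approx(1 / 100)
        assert r1.raw_proportion == 0.0

    def test_refit_mode_agrees_on_strong_effect(self):
        gd = simulate_gene_dataset(lm.SimulationConfig(n_control=15, n_mutant=15),
                                   lm.GeneEffect(beta=np.log(1.4)), seed=61)
        fast = lm.permutation_test(gd, B=49, seed=3)
        slow = lm.permutation_test(gd, B=49, seed=3, refit=True)
        assert fast.perm_p == pytest.approx(1 / 50)
        assert slow.perm_p == pytest.approx(1 / 50)

    def test_null_p_roughly_uniform(self):
        ps = []
        for rep in range(80):
            gd = simulate_gene_dataset(
                lm.SimulationConfig(n_control=12, n_mutant=12),
                lm.GeneEffect(), seed=700 + rep)
            ps.append(lm.permutation_test(gd, B=79, seed=rep).perm_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_invalid_inputs(self):
        gd = simulate_gene_dataset(lm.SimulationConfig(), lm.GeneEffect(), seed=62)
        with pytest.raises(ValueError):
            lm.permutation_test(gd, B=0)
        with pytest.raises(ValueError):
            lm.permutation_test(gd[gd.genotype == "control"])


class TestWelch:
    def test_identical_samples(self):
        t, df, p = lm.welch_test([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0 and p == 1

    def test_satterthwaite_limit_equal_groups(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=20)
        b = rng.permutation(a) + 0.5  # same variance, equal n
        _, df, _ = lm.welch_test(a, b)
        assert df == pytest.approx(38, abs=1e-6)

    def test_hand_computed_case(self):
        c, m = np.array([1.0, 2, 3]), np.array([2.0, 3, 4, 5])
        t, df, p = lm.welch_test(c, m)
        se = np.sqrt(c.var(ddof=1) / 3 + m.var(ddof=1) / 4)
        t_direct = (m.mean() - c.mean()) / se
        df_direct = se**4 / ((c.var(ddof=1) / 3) ** 2 / 2
                             + (m.var(ddof=1) / 4) ** 2 / 3)
        assert t == pytest.approx(t_direct, abs=1e-12)
        assert df == pytest.approx(df_direct, abs=1e-9)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_direct), df_direct), abs=1e-12)


class TestConsensus:
    @pytest.mark.parametrize("ps,label", [
        ((0.01, 0.01, 0.04), "ALL SIG"),
        ((0.5, 0.9, 0.2), "ALL NS"),
        ((0.01, 0.2, 0.04), "MIXED"),
    ])
    def test_rule(self, ps, label):
        assert lm.consensus_classify(*ps) == label

    def test_strong_effects_reach_all_sig(self):
        hits = 0
        for rep in range(20):
            gd = simulate_gene_dataset(
                lm.SimulationConfig(n_control=40, n_mutant=40),
                lm.GeneEffect(beta=np.log(1.2)), seed=800 + rep)
            r = lm.gene_robustness(gd, B=199, seed=rep)
            hits += r["consensus"] == "ALL SIG"
        assert hits >= 18  # >= 90% of screens
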