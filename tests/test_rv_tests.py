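"""Unit, oracle and property tests for the association tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from rvth import rv_tests as rt
from rvth._quadform import chi2_mixture_sf


def toy_dataset(n=6, seed=0):
    """Small mixed dataset with an overlapping covariate (no separation)."""
    y = np.array([1, 1, 1, 0, 0, 0][:n])
    covs = {
        0: np.array([0.5, -1.2, 0.3, 0.8, -0.7, 0.1]),
        3: np.array([1.1, -0.4, 0.2, 0.9, -1.5, 0.6]),
        5: np.array([-0.3, 0.7, 1.4, 0.5, -0.9, -0.2]),
    }
    return y, covs.get(seed, covs[0])[:n]


class TestNullModel:
    def test_balanced_intercept_only_fit(self):
        y = np.repeat([1, 0], 50)
        model = rt.fit_null(y, None)
        np.testing.assert_allclose(model.fitted_probs, 0.5)
        assert set(np.round(model.residuals, 12)) == {1.0, -1.0}

    def test_pearson_residual_definition(self):
        y, cov = toy_dataset(seed=3)
        model = rt.fit_null(y, cov)
        mu = model.fitted_probs
        np.testing.assert_allclose(
            model.residuals, (y - mu) / np.sqrt(mu * (1 - mu)), rtol=1e-12
        )

    def test_perfect_separation_raises(self):
        y = np.repeat([1, 0], 20)
        with pytest.raises(ValueError):
            rt.fit_null(y, y.astype(float))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            rt.fit_null(np.ones(10), None)


class TestTHStatistic:
    def test_sum_of_squares_of_centered_carrier_residuals(self):
        residuals = np.array([1.0, -1.0, 2.0, -2.0])  # mean already 0
        assert rt.th_statistic(residuals, np.array([0, 1, 2])) == pytest.approx(6.0)

    def test_constant_residuals_give_zero(self):
        assert rt.th_statistic(np.full(10, 3.7), np.arange(4)) == pytest.approx(0.0)

    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=12))
    def test_global_sign_flip_invariance(self, values):
        r = np.array(values)
        idx = np.arange(len(values))[::2]
        assert rt.th_statistic(r, idx) == pytest.approx(rt.th_statistic(-r, idx), abs=1e-9)


class TestTHTest:
    def test_degenerate_balanced_residuals_give_p_one(self):
        """Without an informative covariate every resample ties the observed value."""
        y = np.repeat([1, 0], 100)
        g = np.zeros(200, dtype=int)
        g[[0, 5, 120]] = 1
        res = rt.th_test(y, None, g, n_resamples=500, rng=np.random.default_rng(0))
        assert res.p_value == 1.0

    def test_no_carriers_and_all_carriers_are_degenerate(self):
        y, cov = toy_dataset()
        r0 = rt.th_test(y, cov, np.zeros(6, dtype=int), 100, np.random.default_rng(0))
        r1 = rt.th_test(y, cov, np.ones(6, dtype=int), 100, np.random.default_rng(0))
        assert r0.p_value == 1.0 and r0.degenerate
        assert r1.p_value == 1.0 and r1.degenerate

    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_resampling_matches_subset_enumeration(self, m):
        """p from resampling converges to the exact mean over all C(n,m) subsets."""
        y, cov = toy_dataset(seed=5)
        model = rt.fit_null(y, cov)
        r2 = (model.residuals - model.residuals.mean()) ** 2
        carriers = np.arange(m)
        obs = r2[carriers].sum()
        subsets = list(itertools.combinations(range(6), m))
        exact = np.mean([r2[list(s)].sum() >= obs - 1e-12 for s in subsets])
        g = np.zeros(6, dtype=int)
        g[carriers] = 1
        B = 20_000
        res = rt.th_test(y, cov, g, B, np.random.default_rng(m))
        se = np.sqrt(max(exact * (1 - exact), 0.25 / len(subsets)) / B)
        assert abs(res.p_value - exact) < 3 * se + 2 / (B + 1)

    def test_subject_reordering_leaves_p_within_mc_error(self):
        rng = np.random.default_rng(8)
        n = 200
        y = np.zeros(n, dtype=int)
        y[:100] = 1
        cov = rng.standard_normal(n) + y
        g = (rng.random(n) < 0.1).astype(int)
        B = 20_000
        p1 = rt.th_test(y, cov, g, B, np.random.default_rng(1)).p_value
        perm = rng.permutation(n)
        p2 = rt.th_test(y[perm], cov[perm], g[perm], B, np.random.default_rng(2)).p_value
        se = np.sqrt(2 * max(p1 * (1 - p1), 0.01) / B)
        assert abs(p1 - p2) < 3 * se

    def test_resampling_p_value_floor(self):
        rng = np.random.default_rng(9)
        n = 400
        y = np.zeros(n, dtype=int)
        y[:200] = 1
        cov = rng.standard_normal(n) + 2.0 * y
        g = np.zeros(n, dtype=int)
        g[np.argsort(cov)[-8:]] = 1  # carriers with extreme residual mass
        res = rt.th_test(y, cov, g, 200, rng)
        assert res.p_value >= 1 / 201


class TestRCS:
    def test_identical_carriage_rates_give_null_result(self):
        y = np.repeat([1, 0], 1000)
        g = np.zeros(2000, dtype=int)
        g[:20] = 1
        g[1000:1020] = 1
        res = rt.rcs_test(y, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-6)
        assert res.p_value > 0.999

    def test_lrt_matches_two_binomial_closed_form(self):
        """With carriage as the only regressor, the LRT reduces to 2x2 binomial form."""
        y = np.concatenate([np.ones(1000), np.zeros(1000)])
        g = np.zeros(2000, dtype=int)
        g[:30] = 1        # 30 carrier cases
        g[1000:1010] = 1  # 10 carrier controls

        def binom_ll(k, n):
            p = k / n
            out = 0.0
            if 0 < p < 1:
                out = k * np.log(p) + (n - k) * np.log(1 - p)
            return out

        ll_full = binom_ll(30, 40) + binom_ll(970, 1960)
        ll_null = binom_ll(1000, 2000)
        lrt = 2 * (ll_full - ll_null)
        res = rt.rcs_test(y, g)
        assert res.statistic == pytest.approx(lrt, rel=1e-5)
        assert res.p_value == pytest.approx(stats.chi2.sf(lrt, 1), rel=1e-4)

    def test_constant_carriage_is_degenerate(self):
        y = np.repeat([1, 0], 10)
        res = rt.rcs_test(y, np.zeros(20, dtype=int))
        assert res.p_value == 1.0 and res.degenerate

    def test_uncorrelated_covariate_preserves_conclusion(self):
        rng = np.random.default_rng(12)
        y = np.repeat([1, 0], 500)
        g = np.zeros(1000, dtype=int)
        g[:60] = 1   # strongly case-enriched carriage
        g[500:510] = 1
        cov = rng.standard_normal(1000)
        p_plain = rt.rcs_test(y, g).p_value
        p_adj = rt.rcs_test(y, g, cov).p_value
        assert p_plain < 1e-6 and p_adj < 1e-6


class TestCAlpha:
    def test_two_copies_in_cases_worked_example(self):
        t, c = rt.calpha_statistic([2], [2], 0.5)
        assert t == pytest.approx(0.5)
        assert c == pytest.approx(0.25)

    def test_singletons_are_uninformative_at_balanced_sampling(self):
        t, c = rt.calpha_statistic([1, 0, 1], [1, 1, 1], 0.5)
        assert t == pytest.approx(0.0)
        assert c == pytest.approx(0.0)

    @given(
        st.lists(st.tuples(st.integers(0, 6), st.integers(0, 6)), min_size=1, max_size=6)
    )
    def test_additivity_over_variants(self, pairs):
        nj = np.array([max(a, b) for a, b in pairs])
        yj = np.array([min(a, b) for a, b in pairs])
        t1, c1 = rt.calpha_statistic(yj, nj, 0.3)
        t2, c2 = rt.calpha_statistic(np.tile(yj, 2), np.tile(nj, 2), 0.3)
        assert t2 == pytest.approx(2 * t1, abs=1e-12)
        assert c2 == pytest.approx(2 * c1, abs=1e-12)

    def test_asymptotic_two_variant_example(self):
        # 4 subjects, 2 cases; both variants carried by both cases only
        geno = np.array([[1, 1], [1, 1], [0, 0], [0, 0]])
        y = np.array([1, 1, 0, 0])
        res = rt.calpha_test(geno, y, "asymptotic")
        assert res.statistic == pytest.approx(np.sqrt(2.0))
        assert res.p_value == pytest.approx(stats.norm.sf(np.sqrt(2.0)), rel=1e-6)

    def test_permutation_matches_label_enumeration(self):
        geno = np.array(
            [[1, 0], [1, 1], [0, 1], [0, 0], [1, 0], [0, 0]]
        )
        y = np.array([1, 1, 1, 0, 0, 0])
        nj = geno.sum(0)
        p0 = 0.5
        t_obs = rt.calpha_statistic(y @ geno, nj, p0)[0]
        stars = []
        for cases in itertools.combinations(range(6), 3):
            yy = np.zeros(6)
            yy[list(cases)] = 1
            stars.append(rt.calpha_statistic(yy @ geno, nj, p0)[0])
        exact = np.mean([s >= t_obs - 1e-12 for s in stars])
        B = 20_000
        res = rt.calpha_test(geno, y, "permutation", B, np.random.default_rng(3))
        se = np.sqrt(exact * (1 - exact) / B)
        assert abs(res.p_value - exact) < 3 * se + 2 / (B + 1)

    def test_all_singletons_permutation_is_degenerate_tie(self):
        geno = np.eye(4, dtype=int)
        y = np.array([1, 1, 0, 0])
        res = rt.calpha_test(geno, y, "permutation", 500, np.random.default_rng(4))
        assert res.p_value == 1.0
        res_a = rt.calpha_test(geno, y, "asymptotic")
        assert res_a.p_value == 1.0 and res_a.degenerate


class TestSKAT:
    def test_orthogonal_single_variant_gives_zero_score(self):
        y = np.array([1, 0, 1, 0])
        geno = np.array([[1], [1], [0], [0]])
        res = rt.skat_test(y, geno, weights="unweighted")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_beta_density_maf_weight_closed_form(self):
        geno = np.zeros((200, 1))
        geno[:2, 0] = 1  # sample MAF = 2/400 = 0.005
        w = rt._beta_maf_weights(geno)
        expected = (25 * (1 - 0.005) ** 24) ** 2
        assert w[0] == pytest.approx(expected, rel=1e-12)
        assert np.sqrt(expected) == pytest.approx(22.17, abs=0.01)

    def test_monomorphic_genotypes_degenerate(self):
        y = np.repeat([1, 0], 10)
        res = rt.skat_test(y, np.zeros((20, 3)))
        assert res.p_value == 1.0 and res.degenerate

    def test_variant_reordering_invariance(self):
        rng = np.random.default_rng(21)
        y = np.repeat([1, 0], 100)
        geno = (rng.random((200, 6)) < 0.05).astype(float)
        p1 = rt.skat_test(y, geno).p_value
        p2 = rt.skat_test(y, geno[:, ::-1]).p_value
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_bootstrap_p_floor_and_mode_tags(self):
        rng = np.random.default_rng(22)
        y = np.repeat([1, 0], 100)
        geno = (rng.random((200, 4)) < 0.05).astype(float)
        res = rt.skat_test(y, geno, mode="bootstrap", n_boot=100, rng=rng)
        assert res.mode == "bootstrap" and res.n_resamples == 100
        assert 1 / 101 <= res.p_value <= 1.0


class TestQuadformTail:
    @pytest.mark.parametrize("lam,df", [([1.0], 1), ([1.0, 1.0, 1.0], 3)])
    def test_equal_weights_reduce_to_chi_square(self, lam, df):
        for x in (0.5, 2.0, 5.0, 10.0):
            assert chi2_mixture_sf(x, np.array(lam)) == pytest.approx(
                stats.chi2.sf(x, df), abs=1e-6
            )

    def test_unequal_weights_match_simulation(self):
        lam = np.array([4.0, 1.0, 0.25])
        rng = np.random.default_rng(30)
        qs = (rng.standard_normal((400_000, 3)) ** 2 * lam).sum(1)
        for x in (2.0, 10.0, 20.0):
            sim = (qs > x).mean()
            se = np.sqrt(sim * (1 - sim) / qs.size)
            assert abs(chi2_mixture_sf(x, lam) - sim) < 4 * se


class TestNullUniformity:
    def test_null_p_values_are_uniform_for_calibrated_tests(self, null_size_run):
        """Over 5000 null cohorts the p-values of the resampling/LRT tests are
        uniform; the C-alpha permutation p is checked only against
        anti-conservative departures, since ties in its discrete statistic
        make it super-uniform (validly conservative) by construction."""
        _, pvals = null_size_run
        for method in ("TH", "RCS-C", "SK-R"):
            p = pvals[method]
            p = p[~np.isnan(p)]
            assert stats.kstest(p, "uniform").pvalue > 0.001, method
        p = pvals["CA-P"]
        p = p[~np.isnan(p)]
        assert stats.kstest(p, "uniform", alternative="greater").pvalue > 0.001
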