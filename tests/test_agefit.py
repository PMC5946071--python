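"""Age-regression machinery against closed-form and brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methaging import agefit, synthio


def simple_ols_oracle(y, x):
    """Closed-form simple regression: slope, intercept, two-sided p."""
    from scipy import stats

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    s2 = (resid ** 2).sum() / (n - 2)
    se = np.sqrt(s2 / sxx)
    t = slope / se if se > 0 else np.inf
    p = 2 * stats.t.sf(abs(t), n - 2)
    return slope, intercept, p


class TestLinearFit:
    def test_hand_computed_slope(self):
        # Sxy = 7.6, Sxx = 585
        slope, _, _ = agefit.fit_site_linear(
            [0.1, 0.2, 0.4, 0.5], [3, 12, 24, 35])
        assert slope == pytest.approx(7.6 / 585, abs=1e-12)

    def test_constant_fractions_zero_slope(self):
        slope, _, _ = agefit.fit_site_linear([0.3] * 5, [3, 9, 15, 21, 27])
        assert slope == pytest.approx(0.0, abs=1e-14)

    def test_noiseless_line_exact(self):
        ages = np.array([3.0, 9, 15, 21, 27, 35])
        slope, intercept, p = agefit.fit_site_linear(0.2 + 0.01 * ages, ages)
        assert slope == pytest.approx(0.01, abs=1e-12)
        assert intercept == pytest.approx(0.2, abs=1e-12)

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(4, 40)
            x = rng.uniform(1, 40, n)
            y = rng.uniform(0, 1, n)
            slope, intercept, p = agefit.fit_site_linear(y, x)
            s0, i0, p0 = simple_ols_oracle(y, x)
            assert slope == pytest.approx(s0, abs=1e-10)
            assert intercept == pytest.approx(i0, abs=1e-10)
            assert p == pytest.approx(p0, abs=1e-10)

    def test_confounder_changes_fit(self):
        rng = np.random.default_rng(1)
        ages = np.tile([3.0, 12, 24, 35], 5)
        conf = rng.normal(0, 1, 20)
        y = 0.3 + 0.002 * ages + 0.05 * conf
        slope, _, _ = agefit.fit_site_linear(y, ages, conf[:, None])
        assert slope == pytest.approx(0.002, abs=1e-10)

    def test_collinear_design_names_columns(self):
        ages = np.array([3.0, 12, 24, 35])
        with pytest.raises(ValueError, match="confounder_0"):
            agefit.fit_site_linear([0.1, 0.2, 0.3, 0.4], ages, ages[:, None])

    def test_slope_estimates_unbiased(self):
        rng = np.random.default_rng(2)
        ages = np.repeat(np.linspace(3, 35, 16), 4)
        true = rng.choice([-0.005, 0.005], 1000)
        Y = 0.4 + true[:, None] * ages[None, :] + rng.normal(0, 0.05, (1000, len(ages)))
        fit = agefit.fit_linear_many(Y, ages)
        err = fit["slope"].to_numpy() - true
        se_mean = fit["se"].mean() / np.sqrt(1000)
        assert abs(err.mean()) < 2 * se_mean


def bh_oracle(pvals):
    """Brute-force BH step-up."""
    p = np.asarray(pvals, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = running
    return q


class TestBH:
    def test_worked_example(self):
        assert np.allclose(agefit.adjust_pvalues([0.01, 0.02, 0.03]),
                           [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert agefit.adjust_pvalues([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(agefit.adjust_pvalues([1.0, 1.0]), 1.0)

    def test_all_orderings_of_six_pvalues_match_oracle(self):
        base = [0.001, 0.008, 0.039, 0.041, 0.27, 0.9]
        for perm in itertools.permutations(base):
            assert np.allclose(agefit.adjust_pvalues(list(perm)),
                               bh_oracle(perm), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            agefit.adjust_pvalues([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_q_at_least_p_and_monotone(self, pvals):
        q = agefit.adjust_pvalues(pvals)
        p = np.array(pvals)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestTransformGrid:
    def test_noiseless_linear_data_prefers_linear_model(self):
        ages = np.linspace(3, 35, 40)
        m = 0.2 + 0.01 * ages
        models, _, best = agefit.fit_transform_grid(m[None, :], ages)
        assert models[best[0]] == ("age", 1)

    def test_singleton_grid(self):
        ages = np.linspace(3, 35, 20)
        models, _, best = agefit.fit_transform_grid(
            np.random.default_rng(0).uniform(0.2, 0.8, 20)[None, :],
            ages, grid=(1,), responses=("age",))
        assert models[best[0]] == ("age", 1)

    def test_recovers_generating_family_in_identifiable_regime(self):
        # at noise SD 0.002 on m the -13 predictor's noise amplification is
        # small enough for the generating family to dominate the grid
        rng = np.random.default_rng(7)
        ages = np.linspace(3, 35, 100)
        hits = 0
        for _ in range(100):
            m_lo = rng.uniform(0.1, 0.3)
            a, b = synthio.late_accel_from_endpoints(
                3, 35, m_lo, m_lo + rng.uniform(0.15, 0.35))
            m = synthio.simulate_trajectory(
                synthio.SiteClassSpec("late_accel", a=a, b=b), ages)
            noisy = np.clip(m + rng.normal(0, 0.002, 100), 1e-4, 1 - 1e-4)
            models, _, best = agefit.fit_transform_grid(noisy[None, :], ages)
            hits += models[best[0]] == ("age", -13)
        assert hits >= 90

    def test_early_change_prefers_ln_age(self):
        rng = np.random.default_rng(8)
        ages = np.linspace(3, 35, 100)
        m = 0.3 + 0.06 * np.log(ages)
        noisy = np.clip(m + rng.normal(0, 0.002, 100), 0, 1)
        models, _, best = agefit.fit_transform_grid(noisy[None, :], ages)
        assert models[best[0]][0] == "ln_age"


class TestDynamics:
    @pytest.mark.parametrize("resp,power,label", [
        ("age", -13, agefit.DYN_LATE),
        ("age", -5, agefit.DYN_LATE),
        ("ln_age", 1, agefit.DYN_EARLY),
        ("ln_age", -13, agefit.DYN_EARLY),
        ("age", 1, agefit.DYN_LINEAR),
        ("age", -1, agefit.DYN_LINEAR),
    ])
    def test_rule_table(self, resp, power, label):
        assert agefit.classify_dynamics(resp, power) == label

    def test_rejects_nonsignificant(self):
        with pytest.raises(ValueError):
            agefit.classify_dynamics("age", 1, significant=False)


class TestGlobalTrend:
    def test_null_cohort_flat(self):
        rng = np.random.default_rng(3)
        ages = np.repeat([3.0, 12, 24, 35], 6)
        Y = rng.uniform(0.3, 0.7, (200, 24)) * 0 + 0.5 + rng.normal(0, 0.02, (200, 24))
        slope, p = agefit.global_trend(Y, ages)
        assert abs(slope) < 0.002 and p > 0.05

    def test_loss_majority_gives_negative_slope(self):
        ages = np.repeat([3.0, 12, 24, 35], 3)
        gain = 0.3 + 0.005 * ages
        loss = 0.7 - 0.005 * ages
        Y = np.vstack([np.tile(gain, (10, 1)), np.tile(loss, (30, 1))])
        slope, p = agefit.global_trend(Y, ages)
        assert slope < 0

    def test_insufficient_samples_error(self):
        with pytest.raises(ValueError):
            agefit.global_trend(np.array([[0.5], [0.4]]), [3.0])


class TestPermutationCompare:
    def test_identical_sets(self):
        frac = np.random.default_rng(0).uniform(0, 1, (10, 4))
        d, p = agefit.compare_site_set_means([0, 1], [0, 1], frac, n_perm=99)
        assert d == 0 and p == 1.0

    def test_maximal_separation(self):
        frac = np.vstack([np.zeros((100, 3)), np.ones((100, 3))])
        d, p = agefit.compare_site_set_means(
            np.arange(100), np.arange(100, 200), frac, n_perm=9999, seed=1)
        assert d == -1.0 and p == pytest.approx(1 / 10_000)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(4)
        frac = rng.uniform(0, 1, (60, 5))
        r1 = agefit.compare_site_set_means(np.arange(30), np.arange(30, 60),
                                           frac, n_perm=500, seed=11)
        r2 = agefit.compare_site_set_means(np.arange(30), np.arange(30, 60),
                                           frac, n_perm=500, seed=11)
        assert r1 == r2

    def test_rejects_zero_permutations(self):
        with pytest.raises(ValueError):
            agefit.compare_site_set_means([0], [1], np.zeros((2, 2)), n_perm=0)


class TestFitAllSites:
    def test_direction_consistent_with_slope_and_q(self, small_cohort, control_view):
        cmat, ages = control_view
        fits = agefit.fit_all_sites(cmat, ages)
        sig = fits["q"] < 0.05
        assert (fits.loc[~sig, "direction"] == "none").all()
        gain = fits["direction"] == "gain"
        assert (fits.loc[gain, "slope"] > 0).all()
        assert (fits.loc[sig, "dynamics"] != "none").all()
        assert (fits["q"] >= fits["p"] - 1e-12).all()
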