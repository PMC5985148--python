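"""Trend regressions, LOESS, and generalized differencing."""

import numpy as np
import pytest

from canalize.trends import (
    fit_loess,
    fit_ols,
    gen_diff_correlation,
    generalized_differences,
    sample_size_diagnostics,
    spearman_exact,
    subset_regressions,
)

# Reference local-regression values computed once with an independent
# implementation (R 4.3.3 loess, surface="direct") on this fixture.
LOESS_FIXTURE = {
    "x": [
        0.052653045655747244, 0.3568027877359614, 0.43942007961383367,
        1.6021203385784455, 2.1530869823559895, 2.2520718999059186,
        2.548695876541246, 2.7842561210077332, 3.0016628491122543,
        3.0303242681931355, 4.450763058826466, 4.679349528437208,
        5.045482589579533, 5.534973520744924, 6.125396042730308,
        6.221792294411626, 6.2509546660466695, 7.756856902451935,
        7.92661919213753, 7.9706942875204625, 8.212284183827663,
        8.735534453962618, 8.972138009695755, 9.889601476818848,
        9.955002834343926,
    ],
    "y": [
        0.9518814124497934, 0.30782840611048334, 0.770325298086073,
        -0.043444125897874275, -0.5216112986677399, -1.0123183044274153,
        -0.9487638601797513, -1.1814615433737117, -1.1924350989312664,
        -0.72859140141493, -0.4605351545202342, -0.04116386750465874,
        0.548065625252693, 0.5870065058524332, 0.9596515936534542,
        1.0257320766517284, 1.0154260814122475, -0.20929185279659512,
        -0.053538642190403794, 0.2232579950599602, -0.7374712578590805,
        -0.5568816583062952, -0.8694571717736317, -1.054268289640878,
        -0.3625892310253568,
    ],
    "fitted_span075_deg2": [
        0.980954332232, 0.613500231512, 0.520669369238,
        -0.466374824248, -0.725029324564, -0.757406223646,
        -0.829241139439, -0.859855005804, -0.86776991012,
        -0.867367246775, -0.199676154587, 0.003191655855,
        0.372296120657, 0.651468183781, 0.781581113523,
        0.827626567, 0.825289302666, 0.118330896861,
        0.041975049445, 0.021875899997, -0.090571149624,
        -0.347155593582, -0.467931906676, -0.946791714567,
        -0.980721472113,
    ],
    "fitted_span05_deg1": [
        0.839786188487, 0.630806861098, 0.574061876863,
        -0.219815488437, -0.590584913444, -0.657354154872,
        -0.791525196999, -0.819100332539, -0.743194088105,
        -0.73008707065, -0.13027030433, 0.01567863014,
        0.247318429342, 0.556199596839, 0.533137880421,
        0.546566053041, 0.550813218517, -0.031009296779,
        -0.133294931005, -0.155785471538, -0.262233065003,
        -0.463800562653, -0.550017776436, -0.860397052247,
        -0.880824744673,
    ],
}


class TestOls:
    def test_exact_line(self):
        x = np.arange(5.0)
        fit = fit_ols(x, 2 * x)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)

    def test_hand_least_squares(self):
        fit = fit_ols([0, 1, 2], [0, 1, 0])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1 / 3, abs=1e-12)
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(0, 10, 40)
        y = 0.3 - 0.02 * x + rng.normal(0, 0.1, 40)
        fit = fit_ols(x, y)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)
        assert abs(fit.residuals.sum()) < 1e-10

    def test_degenerate_x_fatal(self):
        with pytest.raises(ValueError):
            fit_ols([2, 2, 2], [1, 2, 3])


class TestLoess:
    def test_constant_input_gives_constant_fit(self):
        x = np.linspace(0, 1, 12)
        fit = fit_loess(x, np.full(12, 0.4))
        np.testing.assert_allclose(fit.fitted, 0.4, atol=1e-10)
        assert np.all(fit.se >= 0)

    def test_full_span_degree_one_recovers_line(self):
        x = np.linspace(0, 5, 15)
        fit = fit_loess(x, 1.5 * x - 2.0, span=1.0, degree=1)
        np.testing.assert_allclose(fit.fitted, 1.5 * x - 2.0, atol=1e-8)

    @pytest.mark.parametrize(
        "span,degree,key",
        [(0.75, 2, "fitted_span075_deg2"), (0.5, 1, "fitted_span05_deg1")],
    )
    def test_matches_independent_reference(self, span, degree, key):
        fit = fit_loess(LOESS_FIXTURE["x"], LOESS_FIXTURE["y"],
                        span=span, degree=degree)
        np.testing.assert_allclose(fit.fitted, LOESS_FIXTURE[key], atol=1e-6)

    def test_span_too_small_for_degree_fatal(self):
        with pytest.raises(ValueError, match="span"):
            fit_loess(np.arange(10.0), np.arange(10.0), span=0.2, degree=2)


class TestSubsets:
    def test_empty_exclusion_reproduces_full_fit(self, rng):
        x = rng.uniform(0, 10, 20)
        y = rng.uniform(0.05, 0.5, 20)  # nothing is invariant
        full = fit_ols(x, y)
        sub = subset_regressions(x, y, "exclude_invariant")
        assert sub.slope == pytest.approx(full.slope, abs=1e-12)
        assert sub.n_points == full.n_points

    def test_exclusions_filter_the_right_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([0.0, 0.1, 0.0, 0.3, 0.2, 0.4])
        periods = ["Carboniferous", "Permian", "Permian",
                   "Carboniferous", "Jurassic", "Triassic"]
        inv = subset_regressions(x, y, "exclude_invariant")
        assert inv.n_points == 4
        carb = subset_regressions(x, y, "exclude_bin", periods=periods,
                                  exclude_bin="Carboniferous")
        assert carb.n_points == 4 and carb.label == "exclude_Carboniferous"


class TestGeneralizedDifferences:
    def test_perfectly_linear_series_errors(self):
        t = np.arange(5.0)
        with pytest.raises(ValueError, match="no signal"):
            generalized_differences(2.0 * t + 1.0, t)

    def test_hand_computed_example(self):
        # OLS on (t, y): slope 0.8, intercept 0.5; residuals follow
        gd, rho, e = generalized_differences([1.0, 3.0, 2.0, 4.0],
                                             [1.0, 2.0, 3.0, 4.0])
        np.testing.assert_allclose(e, [-0.3, 0.9, -0.9, 0.3], atol=1e-12)
        assert rho == pytest.approx(-0.75, abs=1e-12)
        np.testing.assert_allclose(gd, [0.675, -0.225, -0.375], atol=1e-12)

    def test_output_length_and_zero_rho_limit(self, rng):
        t = np.arange(12.0)
        y = rng.normal(0, 1, 12)
        gd, rho, e = generalized_differences(y, t)
        assert gd.size == 11
        np.testing.assert_allclose(gd, (e[1:] - rho * e[:-1]), atol=1e-12)

    def test_white_noise_transform_is_unautocorrelated_in_mean(self):
        """Mean lag-1 autocorrelation of the transformed series ~ 0."""
        rng = np.random.default_rng(77)
        t = np.arange(50.0)
        acs = []
        for _ in range(500):
            gd, _, _ = generalized_differences(rng.normal(0, 1, 50), t)
            gdc = gd - gd.mean()
            acs.append(float(gdc[:-1] @ gdc[1:] / (gdc @ gdc)))
        assert abs(np.mean(acs)) < 0.05


class TestCorrelation:
    def test_identical_series_give_rho_one(self, rng):
        t = np.arange(8.0)
        y = rng.normal(0, 1, 8)
        res = gen_diff_correlation(y, y, t)
        assert res.rho == pytest.approx(1.0)

    def test_symmetry_in_the_two_series(self, rng):
        t = np.arange(9.0)
        y1, y2 = rng.normal(0, 1, 9), rng.normal(0, 1, 9)
        a = gen_diff_correlation(y1, y2, t)
        b = gen_diff_correlation(y2, y1, t)
        assert a.rho == pytest.approx(b.rho, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_spearman_exact_monotone_pair(self):
        rho, p = spearman_exact([1, 2, 3, 4, 5], [10, 20, 40, 80, 160])
        assert rho == 1.0
        assert p == pytest.approx(2 / 120)  # two of 5! permutations reach |1|

    def test_exact_p_agrees_with_t_approximation_in_order(self, rng):
        y1, y2 = rng.normal(0, 1, 8), rng.normal(0, 1, 8)
        from scipy.stats import spearmanr

        rho_ex, p_ex = spearman_exact(y1, y2)
        rho_t, _ = spearmanr(y1, y2)
        assert rho_ex == pytest.approx(rho_t, abs=1e-12)
        assert 0.0 <= p_ex <= 1.0

    def test_mismatched_lengths_fatal(self):
        with pytest.raises(ValueError):
            gen_diff_correlation([1, 2, 3], [1, 2, 3, 4], [0, 1, 2, 3])


def test_sample_size_diagnostics_zero_cv_degenerate_case(template_run):
    from canalize.timescale import build_bin_series
    from canalize.variation import SpeciesSummary

    flat = [
        SpeciesSummary(f"s{i}", "Permian", 5 + i, 10, 3.0, 0.0, 0.0, 0.0)
        for i in range(4)
    ] + [
        SpeciesSummary(f"t{i}", "Triassic", 5, 10, 3.0, 0.0, 0.0, 0.0)
        for i in range(4)
    ]
    series = build_bin_series(flat)
    d1, d2 = sample_size_diagnostics(flat, series)
    assert d1.slope == 0.0 and d2.slope == 0.0
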