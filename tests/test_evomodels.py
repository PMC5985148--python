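"""Likelihoods, ML fits and AICc comparison of the three evolution models."""

import math

import numpy as np
import pytest

from canalize.evomodels import (
    aicc,
    akaike_weights,
    compare_modes,
    fit_model,
    loglik,
)
from canalize.simulate import SeriesSimConfig, simulate_cv_series
from canalize.timescale import BinSeries


def make_series(m, eps, dt=1.0, v=None, n=10):
    m = np.asarray(m, dtype=float)
    eps = np.broadcast_to(np.asarray(eps, dtype=float), m.shape).copy()
    B = len(m)
    elapsed = np.arange(B) * dt
    return BinSeries(
        names=[f"b{i}" for i in range(B)],
        t=elapsed[-1] - elapsed,
        elapsed=elapsed,
        m=m,
        v=eps * n,
        n=np.full(B, n),
        eps=eps,
    )


class TestLoglik:
    def test_stasis_joint_iid_density_at_mean(self):
        # all m equal theta, omega=0: logL = B * ln(1/sqrt(2*pi*e))
        e = 0.04
        series = make_series([0.3] * 6, e)
        ll = loglik("Stasis", {"theta": 0.3, "omega": 0.0}, series, "joint")
        assert ll == pytest.approx(6 * math.log(1 / math.sqrt(2 * math.pi * e)), abs=1e-10)

    def test_urw_ad_single_increment_standard_normal(self):
        # one increment d=1 over dt=1 with eps=0, sigma2=1: N(0,1) at 1
        series = make_series([0.0, 1.0], 0.0)
        ll = loglik("URW", {"sigma2_s": 1.0}, series, "ad")
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi) - 0.5, abs=1e-12)

    @pytest.mark.parametrize("parameterization", ["joint", "ad"])
    def test_urw_equals_grw_with_zero_drift(self, parameterization, rng):
        series = make_series(rng.normal(0.2, 0.05, 8), 0.002)
        p_urw = {"sigma2_s": 0.003, "a": 0.2}
        p_grw = {"sigma2_s": 0.003, "a": 0.2, "mu_s": 0.0}
        assert loglik("URW", p_urw, series, parameterization) == pytest.approx(
            loglik("GRW", p_grw, series, parameterization), abs=1e-12
        )

    def test_stasis_joint_equals_per_bin_density_product(self, rng):
        """Diagonal MVN likelihood == product of univariate normal pdfs."""
        from scipy.stats import norm

        m = rng.normal(0.25, 0.08, 9)
        eps = rng.uniform(0.001, 0.01, 9)
        series = make_series(m, eps)
        theta, omega = 0.22, 0.004
        oracle = float(
            np.sum(norm.logpdf(m, loc=theta, scale=np.sqrt(omega + eps)))
        )
        ll = loglik("Stasis", {"theta": theta, "omega": omega}, series, "joint")
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_zero_total_variance_names_offending_bin(self):
        series = make_series([0.1, 0.2, 0.3], 0.0)
        with pytest.raises(ValueError, match="b0"):
            loglik("Stasis", {"theta": 0.2, "omega": 0.0}, series, "joint")


class TestAicc:
    def test_hand_arithmetic(self):
        assert aicc(0.0, 2, 9) == pytest.approx(6.0, abs=1e-12)

    def test_no_penalty_for_zero_parameters(self):
        assert aicc(-3.5, 0, 4) == pytest.approx(7.0)

    def test_strictly_decreasing_in_n(self):
        scores = [aicc(0.0, 2, n) for n in range(4, 40)]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_too_few_observations_fatal(self):
        with pytest.raises(ValueError):
            aicc(0.0, 2, 3)


class TestWeights:
    def test_single_model(self):
        assert akaike_weights([12.3]).tolist() == [1.0]

    def test_hand_evaluation(self):
        w = akaike_weights([6.0, 8.0])
        assert w[0] == pytest.approx(0.731059, abs=1e-6)
        assert w[1] == pytest.approx(0.268941, abs=1e-6)

    def test_sum_to_one_and_shift_invariant(self, rng):
        scores = rng.uniform(10, 40, 5)
        w = akaike_weights(scores)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(w, akaike_weights(scores + 123.4), atol=1e-12)

    def test_minimum_aicc_gets_largest_weight(self, rng):
        scores = rng.uniform(10, 40, 4)
        w = akaike_weights(scores)
        assert np.argmax(w) == np.argmin(scores)


class TestFit:
    def test_constant_series_yields_stasis_at_floor(self):
        series = make_series([0.3] * 8, 0.01)
        fit = fit_model("Stasis", series, "joint", seed=0)
        assert fit.params["theta"] == pytest.approx(0.3, abs=1e-6)
        assert fit.params["omega"] <= 1e-8

    def test_two_point_urw_ad_closed_form_mle(self):
        """For a single increment d over dt with eps=0 the URW MLE is
        sigma2 = d^2/dt; check by maximizing the likelihood on a grid."""
        series = make_series([0.0, 1.0], 0.0)
        grid = np.geomspace(0.01, 100, 20001)
        lls = [loglik("URW", {"sigma2_s": s}, series, "ad") for s in grid]
        assert grid[int(np.argmax(lls))] == pytest.approx(1.0, rel=1e-3)

    def test_fit_is_optimal_against_random_probes(self, rng):
        series = make_series(rng.normal(0.2, 0.1, 10), 0.003)
        for model in ("Stasis", "URW", "GRW"):
            fit = fit_model(model, series, "joint", seed=1,
                            correct_variance_bias=False)
            for _ in range(25):
                if model == "Stasis":
                    probe = {"theta": rng.normal(0.2, 0.1),
                             "omega": rng.uniform(1e-6, 0.05)}
                else:
                    probe = {"a": rng.normal(0.2, 0.1),
                             "sigma2_s": rng.uniform(1e-6, 0.05)}
                    if model == "GRW":
                        probe["mu_s"] = rng.normal(0, 0.02)
                assert fit.logL >= loglik(model, probe, series, "joint") - 1e-6

    def test_variance_bias_correction_scales_raw_mle(self):
        series = make_series(np.linspace(0.1, 0.4, 12), 0.002)
        raw = fit_model("Stasis", series, "joint", seed=0,
                        correct_variance_bias=False)
        cor = fit_model("Stasis", series, "joint", seed=0)
        assert cor.params["omega"] == pytest.approx(
            raw.params["omega"] * 12 / 11, rel=1e-6
        )
        assert cor.logL == pytest.approx(raw.logL, abs=1e-9)

    def test_recovers_stasis_parameters_on_long_series(self):
        cfg = SeriesSimConfig("Stasis", {"theta": 0.2, "omega": 0.01},
                              n_per_bin=20, within_bin_sd=0.05,
                              elapsed=np.arange(50) * 10.0)
        errs = []
        for seed in range(30):
            fit = fit_model("Stasis", simulate_cv_series(cfg, seed=seed),
                            "joint", seed=seed)
            errs.append(abs(fit.params["theta"] - 0.2) / 0.2)
        assert np.median(errs) < 0.05


class TestCompare:
    def test_three_bin_series_reports_insufficient_data(self):
        series = make_series([0.1, 0.2, 0.3], 0.01)
        comp = compare_modes(series)
        assert comp.insufficient and comp.winner is None and comp.fits == []

    def test_weights_sum_to_one_and_winner_has_min_aicc(self, rng):
        series = make_series(rng.normal(0.2, 0.08, 9), 0.002)
        comp = compare_modes(series, seed=3)
        w = [f.akaike_weight for f in comp.fits]
        assert sum(w) == pytest.approx(1.0, abs=1e-12)
        best = min(comp.fits, key=lambda f: f.aicc)
        assert comp.winner == best.model
        assert best.akaike_weight == max(w)

    def test_joint_and_ad_agree_on_strong_directional_signal(self):
        cfg = SeriesSimConfig("GRW", {"mu_s": 0.01, "sigma2_s": 0.0002, "a": 0.2},
                              n_per_bin=25, within_bin_sd=0.05,
                              elapsed=np.arange(20) * 10.0)
        series = simulate_cv_series(cfg, seed=5)
        assert compare_modes(series, "joint", seed=5).winner == "GRW"
        assert compare_modes(series, "ad", seed=5).winner == "GRW"
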