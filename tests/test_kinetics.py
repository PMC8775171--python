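import math

import numpy as np
import pandas as pd
import pytest

from conftest import central_difference
from pulsedigest.kinetics import (
    DigestionTimeCourse,
    FitError,
    FractionalConversionModel,
    KineticFit,
    LagLogisticModel,
    discriminate_models,
    eval_fractional_conversion,
    eval_logistic,
    fit_kinetic_model,
    initial_reaction_rate,
    normalized_digestion_correlation,
)
from pulsedigest.synthetic import generate_digestion_timecourse


def make_fit(model, params, n_obs=9):
    free = [k for k in params]
    return KineticFit(
        model=model, params=params,
        standard_errors={k: 0.0 for k in params},
        covariance=np.zeros((len(free), len(free))), free_names=free,
        sse=0.0, n_obs=n_obs, r2_adjusted=1.0, time_range=(0.0, 180.0),
    )


class TestModelFunctions:
    def test_fractional_conversion_boundaries(self):
        assert eval_fractional_conversion(0.0, 12.0, 90.0, 0.02) == pytest.approx(12.0)
        # half-life construction: k = ln2/30 reaches the midpoint at t = 30
        assert eval_fractional_conversion(30.0, 0.0, 100.0, math.log(2) / 30) == pytest.approx(50.0)
        assert eval_fractional_conversion(2000.0, 0.0, 87.0, 0.01) == pytest.approx(87.0, abs=1e-6)

    def test_logistic_lag_point_and_asymptote(self):
        # at t = lambda the exponent collapses to 2: value is Cf/(1+e^2)
        assert eval_logistic(11.0, 100.0, 1.3, 11.0) == 100.0 / (1.0 + np.exp(2.0))
        assert eval_logistic(1e4, 100.0, 1.3, 11.0) == pytest.approx(100.0)

    def test_logistic_inflection_slope_is_kmax(self):
        cf, kmax, lag = 100.0, 1.3, 11.0
        t_inflection = lag + cf / (2.0 * kmax)  # exponent zero
        slope = central_difference(lambda t: eval_logistic(t, cf, kmax, lag), t_inflection)
        assert slope == pytest.approx(kmax, rel=1e-6)

    def test_curves_monotone(self):
        t = np.linspace(0, 180, 200)
        fc = eval_fractional_conversion(t, 0.0, 90.0, 0.02)
        lg = eval_logistic(t, 100.0, 1.3, 11.0)
        assert np.all(np.diff(fc) > 0) and fc.min() >= 0 and fc.max() <= 90
        assert np.all(np.diff(lg) > 0)


class TestFitting:
    def test_zero_noise_fc_recovery(self):
        t = np.arange(0, 181, 5, dtype=float)
        y = eval_fractional_conversion(t, 0.0, 91.67, 0.018)
        est = FractionalConversionModel(fix_ci=0.0).fit(t, y)
        assert est.params_["Cf"] == pytest.approx(91.67, rel=1e-6)
        assert est.params_["k"] == pytest.approx(0.018, rel=1e-6)
        assert est.r2_adjusted_ == pytest.approx(1.0)

    def test_zero_noise_logistic_recovery(self):
        t = np.arange(0, 181, 5, dtype=float)
        y = eval_logistic(t, 100.0, 1.3, 11.0)
        est = LagLogisticModel().fit(t, y)
        assert est.params_["Cf"] == pytest.approx(100.0, rel=1e-6)
        assert est.params_["kmax"] == pytest.approx(1.3, rel=1e-6)
        assert est.params_["lambda"] == pytest.approx(11.0, rel=1e-6)

    def test_free_ci_estimated(self):
        t = np.arange(0, 181, 10, dtype=float)
        y = eval_fractional_conversion(t, 25.0, 88.73, 0.039)
        est = FractionalConversionModel().fit(t, y)
        assert est.params_["Ci"] == pytest.approx(25.0, rel=1e-6)

    def test_fit_invariant_to_observation_order(self, cp_starch_noiseless):
        tc = cp_starch_noiseless
        shuffled = DigestionTimeCourse(
            analyte=tc.analyte,
            observations=tc.observations.sample(frac=1.0, random_state=4),
            label=tc.label,
        )
        a = fit_kinetic_model(tc, fix_ci=0.0)
        b = fit_kinetic_model(shuffled, fix_ci=0.0)
        assert a.params == pytest.approx(b.params)

    def test_covariance_symmetric_psd(self):
        tc = generate_digestion_timecourse("CP", "starch", seed=8)
        fit = fit_kinetic_model(tc, fix_ci=0.0)
        cov = fit.covariance
        assert np.allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) >= -1e-12)
        assert fit.r2_adjusted <= 1.0

    def test_too_few_observations(self):
        obs = pd.DataFrame({"time_min": [0, 10, 20], "value": [0.0, 1.0, 2.0]})
        tc = DigestionTimeCourse(analyte="starch", observations=obs)
        with pytest.raises(ValueError, match="5 distinct times"):
            fit_kinetic_model(tc)

    def test_logistic_never_beats_fc_on_lag_free_data(self, cp_starch_noiseless):
        """On data generated without a lag the logistic family cannot undercut
        the fractional conversion SSE beyond numerical tolerance."""
        fc = fit_kinetic_model(cp_starch_noiseless, fix_ci=0.0)
        lg = fit_kinetic_model(cp_starch_noiseless, model="logistic")
        assert lg.sse >= fc.sse - 1e-9


class TestInitialRate:
    def test_reported_protein_rate(self):
        fit = make_fit("fractional_conversion", {"Ci": 0.0, "Cf": 36.84, "k": 0.021})
        assert round(initial_reaction_rate(fit), 2) == 0.77

    def test_flat_curve_rate_zero(self):
        fit = make_fit("fractional_conversion", {"Ci": 40.0, "Cf": 40.0, "k": 0.05})
        assert initial_reaction_rate(fit) == 0.0

    @pytest.mark.parametrize(
        "model, params",
        [
            ("fractional_conversion", {"Ci": 0.0, "Cf": 91.67, "k": 0.018}),
            ("logistic", {"Cf": 100.0, "kmax": 1.3, "lambda": 11.0}),
        ],
    )
    def test_matches_central_finite_difference(self, model, params):
        fit = make_fit(model, params)
        numeric = central_difference(lambda t: float(fit.predict(t)), 0.0)
        assert initial_reaction_rate(fit) == pytest.approx(numeric, rel=1e-6)


class TestDiscrimination:
    def test_lagged_data_selects_logistic(self):
        tc = generate_digestion_timecourse("BB", "starch", seed=21, noise_sd=1.0)
        decision = discriminate_models(tc)
        assert decision["choice"] == "logistic"
        lo, hi = decision["diagnostics"]["lambda_ci"]
        assert lo > 0

    def test_lag_free_data_selects_fractional_conversion(self):
        tc = generate_digestion_timecourse("CP", "starch", seed=22, noise_sd=1.0)
        decision = discriminate_models(tc)
        assert decision["choice"] == "fractional_conversion"

    def test_zero_lag_boundary_reports_ci_containing_zero(self):
        t = np.arange(0, 181, 5, dtype=float)
        rng = np.random.default_rng(5)
        y = eval_logistic(t, 100.0, 1.3, 0.0) + rng.normal(0, 1.0, t.size)
        tc = DigestionTimeCourse(
            analyte="starch", observations=pd.DataFrame({"time_min": t, "value": y})
        )
        decision = discriminate_models(tc)
        lo, _hi = decision["diagnostics"]["lambda_ci"]
        assert lo <= 0


class TestNormalizedCorrelation:
    def test_identical_fits_give_identity(self):
        fit = make_fit("fractional_conversion", {"Ci": 0.0, "Cf": 90.0, "k": 0.02})
        res = normalized_digestion_correlation(fit, fit)
        assert res["pearson_r"] == pytest.approx(1.0)
        assert res["starch_normalized"] == pytest.approx(res["protein_normalized"])

    def test_faster_protein_dominates_trajectory(self):
        starch = make_fit("fractional_conversion", {"Ci": 0.0, "Cf": 90.0, "k": 0.01})
        protein = make_fit("fractional_conversion", {"Ci": 0.0, "Cf": 40.0, "k": 0.08})
        res = normalized_digestion_correlation(starch, protein)
        assert np.all(res["protein_normalized"] >= res["starch_normalized"] - 1e-12)

    def test_r_matches_direct_summation(self):
        starch = make_fit("fractional_conversion", {"Ci": 0.0, "Cf": 91.67, "k": 0.018})
        protein = make_fit("fractional_conversion", {"Ci": 5.0, "Cf": 36.84, "k": 0.021})
        res = normalized_digestion_correlation(starch, protein)
        x, y = res["starch_normalized"], res["protein_normalized"]
        xc, yc = x - x.mean(), y - y.mean()
        brute = float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))
        assert res["pearson_r"] == pytest.approx(brute, abs=1e-12)

    def test_nonpositive_plateau_rejected(self):
        good = make_fit("fractional_conversion", {"Ci": 0.0, "Cf": 90.0, "k": 0.02})
        bad = make_fit("fractional_conversion", {"Ci": 0.0, "Cf": -1.0, "k": 0.02})
        with pytest.raises(ValueError, match="Cf"):
            normalized_digestion_correlation(good, bad)
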