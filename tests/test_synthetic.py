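import numpy as np
import pandas as pd
import pytest

from pulsedigest.assay import fit_linear_calibration, quantify_plate
from pulsedigest.kinetics import fit_kinetic_model
from pulsedigest.synthetic import (
    PRESETS,
    PSDMode,
    generate_assay_plate,
    generate_digestion_timecourse,
    generate_hardness_measurements,
    generate_psd,
    truth_curve,
)
from pulsedigest.texture import fit_hardness_profile


class TestDigestionGenerator:
    def test_zero_noise_equals_truth(self, cp_starch_noiseless):
        tc = cp_starch_noiseless
        expected = truth_curve("CP", "starch", tc.times)
        np.testing.assert_allclose(tc.values, expected)

    def test_fixed_seed_reproducible(self):
        a = generate_digestion_timecourse("PE", "starch", seed=42)
        b = generate_digestion_timecourse("PE", "starch", seed=42)
        pd.testing.assert_frame_equal(a.observations, b.observations)
        c = generate_digestion_timecourse("PE", "starch", seed=43)
        assert not np.allclose(b.values, c.values)

    def test_noise_scale_matches_requested_sd(self):
        tc = generate_digestion_timecourse(
            "CP", "starch", seed=44, times=[60.0], noise_sd=2.0, n_replicates=1000
        )
        sd = tc.values.std(ddof=1)
        assert sd == pytest.approx(2.0, rel=0.05)

    def test_unknown_analyte_rejected(self):
        with pytest.raises(KeyError, match="analyte"):
            generate_digestion_timecourse("CP", "fibre", seed=1)


class TestAssayPlateInversion:
    @pytest.fixture()
    def maltose_cal(self):
        return fit_linear_calibration([(0.5, 0.25), (1.0, 0.5), (1.5, 0.75), (2.0, 1.0)])

    def test_zero_noise_round_trip(self, cp_starch_noiseless, maltose_cal):
        totals = {"total_starch": 10.0}  # mg basis
        plate = generate_assay_plate(cp_starch_noiseless, maltose_cal, totals, seed=0)
        recovered = quantify_plate(plate, maltose_cal, totals)
        np.testing.assert_allclose(
            np.sort(recovered.values), np.sort(cp_starch_noiseless.values), atol=1e-9
        )

    def test_zero_percent_gives_blank_level_absorbance(self, maltose_cal, cp_starch_noiseless):
        plate = generate_assay_plate(
            cp_starch_noiseless, maltose_cal, {"total_starch": 10.0}, seed=0
        )
        t0 = plate[plate["time_min"] == 0.0]
        blank = -maltose_cal.intercept / maltose_cal.slope
        np.testing.assert_allclose(t0["absorbance"], blank, atol=1e-12)

    def test_unrepresentable_value_raises(self, maltose_cal, cp_starch_noiseless):
        with pytest.raises(ValueError, match="not representable"):
            generate_assay_plate(
                cp_starch_noiseless, maltose_cal, {"total_starch": 1e9}, seed=0,
                dilutions=(1.0,),
            )

    def test_protein_plate_round_trip(self, maltose_cal):
        tc = generate_digestion_timecourse("CP", "bioaccessible_protein", seed=4, noise_sd=0.0)
        cal = fit_linear_calibration(
            [(12.5, 0.1), (25.0, 0.2), (50.0, 0.4), (100.0, 0.8)], analyte="L-serine"
        )
        totals = {"nh2_total": 80.0, "nh2_initial": 2.0}
        plate = generate_assay_plate(tc, cal, totals, seed=0)
        assert set(plate["assay"]) == {"OPA_TCA"}
        recovered = quantify_plate(plate, cal, totals)
        np.testing.assert_allclose(np.sort(recovered.values), np.sort(tc.values), atol=1e-9)

    def test_noisy_absorbances_unbiased(self, maltose_cal):
        tc = generate_digestion_timecourse(
            "CP", "starch", seed=5, times=[90.0], noise_sd=0.0, n_replicates=400
        )
        plate = generate_assay_plate(
            tc, maltose_cal, {"total_starch": 10.0}, seed=6, absorbance_noise=0.005
        )
        recovered = quantify_plate(plate, maltose_cal, {"total_starch": 10.0})
        truth = float(truth_curve("CP", "starch", 90.0))
        sem = recovered.values.std(ddof=1) / np.sqrt(len(recovered.values))
        assert abs(recovered.values.mean() - truth) < 4 * sem


class TestHardnessGenerator:
    def test_zero_cv_equals_truth(self):
        profile = generate_hardness_measurements("BB", seed=1, cv=0.0)
        means = profile.measurements.groupby("cook_time_min")["force_N"].mean()
        expected = truth_curve("BB", "hardness", means.index.to_numpy())
        np.testing.assert_allclose(means.to_numpy(), expected)

    def test_scatter_proportional_to_mean(self):
        profile = generate_hardness_measurements("BB", seed=2, n_seeds=4000, cv=0.10)
        grouped = profile.measurements.groupby("cook_time_min")["force_N"]
        cv = (grouped.std(ddof=1) / grouped.mean()).to_numpy()
        np.testing.assert_allclose(cv, 0.10, rtol=0.08)

    def test_plateau_means_near_residual_hardness(self):
        profile = generate_hardness_measurements("BB", seed=3, n_seeds=500)
        late = profile.measurements.query("cook_time_min >= 120")
        assert late["force_N"].mean() == pytest.approx(42.0, rel=0.02)


class TestPsdGenerator:
    def test_volumes_sum_to_100_exactly(self):
        dist = generate_psd([PSDMode(30.0, 1.5, 0.2), PSDMode(105.0, 1.08, 0.8)])
        assert dist.volume_percent.sum() == pytest.approx(100.0, abs=1e-9)

    def test_shares_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            generate_psd([PSDMode(30.0, 1.5, 0.4), PSDMode(105.0, 1.1, 0.4)])


@pytest.mark.parametrize("name", sorted(PRESETS))
def test_round_trip_zero_noise_recovers_preset_truth(name):
    """Generation followed by analysis is the identity on preset truths."""
    preset = PRESETS[name]
    for analyte, truth in preset.kinetics.items():
        if analyte == "hardness":
            profile = generate_hardness_measurements(name, seed=0, cv=0.0)
            fit = fit_hardness_profile(profile)
        else:
            tc = generate_digestion_timecourse(name, analyte, seed=0, noise_sd=0.0)
            if truth.model == "logistic":
                fit = fit_kinetic_model(tc, model="logistic")
            else:
                fix = truth.params["Ci"] if analyte == "starch" else None
                fit = fit_kinetic_model(tc, fix_ci=fix)
        for pname, pvalue in truth.params.items():
            assert fit.params[pname] == pytest.approx(pvalue, rel=1e-6, abs=1e-9), (
                name, analyte, pname,
            )
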