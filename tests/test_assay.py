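import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pulsedigest.assay import (
    CalibrationError,
    CalibrationCurve,
    ProteinAssayReadings,
    StarchAssayReading,
    digested_soluble_protein_percent,
    digested_starch_percent,
    fit_linear_calibration,
    quantify_plate,
    readily_bioaccessible_protein_percent,
)


class TestCalibration:
    def test_exact_line_recovered(self):
        standards = [(2 * a, a) for a in (0.25, 0.5, 0.75, 1.0)]
        cal = fit_linear_calibration(standards)
        assert cal.slope == pytest.approx(2.0)
        assert cal.intercept == pytest.approx(0.0, abs=1e-12)
        assert cal.r_squared == pytest.approx(1.0)

    def test_noisy_slope_within_three_se(self):
        # closed-form OLS oracle: SE(slope) = sigma_hat / sqrt(Sxx)
        rng = np.random.default_rng(11)
        absorbance = np.linspace(0.1, 1.0, 8)
        conc = 2.0 * absorbance + rng.normal(0, 0.02, absorbance.size)
        cal = fit_linear_calibration(list(zip(conc, absorbance)))
        resid = conc - (cal.slope * absorbance + cal.intercept)
        sigma2 = resid @ resid / (len(conc) - 2)
        sxx = np.sum((absorbance - absorbance.mean()) ** 2)
        se_slope = np.sqrt(sigma2 / sxx)
        assert abs(cal.slope - 2.0) < 3 * se_slope

    def test_too_few_or_degenerate_standards(self):
        with pytest.raises(CalibrationError):
            fit_linear_calibration([(1.0, 0.5), (2.0, 1.0)])
        with pytest.raises(CalibrationError):
            fit_linear_calibration([(1.0, 0.5)] * 4)

    def test_out_of_range_extrapolates_with_warning(self):
        cal = CalibrationCurve("maltose", slope=2.0, intercept=0.0, valid_range=(0.5, 2.0))
        with pytest.warns(UserWarning, match="extrapolating"):
            assert cal.concentration(5.0) == pytest.approx(10.0)


class TestStarchPercent:
    @pytest.mark.parametrize(
        "maltose, total, expected",
        [
            (50.0, 50.0, 95.0),  # the 0.95 disaccharide->starch factor
            (0.0, 50.0, 0.0),
            (42.1, 50.0, 79.99),  # 42.1 * 0.95 / 50 * 100
        ],
    )
    def test_values(self, maltose, total, expected):
        r = StarchAssayReading(maltose_equivalents=maltose, total_starch=total)
        assert digested_starch_percent(r) == pytest.approx(expected)

    def test_zero_total_starch_rejected(self):
        with pytest.raises(ZeroDivisionError):
            StarchAssayReading(maltose_equivalents=1.0, total_starch=0.0)

    @given(st.floats(0, 100), st.floats(0, 100), st.floats(1, 200))
    def test_linear_in_maltose(self, m1, m2, total):
        p1 = digested_starch_percent(StarchAssayReading(m1, total))
        p2 = digested_starch_percent(StarchAssayReading(m2, total))
        p_sum = digested_starch_percent(StarchAssayReading(m1 + m2, total))
        assert p_sum == pytest.approx(p1 + p2, abs=1e-9)


class TestProteinPercents:
    @pytest.mark.parametrize(
        "initial, total, hydrolyzed, expected",
        [(5.0, 100.0, 5.0, 0.0), (0.0, 100.0, 100.0, 100.0), (10.0, 200.0, 110.0, 50.0)],
    )
    def test_soluble_values(self, initial, total, hydrolyzed, expected):
        r = ProteinAssayReadings(nh2_initial=initial, nh2_total=total,
                                 nh2_hydrolyzed=hydrolyzed, nh2_tca=hydrolyzed)
        assert digested_soluble_protein_percent(r) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "initial, total, tca, expected", [(5.0, 100.0, 5.0, 0.0), (0.0, 100.0, 37.0, 37.0)]
    )
    def test_bioaccessible_values(self, initial, total, tca, expected):
        r = ProteinAssayReadings(nh2_initial=initial, nh2_total=total,
                                 nh2_hydrolyzed=total, nh2_tca=tca)
        assert readily_bioaccessible_protein_percent(r) == pytest.approx(expected)

    def test_zero_total_rejected(self):
        r = ProteinAssayReadings(nh2_initial=0.0, nh2_total=0.0,
                                 nh2_hydrolyzed=0.0, nh2_tca=0.0)
        with pytest.raises(ZeroDivisionError):
            digested_soluble_protein_percent(r)

    def test_below_baseline_flagged_not_fatal(self):
        with pytest.warns(UserWarning):
            r = ProteinAssayReadings(nh2_initial=10.0, nh2_total=100.0,
                                     nh2_hydrolyzed=8.0, nh2_tca=8.0)
        with pytest.warns(UserWarning, match="negative"):
            assert digested_soluble_protein_percent(r) == pytest.approx(-2.0)

    @given(
        st.floats(0, 10),
        st.floats(50, 200),
        st.floats(0, 40),
        st.floats(0, 40),
        st.floats(0.01, 100),
    )
    def test_tca_never_exceeds_hydrolyzed_fraction_and_rescaling(
        self, initial, total, d_tca, extra, scale
    ):
        """TCA-soluble digestion <= fully hydrolysed digestion whenever the
        TCA reading is the smaller; both are invariant to a common rescale."""
        tca = initial + d_tca
        hydrolyzed = tca + extra
        r = ProteinAssayReadings(initial, total, hydrolyzed, tca)
        bio = readily_bioaccessible_protein_percent(r)
        sol = digested_soluble_protein_percent(r)
        assert bio <= sol + 1e-9
        scaled = ProteinAssayReadings(
            initial * scale, total * scale, hydrolyzed * scale, tca * scale
        )
        assert readily_bioaccessible_protein_percent(scaled) == pytest.approx(bio, abs=1e-6)
        assert digested_soluble_protein_percent(scaled) == pytest.approx(sol, abs=1e-6)


def test_quantify_plate_rejects_mixed_assays():
    import pandas as pd

    plate = pd.DataFrame(
        {"sample_id": ["a", "a"], "time_min": [0, 5], "assay": ["DNS", "OPA_TCA"],
         "absorbance": [0.1, 0.2], "dilution_factor": [1, 1]}
    )
    cal = CalibrationCurve("maltose", slope=2.0, intercept=0.0, valid_range=(0.0, 10.0))
    with pytest.raises(ValueError, match="single assay"):
        quantify_plate(plate, cal, {"total_starch": 10.0})
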