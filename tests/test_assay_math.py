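"""Assay unit calculations: TRU, standard-curve activity, haemolysis, clotting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vespaquant.assay_math import (
    AssayMeasurement,
    ClottingResult,
    StandardCurve,
    clotting_delay,
    relative_haemolysis,
    specific_activity_from_curve,
    turbidity_reduction_units,
)
from vespaquant.errors import DegenerateDataError, ValidationError


class TestTurbidityReductionUnits:
    def test_half_reduction_is_one_tru(self):
        m = AssayMeasurement(a_sample=0.5, a_control=1.0)
        assert turbidity_reduction_units(m) == pytest.approx(1.0)

    def test_no_reduction_is_zero(self):
        m = AssayMeasurement(a_sample=1.0, a_control=1.0)
        assert turbidity_reduction_units(m) == 0.0

    def test_microgram_scale_dose_and_incubation(self):
        # 2.5 ug venom over 20 min: 1 TRU / (0.0025 mg * 20 min) = 20
        m = AssayMeasurement(
            a_sample=0.5, a_control=1.0, venom_mass_mg=0.0025,
            incubation_time_min=20.0,
        )
        assert turbidity_reduction_units(m) == pytest.approx(20.0)

    def test_negative_reduction_warns_and_reports_zero(self):
        m = AssayMeasurement(a_sample=1.2, a_control=1.0)
        with pytest.warns(UserWarning, match="exceeds control"):
            assert turbidity_reduction_units(m) == 0.0

    def test_missing_control_rejected(self):
        with pytest.raises(ValidationError):
            turbidity_reduction_units(AssayMeasurement(a_sample=0.5))

    @given(st.floats(0.001, 10), st.floats(0.1, 120))
    def test_scales_inversely_with_mass_and_time(self, mass, minutes):
        base = turbidity_reduction_units(
            AssayMeasurement(a_sample=0.25, a_control=1.0)
        )
        scaled = turbidity_reduction_units(
            AssayMeasurement(
                a_sample=0.25, a_control=1.0,
                venom_mass_mg=mass, incubation_time_min=minutes,
            )
        )
        assert scaled == pytest.approx(base / (mass * minutes), rel=1e-12)


class TestStandardCurve:
    def test_two_point_curve_is_exact(self):
        curve = StandardCurve.fit([(0.0, 0.0), (10.0, 1.0)])
        assert curve.slope == pytest.approx(0.1)
        assert curve.intercept == pytest.approx(0.0, abs=1e-15)
        assert all(abs(r) < 1e-12 for r in curve.residuals)

    def test_specific_activity_hand_example(self):
        curve = StandardCurve.fit([(0.0, 0.0), (10.0, 1.0)])
        m = AssayMeasurement(
            a_sample=0.5, venom_mass_mg=0.005, incubation_time_min=40.0
        )
        assert specific_activity_from_curve(curve, m) == pytest.approx(25.0)

    def test_absorbance_at_intercept_gives_zero(self):
        curve = StandardCurve.fit([(0.0, 0.2), (10.0, 1.2)])
        m = AssayMeasurement(a_sample=0.2)
        assert specific_activity_from_curve(curve, m) == pytest.approx(0.0, abs=1e-12)

    def test_zero_slope_unusable(self):
        curve = StandardCurve.fit([(0.0, 1.0), (10.0, 1.0)])
        with pytest.raises(DegenerateDataError):
            specific_activity_from_curve(curve, AssayMeasurement(a_sample=0.5))

    def test_extrapolation_beyond_range_warns(self):
        curve = StandardCurve.fit([(0.0, 0.0), (10.0, 1.0)])
        with pytest.warns(UserWarning, match="extrapolated"):
            specific_activity_from_curve(curve, AssayMeasurement(a_sample=2.0))

    def test_noise_free_recovery_on_many_points(self):
        # planted line A = 0.05*nmol + 0.1, read back exactly
        amounts = np.linspace(0, 50, 12)
        curve = StandardCurve.fit([(a, 0.05 * a + 0.1) for a in amounts])
        m = AssayMeasurement(a_sample=0.05 * 30 + 0.1, venom_mass_mg=2.0,
                             incubation_time_min=3.0)
        assert specific_activity_from_curve(curve, m) == pytest.approx(30 / 6.0)

    def test_degenerate_points_rejected(self):
        with pytest.raises(ValidationError):
            StandardCurve.fit([(5.0, 1.0), (5.0, 2.0)])
        with pytest.raises(ValidationError):
            StandardCurve.fit([(5.0, 1.0)])


class TestRelativeHaemolysis:
    def test_positive_control_is_100_percent(self):
        m = AssayMeasurement(a_sample=1.4, a_blank=0.1, a_positive=1.4)
        assert relative_haemolysis(m) == pytest.approx(100.0)

    def test_blank_is_0_percent(self):
        m = AssayMeasurement(a_sample=0.1, a_blank=0.1, a_positive=1.4)
        assert relative_haemolysis(m) == pytest.approx(0.0)

    def test_midpoint_is_50_percent(self):
        m = AssayMeasurement(a_sample=0.75, a_blank=0.1, a_positive=1.4)
        assert relative_haemolysis(m) == pytest.approx(50.0)

    def test_invalid_positive_control_rejected(self):
        m = AssayMeasurement(a_sample=0.5, a_blank=0.6, a_positive=0.5)
        with pytest.raises(ValidationError):
            relative_haemolysis(m)

    def test_uncorrected_mode_ignores_blank(self):
        m = AssayMeasurement(a_sample=0.7, a_blank=0.1, a_positive=1.4)
        assert relative_haemolysis(m, blank_corrected=False) == pytest.approx(50.0)

    @given(st.floats(0.0, 5.0), st.floats(0.01, 2.0), st.floats(0.0, 3.0))
    def test_affine_invariance(self, shift, span, sample_offset):
        blank, positive = 0.2, 0.2 + span
        sample = blank + sample_offset * span
        base = relative_haemolysis(
            AssayMeasurement(a_sample=sample, a_blank=blank, a_positive=positive)
        )
        shifted = relative_haemolysis(
            AssayMeasurement(
                a_sample=sample + shift, a_blank=blank + shift,
                a_positive=positive + shift,
            )
        )
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestClottingDelay:
    def test_anticoagulant_fold_change(self):
        d = clotting_delay(ClottingResult(control_time_s=32.0, venom_time_s=235.0))
        assert d.delay_s == pytest.approx(203.0)
        assert d.fold == pytest.approx(235 / 32)
        assert not d.censored

    def test_no_effect_is_unity(self):
        d = clotting_delay(ClottingResult(control_time_s=30.0, venom_time_s=30.0))
        assert d.delay_s == 0.0 and d.fold == 1.0

    def test_censored_result_is_lower_bound(self):
        d = clotting_delay(
            ClottingResult(
                control_time_s=32.0, venom_time_s=1800.0,
                censored=True, censoring_limit_s=1800.0,
            )
        )
        assert d.fold == pytest.approx(56.25)
        assert d.censored

    def test_censoring_consistency_enforced(self):
        with pytest.raises(ValidationError):
            ClottingResult(
                control_time_s=30.0, venom_time_s=100.0,
                censored=True, censoring_limit_s=1800.0,
            )


def test_measurement_invariants():
    with pytest.raises(ValidationError):
        AssayMeasurement(a_sample=-0.1)
    with pytest.raises(ValidationError):
        AssayMeasurement(a_sample=0.1, venom_mass_mg=0.0)
    with pytest.raises(ValidationError):
        AssayMeasurement(a_sample=0.1, incubation_time_min=0.0)
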