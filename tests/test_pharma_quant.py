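"""Calibration, recovery correction, and removal mass balance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from granulefate.errors import CalibrationError, DataError, RecoveryError
from granulefate.pharma_quant import (
    SpikeRecoverySet,
    compute_recovery,
    concentration_factor,
    correct_for_recovery,
    correct_measurements,
    fit_calibration,
    quantify,
    removal_percent,
    removal_series,
    solid_phase_concentration,
    total_nitrogen_removal,
)


class TestCalibration:
    def test_two_point_exact_fit(self):
        curve = fit_calibration([(0, 0), (100, 1000)])
        assert curve.slope == pytest.approx(10.0)
        assert curve.intercept == pytest.approx(0.0)
        assert curve.r_squared == pytest.approx(1.0)

    def test_collinear_points_with_intercept(self):
        # hand least squares: perfectly collinear, slope 10, intercept 5
        curve = fit_calibration([(0, 5), (50, 505), (100, 1005)])
        assert curve.slope == pytest.approx(10.0)
        assert curve.intercept == pytest.approx(5.0)
        assert curve.r_squared == pytest.approx(1.0)

    def test_degenerate_inputs(self):
        with pytest.raises(CalibrationError):
            fit_calibration([(50, 100), (50, 200)])  # one nominal level
        with pytest.raises(CalibrationError):
            fit_calibration([(0, 100), (50, 100), (100, 100)])  # flat areas

    def test_quantify_inverts_curve(self):
        curve = fit_calibration([(0, 0), (100, 1000)])
        assert quantify(1000.0, curve).conc == pytest.approx(100.0)
        q0 = quantify(curve.intercept, curve)
        assert q0.conc == 0.0 and not q0.below_range

    def test_quantify_below_intercept_clips_and_flags(self):
        curve = fit_calibration([(0, 50), (100, 1050)])
        q = quantify(10.0, curve)
        assert q.conc == 0.0 and q.below_range

    def test_calibration_quantify_round_trip_on_standards(self):
        pts = [(0.0, 12.0), (25.0, 262.0), (100.0, 1012.0)]
        curve = fit_calibration(pts)
        for nominal, area in pts:
            assert quantify(area, curve).conc == pytest.approx(nominal, abs=1e-9)


class TestConcentrationFactor:
    def test_worked_example(self):
        assert concentration_factor(100.0, 1.0) == 100.0

    def test_identity_and_scaling(self):
        assert concentration_factor(7.0, 7.0) == 1.0
        assert concentration_factor(50.0, 2.0) == 25.0

    @pytest.mark.parametrize("loaded,extract", [(0, 1), (1, 0), (-5, 1)])
    def test_nonpositive_volumes(self, loaded, extract):
        with pytest.raises(DataError):
            concentration_factor(loaded, extract)


class TestRecovery:
    def test_perfect_recovery(self):
        s = SpikeRecoverySet(150.0, 50.0, 150.0)
        assert compute_recovery(s) == pytest.approx(1.0)

    def test_hand_evaluated_formula(self):
        s = SpikeRecoverySet(140.0, 45.0, 145.0)
        assert compute_recovery(s) == pytest.approx(0.95)

    def test_total_loss_and_undefined(self):
        assert compute_recovery(SpikeRecoverySet(50.0, 50.0, 150.0)) == 0.0
        with pytest.raises(RecoveryError):
            compute_recovery(SpikeRecoverySet(150.0, 100.0, 100.0))

    def test_over_recovery_propagates_unclipped(self):
        # over-recovery (e.g. matrix enhancement) is legitimate, ~117 %
        s = SpikeRecoverySet(162.0, 45.0, 145.0)
        assert compute_recovery(s) == pytest.approx(1.17)

    def test_correct_for_recovery_examples(self):
        assert correct_for_recovery(80.0, 0.8) == pytest.approx(100.0)
        assert correct_for_recovery(55.5, 1.0) == 55.5
        assert correct_for_recovery(117.0, 1.17) == pytest.approx(100.0)
        with pytest.raises(RecoveryError):
            correct_for_recovery(10.0, 0.0)
        with pytest.raises(RecoveryError):
            correct_for_recovery(10.0, 2.5)

    @settings(derandomize=True, max_examples=100)
    @given(
        true=st.floats(min_value=0.0, max_value=1e4),
        r=st.floats(min_value=1e-6, max_value=2.0),
    )
    def test_recovery_round_trip(self, true, r):
        assert correct_for_recovery(true * r, r) == pytest.approx(
            true, rel=1e-12, abs=1e-9
        )


class TestRemoval:
    @pytest.mark.parametrize(
        "influent,effluent,expected",
        [(150, 0, 100.0), (150, 150, 0.0), (150, 300, -100.0)],
    )
    def test_sign_convention(self, influent, effluent, expected):
        assert removal_percent(influent, effluent) == pytest.approx(expected)

    def test_zero_influent_is_flagged_undefined(self):
        assert np.isnan(removal_percent(0.0, 10.0))

    @settings(derandomize=True, max_examples=100)
    @given(
        inf=st.floats(min_value=1e-3, max_value=1e4),
        eff=st.floats(min_value=0.0, max_value=1e4),
        k=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scale_invariance(self, inf, eff, k):
        assert removal_percent(k * inf, k * eff) == pytest.approx(
            removal_percent(inf, eff), rel=1e-9, abs=1e-9
        )

    def test_removal_series_from_tidy_table(self):
        conc = pd.DataFrame(
            {
                "compound": ["DCF"] * 4,
                "day": [0, 0, 5, 5],
                "phase": ["influent", "effluent"] * 2,
                "corrected_conc": [150.0, 75.0, 150.0, 300.0],
            }
        )
        out = removal_series(conc)
        assert out["removal_percent"].tolist() == pytest.approx([50.0, -100.0])
        assert out["defined"].all()


class TestTotalNitrogen:
    def test_hand_arithmetic(self):
        assert total_nitrogen_removal(
            {"NH3-N": 40, "NO2-N": 5, "NO3-N": 5},
            {"NH3-N": 10, "NO2-N": 2, "NO3-N": 3},
        ) == pytest.approx(70.0)

    def test_all_removed_and_ammonia_only_reduction(self):
        assert total_nitrogen_removal([50, 0, 0], [0, 0, 0]) == 100.0
        tn = total_nitrogen_removal([50, 0, 0], [15, 0, 0])
        assert tn == pytest.approx(removal_percent(50, 15))

    def test_missing_species_rejected(self):
        with pytest.raises(DataError):
            total_nitrogen_removal({"NH3-N": 40}, {"NH3-N": 10})


class TestSolidPhase:
    def test_unit_arithmetic(self):
        assert solid_phase_concentration(100.0, 10.0, 1.0) == pytest.approx(1.0)
        assert solid_phase_concentration(0.0, 10.0, 1.0) == 0.0

    def test_dry_weight_scaling(self):
        one = solid_phase_concentration(100.0, 10.0, 1.0)
        assert solid_phase_concentration(100.0, 10.0, 2.0) == pytest.approx(one / 2)

    def test_nonpositive_dry_weight(self):
        with pytest.raises(DataError):
            solid_phase_concentration(100.0, 10.0, 0.0)


def test_correct_measurements_table():
    conc = pd.DataFrame(
        {
            "compound": ["DCF", "DCF", "ERY"],
            "phase": ["influent", "solid", "effluent"],
            "raw_conc": [97.0, 75.0, 117.0],
        }
    )
    rec = pd.DataFrame(
        {
            "compound": ["DCF", "DCF", "ERY"],
            "phase": ["aqueous", "solid", "aqueous"],
            "recovery_mean": [0.97, 0.75, 1.17],
        }
    )
    out = correct_measurements(conc, rec)
    assert out["corrected_conc"].tolist() == pytest.approx([100.0, 100.0, 100.0])
    with pytest.raises(DataError):
        correct_measurements(conc.assign(compound="GEM"), rec)
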