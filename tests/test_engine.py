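import math

import numpy as np
import pytest

from retmod.engine import (
    LSSCoefficients,
    elution_state,
    predict_peak,
    predict_peak_width,
    predict_retention_time,
    retention_factor,
)
from retmod.errors import InvalidConfigurationError
from retmod.system import ColumnSpec, GradientProgram, InstrumentSpec, RunConditions


def closed_form_single_ramp_rt(
    log_kw: float,
    S: float,
    phi0: float,
    phif: float,
    tG: float,
    t0: float,
    td: float,
) -> float:
    """Independent oracle: the closed-form LSS retention time for a single
    linear ramp with dwell delay and final-composition hold.

    Piecewise: elution during the dwell (isocratic at phi0), during the ramp
    (the LSS dwell equation) or during the post-program hold (isocratic at
    phif after subtracting the fraction migrated earlier).
    """
    k0 = 10.0 ** (log_kw - S * phi0)
    if t0 * k0 <= td:
        return t0 + t0 * k0
    b = t0 * S * (phif - phi0) / tG
    te = td + (t0 / b) * math.log10(
        math.log(10.0) * k0 * b * (1.0 - td / (t0 * k0)) + 1.0
    )
    if te <= td + tG:
        return t0 + te
    frac_dwell = td / (t0 * k0)
    frac_ramp = (10.0 ** (b * tG / t0) - 1.0) / (k0 * b * math.log(10.0))
    kf = 10.0 ** (log_kw - S * phif)
    remaining = 1.0 - frac_dwell - frac_ramp
    return t0 + td + tG + remaining * t0 * kf


@pytest.fixture(scope="module")
def setup():
    column = ColumnSpec(t0_min=5.65, t0_flow_ml_min=0.5)
    instrument = InstrumentSpec(dwell_volume_ml=1.0)
    conditions = RunConditions(flow_ml_min=0.5, temperature_c=25.0)
    return column, instrument, conditions


class TestRetentionFactor:
    def test_direct_evaluation(self):
        assert retention_factor(LSSCoefficients(3.0, 4.0), 0.5) == pytest.approx(10.0)

    def test_phi_zero_limit(self):
        assert retention_factor(LSSCoefficients(3.0, 4.0), 0.0) == pytest.approx(1000.0)

    def test_degenerate_slope_is_composition_independent(self):
        c = LSSCoefficients(2.0, 0.0)
        assert retention_factor(c, 0.1) == retention_factor(c, 0.9) == pytest.approx(100.0)

    def test_negative_slope_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            LSSCoefficients(3.0, -1.0)


class TestGradientSolver:
    def test_isocratic_identity(self, setup):
        # S = 0, k = 4: the program is irrelevant, tR = t0 (1 + k)
        column, instrument, conditions = setup
        col5 = ColumnSpec(t0_min=5.0, t0_flow_ml_min=0.5)
        for prog in (
            GradientProgram.linear(0.3, 1.0, 20.0),
            GradientProgram.linear(0.1, 0.9, 60.0),
            GradientProgram([(0.0, 0.5), (10.0, 0.8), (30.0, 1.0)]),
        ):
            tr = predict_retention_time(
                LSSCoefficients(math.log10(4.0), 0.0), prog, conditions, col5, instrument
            )
            assert tr == pytest.approx(25.0, abs=1e-9)

    def test_unretained_limit(self, setup):
        column, instrument, conditions = setup
        col5 = ColumnSpec(t0_min=5.0, t0_flow_ml_min=0.5)
        prog = GradientProgram.linear(0.3, 1.0, 20.0)
        tr = predict_retention_time(
            LSSCoefficients(-6.0, 4.0), prog, conditions, col5, instrument
        )
        assert tr == pytest.approx(5.0, abs=1e-3)

    def test_matches_closed_form_worked_case(self, setup):
        column, instrument, conditions = setup
        prog = GradientProgram.linear(0.30, 1.00, 20.0)
        tr = predict_retention_time(
            LSSCoefficients(3.0, 4.0), prog, conditions, column, instrument
        )
        assert tr == pytest.approx(22.38, abs=1e-2)
        oracle = closed_form_single_ramp_rt(3.0, 4.0, 0.30, 1.00, 20.0, 5.65, 2.0)
        assert tr == pytest.approx(oracle, abs=1e-3)

    @pytest.mark.parametrize("tG", [20.0, 60.0])
    @pytest.mark.parametrize("td", [0.0, 2.0])
    def test_solver_equals_closed_form_over_sweep(self, setup, tG, td):
        column, _, conditions = setup
        instrument = InstrumentSpec(dwell_volume_ml=td * 0.5)
        prog = GradientProgram.linear(0.30, 1.00, tG)
        for log_kw in np.linspace(1.0, 5.0, 9):
            for S in np.linspace(2.0, 10.0, 9):
                tr = predict_retention_time(
                    LSSCoefficients(log_kw, S), prog, conditions, column, instrument
                )
                oracle = closed_form_single_ramp_rt(
                    log_kw, S, 0.30, 1.00, tG, 5.65, td
                )
                assert tr == pytest.approx(oracle, abs=1e-3), (log_kw, S, tG, td)

    def test_tr_never_below_t0(self, setup):
        column, instrument, conditions = setup
        prog = GradientProgram.linear(0.30, 1.00, 20.0)
        for log_kw in (-8.0, -2.0, 0.0, 2.0, 5.0):
            tr = predict_retention_time(
                LSSCoefficients(log_kw, 5.0), prog, conditions, column, instrument
            )
            assert tr >= 5.65 - 1e-9

    def test_monotone_in_initial_phi(self, setup):
        column, instrument, conditions = setup
        c = LSSCoefficients(3.0, 5.0)
        trs = [
            predict_retention_time(
                c, GradientProgram.linear(phi0, 1.0, 20.0), conditions, column, instrument
            )
            for phi0 in (0.2, 0.3, 0.4, 0.5)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(trs, trs[1:]))

    def test_monotone_in_gradient_time(self, setup):
        column, instrument, conditions = setup
        c = LSSCoefficients(3.0, 5.0)
        trs = [
            predict_retention_time(
                c, GradientProgram.linear(0.3, 1.0, tG), conditions, column, instrument
            )
            for tG in (20.0, 30.0, 45.0, 60.0)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(trs, trs[1:]))

    def test_monotone_in_flow(self, setup):
        column, instrument, _ = setup
        c = LSSCoefficients(3.0, 5.0)
        prog = GradientProgram.linear(0.3, 1.0, 20.0)
        trs = [
            predict_retention_time(
                c, prog, RunConditions(flow_ml_min=f, temperature_c=25.0),
                column, instrument,
            )
            for f in (0.4, 0.5, 0.7, 1.0)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(trs, trs[1:]))

    def test_increasing_in_log_kw(self, setup):
        column, instrument, conditions = setup
        prog = GradientProgram.linear(0.3, 1.0, 20.0)
        trs = [
            predict_retention_time(
                LSSCoefficients(lkw, 5.0), prog, conditions, column, instrument
            )
            for lkw in (1.0, 2.0, 3.0, 4.0)
        ]
        assert all(b > a for a, b in zip(trs, trs[1:]))

    def test_multisegment_program_continuity(self, setup):
        # a two-segment ramp that happens to be collinear equals one segment
        column, instrument, conditions = setup
        c = LSSCoefficients(3.0, 4.0)
        one = GradientProgram.linear(0.30, 1.00, 20.0)
        two = GradientProgram([(0.0, 0.30), (10.0, 0.65), (20.0, 1.00)])
        tr1 = predict_retention_time(c, one, conditions, column, instrument)
        tr2 = predict_retention_time(c, two, conditions, column, instrument)
        assert tr1 == pytest.approx(tr2, abs=1e-9)


class TestElutionState:
    def test_isocratic_elution_k(self, setup):
        column, instrument, conditions = setup
        prog = GradientProgram.linear(0.3, 1.0, 20.0)
        phi_e, k_e = elution_state(
            LSSCoefficients(math.log10(4.0), 0.0), prog, conditions, column, instrument
        )
        assert k_e == pytest.approx(4.0)

    def test_unretained_elutes_at_initial_phi(self, setup):
        column, instrument, conditions = setup
        prog = GradientProgram.linear(0.3, 1.0, 20.0)
        phi_e, _ = elution_state(
            LSSCoefficients(-6.0, 4.0), prog, conditions, column, instrument
        )
        assert phi_e == pytest.approx(0.30, abs=1e-6)

    def test_elution_phi_consistent_with_retention_time(self, setup):
        # phi at elution equals the inlet composition evaluated at t_e
        from retmod.system import inlet_composition

        column, instrument, conditions = setup
        prog = GradientProgram.linear(0.30, 1.00, 20.0)
        c = LSSCoefficients(3.0, 4.0)
        tr = predict_retention_time(c, prog, conditions, column, instrument)
        phi_e, _ = elution_state(c, prog, conditions, column, instrument)
        assert phi_e == pytest.approx(
            inlet_composition(prog, instrument, 0.5, tr - 5.65), abs=1e-9
        )


class TestPeakWidth:
    def test_hand_arithmetic(self):
        assert predict_peak_width(1.0, 5.0, 10000) == pytest.approx(0.4)

    def test_unretained_width(self):
        assert predict_peak_width(0.0, 5.0, 10000) == pytest.approx(4 * 5.0 / 100.0)

    def test_compression_scales_linearly(self):
        assert predict_peak_width(1.0, 5.0, 10000, compression=0.85) == pytest.approx(0.34)

    def test_invalid_plate_count(self):
        with pytest.raises(InvalidConfigurationError):
            predict_peak_width(1.0, 5.0, 0.0)

    def test_predict_peak_bundles_state(self, setup):
        column, instrument, conditions = setup
        prog = GradientProgram.linear(0.30, 1.00, 20.0)
        peak = predict_peak("x", LSSCoefficients(3.0, 4.0), prog, conditions,
                            column, instrument)
        assert peak.retention_time == pytest.approx(22.38, abs=1e-2)
        assert peak.width_4sigma > 0
        assert peak.elution_k == pytest.approx(
            retention_factor(LSSCoefficients(3.0, 4.0), peak.elution_phi)
        )
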