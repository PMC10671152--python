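"""LSS retention engine: retention factor, gradient elution time, peak width.

The model is the linear solvent strength (LSS) relation

    log10 k(phi) = log10 kw - S * phi

combined with the ideal gradient migration equation: a solute dissolving in
the dwell-delayed inlet composition phi_in(t) elutes at t_e solving

    integral_0^{t_e} dt / (t0 * k(phi_in(t))) = 1,        tR = t0 + t_e.

Because phi_in(t) is piecewise linear, k(t) is piecewise exponential and the
migration integral has a closed form on every segment; the solver walks the
segments, accumulating migrated fraction, and inverts the closed form inside
the segment where the fraction reaches 1.  Solutes that survive the program
elute under the indefinite final-phi isocratic hold.  The result is exact to
floating-point rounding; a self-consistency check verifies the integral at
t_e equals 1 within 1e-6 on every call.

Assumptions (shared with published LSS closed forms): the solute experiences
the programmed composition delayed only by the dwell volume — gradient
traversal of the column itself is neglected; no curvature in log k vs phi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidConfigurationError, SolverError
from .system import (
    ColumnSpec,
    GradientProgram,
    InstrumentSpec,
    RunConditions,
    dead_time,
)

__all__ = [
    "LSSCoefficients",
    "PeakRecord",
    "retention_factor",
    "predict_retention_time",
    "elution_state",
    "predict_peak_width",
    "predict_peak",
]

LN10 = math.log(10.0)

#: Migration-integral self-consistency tolerance (dimensionless fraction).
INTEGRAL_TOL = 1e-6


@dataclass(frozen=True)
class LSSCoefficients:
    """Per-analyte LSS parameters at one (temperature, ternary) node.

    log_kw is log10 of the retention factor extrapolated to pure water
    (phi = 0); S is the LSS slope per unit phi.  Reverse-phase convention:
    S >= 0, retention decreases with organic strength.
    """

    log_kw: float
    S: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_kw):
            raise InvalidConfigurationError("log_kw must be finite")
        if not math.isfinite(self.S) or self.S < 0:
            raise InvalidConfigurationError("S must be finite and >= 0")


@dataclass(frozen=True)
class PeakRecord:
    """A predicted chromatographic peak."""

    analyte_id: str
    retention_time: float
    width_4sigma: float
    elution_phi: float
    elution_k: float
    area: float | None = None


def retention_factor(coeffs: LSSCoefficients, phi: float) -> float:
    """Retention factor k = 10**(log_kw - S*phi) at organic fraction phi."""
    return 10.0 ** (coeffs.log_kw - coeffs.S * phi)


def _inlet_segments(
    program: GradientProgram, dwell_min: float
) -> list[tuple[float, float, float, float]]:
    """Piecewise-linear inlet composition as (t_start, t_end, phi_start, slope).

    The final entry has t_end = inf (indefinite hold at the final phi).
    """
    segs: list[tuple[float, float, float, float]] = []
    pts = program.breakpoints
    if dwell_min > 0:
        segs.append((0.0, dwell_min, pts[0][1], 0.0))
    for (t1, p1), (t2, p2) in zip(pts, pts[1:]):
        a, b = t1 + dwell_min, t2 + dwell_min
        segs.append((a, b, p1, (p2 - p1) / (t2 - t1)))
    last_t = pts[-1][0] + dwell_min
    segs.append((last_t, math.inf, pts[-1][1], 0.0))
    return segs


def _segment_fraction(k_start: float, gamma: float, dt: float, t0: float) -> float:
    """Migrated fraction over dt within one segment.

    k(t) = k_start * exp(-gamma * t'), gamma = S * slope * ln10.
    """
    if gamma == 0.0:
        return dt / (t0 * k_start)
    return math.expm1(gamma * dt) / (t0 * k_start * gamma)


def _invert_segment(k_start: float, gamma: float, frac: float, t0: float) -> float:
    """Time within a segment at which the migrated fraction reaches ``frac``."""
    if gamma == 0.0:
        return frac * t0 * k_start
    return math.log1p(frac * t0 * k_start * gamma) / gamma


def _solve_elution(
    coeffs: LSSCoefficients,
    program: GradientProgram,
    conditions: RunConditions,
    column: ColumnSpec,
    instrument: InstrumentSpec,
) -> tuple[float, float, float]:
    """Return (t_e, t0, elution_phi) for the migration equation."""
    t0 = dead_time(column, conditions.flow_ml_min)
    td = instrument.dwell_time(conditions.flow_ml_min)
    segs = _inlet_segments(program, td)

    migrated = 0.0
    for t_a, t_b, phi_a, slope in segs:
        k_a = retention_factor(coeffs, phi_a)
        gamma = coeffs.S * slope * LN10
        dt_seg = t_b - t_a
        remaining = 1.0 - migrated
        if math.isinf(dt_seg):
            dt_star = _invert_segment(k_a, gamma, remaining, t0)
            t_e = t_a + dt_star
            phi_e = phi_a + slope * dt_star
            break
        frac = _segment_fraction(k_a, gamma, dt_seg, t0)
        if frac >= remaining:
            dt_star = _invert_segment(k_a, gamma, remaining, t0)
            t_e = t_a + dt_star
            phi_e = phi_a + slope * dt_star
            break
        migrated += frac
    else:  # pragma: no cover - final segment always terminates
        raise SolverError("migration never completed (unreachable)")

    # self-consistency: re-integrate 0..t_e and demand the fraction is 1
    total = 0.0
    for t_a, t_b, phi_a, slope in segs:
        if t_e <= t_a:
            break
        k_a = retention_factor(coeffs, phi_a)
        gamma = coeffs.S * slope * LN10
        dt_here = min(t_b, t_e) - t_a
        total += _segment_fraction(k_a, gamma, dt_here, t0)
    if abs(total - 1.0) > INTEGRAL_TOL:
        raise SolverError(
            f"migration integral at elution is {total:.8f} (expected 1 "
            f"+/- {INTEGRAL_TOL}); log_kw={coeffs.log_kw}, S={coeffs.S}"
        )
    return t_e, t0, phi_e


def predict_retention_time(
    coeffs: LSSCoefficients,
    program: GradientProgram,
    conditions: RunConditions,
    column: ColumnSpec,
    instrument: InstrumentSpec,
) -> float:
    """Retention time tR = t0 + t_e in minutes under the given method."""
    t_e, t0, _ = _solve_elution(coeffs, program, conditions, column, instrument)
    return t0 + t_e


def elution_state(
    coeffs: LSSCoefficients,
    program: GradientProgram,
    conditions: RunConditions,
    column: ColumnSpec,
    instrument: InstrumentSpec,
) -> tuple[float, float]:
    """(elution_phi, elution_k): inlet composition and retention factor at t_e."""
    _, _, phi_e = _solve_elution(coeffs, program, conditions, column, instrument)
    return phi_e, retention_factor(coeffs, phi_e)


def predict_peak_width(
    elution_k: float,
    t0: float,
    plate_count: float,
    compression: float = 1.0,
) -> float:
    """Baseline (4 sigma) peak width in minutes.

    w = compression * 4 * t0 * (1 + k_e) / sqrt(N): the isocratic width at
    the elution retention factor, optionally scaled by a gradient peak
    compression factor (1.0 = disabled).
    """
    if plate_count <= 0:
        raise InvalidConfigurationError("plate count must be positive")
    return compression * 4.0 * t0 * (1.0 + elution_k) / math.sqrt(plate_count)


def predict_peak(
    analyte_id: str,
    coeffs: LSSCoefficients,
    program: GradientProgram,
    conditions: RunConditions,
    column: ColumnSpec,
    instrument: InstrumentSpec,
    compression: float = 1.0,
    area: float | None = None,
) -> PeakRecord:
    """Full peak prediction: retention time, elution state and width."""
    t_e, t0, phi_e = _solve_elution(coeffs, program, conditions, column, instrument)
    k_e = retention_factor(coeffs, phi_e)
    width = predict_peak_width(k_e, t0, column.effective_plate_count(), compression)
    return PeakRecord(
        analyte_id=analyte_id,
        retention_time=t0 + t_e,
        width_4sigma=width,
        elution_phi=phi_e,
        elution_k=k_e,
        area=area,
    )
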