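"""Column, instrument and mobile-phase program descriptions.

The system model answers one question for the retention engine: what organic
fraction (phi) does the column inlet experience at time t?  That is the
programmed gradient, delivered piecewise-linearly by the pump, delayed by the
dwell time tD = dwell_volume / flow, and held at its final composition after
the program ends.

Units follow chromatographic convention: column geometry in mm/µm, volumes in
mL, flow in mL/min, time in minutes, temperature in °C at the interface
(kelvin internally), and phi as a fraction in [0, 1] (file interfaces accept
percent and convert).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

from .errors import InvalidConditionsError, InvalidConfigurationError

__all__ = [
    "ColumnSpec",
    "InstrumentSpec",
    "GradientProgram",
    "RunConditions",
    "dead_time",
    "inlet_composition",
    "rescale_flow",
]

#: Typical total porosity of packed silica beds; used when no measured dead
#: time is available.
DEFAULT_POROSITY = 0.68

#: Reduced plate height used for the default plate-count estimate
#: N = L / (h * dp).
DEFAULT_REDUCED_PLATE_HEIGHT = 2.5


@dataclass(frozen=True)
class ColumnSpec:
    """Geometry and efficiency of an HPLC column.

    Parameters
    ----------
    length_mm, id_mm, particle_um
        Column length, internal diameter and particle size.
    porosity
        Total porosity (fraction of the empty-tube volume available to the
        mobile phase); 0.68 is a typical value for packed silica.
    plate_count
        Optional explicit plate count N; when absent N is estimated from a
        reduced plate height of 2.5 as N = L / (2.5 * dp).
    t0_min
        Optional measured dead time at ``t0_flow_ml_min``; takes precedence
        over the geometric Vm/F estimate.
    """

    length_mm: float = 250.0
    id_mm: float = 4.6
    particle_um: float = 10.0
    porosity: float = DEFAULT_POROSITY
    plate_count: float | None = None
    t0_min: float | None = None
    t0_flow_ml_min: float | None = None

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.id_mm <= 0 or self.particle_um <= 0:
            raise InvalidConfigurationError(
                "column geometry (length, id, particle size) must be positive"
            )
        if not 0 < self.porosity < 1:
            raise InvalidConfigurationError(
                f"total porosity must lie in (0, 1), got {self.porosity}"
            )
        if self.plate_count is not None and self.plate_count <= 0:
            raise InvalidConfigurationError("plate_count must be positive")
        if self.t0_min is not None:
            if self.t0_min <= 0:
                raise InvalidConfigurationError("measured t0 must be positive")
            if self.t0_flow_ml_min is None or self.t0_flow_ml_min <= 0:
                raise InvalidConfigurationError(
                    "a measured t0 requires the flow it was measured at "
                    "(t0_flow_ml_min > 0)"
                )

    @property
    def dead_volume_ml(self) -> float:
        """Mobile-phase (void) volume Vm = porosity * pi * (id/2)^2 * L, in mL."""
        radius_cm = self.id_mm / 20.0
        length_cm = self.length_mm / 10.0
        return self.porosity * math.pi * radius_cm**2 * length_cm

    def effective_plate_count(self) -> float:
        """Plate count: explicit override, else N = L / (h * dp) with h = 2.5."""
        if self.plate_count is not None:
            return float(self.plate_count)
        return (self.length_mm * 1000.0) / (
            DEFAULT_REDUCED_PLATE_HEIGHT * self.particle_um
        )


@dataclass(frozen=True)
class InstrumentSpec:
    """Instrument plumbing relevant to gradient delivery.

    dwell_volume_ml is the volume between the gradient mixer and the column
    head; it delays the programmed gradient by tD = VD / F.
    """

    dwell_volume_ml: float = 1.0

    def __post_init__(self) -> None:
        if self.dwell_volume_ml < 0:
            raise InvalidConfigurationError("dwell volume must be >= 0")

    def dwell_time(self, flow_ml_min: float) -> float:
        """Dwell time tD = VD / F in minutes."""
        if flow_ml_min <= 0:
            raise InvalidConditionsError("flow must be positive")
        return self.dwell_volume_ml / flow_ml_min


@dataclass(frozen=True)
class GradientProgram:
    """Piecewise-linear organic fraction phi(t) programmed at the pump.

    ``breakpoints`` is an ordered sequence of (time_min, phi) pairs; the first
    time must be 0, times strictly increase, and phi lies in [0, 1].  After
    the last breakpoint the final phi is held indefinitely.
    """

    breakpoints: tuple[tuple[float, float], ...]

    def __init__(self, breakpoints: Sequence[Sequence[float]]):
        pts = tuple((float(t), float(p)) for t, p in breakpoints)
        if not pts:
            raise InvalidConfigurationError("a gradient program needs >= 1 breakpoint")
        if pts[0][0] != 0.0:
            raise InvalidConfigurationError("first breakpoint must be at t = 0")
        for (t1, _), (t2, _) in zip(pts, pts[1:]):
            if t2 <= t1:
                raise InvalidConfigurationError("breakpoint times must strictly increase")
        for _, p in pts:
            if not 0.0 <= p <= 1.0:
                raise InvalidConfigurationError("phi must lie in [0, 1]")
        object.__setattr__(self, "breakpoints", pts)

    @classmethod
    def linear(cls, phi0: float, phif: float, t_gradient: float) -> "GradientProgram":
        """Single linear ramp phi0 -> phif over t_gradient minutes."""
        return cls([(0.0, phi0), (t_gradient, phif)])

    @classmethod
    def from_percent_table(cls, rows: Sequence[Sequence[float]]) -> "GradientProgram":
        """Build from a (time_min, organic_percent) table as printed in methods."""
        return cls([(t, pct / 100.0) for t, pct in rows])

    @property
    def initial_phi(self) -> float:
        return self.breakpoints[0][1]

    @property
    def final_phi(self) -> float:
        return self.breakpoints[-1][1]

    @property
    def duration(self) -> float:
        """Time of the last breakpoint (the programmed span), minutes."""
        return self.breakpoints[-1][0]

    def phi_at(self, t: float) -> float:
        """Programmed phi at pump time t (hold before 0 and after the end)."""
        pts = self.breakpoints
        if t <= pts[0][0]:
            return pts[0][1]
        if t >= pts[-1][0]:
            return pts[-1][1]
        for (t1, p1), (t2, p2) in zip(pts, pts[1:]):
            if t1 <= t <= t2:
                if t == t1:
                    return p1
                if t == t2:
                    return p2
                return p1 + (p2 - p1) * (t - t1) / (t2 - t1)
        raise AssertionError("unreachable")

    def stretched_to(self, new_duration: float) -> "GradientProgram":
        """Rescale all breakpoint times so the program spans new_duration.

        Used by robustness scans that perturb the gradient time of an
        arbitrary (possibly multi-segment) program.
        """
        if new_duration <= 0:
            raise InvalidConfigurationError("gradient duration must be positive")
        factor = new_duration / self.duration
        return GradientProgram([(t * factor, p) for t, p in self.breakpoints])


@dataclass(frozen=True)
class RunConditions:
    """Operating point: flow (mL/min), column temperature (°C) and ternary
    fraction x = fraction of the secondary organic modifier (MeOH) in the
    organic blend (0 = neat ACN, 1 = neat MeOH)."""

    flow_ml_min: float
    temperature_c: float
    ternary_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.flow_ml_min <= 0:
            raise InvalidConditionsError("flow must be positive")
        if not 0.0 <= self.ternary_fraction <= 1.0:
            raise InvalidConditionsError("ternary fraction must lie in [0, 1]")

    @property
    def temperature_k(self) -> float:
        return self.temperature_c + 273.15

    def with_flow(self, new_flow: float) -> "RunConditions":
        return replace(self, flow_ml_min=new_flow)


def dead_time(column: ColumnSpec, flow_ml_min: float) -> float:
    """Column dead time t0 in minutes at the given flow.

    Uses a measured t0 (rescaled by inverse flow) when the column carries
    one; otherwise the geometric estimate t0 = Vm / F.
    """
    if flow_ml_min <= 0:
        raise InvalidConditionsError("flow must be positive")
    if column.t0_min is not None:
        return column.t0_min * (column.t0_flow_ml_min / flow_ml_min)
    return column.dead_volume_ml / flow_ml_min


def inlet_composition(
    program: GradientProgram,
    instrument: InstrumentSpec,
    flow_ml_min: float,
    t: float,
) -> float:
    """Organic fraction experienced at the column inlet at time t.

    The pump program arrives delayed by the dwell time tD = VD / F; before
    tD the inlet sees the initial phi, after the program it holds the final
    phi.
    """
    if t < 0:
        raise InvalidConditionsError("time must be >= 0")
    td = instrument.dwell_time(flow_ml_min)
    return program.phi_at(t - td)


def rescale_flow(
    conditions: RunConditions,
    column: ColumnSpec,
    instrument: InstrumentSpec,
    new_flow: float,
) -> dict:
    """Timing quantities after a flow change.

    t0 and tD scale by old_flow/new_flow; retention coefficients and plate
    count are left unchanged (a documented simplification — small efficiency
    losses at higher flow are ignored).  Returns the updated conditions and
    the new t0/tD in minutes.
    """
    if new_flow <= 0:
        raise InvalidConditionsError("flow must be positive")
    return {
        "conditions": conditions.with_flow(new_flow),
        "t0_min": dead_time(column, new_flow),
        "dwell_min": instrument.dwell_time(new_flow),
    }
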