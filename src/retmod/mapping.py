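"""Virtual chromatograms, critical-resolution maps, MODR and robustness.

A virtual chromatogram is the set of predicted peaks for the included
analytes at one setpoint.  Resolution between adjacent peaks uses the
baseline-width form Rs = 2 (tR2 - tR1) / (w1 + w2) with 4-sigma widths; the
critical resolution Rs,crit is the minimum over adjacent pairs (tie-break:
the earlier-eluting pair).  The method operable design region (MODR) is the
set of grid cells with Rs,crit >= 1.5 (baseline separation), and the
robustness scan evaluates a full factorial of small perturbations around a
setpoint to find the worst-case Rs,crit.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibrate import AnalyteCubeModel, interpolate_coefficients
from .engine import PeakRecord, predict_peak
from .errors import ValidationError
from .system import ColumnSpec, GradientProgram, InstrumentSpec, RunConditions

__all__ = [
    "VirtualChromatogram",
    "ResolutionMap",
    "GridSpec",
    "resolution",
    "simulate_separation",
    "critical_resolution",
    "compute_resolution_map",
    "extract_modr",
    "robustness_scan",
]

BASELINE_RS = 1.5


def resolution(peak1: PeakRecord, peak2: PeakRecord) -> float:
    """Rs = 2 |tR2 - tR1| / (w1 + w2) with baseline (4 sigma) widths."""
    return (
        2.0
        * abs(peak2.retention_time - peak1.retention_time)
        / (peak1.width_4sigma + peak2.width_4sigma)
    )


@dataclass(frozen=True)
class VirtualChromatogram:
    """Predicted peaks (sorted by retention time) and adjacent-pair resolutions."""

    peaks: tuple[PeakRecord, ...]
    adjacent_resolutions: tuple[tuple[tuple[str, str], float], ...]
    critical: tuple[tuple[str, str], float] | None

    @property
    def retention_times(self) -> dict[str, float]:
        return {p.analyte_id: p.retention_time for p in self.peaks}


def simulate_separation(
    models: dict[str, AnalyteCubeModel],
    program: GradientProgram,
    conditions: RunConditions,
    column: ColumnSpec,
    instrument: InstrumentSpec,
    include: set[str] | None = None,
    compression: float = 1.0,
) -> VirtualChromatogram:
    """Predict the chromatogram for the included analytes at one setpoint.

    Exclusion of an analyte never changes the predictions for the others:
    each peak is computed independently and only the adjacency (hence the
    resolution list) is recomputed.
    """
    include = set(models) if include is None else set(include)
    if not include:
        raise ValidationError("include must name at least one modeled analyte")
    unknown = include - set(models)
    if unknown:
        raise ValidationError(f"analytes not in the model set: {sorted(unknown)}")
    peaks = []
    for name in sorted(include):
        coeffs = interpolate_coefficients(
            models[name], conditions.temperature_c, conditions.ternary_fraction
        )
        peaks.append(
            predict_peak(name, coeffs, program, conditions, column, instrument,
                         compression=compression)
        )
    peaks.sort(key=lambda p: (p.retention_time, p.analyte_id))
    adjacent = tuple(
        ((p1.analyte_id, p2.analyte_id), resolution(p1, p2))
        for p1, p2 in zip(peaks, peaks[1:])
    )
    critical = min(adjacent, key=lambda e: e[1]) if adjacent else None
    return VirtualChromatogram(
        peaks=tuple(peaks), adjacent_resolutions=adjacent, critical=critical
    )


def critical_resolution(
    chromatogram: VirtualChromatogram,
) -> tuple[tuple[str, str], float] | None:
    """The limiting (pair, Rs) of a chromatogram; None with fewer than 2 peaks.

    Ties resolve to the earlier-eluting pair (the adjacency list is already
    in elution order and ``min`` keeps the first minimum).
    """
    if not chromatogram.adjacent_resolutions:
        return None
    return min(chromatogram.adjacent_resolutions, key=lambda e: e[1])


@dataclass(frozen=True)
class GridSpec:
    """Design-space grid: gradient time, temperature and ternary axes.

    Defaults span the calibrated cube at desk-scale density.
    """

    tG_min: tuple[float, ...] = tuple(np.linspace(20.0, 60.0, 21))
    temp_c: tuple[float, ...] = tuple(np.linspace(5.0, 35.0, 31))
    ternary_fraction: tuple[float, ...] = tuple(np.linspace(0.0, 1.0, 11))
    phi0: float = 0.30
    phif: float = 1.00
    flow_ml_min: float = 0.5


@dataclass
class ResolutionMap:
    """Rs,crit over a tG x T x tC grid with the limiting pair per cell."""

    tG_axis: tuple[float, ...]
    T_axis: tuple[float, ...]
    tC_axis: tuple[float, ...]
    values: np.ndarray                      # shape (n_tG, n_T, n_tC)
    limiting_pairs: np.ndarray              # object array, same shape
    included: tuple[str, ...]
    grid: GridSpec = field(default=None)  # type: ignore[assignment]

    def to_frame(self, decimals: int | None = 2) -> pd.DataFrame:
        """Long-format export; Rs rounded only at this reporting layer."""
        rows = []
        for i, tG in enumerate(self.tG_axis):
            for j, T in enumerate(self.T_axis):
                for k, x in enumerate(self.tC_axis):
                    rs = self.values[i, j, k]
                    rows.append(
                        {
                            "tG_min": tG,
                            "temp_c": T,
                            "ternary_fraction": x,
                            "rs_crit": round(float(rs), decimals)
                            if decimals is not None
                            else float(rs),
                            "limiting_pair": "|".join(self.limiting_pairs[i, j, k]),
                        }
                    )
        return pd.DataFrame(rows)


def compute_resolution_map(
    models: dict[str, AnalyteCubeModel],
    grid: GridSpec,
    column: ColumnSpec,
    instrument: InstrumentSpec,
    include: set[str] | None = None,
    compression: float = 1.0,
) -> ResolutionMap:
    """Evaluate Rs,crit on every grid cell (deterministic cell order)."""
    include = set(models) if include is None else set(include)
    if len(include) < 2:
        raise ValidationError("a resolution map needs at least two included analytes")
    any_model = next(iter(models.values()))
    T_lo, T_hi = any_model.T_levels
    if min(grid.temp_c) < T_lo or max(grid.temp_c) > T_hi:
        warnings.warn(
            "grid temperature axis extrapolates outside the calibrated range",
            stacklevel=2,
        )
    shape = (len(grid.tG_min), len(grid.temp_c), len(grid.ternary_fraction))
    values = np.empty(shape)
    pairs = np.empty(shape, dtype=object)
    for i, tG in enumerate(grid.tG_min):
        program = GradientProgram.linear(grid.phi0, grid.phif, tG)
        for j, T in enumerate(grid.temp_c):
            for k, x in enumerate(grid.ternary_fraction):
                cond = RunConditions(
                    flow_ml_min=grid.flow_ml_min, temperature_c=T, ternary_fraction=x
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    chrom = simulate_separation(
                        models, program, cond, column, instrument, include,
                        compression=compression,
                    )
                pair, rs = chrom.critical
                values[i, j, k] = rs
                pairs[i, j, k] = pair
    return ResolutionMap(
        tG_axis=tuple(grid.tG_min),
        T_axis=tuple(grid.temp_c),
        tC_axis=tuple(grid.ternary_fraction),
        values=values,
        limiting_pairs=pairs,
        included=tuple(sorted(include)),
        grid=grid,
    )


def extract_modr(
    rs_map: ResolutionMap, threshold: float = BASELINE_RS
) -> dict:
    """Cells meeting the baseline-separation criterion Rs,crit >= threshold.

    An empty MODR is a valid outcome (no operable region exists for the
    included analyte set).
    """
    passing = []
    for i, tG in enumerate(rs_map.tG_axis):
        for j, T in enumerate(rs_map.T_axis):
            for k, x in enumerate(rs_map.tC_axis):
                if rs_map.values[i, j, k] >= threshold:
                    passing.append(
                        {
                            "tG_min": float(tG),
                            "temp_c": float(T),
                            "ternary_fraction": float(x),
                            "rs_crit": float(rs_map.values[i, j, k]),
                        }
                    )
    n_total = int(np.prod(rs_map.values.shape))
    return {
        "threshold": threshold,
        "included": list(rs_map.included),
        "n_cells": n_total,
        "n_passing": len(passing),
        "fraction_passing": len(passing) / n_total,
        "empty": not passing,
        "cells": passing,
    }


def robustness_scan(
    models: dict[str, AnalyteCubeModel],
    program: GradientProgram,
    conditions: RunConditions,
    column: ColumnSpec,
    instrument: InstrumentSpec,
    tolerances: dict[str, float],
    levels: int = 3,
    include: set[str] | None = None,
) -> dict:
    """Full-factorial in-silico robustness scan around a setpoint.

    ``tolerances`` gives the half-width of the scanned interval per
    parameter, keyed by 'tG_min', 'temp_c', 'ternary_fraction',
    'flow_ml_min' (omit or 0 to leave a parameter nominal).  With 3 levels
    each parameter takes {-d, 0, +d}; with 2 levels {-d, +d} and the nominal
    point is evaluated additionally.  Returns nominal/min/max Rs,crit and
    the per-combination table.
    """
    if levels not in (2, 3):
        raise ValidationError("levels must be 2 or 3")
    valid_keys = {"tG_min", "temp_c", "ternary_fraction", "flow_ml_min"}
    unknown = set(tolerances) - valid_keys
    if unknown:
        raise ValidationError(f"unknown robustness parameters: {sorted(unknown)}")
    if any(d < 0 for d in tolerances.values()):
        raise ValidationError("tolerances must be >= 0")

    nominal = {
        "tG_min": program.duration,
        "temp_c": conditions.temperature_c,
        "ternary_fraction": conditions.ternary_fraction,
        "flow_ml_min": conditions.flow_ml_min,
    }
    offsets = [-1.0, 0.0, 1.0] if levels == 3 else [-1.0, 1.0]
    active = [k for k in ("tG_min", "temp_c", "ternary_fraction", "flow_ml_min")
              if tolerances.get(k, 0.0) > 0]

    def evaluate(point: dict[str, float]) -> float:
        x = point["ternary_fraction"]
        if not 0.0 <= x <= 1.0:
            warnings.warn(
                f"ternary fraction {x:.3f} outside [0, 1]; clipped", stacklevel=2
            )
            x = min(max(x, 0.0), 1.0)
        prog = (
            program
            if point["tG_min"] == nominal["tG_min"]
            else program.stretched_to(point["tG_min"])
        )
        cond = RunConditions(
            flow_ml_min=point["flow_ml_min"],
            temperature_c=point["temp_c"],
            ternary_fraction=x,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chrom = simulate_separation(
                models, prog, cond, column, instrument, include
            )
        crit = chrom.critical
        return float(crit[1]) if crit is not None else float("nan")

    rows = []
    combos = list(itertools.product(offsets, repeat=len(active)))
    nominal_combo = tuple(0.0 for _ in active)
    if nominal_combo not in combos:
        combos.append(nominal_combo)
    for combo in combos:
        point = dict(nominal)
        for key, sign in zip(active, combo):
            point[key] = nominal[key] + sign * tolerances[key]
        rs = evaluate(point)
        rows.append({**point, "rs_crit": rs, "is_nominal": combo == nominal_combo})
    table = pd.DataFrame(rows)
    nominal_rs = float(table.loc[table["is_nominal"], "rs_crit"].iloc[0])
    return {
        "nominal_rs_crit": nominal_rs,
        "min_rs_crit": float(table["rs_crit"].min()),
        "max_rs_crit": float(table["rs_crit"].max()),
        "n_combinations": len(table),
        "table": table,
    }


def plot_resolution_map(rs_map: ResolutionMap, tC_index: int = 0, ax=None):
    """Render one ternary slice of the map as a tG x T heat map (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    img = ax.imshow(
        rs_map.values[:, :, tC_index].T,
        origin="lower",
        aspect="auto",
        extent=(
            rs_map.tG_axis[0],
            rs_map.tG_axis[-1],
            rs_map.T_axis[0],
            rs_map.T_axis[-1],
        ),
        cmap="RdYlGn",
        vmin=0.0,
        vmax=max(2.0 * BASELINE_RS, float(rs_map.values.max())),
    )
    ax.figure.colorbar(img, ax=ax, label="Rs,crit")
    ax.set_xlabel("gradient time (min)")
    ax.set_ylabel("temperature (°C)")
    ax.set_title(f"ternary fraction x = {rs_map.tC_axis[tC_index]:.2f}")
    return ax
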