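"""Calibration of per-analyte LSS coefficient surfaces from a tG-T-tC design.

The experimental design is the 12-run cube used for gradient method
modeling: two gradient times (default 20 and 60 min, a three-fold ratio),
two column temperatures (default 5 and 35 °C) and three ternary compositions
of the organic modifier (default neat ACN, 50/50, neat MeOH), every run a
linear 30 -> 100 %B ramp at 0.5 mL/min.

At each of the six (T, tC) nodes the two gradient times identify the two LSS
parameters (log kw, S) of each analyte: initial values come from the
classical two-run gradient algebra and are refined against the full forward
model (dwell and post-program hold included) so that both measured retention
times are reproduced to <= 1e-4 min.  Between nodes, both coefficients are
interpolated linearly in 1/T (van't Hoff form — the only identifiable law
with two temperature levels) and quadratically (Lagrange) in the ternary
fraction x (three levels).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .engine import LSSCoefficients, predict_retention_time
from .errors import (
    FitFailureError,
    IncompleteDesignError,
    InvalidConditionsError,
    InvalidDesignError,
    SchemaError,
    UnidentifiableParametersError,
)
from .system import ColumnSpec, GradientProgram, InstrumentSpec, RunConditions, dead_time

__all__ = [
    "DesignSpec",
    "CornerRun",
    "build_design",
    "corner_table_columns",
    "validate_corner_table",
    "fit_node_coefficients",
    "AnalyteCubeModel",
    "assemble_cube",
    "interpolate_coefficients",
    "cube_models_to_json",
    "cube_models_from_json",
]

# fit bounds and tolerances
LOG_KW_BOUNDS = (-2.0, 12.0)
S_BOUNDS = (0.1, 100.0)
FIT_TOL_MIN = 1e-4          # max |predicted - measured| per node fit, minutes
CUBE_REPRO_TOL_MIN = 5e-3   # max reproduction error over all 12 runs, minutes
T_EXTRAPOLATION_LIMIT_C = 10.0

#: CSV schema for corner-run tables.
corner_table_columns = (
    "run_id",
    "tG_min",
    "temp_c",
    "ternary_fraction",
    "flow_ml_min",
    "analyte",
    "rt_min",
    "area",
    "mixture_id",
)


@dataclass(frozen=True)
class DesignSpec:
    """The tG-T-tC calibration design (defaults: the 12-run cube)."""

    tG_levels: tuple[float, float] = (20.0, 60.0)
    T_levels: tuple[float, float] = (5.0, 35.0)
    tC_levels: tuple[float, ...] = (0.0, 0.5, 1.0)
    phi0: float = 0.30
    phif: float = 1.00
    flow_ml_min: float = 0.5

    def __post_init__(self) -> None:
        if len(self.tG_levels) != 2:
            raise InvalidDesignError("exactly 2 gradient-time levels are required")
        if len(self.T_levels) != 2:
            raise InvalidDesignError("exactly 2 temperature levels are required")
        if len(self.tC_levels) != 3:
            raise InvalidDesignError("exactly 3 ternary-composition levels are required")
        if not self.tG_levels[0] < self.tG_levels[1]:
            raise InvalidDesignError("tG levels must increase")
        if not self.T_levels[0] < self.T_levels[1]:
            raise InvalidDesignError("T levels must increase")
        if sorted(set(self.tC_levels)) != sorted(self.tC_levels):
            raise InvalidDesignError("tC levels must be distinct and sorted")
        if not self.phi0 < self.phif:
            raise InvalidDesignError("phi0 must be below phif")
        if self.flow_ml_min <= 0:
            raise InvalidDesignError("flow must be positive")
        if self.tG_levels[1] / self.tG_levels[0] < 3.0:
            warnings.warn(
                "gradient-time ratio below 3 weakens the two-run fit; "
                "a three-fold spread is recommended",
                stacklevel=2,
            )

    @property
    def n_runs(self) -> int:
        return len(self.tG_levels) * len(self.T_levels) * len(self.tC_levels)

    def program(self, tG: float) -> GradientProgram:
        return GradientProgram.linear(self.phi0, self.phif, tG)


@dataclass(frozen=True)
class CornerRun:
    """One calibration run: its design coordinates, program and conditions."""

    run_id: str
    tG_min: float
    temp_c: float
    ternary_fraction: float
    program: GradientProgram
    conditions: RunConditions


def build_design(spec: DesignSpec) -> list[CornerRun]:
    """Enumerate the corner runs (tC outer, T middle, tG inner; deterministic)."""
    runs: list[CornerRun] = []
    idx = 1
    for x in spec.tC_levels:
        for T in spec.T_levels:
            for tG in spec.tG_levels:
                runs.append(
                    CornerRun(
                        run_id=f"run{idx:02d}",
                        tG_min=tG,
                        temp_c=T,
                        ternary_fraction=x,
                        program=spec.program(tG),
                        conditions=RunConditions(
                            flow_ml_min=spec.flow_ml_min,
                            temperature_c=T,
                            ternary_fraction=x,
                        ),
                    )
                )
                idx += 1
    return runs


def validate_corner_table(table: pd.DataFrame, spec: DesignSpec) -> pd.DataFrame:
    """Check a corner-run table against the design; return it normalized.

    Every (tG, T, tC) cell must be present for every analyte, retention
    times positive, one row per analyte per run.
    """
    missing_cols = [c for c in corner_table_columns[:7] if c not in table.columns]
    if missing_cols:
        raise SchemaError(f"corner table missing columns: {missing_cols}")
    if (table["rt_min"] <= 0).any():
        bad = table.index[table["rt_min"] <= 0].tolist()
        raise SchemaError(f"non-positive retention times at rows {bad}")
    dup = table.duplicated(subset=["tG_min", "temp_c", "ternary_fraction", "analyte"])
    if dup.any():
        raise SchemaError(
            f"duplicate (run, analyte) rows at {table.index[dup].tolist()}"
        )
    missing: list[tuple] = []
    analytes = sorted(table["analyte"].unique())
    for x in spec.tC_levels:
        for T in spec.T_levels:
            for tG in spec.tG_levels:
                sel = (
                    np.isclose(table["tG_min"], tG)
                    & np.isclose(table["temp_c"], T)
                    & np.isclose(table["ternary_fraction"], x)
                )
                if not sel.any():
                    missing.append((tG, T, x))
                    continue
                absent = set(analytes) - set(table.loc[sel, "analyte"])
                missing.extend((tG, T, x, a) for a in sorted(absent))
    if missing:
        raise IncompleteDesignError(
            f"corner table missing design cells (tG, T, tC[, analyte]): {missing}",
            missing_cells=missing,
        )
    return table


# ---------------------------------------------------------------------------
# node fitting
# ---------------------------------------------------------------------------

def _two_run_initial_guess(
    tr_short: float,
    tr_long: float,
    tG_short: float,
    tG_long: float,
    phi0: float,
    dphi: float,
    t0: float,
    td: float,
) -> tuple[float, float] | None:
    """Classical two-gradient-run LSS algebra (Snyder), used only to start
    the full-model refinement.  Returns (log_kw, S) or None if degenerate."""
    beta = tG_long / tG_short
    denom = tr_short - tr_long / beta - (1.0 - 1.0 / beta) * (t0 + td)
    if denom <= 0:
        return None
    b1 = t0 * math.log10(beta) / denom
    if b1 <= 0:
        return None
    expo = b1 * (tr_short - t0 - td) / t0
    k0 = (10.0**expo - 1.0) / (2.3 * b1)
    if k0 <= 0:
        return None
    S = b1 * tG_short / (t0 * dphi)
    log_kw = math.log10(k0) + S * phi0
    return log_kw, S


_GRID_STARTS = [(1.5, 3.0), (2.5, 4.0), (3.5, 6.0), (4.5, 8.0), (6.0, 12.0), (2.0, 20.0)]


def fit_node_coefficients(
    tr_short: float,
    tr_long: float,
    short_run: CornerRun,
    long_run: CornerRun,
    column: ColumnSpec,
    instrument: InstrumentSpec,
) -> LSSCoefficients:
    """Fit (log_kw, S) so the forward model reproduces both retention times.

    The two runs must differ only in gradient time.  Raises
    UnidentifiableParametersError when the solute is unretained or elutes
    before the gradients diverge, FitFailureError if no start converges to a
    residual <= 1e-4 min.
    """
    if short_run.tG_min >= long_run.tG_min:
        raise InvalidDesignError("short_run must have the smaller gradient time")
    for a, b in (
        (short_run.temp_c, long_run.temp_c),
        (short_run.ternary_fraction, long_run.ternary_fraction),
        (short_run.conditions.flow_ml_min, long_run.conditions.flow_ml_min),
    ):
        if not math.isclose(a, b):
            raise InvalidDesignError("node runs must differ only in gradient time")

    t0 = dead_time(column, short_run.conditions.flow_ml_min)
    td = instrument.dwell_time(short_run.conditions.flow_ml_min)
    margin = 1e-3
    if tr_short <= t0 + margin or tr_long <= t0 + margin:
        raise UnidentifiableParametersError(
            f"solute unretained (tR <= t0 = {t0:.3f} min): cannot identify (log_kw, S)"
        )
    if abs(tr_short - tr_long) <= margin and tr_short <= t0 * 1.05 + td:
        raise UnidentifiableParametersError(
            "solute elutes within the dwell/initial hold in both runs"
        )

    phi0 = short_run.program.initial_phi
    dphi = short_run.program.final_phi - phi0

    def residuals(theta: np.ndarray) -> np.ndarray:
        coeffs = LSSCoefficients(float(theta[0]), float(theta[1]))
        r1 = predict_retention_time(
            coeffs, short_run.program, short_run.conditions, column, instrument
        )
        r2 = predict_retention_time(
            coeffs, long_run.program, long_run.conditions, column, instrument
        )
        return np.array([r1 - tr_short, r2 - tr_long])

    starts: list[tuple[float, float]] = []
    guess = _two_run_initial_guess(
        tr_short, tr_long, short_run.tG_min, long_run.tG_min, phi0, dphi, t0, td
    )
    if guess is not None:
        starts.append(guess)
    starts.extend(_GRID_STARTS)

    lo = np.array([LOG_KW_BOUNDS[0], S_BOUNDS[0]])
    hi = np.array([LOG_KW_BOUNDS[1], S_BOUNDS[1]])
    best: tuple[float, float, float] | None = None  # (max_resid, S, log_kw)
    for log_kw0, S0 in starts:
        x0 = np.clip([log_kw0, S0], lo, hi)
        try:
            sol = least_squares(
                residuals, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14
            )
        except Exception:
            continue
        max_resid = float(np.max(np.abs(sol.fun)))
        cand = (max_resid, float(sol.x[1]), float(sol.x[0]))
        # lowest residual wins; on (near-)ties the smallest S
        if best is None or cand[0] < best[0] - 1e-12 or (
            abs(cand[0] - best[0]) <= 1e-12 and cand[1] < best[1]
        ):
            best = cand
        if max_resid <= FIT_TOL_MIN / 10:
            break
    if best is None or best[0] > FIT_TOL_MIN:
        raise FitFailureError(
            f"two-run fit residual {best[0] if best else math.nan:.3g} min exceeds "
            f"{FIT_TOL_MIN} (tR = {tr_short:.3f}, {tr_long:.3f} min)",
            residuals=None if best is None else best[0],
        )
    return LSSCoefficients(log_kw=best[2], S=best[1])


# ---------------------------------------------------------------------------
# the coefficient cube
# ---------------------------------------------------------------------------

@dataclass
class AnalyteCubeModel:
    """LSS coefficient surfaces for one analyte over the (T, tC) node grid.

    ``nodes`` maps (temp_c, ternary_fraction) -> LSSCoefficients for the
    2 x 3 grid; interpolation is linear in 1/T(K) and quadratic (Lagrange)
    in the ternary fraction, exact at the nodes.
    """

    analyte_id: str
    T_levels: tuple[float, float]
    tC_levels: tuple[float, ...]
    nodes: dict[tuple[float, float], LSSCoefficients]
    fit_residual_min: float = 0.0
    metadata: dict = field(default_factory=dict)

    def interpolate(self, temp_c: float, x: float) -> LSSCoefficients:
        return interpolate_coefficients(self, temp_c, x)

    def to_dict(self) -> dict:
        return {
            "analyte_id": self.analyte_id,
            "T_levels": list(self.T_levels),
            "tC_levels": list(self.tC_levels),
            "nodes": [
                {"temp_c": T, "ternary_fraction": x, "log_kw": c.log_kw, "S": c.S}
                for (T, x), c in sorted(self.nodes.items())
            ],
            "fit_residual_min": self.fit_residual_min,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalyteCubeModel":
        nodes = {
            (n["temp_c"], n["ternary_fraction"]): LSSCoefficients(n["log_kw"], n["S"])
            for n in d["nodes"]
        }
        return cls(
            analyte_id=d["analyte_id"],
            T_levels=tuple(d["T_levels"]),
            tC_levels=tuple(d["tC_levels"]),
            nodes=nodes,
            fit_residual_min=d.get("fit_residual_min", 0.0),
            metadata=d.get("metadata", {}),
        )


def _vant_hoff_interp(v1: float, v2: float, T1_k: float, T2_k: float, T_k: float) -> float:
    """Linear interpolation in reciprocal absolute temperature."""
    w = (1.0 / T_k - 1.0 / T1_k) / (1.0 / T2_k - 1.0 / T1_k)
    return v1 + (v2 - v1) * w


def _lagrange3(xs: tuple[float, ...], ys: list[float], x: float) -> float:
    """Quadratic Lagrange interpolation through three (x, y) points."""
    x0, x1, x2 = xs
    y0, y1, y2 = ys
    l0 = (x - x1) * (x - x2) / ((x0 - x1) * (x0 - x2))
    l1 = (x - x0) * (x - x2) / ((x1 - x0) * (x1 - x2))
    l2 = (x - x0) * (x - x1) / ((x2 - x0) * (x2 - x1))
    return y0 * l0 + y1 * l1 + y2 * l2


def interpolate_coefficients(
    model: AnalyteCubeModel, temp_c: float, x: float
) -> LSSCoefficients:
    """LSS coefficients at an arbitrary (T, x) inside the calibrated cube.

    log_kw and S are each interpolated linearly in 1/T(K) at the three tC
    nodes and then quadratically (Lagrange) in x.  Queries at design nodes
    return the fitted node coefficients exactly.  Temperature extrapolation
    beyond the calibrated range is allowed up to +/-10 °C with a warning;
    x must lie in [0, 1].
    """
    if not 0.0 <= x <= 1.0:
        raise InvalidConditionsError(f"ternary fraction {x} outside [0, 1]")
    T1, T2 = model.T_levels
    if temp_c < T1 - T_EXTRAPOLATION_LIMIT_C or temp_c > T2 + T_EXTRAPOLATION_LIMIT_C:
        raise InvalidConditionsError(
            f"temperature {temp_c} °C more than {T_EXTRAPOLATION_LIMIT_C} °C outside "
            f"the calibrated range [{T1}, {T2}]"
        )
    if not T1 <= temp_c <= T2:
        warnings.warn(
            f"temperature {temp_c} °C extrapolates outside the calibrated "
            f"range [{T1}, {T2}] °C",
            stacklevel=2,
        )
    # exact node queries return fitted coefficients bit-for-bit
    for (Tn, xn), c in model.nodes.items():
        if temp_c == Tn and x == xn:
            return c
    T1_k, T2_k = T1 + 273.15, T2 + 273.15
    T_k = temp_c + 273.15
    log_kw_at_x: list[float] = []
    S_at_x: list[float] = []
    for xn in model.tC_levels:
        c1 = model.nodes[(T1, xn)]
        c2 = model.nodes[(T2, xn)]
        log_kw_at_x.append(_vant_hoff_interp(c1.log_kw, c2.log_kw, T1_k, T2_k, T_k))
        S_at_x.append(_vant_hoff_interp(c1.S, c2.S, T1_k, T2_k, T_k))
    log_kw = _lagrange3(model.tC_levels, log_kw_at_x, x)
    S = _lagrange3(model.tC_levels, S_at_x, x)
    if S < 0:
        warnings.warn(
            f"interpolated S = {S:.4f} < 0 for {model.analyte_id} at "
            f"(T={temp_c}, x={x}); clipping to 0",
            stacklevel=2,
        )
        S = 0.0
    return LSSCoefficients(log_kw=log_kw, S=S)


def assemble_cube(
    table: pd.DataFrame,
    column: ColumnSpec,
    instrument: InstrumentSpec,
    spec: DesignSpec | None = None,
) -> dict[str, AnalyteCubeModel]:
    """Fit one AnalyteCubeModel per analyte from a complete corner-run table.

    Performs one two-run fit per (T, tC) node and verifies the assembled
    model reproduces every input retention time within 5e-3 min.
    """
    spec = spec or DesignSpec()
    table = validate_corner_table(table, spec)
    runs = {
        (r.tG_min, r.temp_c, r.ternary_fraction): r for r in build_design(spec)
    }
    tG_short, tG_long = spec.tG_levels
    models: dict[str, AnalyteCubeModel] = {}
    for analyte, sub in table.groupby("analyte", sort=True):
        nodes: dict[tuple[float, float], LSSCoefficients] = {}
        max_resid = 0.0
        for x in spec.tC_levels:
            for T in spec.T_levels:
                cell = sub[
                    np.isclose(sub["temp_c"], T)
                    & np.isclose(sub["ternary_fraction"], x)
                ]
                tr_by_tG = {
                    float(r["tG_min"]): float(r["rt_min"]) for _, r in cell.iterrows()
                }
                try:
                    coeffs = fit_node_coefficients(
                        tr_by_tG[tG_short],
                        tr_by_tG[tG_long],
                        runs[(tG_short, T, x)],
                        runs[(tG_long, T, x)],
                        column,
                        instrument,
                    )
                except (UnidentifiableParametersError, FitFailureError) as exc:
                    raise type(exc)(
                        f"analyte {analyte!r}, node (T={T} °C, x={x}): {exc}"
                    ) from exc
                nodes[(T, x)] = coeffs
                for tG, tr in tr_by_tG.items():
                    run = runs[(tG, T, x)]
                    pred = predict_retention_time(
                        coeffs, run.program, run.conditions, column, instrument
                    )
                    max_resid = max(max_resid, abs(pred - tr))
        model = AnalyteCubeModel(
            analyte_id=str(analyte),
            T_levels=spec.T_levels,
            tC_levels=spec.tC_levels,
            nodes=nodes,
            fit_residual_min=max_resid,
            metadata={
                "design": {
                    "tG_levels": list(spec.tG_levels),
                    "phi0": spec.phi0,
                    "phif": spec.phif,
                    "flow_ml_min": spec.flow_ml_min,
                }
            },
        )
        if max_resid > CUBE_REPRO_TOL_MIN:
            raise FitFailureError(
                f"cube for {analyte!r} reproduces corner runs only to "
                f"{max_resid:.2e} min (tolerance {CUBE_REPRO_TOL_MIN})",
                residuals=max_resid,
            )
        models[str(analyte)] = model
    return models


def cube_models_to_json(models: dict[str, AnalyteCubeModel]) -> str:
    """Serialize fitted models to the documented JSON schema."""
    return json.dumps(
        {"schema": "retmod-cube-v1", "analytes": [m.to_dict() for m in models.values()]},
        indent=2,
        sort_keys=True,
    )


def cube_models_from_json(text: str) -> dict[str, AnalyteCubeModel]:
    d = json.loads(text)
    if d.get("schema") != "retmod-cube-v1":
        raise SchemaError("not a retmod cube-model JSON (schema key missing/unknown)")
    models = [AnalyteCubeModel.from_dict(a) for a in d["analytes"]]
    return {m.analyte_id: m for m in models}
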