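"""Synthetic ground truth and simulated data for every pipeline stage.

The generator emulates the study conditions of the 12-run tG-T-tC design:
nine analytes (an API plus eight related substances), linear 30 -> 100 %B
gradients of 20 and 60 min at 5 and 35 °C over three ternary compositions,
0.5 mL/min.  Each analyte's truth is a continuous parametric LSS surface,

    log10 kw(T, x) = base + b_vh * (1/T - 1/T_mid) + a1*x + 4*a2*x*(1-x)
    S(T, x)       = S0   + c_vh * (1/T - 1/T_mid) + s1*x + 4*s2*x*(1-x)

i.e. van't Hoff (linear in reciprocal kelvin) in temperature and quadratic
in the ternary fraction x — the same family the calibration interpolates, so
noiseless round trips are exact by construction.  Parameter ranges are
chosen to give paper-like retention spans (roughly 15-70 min over the
default corner runs); draws whose corner retention times leave
[t0 + 2 min, 1.5 x longest gradient] are resampled.

Noise is additive gaussian on retention times (default SD 0.02 min, which
propagates to prediction errors of the order seen in real validation runs)
and multiplicative gaussian on areas (default CV 3%).  Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibrate import DesignSpec, build_design, corner_table_columns
from .engine import LSSCoefficients, predict_retention_time
from .errors import GenerationError, ValidationError
from .system import ColumnSpec, GradientProgram, InstrumentSpec, RunConditions, dead_time
from .tracking import MixtureScheme, ObservedPeak

__all__ = [
    "AnalyteTruth",
    "NoiseModel",
    "EZETIMIBE_ROSTER",
    "ezetimibe_scheme",
    "distinct_concentration_scheme",
    "sample_truth",
    "truth_corner_nodes",
    "simulate_corner_table",
    "render_mixture_peaklists",
    "render_trace",
]

T_MID_K = 293.15  # reference temperature for the van't Hoff expansion (20 °C)

#: The nine-compound roster: the API and its achiral related substances,
#: with the nominal concentrations (µg/mL) of the full artificial mixture.
EZETIMIBE_ROSTER: tuple[tuple[str, float], ...] = (
    ("ezetimibe", 1000.0),
    ("ezetimibe_diol", 12.0),
    ("desfluoro_ezetimibe", 4.0),
    ("monofluoro_ezetimibe", 6.0),
    ("rrs_ezetimibe", 8.0),
    ("thp_compound", 6.0),
    ("ezetimibe_ketone", 8.0),
    ("benzylated_ezetimibe", 8.0),
    ("tbdms_ketone", 6.0),
)

_MIX2 = (
    "ezetimibe_diol",
    "monofluoro_ezetimibe",
    "rrs_ezetimibe",
    "ezetimibe_ketone",
    "benzylated_ezetimibe",
    "tbdms_ketone",
)
_MIX3 = ("desfluoro_ezetimibe", "thp_compound")


def ezetimibe_scheme() -> MixtureScheme:
    """The three-mixture spiking scheme: mix1 = all nine compounds,
    mix2 = six impurities, mix3 = desfluoro + THP, at their nominal
    concentrations."""
    conc = dict(EZETIMIBE_ROSTER)
    return MixtureScheme(
        {
            "mix1": dict(conc),
            "mix2": {a: conc[a] for a in _MIX2},
            "mix3": {a: conc[a] for a in _MIX3},
        }
    )


def distinct_concentration_scheme() -> MixtureScheme:
    """Same mixture memberships, but with concentrations spaced >= 1.5x
    within every signature group so that area evidence can resolve all
    labels.  The nominal scheme contains within-group concentration ties
    (several impurities at 8 µg/mL) that no area-based tracker can separate.
    """
    conc = {
        "ezetimibe": 1000.0,
        "ezetimibe_diol": 4.0,
        "monofluoro_ezetimibe": 6.0,
        "rrs_ezetimibe": 9.0,
        "ezetimibe_ketone": 13.5,
        "benzylated_ezetimibe": 20.0,
        "tbdms_ketone": 30.0,
        "desfluoro_ezetimibe": 4.0,
        "thp_compound": 6.0,
    }
    return MixtureScheme(
        {
            "mix1": dict(conc),
            "mix2": {a: conc[a] for a in _MIX2},
            "mix3": {a: conc[a] for a in _MIX3},
        }
    )


@dataclass(frozen=True)
class AnalyteTruth:
    """Ground-truth LSS surface and detector properties of one analyte."""

    analyte_id: str
    base_log_kw: float
    vh_log_kw: float      # d log_kw / d(1/T), kelvin
    tern_log_kw: tuple[float, float]   # (a1, a2)
    base_S: float
    vh_S: float
    tern_S: tuple[float, float]        # (s1, s2)
    concentration: float               # µg/mL in the full mixture
    response_factor: float             # area per µg/mL (relative)

    def coefficients_at(self, temp_c: float, x: float) -> LSSCoefficients:
        inv_dT = 1.0 / (temp_c + 273.15) - 1.0 / T_MID_K
        a1, a2 = self.tern_log_kw
        s1, s2 = self.tern_S
        log_kw = self.base_log_kw + self.vh_log_kw * inv_dT + a1 * x + 4 * a2 * x * (1 - x)
        S = self.base_S + self.vh_S * inv_dT + s1 * x + 4 * s2 * x * (1 - x)
        return LSSCoefficients(log_kw=log_kw, S=max(S, 0.0))


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: additive SD on retention times (min) and
    multiplicative CV on areas."""

    rt_sd_min: float = 0.02
    area_cv: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rt_sd_min < 0 or self.area_cv < 0:
            raise ValidationError("noise SDs must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _corner_rts(
    truth: AnalyteTruth,
    design: DesignSpec,
    column: ColumnSpec,
    instrument: InstrumentSpec,
) -> list[float]:
    rts = []
    for run in build_design(design):
        coeffs = truth.coefficients_at(run.temp_c, run.ternary_fraction)
        rts.append(
            predict_retention_time(coeffs, run.program, run.conditions, column, instrument)
        )
    return rts


def sample_truth(
    n_analytes: int = 9,
    seed: int = 0,
    design: DesignSpec | None = None,
    column: ColumnSpec | None = None,
    instrument: InstrumentSpec | None = None,
    max_attempts: int = 500,
) -> list[AnalyteTruth]:
    """Draw a ground-truth analyte set consistent with the design.

    base log_kw ~ U[1.5, 4.5], S ~ U[3, 8]; the van't Hoff slope gives a
    1-3% decrease in k per °C; ternary perturbations are quadratic with
    amplitude <= 0.5 (log_kw) and <= 1.5 (S).  Draws are rejected and
    retried until every corner retention time lies in
    [t0 + 2 min, 1.5 x longest gradient time].
    """
    if n_analytes < 1:
        raise GenerationError("n_analytes must be >= 1")
    design = design or DesignSpec()
    column = column or ColumnSpec()
    instrument = instrument or InstrumentSpec()
    rng = np.random.default_rng(seed)

    # paper-like retention span: corner runs of the emulated study elute
    # roughly between 15 and 80 min — comfortably past the dwell + initial
    # hold (so both LSS parameters are identifiable) and within 1.5 x the
    # longest gradient
    t0 = dead_time(column, design.flow_ml_min)
    rt_lo = max(15.0, t0 + 2.0)
    rt_hi = min(80.0, 1.5 * max(design.tG_levels))

    if n_analytes == len(EZETIMIBE_ROSTER):
        roster = list(EZETIMIBE_ROSTER)
    else:
        roster = [(f"analyte_{i + 1:02d}", 4.0 * 1.5**i) for i in range(n_analytes)]

    out: list[AnalyteTruth] = []
    for analyte_id, concentration in roster:
        for _ in range(max_attempts):
            base_log_kw = rng.uniform(1.5, 4.5)
            base_S = rng.uniform(3.0, 8.0)
            # k decreasing 1-3% per °C: d ln k/dT = -r  =>  d log_kw/d(1/T) = r*T^2/ln10
            rate = rng.uniform(0.01, 0.03)
            vh_log_kw = rate * T_MID_K**2 / math.log(10.0)
            vh_S = rng.uniform(-2000.0, 2000.0)
            tern_log_kw = (rng.uniform(-0.35, 0.35), rng.uniform(-0.15, 0.15))
            tern_S = (rng.uniform(-1.0, 1.0), rng.uniform(-0.5, 0.5))
            truth = AnalyteTruth(
                analyte_id=analyte_id,
                base_log_kw=base_log_kw,
                vh_log_kw=vh_log_kw,
                tern_log_kw=tern_log_kw,
                base_S=base_S,
                vh_S=vh_S,
                tern_S=tern_S,
                concentration=concentration,
                response_factor=rng.uniform(0.97, 1.03),
            )
            rts = _corner_rts(truth, design, column, instrument)
            if min(rts) >= rt_lo and max(rts) <= rt_hi:
                out.append(truth)
                break
        else:
            raise GenerationError(
                f"could not draw feasible truth for {analyte_id!r} in "
                f"{max_attempts} attempts"
            )
    return out


def truth_corner_nodes(
    truth: AnalyteTruth, design: DesignSpec
) -> dict[tuple[float, float], LSSCoefficients]:
    """Truth coefficients evaluated at the design's six (T, tC) nodes."""
    return {
        (T, x): truth.coefficients_at(T, x)
        for x in design.tC_levels
        for T in design.T_levels
    }


def simulate_corner_table(
    truth: list[AnalyteTruth],
    design: DesignSpec | None = None,
    noise: NoiseModel | None = None,
    column: ColumnSpec | None = None,
    instrument: InstrumentSpec | None = None,
) -> pd.DataFrame:
    """Forward-simulate the full corner-run table (one row per run x analyte)."""
    design = design or DesignSpec()
    noise = noise or NoiseModel()
    column = column or ColumnSpec()
    instrument = instrument or InstrumentSpec()
    rng = noise.rng()
    rows = []
    for run in build_design(design):
        for t in truth:
            coeffs = t.coefficients_at(run.temp_c, run.ternary_fraction)
            rt = predict_retention_time(
                coeffs, run.program, run.conditions, column, instrument
            )
            rt += rng.normal(0.0, noise.rt_sd_min) if noise.rt_sd_min > 0 else 0.0
            area = t.concentration * t.response_factor
            area *= 1.0 + (rng.normal(0.0, noise.area_cv) if noise.area_cv > 0 else 0.0)
            rows.append(
                {
                    "run_id": run.run_id,
                    "tG_min": run.tG_min,
                    "temp_c": run.temp_c,
                    "ternary_fraction": run.ternary_fraction,
                    "flow_ml_min": run.conditions.flow_ml_min,
                    "analyte": t.analyte_id,
                    "rt_min": rt,
                    "area": area,
                    "mixture_id": "mix1",
                }
            )
    return pd.DataFrame(rows, columns=list(corner_table_columns))


def render_mixture_peaklists(
    truth: list[AnalyteTruth],
    scheme: MixtureScheme,
    program: GradientProgram,
    conditions: RunConditions,
    column: ColumnSpec | None = None,
    instrument: InstrumentSpec | None = None,
    noise: NoiseModel | None = None,
    run_id: str = "run01",
) -> dict[str, list[ObservedPeak]]:
    """Simulated peak lists for each mixture injection of one condition.

    Each mixture contains only its member analytes; retention times differ
    between injections only by replicate noise and areas scale with the
    mixture's nominal concentration and the analyte's response factor.
    """
    column = column or ColumnSpec()
    instrument = instrument or InstrumentSpec()
    noise = noise or NoiseModel()
    rng = noise.rng()
    by_id = {t.analyte_id: t for t in truth}
    unknown = set(scheme.analytes) - set(by_id)
    if unknown:
        raise ValidationError(f"scheme references unknown analytes: {sorted(unknown)}")
    out: dict[str, list[ObservedPeak]] = {}
    for mid in scheme.mixture_ids:
        peaks = []
        for analyte, conc in sorted(scheme.mixtures[mid].items()):
            t = by_id[analyte]
            coeffs = t.coefficients_at(conditions.temperature_c, conditions.ternary_fraction)
            rt = predict_retention_time(coeffs, program, conditions, column, instrument)
            rt += rng.normal(0.0, noise.rt_sd_min) if noise.rt_sd_min > 0 else 0.0
            area = conc * t.response_factor
            area *= 1.0 + (rng.normal(0.0, noise.area_cv) if noise.area_cv > 0 else 0.0)
            peaks.append(
                ObservedPeak(run_id=run_id, mixture_id=mid, rt_min=rt, area=area)
            )
        out[mid] = sorted(peaks, key=lambda p: p.rt_min)
    return out


def render_trace(
    peaks,
    sampling_hz: float = 2.0,
    baseline_sd: float = 0.0,
    t_max: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Detector-style time-intensity trace: a sum of gaussian peaks.

    Each peak contributes a gaussian at its retention time with
    sigma = width_4sigma / 4 and integral equal to its area; optional white
    baseline noise is added on top.  Returns (time_min, intensity).
    """
    if sampling_hz <= 0:
        raise ValidationError("sampling rate must be positive")
    peaks = list(peaks)
    if t_max is None:
        t_max = max((p.retention_time + 3 * p.width_4sigma for p in peaks), default=10.0)
    n = int(round(t_max * 60.0 * sampling_hz)) + 1
    t = np.linspace(0.0, t_max, n)
    y = np.zeros_like(t)
    for p in peaks:
        sigma = p.width_4sigma / 4.0
        area = p.area if p.area is not None else 1.0
        y += area / (sigma * math.sqrt(2 * math.pi)) * np.exp(
            -0.5 * ((t - p.retention_time) / sigma) ** 2
        )
    if baseline_sd > 0:
        y += np.random.default_rng(seed).normal(0.0, baseline_sd, size=y.shape)
    return t, y
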