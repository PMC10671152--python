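"""Predicted-vs-experimental validation metrics and repeatability statistics.

The error metric is the signed relative retention-time error

    error % = (predicted Rt - experimental Rt) / experimental Rt * 100,

summarized per setpoint as the mean of the *absolute* signed errors and per
column as the mean of the per-setpoint means.  Repeatability over repeated
injections is reported as sample mean +/- sample standard deviation (n-1
denominator).  Rounding to 2 decimals (half-up, as in printed tables)
happens only at the reporting layer; raw values are kept internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "ComparisonRow",
    "SetpointReport",
    "retention_error_pct",
    "mean_abs_error",
    "column_summary",
    "repeatability_stats",
    "compare_tables",
    "round_half_up",
]


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round half away from zero, matching printed-table formatting."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ComparisonRow:
    analyte_id: str
    predicted_rt: float
    experimental_rt: float

    def __post_init__(self) -> None:
        if self.experimental_rt <= 0:
            raise ValidationError("experimental retention time must be positive")

    @property
    def error_pct(self) -> float:
        return retention_error_pct(self.predicted_rt, self.experimental_rt)


@dataclass(frozen=True)
class SetpointReport:
    """Per-setpoint comparison: rows plus the mean absolute error in percent."""

    setpoint: str
    rows: tuple[ComparisonRow, ...]
    mean_abs_error_pct: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "analyte": r.analyte_id,
                    "predicted_rt": r.predicted_rt,
                    "experimental_rt": r.experimental_rt,
                    "error_pct": round_half_up(r.error_pct),
                }
                for r in self.rows
            ]
        )


def retention_error_pct(predicted: float, experimental: float) -> float:
    """Signed percent error (predicted - experimental) / experimental * 100."""
    if experimental <= 0:
        raise ValidationError("experimental retention time must be positive")
    return (predicted - experimental) / experimental * 100.0


def mean_abs_error(rows: list[ComparisonRow]) -> float:
    """Mean of |signed error %| over the comparison rows."""
    if not rows:
        raise ValidationError("no comparison rows")
    return float(np.mean([abs(r.error_pct) for r in rows]))


def column_summary(setpoint_means: list[float]) -> float:
    """Overall column accuracy: mean of the per-setpoint mean absolute errors."""
    if not setpoint_means:
        raise ValidationError("no setpoint means")
    return float(np.mean(setpoint_means))


def repeatability_stats(values: list[float]) -> dict:
    """Sample mean and SD (n-1) over repeated injections.

    With n < 2 the SD is undefined and flagged (sd = None).
    """
    if not values:
        raise ValidationError("no values")
    arr = np.asarray(values, dtype=float)
    out = {"n": int(arr.size), "mean": float(arr.mean())}
    if arr.size < 2:
        out["sd"] = None
        out["sd_flag"] = "n < 2: SD undefined"
    else:
        out["sd"] = float(arr.std(ddof=1))
    return out


def compare_tables(
    predicted: pd.DataFrame,
    experimental: pd.DataFrame,
    setpoint: str = "setpoint",
) -> SetpointReport:
    """Build a SetpointReport from two (analyte, rt_min) tables.

    Only analytes present in both tables are compared (a peak absent from a
    setpoint is printed as '-' in validation tables).
    """
    for name, df in (("predicted", predicted), ("experimental", experimental)):
        if not {"analyte", "rt_min"} <= set(df.columns):
            raise ValidationError(f"{name} table needs columns analyte, rt_min")
    merged = predicted.merge(
        experimental, on="analyte", suffixes=("_pred", "_exp")
    ).dropna(subset=["rt_min_pred", "rt_min_exp"])
    if merged.empty:
        raise ValidationError("no overlapping analytes between the tables")
    rows = tuple(
        ComparisonRow(str(r["analyte"]), float(r["rt_min_pred"]), float(r["rt_min_exp"]))
        for _, r in merged.iterrows()
    )
    return SetpointReport(
        setpoint=setpoint, rows=rows, mean_abs_error_pct=mean_abs_error(list(rows))
    )
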