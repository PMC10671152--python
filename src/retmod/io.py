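"""Configuration loading, table I/O and the end-to-end pipeline.

All file interfaces are plain text: CSV for tables, JSON for models, maps
and reports, YAML or JSON for configuration.  Percent columns
(``organic_pct``) are converted to fractions at the boundary; the in-memory
convention is always a fraction in [0, 1].  Outputs carry no timestamps so
reruns with the same inputs and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError as PydanticValidationError

from . import calibrate, mapping, synthetic, validation
from .errors import SchemaError, ValidationError
from .system import ColumnSpec, GradientProgram, InstrumentSpec

__all__ = [
    "ProjectConfig",
    "load_config",
    "load_corner_table",
    "write_corner_table",
    "load_gradient_table",
    "load_setpoint_fixture",
    "load_longterm_fixture",
    "load_setpoint_conditions",
    "run_pipeline",
]


class ColumnConfig(BaseModel):
    length_mm: float = Field(250.0, gt=0)
    id_mm: float = Field(4.6, gt=0)
    particle_um: float = Field(10.0, gt=0)
    porosity: float = Field(0.68, gt=0, lt=1)
    plate_count: float | None = Field(None, gt=0)
    t0_min: float | None = Field(None, gt=0)
    t0_flow_ml_min: float | None = Field(None, gt=0)

    def to_spec(self) -> ColumnSpec:
        return ColumnSpec(**self.model_dump())


class InstrumentConfig(BaseModel):
    dwell_ml: float = Field(1.0, ge=0)

    def to_spec(self) -> InstrumentSpec:
        return InstrumentSpec(dwell_volume_ml=self.dwell_ml)


class DesignConfig(BaseModel):
    tG_levels: tuple[float, float] = (20.0, 60.0)
    T_levels: tuple[float, float] = (5.0, 35.0)
    tC_levels: tuple[float, float, float] = (0.0, 0.5, 1.0)
    phi0: float = Field(0.30, ge=0, le=1)
    phif: float = Field(1.00, ge=0, le=1)
    flow_ml_min: float = Field(0.5, gt=0)

    def to_spec(self) -> calibrate.DesignSpec:
        return calibrate.DesignSpec(**self.model_dump())


class GridConfig(BaseModel):
    tG_points: int = Field(21, ge=1)
    T_points: int = Field(31, ge=1)
    tC_points: int = Field(11, ge=1)
    flow_ml_min: float = Field(0.5, gt=0)

    def to_spec(self, design: calibrate.DesignSpec) -> mapping.GridSpec:
        import numpy as np

        return mapping.GridSpec(
            tG_min=tuple(np.linspace(*design.tG_levels, self.tG_points)),
            temp_c=tuple(np.linspace(*design.T_levels, self.T_points)),
            ternary_fraction=tuple(
                np.linspace(min(design.tC_levels), max(design.tC_levels), self.tC_points)
            ),
            phi0=design.phi0,
            phif=design.phif,
            flow_ml_min=self.flow_ml_min,
        )


class ProjectConfig(BaseModel):
    """Validated project configuration for the CLI and pipeline."""

    column: ColumnConfig = ColumnConfig()
    instrument: InstrumentConfig = InstrumentConfig()
    design: DesignConfig = DesignConfig()
    grid: GridConfig = GridConfig()
    rs_threshold: float = Field(1.5, gt=0)
    corner_table: str | None = None
    n_analytes: int = Field(9, ge=1)
    seed: int = 0
    verbosity: str = "info"


def load_config(path: str | Path) -> ProjectConfig:
    """Load and eagerly validate a YAML/JSON project config.

    Referenced files must exist at load time; validation errors name the
    offending field path.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
    try:
        cfg = ProjectConfig.model_validate(data or {})
    except PydanticValidationError as exc:
        locs = "; ".join(
            ".".join(str(p) for p in e["loc"]) + ": " + e["msg"] for e in exc.errors()
        )
        raise ValidationError(f"invalid config {path}: {locs}") from exc
    if cfg.corner_table is not None:
        table_path = Path(cfg.corner_table)
        if not table_path.is_absolute():
            table_path = path.parent / table_path
        if not table_path.exists():
            raise ValidationError(f"config field corner_table: file not found: {table_path}")
    return cfg


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def load_corner_table(path: str | Path) -> pd.DataFrame:
    """Read a corner-run CSV, with row/column diagnostics on bad input."""
    df = pd.read_csv(path)
    required = set(calibrate.corner_table_columns[:7])
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[df["rt_min"] <= 0].tolist()
    if bad:
        raise SchemaError(f"{path}: non-positive rt_min at rows {bad}")
    return df


def write_corner_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def load_gradient_table(path: str | Path) -> GradientProgram:
    """Read a two-column (time_min, organic_pct) gradient table."""
    df = pd.read_csv(path)
    if not {"time_min", "organic_pct"} <= set(df.columns):
        raise SchemaError(f"{path}: gradient table needs columns time_min, organic_pct")
    return GradientProgram.from_percent_table(df[["time_min", "organic_pct"]].values)


def _data_text(name: str) -> str:
    return resources.files("retmod.data").joinpath(name).read_text()


def load_setpoint_fixture(column: str) -> pd.DataFrame:
    """Bundled predicted/experimental setpoint tables.

    ``column`` is 'chiralcel_od' (cellulose CSP) or 'chiral_cdph'
    (cyclodextrin CSP).
    """
    import io as _io

    return pd.read_csv(_io.StringIO(_data_text(f"{column}_setpoints.csv")))


def load_longterm_fixture(column: str) -> pd.DataFrame:
    """Bundled long-term repeatability tables (initial and 2-year reruns)."""
    import io as _io

    return pd.read_csv(_io.StringIO(_data_text(f"{column}_longterm.csv")))


def load_setpoint_conditions() -> dict:
    """Bundled method conditions (gradient, T, flow, tC) per setpoint."""
    raw = yaml.safe_load(_data_text("validation_setpoints.yaml"))
    out: dict = {}
    for column, sps in raw.items():
        out[column] = {}
        for sp, cond in sps.items():
            out[column][str(sp)] = {
                "temp_c": float(cond["temp_c"]),
                "flow_ml_min": float(cond["flow_ml_min"]),
                "ternary_fraction": float(cond["ternary_fraction"]),
                "program": GradientProgram.from_percent_table(cond["gradient"]),
            }
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: ProjectConfig, out_dir: str | Path, log=print) -> dict:
    """Run track -> fit -> map -> MODR -> validate end to end.

    With no corner table configured, a synthetic study is generated from the
    config seed (truth, three-mixture peak lists, tracking, corner table).
    Writes model JSON, map CSV, MODR JSON and a validation report; returns a
    manifest with the SHA-256 of every artifact.  Deterministic for a fixed
    config and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    column = config.column.to_spec()
    instrument = config.instrument.to_spec()
    design = config.design.to_spec()

    if config.corner_table:
        table = load_corner_table(config.corner_table)
        truth = None
        log(f"loaded corner table {config.corner_table} ({len(table)} rows)")
    else:
        truth = synthetic.sample_truth(
            config.n_analytes, seed=config.seed, design=design,
            column=column, instrument=instrument,
        )
        noise = synthetic.NoiseModel(seed=config.seed)
        scheme = synthetic.distinct_concentration_scheme() if config.n_analytes == 9 else None
        rows = []
        if scheme is not None:
            # three-mixture injections + tracking at every design condition
            from .tracking import assign_peaks, assignments_to_rows

            for i, run in enumerate(calibrate.build_design(design)):
                lists = synthetic.render_mixture_peaklists(
                    truth, scheme, run.program, run.conditions, column, instrument,
                    noise=synthetic.NoiseModel(noise.rt_sd_min, noise.area_cv,
                                               seed=config.seed * 1000 + i),
                    run_id=run.run_id,
                )
                peaks = [p for plist in lists.values() for p in plist]
                assignments = assign_peaks(peaks, scheme)
                rows.append(
                    assignments_to_rows(
                        assignments, run.run_id, run.tG_min, run.temp_c,
                        run.ternary_fraction, run.conditions.flow_ml_min,
                    )
                )
            table = pd.concat(rows, ignore_index=True)
            log(f"generated + tracked synthetic corner table ({len(table)} rows)")
        else:
            table = synthetic.simulate_corner_table(truth, design, noise, column, instrument)
            log(f"generated synthetic corner table ({len(table)} rows)")
        write_corner_table(table, out / "corner_table.csv")

    models = calibrate.assemble_cube(table, column, instrument, design)
    model_path = out / "models.json"
    model_path.write_text(calibrate.cube_models_to_json(models))
    log(f"fitted {len(models)} analyte models "
        f"(max reproduction error {max(m.fit_residual_min for m in models.values()):.2e} min)")

    grid = config.grid.to_spec(design)
    rs_map = mapping.compute_resolution_map(models, grid, column, instrument)
    map_path = out / "resolution_map.csv"
    rs_map.to_frame().to_csv(map_path, index=False)

    modr = mapping.extract_modr(rs_map, config.rs_threshold)
    modr_path = out / "modr.json"
    modr_path.write_text(json.dumps(modr, indent=2, sort_keys=True))
    log(f"MODR: {modr['n_passing']}/{modr['n_cells']} cells at Rs,crit >= "
        f"{config.rs_threshold}")

    report = {
        "n_analytes": len(models),
        "max_fit_residual_min": max(m.fit_residual_min for m in models.values()),
        "modr_fraction": modr["fraction_passing"],
    }
    if truth is not None:
        # predicted vs truth-forward retention times at the map's best cell
        best = max(
            (c for c in modr["cells"]), key=lambda c: c["rs_crit"], default=None
        )
        if best is not None:
            from .system import RunConditions

            prog = GradientProgram.linear(design.phi0, design.phif, best["tG_min"])
            cond = RunConditions(
                flow_ml_min=grid.flow_ml_min,
                temperature_c=best["temp_c"],
                ternary_fraction=best["ternary_fraction"],
            )
            from .engine import predict_retention_time

            rows = []
            for t in truth:
                coeffs = t.coefficients_at(cond.temperature_c, cond.ternary_fraction)
                true_rt = predict_retention_time(coeffs, prog, cond, column, instrument)
                model_coeffs = models[t.analyte_id].interpolate(
                    cond.temperature_c, cond.ternary_fraction
                )
                pred_rt = predict_retention_time(model_coeffs, prog, cond, column, instrument)
                rows.append(validation.ComparisonRow(t.analyte_id, pred_rt, true_rt))
            report["setpoint"] = best
            report["mean_abs_error_pct"] = validation.mean_abs_error(rows)
    report_path = out / "validation_report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))

    manifest = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"artifacts": manifest, "report": report}
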