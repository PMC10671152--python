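import numpy as np
import pytest

from retmod.engine import PeakRecord, predict_peak
from retmod.errors import ValidationError
from retmod.mapping import (
    GridSpec,
    compute_resolution_map,
    critical_resolution,
    extract_modr,
    resolution,
    robustness_scan,
    simulate_separation,
)
from retmod.system import GradientProgram, RunConditions


def _peak(name, tr, width=0.5):
    return PeakRecord(name, tr, width, 0.5, 2.0)


def _brute_force_chromatogram(models, program, cond, column, instrument, include):
    """Independent per-analyte recomputation of peaks and adjacent Rs."""
    peaks = sorted(
        (
            predict_peak(
                name,
                models[name].interpolate(cond.temperature_c, cond.ternary_fraction),
                program,
                cond,
                column,
                instrument,
            )
            for name in include
        ),
        key=lambda p: p.retention_time,
    )
    rs = [
        2 * (b.retention_time - a.retention_time) / (a.width_4sigma + b.width_4sigma)
        for a, b in zip(peaks, peaks[1:])
    ]
    return peaks, rs


class TestResolution:
    def test_formula(self):
        assert resolution(_peak("a", 10.0), _peak("b", 11.0)) == pytest.approx(2.0)

    def test_symmetry_under_peak_swap(self):
        p, q = _peak("a", 10.0, 0.4), _peak("b", 11.3, 0.8)
        assert resolution(p, q) == resolution(q, p)

    def test_coeluting_peaks_give_zero(self):
        assert resolution(_peak("a", 10.0), _peak("b", 10.0)) == 0.0


class TestSimulateSeparation:
    def test_adjacent_resolutions_match_brute_force(
        self, models9, column, instrument
    ):
        prog = GradientProgram.linear(0.30, 1.00, 37.0)
        cond = RunConditions(flow_ml_min=0.5, temperature_c=17.0, ternary_fraction=0.3)
        include = set(models9)
        chrom = simulate_separation(models9, prog, cond, column, instrument, include)
        peaks, rs = _brute_force_chromatogram(
            models9, prog, cond, column, instrument, include
        )
        assert [p.analyte_id for p in chrom.peaks] == [p.analyte_id for p in peaks]
        assert [r for _, r in chrom.adjacent_resolutions] == pytest.approx(rs)
        assert len(chrom.adjacent_resolutions) == len(chrom.peaks) - 1

    def test_single_analyte_has_no_critical_pair(self, models9, column, instrument):
        prog = GradientProgram.linear(0.30, 1.00, 30.0)
        cond = RunConditions(flow_ml_min=0.5, temperature_c=20.0)
        only = sorted(models9)[0]
        chrom = simulate_separation(models9, prog, cond, column, instrument, {only})
        assert chrom.adjacent_resolutions == ()
        assert chrom.critical is None
        assert critical_resolution(chrom) is None

    def test_empty_include_rejected(self, models9, column, instrument):
        prog = GradientProgram.linear(0.30, 1.00, 30.0)
        cond = RunConditions(flow_ml_min=0.5, temperature_c=20.0)
        with pytest.raises(ValidationError):
            simulate_separation(models9, prog, cond, column, instrument, set())

    def test_exclusion_never_shifts_remaining_peaks(self, models9, column, instrument):
        """Dropping analytes from the include set leaves the others'
        retention times and widths untouched."""
        prog = GradientProgram.linear(0.30, 1.00, 45.0)
        cond = RunConditions(flow_ml_min=0.5, temperature_c=10.0, ternary_fraction=0.8)
        full = simulate_separation(models9, prog, cond, column, instrument)
        keep = set(sorted(models9)[:5])
        reduced = simulate_separation(models9, prog, cond, column, instrument, keep)
        full_by_id = {p.analyte_id: p for p in full.peaks}
        for p in reduced.peaks:
            assert p.retention_time == full_by_id[p.analyte_id].retention_time
            assert p.width_4sigma == full_by_id[p.analyte_id].width_4sigma


class TestCriticalResolution:
    def test_minimum_of_adjacent_pairs(self):
        from retmod.mapping import VirtualChromatogram

        chrom = VirtualChromatogram(
            peaks=(),
            adjacent_resolutions=(
                (("a", "b"), 2.1),
                (("b", "c"), 1.3),
                (("c", "d"), 4.0),
            ),
            critical=None,
        )
        pair, rs = critical_resolution(chrom)
        assert pair == ("b", "c") and rs == 1.3

    def test_tie_breaks_to_earlier_pair(self):
        from retmod.mapping import VirtualChromatogram

        chrom = VirtualChromatogram(
            peaks=(),
            adjacent_resolutions=((("a", "b"), 1.5), (("b", "c"), 1.5)),
            critical=None,
        )
        pair, _ = critical_resolution(chrom)
        assert pair == ("a", "b")


@pytest.fixture(scope="module")
def small_map(models9, column, instrument):
    grid = GridSpec(
        tG_min=(20.0, 30.0, 40.0, 50.0, 60.0),
        temp_c=(5.0, 15.0, 25.0, 35.0),
        ternary_fraction=(0.0, 0.5, 1.0),
    )
    return grid, compute_resolution_map(models9, grid, column, instrument)


class TestResolutionMap:
    def test_every_cell_matches_brute_force(self, small_map, models9, column, instrument):
        grid, rs_map = small_map
        include = sorted(models9)
        for i, tG in enumerate(grid.tG_min):
            prog = GradientProgram.linear(0.30, 1.00, tG)
            for j, T in enumerate(grid.temp_c):
                for k, x in enumerate(grid.ternary_fraction):
                    cond = RunConditions(
                        flow_ml_min=0.5, temperature_c=T, ternary_fraction=x
                    )
                    _, rs = _brute_force_chromatogram(
                        models9, prog, cond, column, instrument, include
                    )
                    assert rs_map.values[i, j, k] == pytest.approx(min(rs))

    def test_single_cell_grid_equals_direct_call(self, models9, column, instrument):
        grid = GridSpec(tG_min=(33.0,), temp_c=(22.0,), ternary_fraction=(0.4,))
        rs_map = compute_resolution_map(models9, grid, column, instrument)
        prog = GradientProgram.linear(0.30, 1.00, 33.0)
        cond = RunConditions(flow_ml_min=0.5, temperature_c=22.0, ternary_fraction=0.4)
        chrom = simulate_separation(models9, prog, cond, column, instrument)
        assert rs_map.values[0, 0, 0] == chrom.critical[1]
        assert rs_map.limiting_pairs[0, 0, 0] == chrom.critical[0]

    def test_map_export_rounds_only_at_reporting_layer(self, small_map):
        _, rs_map = small_map
        df = rs_map.to_frame(decimals=2)
        assert len(df) == rs_map.values.size
        raw = rs_map.to_frame(decimals=None)
        assert not np.allclose(df["rs_crit"], np.round(raw["rs_crit"], 8))  # rounded copy
        assert np.allclose(df["rs_crit"], np.round(raw["rs_crit"], 2))


class TestModr:
    def test_filter_equals_brute_force(self, models9, column, instrument):
        grid = GridSpec(
            tG_min=(20.0, 40.0, 60.0),
            temp_c=(5.0, 20.0, 35.0),
            ternary_fraction=(0.0, 1.0),
        )
        rs_map = compute_resolution_map(models9, grid, column, instrument)
        modr = extract_modr(rs_map, threshold=1.5)
        expected = int((rs_map.values >= 1.5).sum())
        assert modr["n_passing"] == expected
        for cell in modr["cells"]:
            assert cell["rs_crit"] >= 1.5

    def test_all_pass_and_empty_cases(self, models9, column, instrument):
        grid = GridSpec(tG_min=(60.0,), temp_c=(20.0,), ternary_fraction=(0.5,))
        rs_map = compute_resolution_map(models9, grid, column, instrument)
        assert extract_modr(rs_map, threshold=0.0)["n_passing"] == 1
        empty = extract_modr(rs_map, threshold=1e9)
        assert empty["n_passing"] == 0 and empty["empty"] is True

    def test_modr_cells_resimulate_above_threshold(self, models9, column, instrument):
        grid = GridSpec(
            tG_min=(30.0, 60.0), temp_c=(5.0, 35.0), ternary_fraction=(0.0, 1.0)
        )
        rs_map = compute_resolution_map(models9, grid, column, instrument)
        modr = extract_modr(rs_map, threshold=1.0)
        for cell in modr["cells"]:
            prog = GradientProgram.linear(0.30, 1.00, cell["tG_min"])
            cond = RunConditions(
                flow_ml_min=0.5,
                temperature_c=cell["temp_c"],
                ternary_fraction=cell["ternary_fraction"],
            )
            chrom = simulate_separation(models9, prog, cond, column, instrument)
            assert chrom.critical[1] >= 1.0


@pytest.fixture(scope="module")
def setpoint():
    return (
        GradientProgram.linear(0.30, 1.00, 40.0),
        RunConditions(flow_ml_min=0.5, temperature_c=20.0, ternary_fraction=0.5),
    )


class TestRobustness:
    def test_three_params_three_levels_give_27_combinations(
        self, models9, column, instrument, setpoint
    ):
        prog, cond = setpoint
        out = robustness_scan(
            models9, prog, cond, column, instrument,
            tolerances={"tG_min": 2.0, "temp_c": 2.0, "ternary_fraction": 0.05},
        )
        assert out["n_combinations"] == 27
        assert out["min_rs_crit"] <= out["nominal_rs_crit"] <= out["max_rs_crit"]

    def test_zero_tolerances_collapse_to_nominal(
        self, models9, column, instrument, setpoint
    ):
        prog, cond = setpoint
        out = robustness_scan(
            models9, prog, cond, column, instrument,
            tolerances={"tG_min": 0.0, "temp_c": 0.0},
        )
        assert out["min_rs_crit"] == out["max_rs_crit"] == out["nominal_rs_crit"]

    def test_worst_case_equals_enumeration(self, models9, column, instrument, setpoint):
        prog, cond = setpoint
        tol = {"tG_min": 2.0, "temp_c": 2.0, "ternary_fraction": 0.05}
        out = robustness_scan(models9, prog, cond, column, instrument, tolerances=tol)
        # independent enumeration
        import itertools

        best = []
        for dtg, dT, dx in itertools.product((-1, 0, 1), repeat=3):
            p = prog.stretched_to(40.0 + dtg * 2.0) if dtg else prog
            c = RunConditions(
                flow_ml_min=0.5,
                temperature_c=20.0 + dT * 2.0,
                ternary_fraction=0.5 + dx * 0.05,
            )
            chrom = simulate_separation(models9, p, c, column, instrument)
            best.append(chrom.critical[1])
        assert out["min_rs_crit"] == pytest.approx(min(best))
        assert out["max_rs_crit"] == pytest.approx(max(best))

    def test_ternary_clipping_warns(self, models9, column, instrument):
        prog = GradientProgram.linear(0.30, 1.00, 40.0)
        cond = RunConditions(flow_ml_min=0.5, temperature_c=20.0, ternary_fraction=0.0)
        with pytest.warns(UserWarning, match="clipped"):
            out = robustness_scan(
                models9, prog, cond, column, instrument,
                tolerances={"ternary_fraction": 0.05}, levels=2,
            )
        assert out["n_combinations"] == 3  # 2 corners + nominal
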