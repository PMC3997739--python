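import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, box

from coralhsm.grid import Grid, GridSpec
from coralhsm.overlap_reports import (
    KM2_PER_NM2,
    SUBSTRATE_HARD,
    SUBSTRATE_MIXED,
    SUBSTRATE_SOFT,
    intensity_by_class,
    niche_summary,
    resample_substrate_majority,
    substrate_cross_tab,
    trawl_line_density,
    zonal_area,
)
from coralhsm.spatial_cv import ConsensusGrid


def _consensus(data, spec, k=4):
    return ConsensusGrid(Grid(np.asarray(data, float), spec), k=k, threshold=0.5)


class TestZonalArea:
    def test_four_cells_class_two(self, small_spec):
        data = np.zeros((10, 10))
        data[0:2, 0:2] = 2
        cons = _consensus(data, small_spec)
        polys = {"P": box(0, 0, 1000, 1000)}
        report = zonal_area(cons, polys)
        assert report.loc["P", "class_2_km2"] == pytest.approx(4 * 0.25)
        assert report.loc["P", "suitable_pct"] == pytest.approx(100.0)
        assert report.loc["P", "class_2_nm2"] == pytest.approx(1.0 / KM2_PER_NM2)

    def test_all_zero_consensus(self, small_spec):
        cons = _consensus(np.zeros((10, 10)), small_spec)
        report = zonal_area(cons, {"P": box(0, 0, 2000, 2000)})
        assert report.loc["P", "suitable_pct"] == 0.0

    def test_outside_polygon_zero_row(self, small_spec):
        cons = _consensus(np.ones((10, 10)), small_spec)
        report = zonal_area(cons, {"far": box(99000, 99000, 99500, 99500)})
        assert report.loc["far", "total_km2"] == 0.0

    def test_matches_brute_force_oracle(self):
        spec = GridSpec(0, 0, 500.0, 10, 10)
        rng = np.random.default_rng(3)
        for _ in range(10):
            data = rng.integers(0, 5, size=(10, 10)).astype(float)
            cons = _consensus(data, spec)
            x0, y0 = rng.uniform(0, 3000, size=2)
            poly = box(x0, y0, x0 + rng.uniform(500, 3000), y0 + rng.uniform(500, 3000))
            report = zonal_area(cons, {"P": poly})
            # oracle: loop over every cell center
            counts = {k: 0 for k in range(5)}
            for r in range(10):
                for c in range(10):
                    center = Point((c + 0.5) * 500, (r + 0.5) * 500)
                    if poly.contains(center):
                        counts[int(data[r, c])] += 1
            for k in range(5):
                assert report.loc["P", f"class_{k}_km2"] == pytest.approx(counts[k] * 0.25)

    def test_class_areas_sum_to_total(self, small_spec):
        rng = np.random.default_rng(0)
        cons = _consensus(rng.integers(0, 5, size=(10, 10)), small_spec)
        report = zonal_area(cons, {"P": box(250, 250, 4750, 4750)})
        class_sum = sum(report.loc["P", f"class_{k}_km2"] for k in range(5))
        assert class_sum == pytest.approx(report.loc["P", "total_km2"])


class TestSubstrateCrossTab:
    def test_uniform_hard(self, small_spec):
        cons = _consensus(np.zeros((10, 10)), small_spec, k=1)
        sub = Grid(np.full((10, 10), float(SUBSTRATE_HARD)), small_spec)
        tab = substrate_cross_tab(cons, sub)
        assert tab.loc[0, "hard_pct"] == pytest.approx(100.0)

    def test_hand_computed_toy(self, small_spec):
        data = np.zeros((10, 10))
        data[:, 5:] = 1
        sub = np.full((10, 10), float(SUBSTRATE_SOFT))
        sub[:, 5:8] = SUBSTRATE_HARD  # class 1: 30 hard, 20 soft
        tab = substrate_cross_tab(_consensus(data, small_spec, k=1), Grid(sub, small_spec))
        assert tab.loc[1, "hard_pct"] == pytest.approx(60.0)
        assert tab.loc[1, "soft_pct"] == pytest.approx(40.0)
        assert tab.loc[0, "soft_pct"] == pytest.approx(100.0)

    def test_percentages_sum_to_100(self, small_spec):
        rng = np.random.default_rng(1)
        cons = _consensus(rng.integers(0, 3, size=(10, 10)), small_spec, k=2)
        sub = Grid(rng.integers(0, 3, size=(10, 10)).astype(float), small_spec)
        tab = substrate_cross_tab(cons, sub)
        for k in tab.index:
            if tab.loc[k, "n_cells"] > 0:
                total = tab.loc[k, ["hard_pct", "mixed_pct", "soft_pct"]].sum()
                assert total == pytest.approx(100.0, abs=0.1)

    def test_absent_class_is_nan(self, small_spec):
        cons = _consensus(np.zeros((10, 10)), small_spec, k=4)
        sub = Grid(np.zeros((10, 10)), small_spec)
        tab = substrate_cross_tab(cons, sub)
        assert np.isnan(tab.loc[3, "hard_pct"])

    def test_majority_resample_tie_break(self):
        fine = GridSpec(0, 0, 250.0, 2, 2)
        coarse = GridSpec(0, 0, 500.0, 1, 1)
        # 2 hard, 2 soft in one coarse cell: tie -> hard
        sub = Grid(np.array([[2.0, 0.0], [0.0, 2.0]]), fine)
        out = resample_substrate_majority(sub, coarse)
        assert out.data[0, 0] == SUBSTRATE_HARD

    def test_finer_grid_resampled(self, small_spec, truth):
        cons = _consensus(np.zeros((10, 10)), small_spec, k=1)
        fine_spec = GridSpec(0, 0, 250.0, 20, 20)
        rng = np.random.default_rng(0)
        sub = Grid(rng.integers(0, 3, size=(20, 20)).astype(float), fine_spec)
        tab = substrate_cross_tab(cons, sub)
        assert tab.loc[0, "n_cells"] == 100


class TestTrawlDensity:
    def test_no_lines_all_zero_unmasked(self, small_spec):
        out = trawl_line_density([], small_spec, min_vessels=0)
        assert (out.grid.data == 0).all()
        assert out.n_masked == 0

    def test_no_lines_masked_with_privacy(self, small_spec):
        out = trawl_line_density([], small_spec)
        assert np.isnan(out.grid.data).all()

    def test_chord_through_center(self):
        # one long straight line through a cell center: chord = 2r = 6 km,
        # density = 6 / (9 pi); privacy disabled
        spec = GridSpec(0, 0, 500.0, 1, 1)
        line = (np.array([[-50_000.0, 250.0], [50_000.0, 250.0]]), "V0")
        out = trawl_line_density([line], spec, radius=3_000.0, min_vessels=0)
        assert out.grid.data[0, 0] == pytest.approx(6.0 / (9 * np.pi), rel=1e-9)

    def test_three_collinear_vessels(self):
        spec = GridSpec(0, 0, 500.0, 1, 1)
        lines = [
            (np.array([[-50_000.0, 250.0], [50_000.0, 250.0]]), f"V{i}") for i in range(3)
        ]
        out = trawl_line_density(lines, spec, radius=3_000.0)
        assert out.grid.data[0, 0] == pytest.approx(3 * 6.0 / (9 * np.pi), rel=1e-9)

    def test_two_vessels_masked(self):
        spec = GridSpec(0, 0, 500.0, 1, 1)
        lines = [
            (np.array([[-50_000.0, 250.0], [50_000.0, 250.0]]), "V0"),
            (np.array([[-50_000.0, 200.0], [50_000.0, 200.0]]), "V1"),
        ]
        out = trawl_line_density(lines, spec)
        assert np.isnan(out.grid.data[0, 0])
        assert out.n_masked == 1

    def test_degenerate_segments_ignored(self, small_spec):
        lines = [(np.array([[100.0, 100.0], [100.0, 100.0]]), "V0")]
        out = trawl_line_density(lines, small_spec, min_vessels=0)
        assert (out.grid.data == 0).all()

    def test_zero_radius_raises(self, small_spec):
        with pytest.raises(ValueError):
            trawl_line_density([], small_spec, radius=0.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        spec = GridSpec(0, 0, 500.0, 6, 6)
        lines = [(rng.uniform(0, 3000, size=(2, 2)), f"V{i}") for i in range(4)]
        out1 = trawl_line_density(lines, spec, min_vessels=0)
        shift = np.array([10_000.0, -4_000.0])
        spec2 = GridSpec(shift[0], shift[1], 500.0, 6, 6)
        lines2 = [(v + shift, vid) for v, vid in lines]
        out2 = trawl_line_density(lines2, spec2, min_vessels=0)
        np.testing.assert_allclose(out1.grid.data, out2.grid.data, rtol=1e-9)


class TestIntensityByClass:
    def test_all_zero_intensity(self, small_spec):
        cons = _consensus(np.zeros((10, 10)), small_spec, k=1)
        intensity = trawl_line_density([], small_spec, min_vessels=0)
        table = intensity_by_class(cons, intensity, bins=[0, 1e-9, 1.0, np.inf])
        assert table.loc[0, "row_total"] == 100
        assert table.iloc[0, 0] == 100  # everything in the zero bin

    def test_total_conservation(self, small_spec):
        rng = np.random.default_rng(4)
        cons = _consensus(rng.integers(0, 3, (10, 10)), small_spec, k=2)
        grid = Grid(rng.uniform(0, 2, (10, 10)), small_spec)
        from coralhsm.overlap_reports import TrawlIntensityGrid

        intensity = TrawlIntensityGrid(grid, radius=3000.0, n_masked=0)
        table = intensity_by_class(cons, intensity, bins=[0, 0.5, 1.0, np.inf])
        assert table["row_total"].sum() == 100

    def test_six_cell_toy(self):
        spec = GridSpec(0, 0, 500.0, 2, 3)
        cons = _consensus([[0, 0, 1], [1, 1, 0]], spec, k=1)
        from coralhsm.overlap_reports import TrawlIntensityGrid

        vals = Grid(np.array([[0.1, 0.6, 0.1], [0.6, 0.6, 0.1]]), spec)
        intensity = TrawlIntensityGrid(vals, radius=3000.0, n_masked=0)
        table = intensity_by_class(cons, intensity, bins=[0, 0.5, np.inf])
        assert table.loc[0, "[0,0.5)"] == 2 and table.loc[0, "[0.5,inf)"] == 1
        assert table.loc[1, "[0,0.5)"] == 1 and table.loc[1, "[0.5,inf)"] == 2


class TestNicheSummary:
    def test_fraction_in_range(self):
        frame = pd.DataFrame({"omega": [0.5, 1.5, 1.8, 2.5]})
        summary, _ = niche_summary(frame, ranges={"omega": (1.0, 2.0)})
        assert summary.loc["omega", "fraction_in_range"] == pytest.approx(0.5)

    def test_all_inside_range(self):
        frame = pd.DataFrame({"omega": [1.0, 1.5, 1.99]})
        summary, _ = niche_summary(frame, ranges={"omega": (1.0, 2.0)})
        assert summary.loc["omega", "fraction_in_range"] == pytest.approx(1.0)

    def test_min_max(self):
        frame = pd.DataFrame({"t": [3.0, 7.0, 5.0]})
        summary, _ = niche_summary(frame)
        assert summary.loc["t", "min"] == 3.0 and summary.loc["t", "max"] == 7.0

    def test_all_nodata_empty_row(self):
        frame = pd.DataFrame({"t": [np.nan, np.nan]})
        summary, traces = niche_summary(frame)
        assert summary.loc["t", "n"] == 0
        assert "t" not in traces

    def test_density_trace_present(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({"t": rng.normal(size=200)})
        _, traces = niche_summary(frame)
        assert len(traces["t"]) == 50
        assert (traces["t"]["density"] >= 0).all()


def test_hard_substrate_increases_with_suitability(pipeline_result):
    """Qualitative cross-tab pattern: hard-substrate share is larger in the
    suitable classes than in class 0."""
    tab = pipeline_result.reports["substrate"]
    occupied = tab[tab["n_cells"] > 20]
    assert occupied["hard_pct"].iloc[-1] > occupied["hard_pct"].iloc[0]
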