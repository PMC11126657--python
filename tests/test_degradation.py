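import math

import numpy as np
import pandas as pd
import pytest

import wetdyn as w
from wetdyn.degradation import (
    METRIC_GROUPS,
    PatchSet,
    Patch,
    assign_cells_to_hexagons,
    build_hexgrid,
    hex_side_for_area,
)


class TestHexGrid:
    def test_side_closed_form_for_standard_unit(self):
        assert hex_side_for_area(40_000.0) == pytest.approx(12_408.0, abs=0.1)

    def test_every_unit_area_exact(self):
        grid = w.GridSpec(200, 200, 30.0)
        hg = build_hexgrid(grid, unit_area_ha=100.0)
        for poly in hg.polygons:
            assert poly.area == pytest.approx(100.0 * 10_000.0, rel=1e-6)

    def test_union_covers_every_cell_center(self):
        grid = w.GridSpec(120, 90, 30.0, origin_x=-500.0, origin_y=777.0)
        hg = build_hexgrid(grid, unit_area_ha=50.0)
        units = assign_cells_to_hexagons(grid, hg)
        assert np.all(units >= 0)

    def test_units_do_not_overlap(self):
        grid = w.GridSpec(60, 60, 30.0)
        hg = build_hexgrid(grid, unit_area_ha=30.0)
        total_intersection = 0.0
        for i in range(len(hg)):
            for j in range(i + 1, len(hg)):
                total_intersection += hg.polygons[i].intersection(hg.polygons[j]).area
        assert total_intersection == pytest.approx(0.0, abs=1e-6)

    def test_small_extent_warns_single_unit(self):
        grid = w.GridSpec(10, 10, 30.0)
        with pytest.warns(UserWarning, match="smaller than one"):
            hg = build_hexgrid(grid, unit_area_ha=40_000.0)
        assert len(hg) >= 1


def one_unit_hexgrid(grid):
    """A hexgrid whose first unit comfortably contains the whole raster."""
    area_ha = (grid.n_rows * grid.n_cols * grid.cell_area_ha) * 50
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_hexgrid(grid, unit_area_ha=area_ha)


class TestPatches:
    def test_square_block_geometry(self):
        grid = w.GridSpec(20, 20, 30.0)
        vals = np.zeros(grid.shape, dtype=int)
        vals[5:15, 5:15] = 1
        raster = w.CategoricalRaster(grid, vals + 1)  # block = class 2, bg = 1
        hg = one_unit_hexgrid(grid)
        patches = w.extract_patches(raster, hg, class_code=2)
        ps = next(p for p in patches.values() if p.n)
        assert ps.n == 1
        assert ps.patches[0].area_m2 == pytest.approx(90_000.0)
        assert ps.patches[0].perimeter_m == pytest.approx(1_200.0)

    def test_diagonal_cells_connectivity(self):
        grid = w.GridSpec(4, 4, 30.0)
        vals = np.zeros(grid.shape, dtype=int)
        vals[1, 1] = vals[2, 2] = 1
        raster = w.CategoricalRaster(grid, vals)
        hg = one_unit_hexgrid(grid)
        four = w.extract_patches(raster, hg, 1, connectivity=4)
        eight = w.extract_patches(raster, hg, 1, connectivity=8)
        assert max(p.n for p in four.values()) == 2
        assert max(p.n for p in eight.values()) == 1

    def test_checkerboard_edges_match_brute_force(self, rng):
        for _ in range(5):
            grid = w.GridSpec(8, 8, 30.0)
            vals = rng.choice([0, 1], size=grid.shape)
            raster = w.CategoricalRaster(grid, vals)
            hg = one_unit_hexgrid(grid)
            ps = next(iter(w.extract_patches(raster, hg, 1, connectivity=4).values()))
            # brute force: count exposed edges of every class-1 cell
            edges = 0
            for r in range(8):
                for c in range(8):
                    if vals[r, c] != 1:
                        continue
                    for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                        rr, cc = r + dr, c + dc
                        if not (0 <= rr < 8 and 0 <= cc < 8) or vals[rr, cc] != 1:
                            edges += 1
            assert ps.total_edge_m == pytest.approx(edges * 30.0)

    def test_absent_class_gives_empty_patchset(self):
        grid = w.GridSpec(5, 5, 30.0)
        raster = w.CategoricalRaster(grid, np.ones(grid.shape, dtype=int))
        hg = one_unit_hexgrid(grid)
        ps = next(iter(w.extract_patches(raster, hg, 3).values()))
        assert ps.n == 0
        assert w.compute_metrics(ps) is None


class TestMetrics:
    def _square_patchset(self):
        # one 10x10-cell square patch at 30 m, alone in a 90,000 m^2 unit
        return PatchSet(
            unit_id=0,
            class_code=1,
            patches=[Patch(area_m2=90_000.0, perimeter_m=1_200.0)],
            unit_land_area_m2=90_000.0,
        )

    def test_square_closed_forms(self):
        m = w.compute_metrics(self._square_patchset())
        assert m["CA"] == pytest.approx(9.0)
        assert m["MPS"] == pytest.approx(9.0)
        assert m["ED"] == pytest.approx(1_200.0 / 90_000.0 * 10_000.0)
        assert m["MPFD"] == pytest.approx(2 * math.log(300) / math.log(90_000))
        assert m["MPFD"] == pytest.approx(1.0, abs=1e-9)
        assert m["MSI"] == pytest.approx(1.0)

    def test_ranges_on_random_landscapes(self, rng):
        legend = w.default_legend()
        grid = w.GridSpec(40, 40, 30.0)
        hg = build_hexgrid(grid, unit_area_ha=20.0)
        for _ in range(10):
            raster = w.CategoricalRaster(grid, rng.choice([1, 2, 3, 4, 5], size=grid.shape))
            table = w.metric_table(raster, hg, legend)
            assert (table["MPFD"] >= 1.0 - 1e-9).all()
            assert (table["MPFD"] <= 2.0 + 1e-9).all()
            assert (table["MSI"] >= 1.0 - 1e-9).all()
            assert (table["ED"] >= 0).all()
            assert (table["CA"] >= 0).all()
            assert (table["MPS"] > 0).all()


class TestNormalization:
    def test_min_max_closed_forms(self):
        table = pd.DataFrame(
            {
                "unit": [0, 1, 2],
                "class": [1, 1, 1],
                "CA": [2.0, 4.0, 8.0],
                "MPS": [1.0, 1.0, 1.0],
                "ED": [0.0, 5.0, 10.0],
                "MPFD": [1.0, 1.5, 2.0],
                "MSI": [1.0, 2.0, 3.0],
            }
        )
        z = w.normalize_metrics(table)
        np.testing.assert_allclose(z["CA"], [0.0, 1 / 3, 1.0])
        np.testing.assert_allclose(z["MPS"], [0.0, 0.0, 0.0])  # degenerate span
        np.testing.assert_allclose(z["ED"], [0.0, 0.5, 1.0])

    def test_scale_invariance_of_z(self):
        table = pd.DataFrame(
            {
                "unit": [0, 1, 2],
                "class": [1, 1, 1],
                "CA": [2.0, 4.0, 8.0],
                "MPS": [1.0, 2.0, 4.0],
                "ED": [1.0, 2.0, 3.0],
                "MPFD": [1.0, 1.2, 1.4],
                "MSI": [1.0, 2.0, 3.0],
            }
        )
        scaled = table.copy()
        scaled["CA"] *= 1000.0
        np.testing.assert_allclose(
            w.normalize_metrics(table)["CA"], w.normalize_metrics(scaled)["CA"]
        )


class TestCodes:
    @pytest.mark.parametrize(
        "z,suitable,group,expected",
        [
            (0.8, False, 1, 4),  # abundant unsuitable cover: worst code
            (0.1, True, 2, 1),  # low edge complexity of suitable cover: best
            (0.25, False, 1, 2),  # lower-closed interval boundary
            (1.0, False, 1, 4),  # final interval closed
            (0.1, False, 2, 4),
            (0.8, True, 1, 1),
        ],
    )
    def test_table_mapping(self, z, suitable, group, expected):
        assert w.assign_codes(z, suitable, group) == expected

    def test_z_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            w.assign_codes(1.2, True, 1)


class TestVulnerabilityAndLd:
    def _uniform_map(self, code, grid=None):
        grid = grid or w.GridSpec(30, 30, 30.0)
        return w.CategoricalRaster(grid, np.full(grid.shape, code))

    def test_all_water_unit_has_v_one_and_zero_ld(self, legend):
        raster = self._uniform_map(2)
        hg = one_unit_hexgrid(raster.grid)
        v = w.vulnerability(raster, hg, legend)
        assert (v == 1.0).all()
        result = w.degradation_scores(raster, hg, legend)
        assert (result.table["LD"] == 0.0).all()

    def test_all_salt_unit_floored_denominator(self, legend):
        raster = self._uniform_map(5)
        hg = one_unit_hexgrid(raster.grid)
        v = w.vulnerability(raster, hg, legend)
        assert (v == 0.0).all()
        result = w.degradation_scores(raster, hg, legend)
        # one class x five metrics, all Z degenerate at 0 -> codes via mapping
        assert (result.table["LD"] == result.table["sum_KI"] / 0.01).all()

    def test_salt_scores_strictly_higher_than_water(self, legend):
        raster_salt = self._uniform_map(5)
        raster_water = self._uniform_map(2)
        hg = one_unit_hexgrid(raster_salt.grid)
        ld_salt = w.degradation_scores(raster_salt, hg, legend).total_ld
        ld_water = w.degradation_scores(raster_water, hg, legend).total_ld
        assert ld_salt > ld_water

    def test_fraction_of_suitable_cells(self, legend):
        grid = w.GridSpec(10, 10, 30.0)
        vals = np.full(grid.shape, 5)
        vals.ravel()[:60] = 3  # 60 suitable of 100
        raster = w.CategoricalRaster(grid, vals)
        hg = one_unit_hexgrid(grid)
        v = w.vulnerability(raster, hg, legend)
        assert v.iloc[0] == pytest.approx(0.6)

    def test_degrading_cover_never_decreases_ld(self, legend, rng):
        """Converting suitable to unsuitable cover in one unit leaves LD no lower."""
        grid = w.GridSpec(40, 40, 30.0)
        vals = rng.choice([1, 2, 3, 4, 5], size=grid.shape)
        raster = w.CategoricalRaster(grid, vals)
        hg = one_unit_hexgrid(grid)
        before = w.degradation_scores(raster, hg, legend).total_ld
        worse_vals = vals.copy()
        suitable_cells = np.argwhere(np.isin(vals, [2, 3, 4]))
        picks = suitable_cells[rng.choice(len(suitable_cells), size=100, replace=False)]
        worse_vals[picks[:, 0], picks[:, 1]] = 5
        after = w.degradation_scores(
            w.CategoricalRaster(grid, worse_vals), hg, legend
        ).total_ld
        assert after >= before - 1e-9

    def test_ld_unchanged_under_metric_rescaling(self, legend):
        """Min-max normalization makes LD invariant to a metric's scale."""
        table = pd.DataFrame(
            {
                "unit": [0, 1],
                "class": [5, 5],
                "CA": [1.0, 2.0],
                "MPS": [1.0, 2.0],
                "ED": [10.0, 20.0],
                "MPFD": [1.1, 1.5],
                "MSI": [1.2, 2.5],
            }
        )
        v = pd.Series({0: 0.5, 1: 0.5})
        base = w.ld_score(w.normalize_metrics(table), legend, v)
        scaled = table.copy()
        scaled["ED"] *= 77.0
        rescaled = w.ld_score(w.normalize_metrics(scaled), legend, v)
        pd.testing.assert_frame_equal(base.table, rescaled.table)

    def test_group_classification_is_quartile(self, legend, rng):
        grid = w.GridSpec(60, 60, 30.0)
        hg = build_hexgrid(grid, unit_area_ha=20.0)
        raster = w.CategoricalRaster(grid, rng.choice([1, 2, 3, 4, 5], size=grid.shape))
        result = w.degradation_scores(raster, hg, legend)
        assert set(result.table["group"]).issubset({1, 2, 3, 4})
        # group is monotone in LD
        ordered = result.table.sort_values("LD")
        assert ordered["group"].is_monotonic_increasing

    def test_geojson_export(self, legend, tmp_path):
        import json

        raster = self._uniform_map(3)
        hg = one_unit_hexgrid(raster.grid)
        result = w.degradation_scores(raster, hg, legend)
        path = tmp_path / "hex.geojson"
        hg.to_geojson(path, properties=result.table)
        payload = json.loads(path.read_text())
        assert payload["type"] == "FeatureCollection"
        props = payload["features"][0]["properties"]
        assert {"id", "V", "sum_KI", "LD", "group"} <= set(props)
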