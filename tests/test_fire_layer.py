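"""Fire-layer reconstruction: filtering, gridding, T_R, polygons, refugia."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fireflora import fire_layer as fl
from tests.conftest import flood_fill_components


def hotspot_df(rows):
    return pd.DataFrame(rows, columns=["longitude", "latitude", "datetime",
                                       "satellite", "temp_kelvin", "confidence"])


class TestFilterHotspots:
    @pytest.mark.parametrize("satellite,temp,conf,kept", [
        ("HIMAWARI8", 450.0, np.nan, False),   # below the 500 K floor
        ("HIMAWARI8", 500.0, np.nan, False),   # strict inequality
        ("HIMAWARI8", 501.0, np.nan, True),
        ("AQUA", 310.0, 60.0, True),
        ("AQUA", 310.0, 50.0, False),          # confidence strict >50
        ("AQUA", -1.0, 90.0, False),           # requires T > 0
        ("TERRA", 400.0, 75.0, True),
        ("SUOMI_NPP", np.nan, 50.0, False),    # strict boundary
        ("SUOMI_NPP", np.nan, 50.1, True),
    ])
    def test_retention_rules(self, satellite, temp, conf, kept):
        df = hotspot_df([(150.0, -33.0, "2019-12-01T03:00:00", satellite,
                          temp, conf)])
        out = fl.filter_hotspots(df)
        assert (len(out) == 1) == kept

    def test_window_bounds(self):
        rows = [(150, -33, ts, "HIMAWARI8", 800.0, np.nan) for ts in
                ("2019-06-30T23:00:00", "2019-07-01T00:00:00",
                 "2020-02-11T23:59:00", "2020-02-12T00:30:00")]
        out = fl.filter_hotspots(hotspot_df(rows))
        assert list(pd.to_datetime(out["datetime"]).dt.date.astype(str)) == \
            ["2019-07-01", "2020-02-11"]

    def test_unknown_satellite_rejected(self, caplog):
        df = hotspot_df([(150, -33, "2019-12-01", "SENTINEL", 900.0, np.nan)])
        with caplog.at_level("WARNING"):
            out = fl.filter_hotspots(df)
        assert len(out) == 0
        assert "unknown satellite" in caplog.text

    def test_empty_output_is_valid(self):
        out = fl.filter_hotspots(hotspot_df([]))
        assert len(out) == 0


class TestGridHotspots:
    @pytest.fixture
    def geo_grid(self):
        return fl.GridSpec.from_extent_lonlat(150.0, -34.0, 150.5, -33.5, 2500.0)

    def test_per_satellite_maxima(self, geo_grid):
        lon, lat = 150.1, -33.8
        df = hotspot_df([
            (lon, lat, "2019-12-01", "HIMAWARI8", 600.0, np.nan),
            (lon, lat, "2019-12-01", "HIMAWARI8", 1200.0, np.nan),
            (lon, lat, "2019-12-01", "AQUA", 400.0, 80.0),
            (lon, lat, "2019-12-01", "TERRA", 450.0, 80.0),
        ])
        cells = fl.grid_hotspots(df, geo_grid)
        assert len(cells) == 1
        cell = next(iter(cells.values()))
        assert cell.t_max_himawari == 1200.0
        assert cell.t_max_modis == 450.0  # pooled Aqua/Terra maximum

    def test_confidence_only_cell(self, geo_grid):
        df = hotspot_df([(150.1, -33.8, "2019-12-01", "SUOMI_NPP",
                          np.nan, 90.0)])
        cells = fl.grid_hotspots(df, geo_grid)
        cell = next(iter(cells.values()))
        assert cell.t_max_himawari is None and cell.t_max_modis is None
        assert cell.confident_detection

    def test_records_outside_grid_dropped(self, geo_grid, caplog):
        df = hotspot_df([(140.0, -20.0, "2019-12-01", "HIMAWARI8",
                          900.0, np.nan)])
        with caplog.at_level("WARNING"):
            cells = fl.grid_hotspots(df, geo_grid)
        assert cells == {}
        assert "outside the grid" in caplog.text


class TestRelativeTemperature:
    @pytest.mark.parametrize("him,modis,t_r,klass", [
        (1999.9, None, 1.0, "VHIGH"),            # upper rescaling bound
        (400.0, None, 0.0, "LOW"),               # lower rescaling bound
        (500.0, None, (500 - 400) / 1599.9, "LOW"),
        (None, 506.0, 1.0, "VHIGH"),             # polar-orbiter bounds
        (None, 302.1, 0.0, "LOW"),
        (1200.0, 506.0, (1200 - 400) / 1599.9, "HIGH"),  # Himawari precedence
        (None, None, None, "ND"),                # confidence-only cell
        (2500.0, None, 1.0, "VHIGH"),            # clipped above 1
    ])
    def test_rescaling(self, him, modis, t_r, klass):
        cell = fl.FireCell(0, 0, t_max_himawari=him, t_max_modis=modis)
        fl.compute_relative_temperature(cell)
        if t_r is None:
            assert cell.t_r is None
        else:
            assert cell.t_r == pytest.approx(t_r)
        assert cell.temp_class == klass

    @pytest.mark.parametrize("t_r,klass", [
        (0.25, "LOW"), (0.2500001, "MED"), (0.50, "MED"), (0.5000001, "HIGH"),
        (0.75, "HIGH"), (0.7500001, "VHIGH"), (1.0, "VHIGH"),
    ])
    def test_class_boundaries_upper_inclusive(self, t_r, klass):
        assert fl.classify_t_r(t_r) == klass

    @given(st.lists(st.floats(min_value=400.0, max_value=1999.9),
                    min_size=2, max_size=10))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_monotone_within_family(self, temps):
        t_rs = []
        for t in sorted(temps):
            cell = fl.FireCell(0, 0, t_max_himawari=t)
            fl.compute_relative_temperature(cell)
            t_rs.append(cell.t_r)
        assert all(a <= b for a, b in zip(t_rs, t_rs[1:]))


class TestPolygoniseAndPrune:
    def test_small_cool_component_removed(self, plain_grid, make_cells):
        cells = make_cells([(0, 0, 900.0), (0, 1, 900.0),
                            (1, 0, 900.0), (1, 1, 900.0)])  # 25 km^2 exactly
        assert fl.polygonise_and_prune(cells, plain_grid()) == []

    def test_small_hot_component_retained(self, plain_grid, make_cells):
        cells = make_cells([(0, 0, 900.0), (0, 1, 1200.0),
                            (1, 0, 900.0), (1, 1, 900.0)])
        fires = fl.polygonise_and_prune(cells, plain_grid())
        assert len(fires) == 1 and fires[0].max_himawari_k == 1200.0

    def test_large_cool_component_retained(self, plain_grid, make_cells):
        cells = make_cells([(0, c, 600.0) for c in range(5)])  # 31.25 km^2
        fires = fl.polygonise_and_prune(cells, plain_grid())
        assert len(fires) == 1 and fires[0].area_ha == 5 * 625.0

    def test_confidence_only_component_prunable(self, plain_grid):
        cells = {(0, 0): fl.FireCell(0, 0)}  # no temperature at all
        assert fl.polygonise_and_prune(cells, plain_grid()) == []

    @pytest.mark.parametrize("area_ha,label", [
        (625.0 * 200, "MEGAFIRE"), (625.0 * 100, "MAJOR"),
        (625.0 * 80, "MAJOR"), (625.0 * 10, "OTHER")])
    def test_size_labels(self, area_ha, label):
        assert fl.size_label(area_ha) == label

    @given(st.integers(min_value=0, max_value=2 ** 63 - 1))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_components_match_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 21))
        mask = rng.random((n, n)) < 0.4
        cells = {(r, c): fl.FireCell(r, c, t_max_himawari=1500.0)
                 for r, c in zip(*np.nonzero(mask))}
        grid = fl.GridSpec(origin_x=0.0, origin_y=0.0, cell_size_m=2500.0,
                           n_rows=n, n_cols=n)
        fires = fl.polygonise_and_prune(cells, grid)
        got = {frozenset(f.cells) for f in fires}
        # every cell is hot (>1000 K), so no component is pruned
        assert got == flood_fill_components(mask, 8)


class TestRefugia:
    def test_enclosed_single_cell(self, plain_grid, make_cells):
        ring = [(r, c) for r in range(3) for c in range(3) if (r, c) != (1, 1)]
        cells = make_cells([(r + 1, c + 1, 1500.0) for r, c in ring])
        fires = fl.polygonise_and_prune(cells, plain_grid())
        refs = fl.identify_unburnt_interior(fires, plain_grid())
        assert len(refs) == 1
        assert refs[0].area_ha == 625.0 and not refs[0].large_flag

    def test_corridor_to_edge_is_not_refugium(self, plain_grid, make_cells):
        # U-shape open to the grid edge
        cells = make_cells([(r, c, 1500.0) for r in range(3) for c in (0, 2)]
                           + [(2, 1, 1500.0)])
        fires = fl.polygonise_and_prune(cells, plain_grid(3, 3))
        assert fl.identify_unburnt_interior(fires, plain_grid(3, 3)) == []

    def test_large_flag_above_5000_ha(self, plain_grid, make_cells):
        burnt = [(r, c, 1500.0) for r in range(5) for c in range(5)
                 if r in (0, 4) or c in (0, 4)]
        fires = fl.polygonise_and_prune(make_cells(burnt), plain_grid())
        refs = fl.identify_unburnt_interior(fires, plain_grid())
        assert len(refs) == 1
        assert refs[0].area_ha == 9 * 625.0 == 5625.0
        assert refs[0].large_flag

    def test_partition_and_disjointness(self, small_scenario):
        layer = fl.build_fire_layer(small_scenario.hotspots,
                                    small_scenario.landscape.fire_grid,
                                    build_geometry=False)
        total = int(layer.burnt_mask.sum())
        assert total == sum(len(f.cells) for f in layer.fires)
        burnt_cells = {cell for f in layer.fires for cell in f.cells}
        refug_cells = {cell for r in layer.refugia for cell in r.cells}
        assert burnt_cells.isdisjoint(refug_cells)


class TestBuildFireLayer:
    def test_empty_records(self, plain_grid):
        grid = fl.GridSpec.from_extent_lonlat(150.0, -34.0, 150.5, -33.5)
        layer = fl.build_fire_layer(pd.DataFrame(columns=fl.HOTSPOT_COLUMNS),
                                    grid)
        assert layer.fires == [] and layer.total_burnt_area_ha == 0

    def test_deterministic(self, small_scenario):
        grid = small_scenario.landscape.fire_grid
        a = fl.build_fire_layer(small_scenario.hotspots, grid, build_geometry=False)
        b = fl.build_fire_layer(small_scenario.hotspots, grid, build_geometry=False)
        assert np.array_equal(a.burnt_mask, b.burnt_mask)
        assert np.array_equal(a.temp_class_codes, b.temp_class_codes)
        assert [f.cells for f in a.fires] == [f.cells for f in b.fires]

    def test_spurious_clusters_absent(self, small_scenario):
        """Isolated cool clusters in the synthetic stream must be pruned."""
        layer = fl.build_fire_layer(small_scenario.hotspots,
                                    small_scenario.landscape.fire_grid,
                                    build_geometry=False)
        truth = small_scenario.truth.burn_mask
        false_pos = layer.burnt_mask & ~truth
        assert false_pos.sum() == 0

    def test_write_round_trip(self, small_scenario, tmp_path):
        from fireflora import io as ffio
        layer = fl.build_fire_layer(small_scenario.hotspots,
                                    small_scenario.landscape.fire_grid)
        layer.write(tmp_path)
        mask, header = ffio.read_ascii_grid(tmp_path / "burnt_mask.asc")
        assert np.array_equal(np.nan_to_num(mask).astype(bool), layer.burnt_mask)
        fires = ffio.read_geojson(tmp_path / "fires.geojson")
        assert len(fires) == len(layer.fires)
        assert {f["properties"]["size_label"] for f in fires} <= \
            {"MEGAFIRE", "MAJOR", "OTHER"}
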