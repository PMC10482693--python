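import numpy as np
import pandas as pd
import pytest

from conftest import landcover_raster, make_grid
from wuimap.fire import (
    exposure_stats,
    filter_vegetation_fires,
    majority_wui_class,
    presence_grid,
    read_fire_events,
)
from wuimap.grid import LandCover, Raster, RasterKind


def events_df(rows):
    return pd.DataFrame(rows, columns=["x", "y", "date", "source", "category"])


def scene_2x2km(tree_cols=100):
    """2 km x 2 km scene at 10 m: left columns tree cover, rest cropland."""
    g = make_grid(n_rows=200, n_cols=200)
    codes = np.full(g.shape, int(LandCover.CROPLAND))
    codes[:, :tree_cols] = int(LandCover.TREE_COVER)
    return landcover_raster(g, codes)


class TestFilter:
    def test_wildland_share_threshold_on_enclosing_cell(self):
        lc = scene_2x2km(tree_cols=100)  # west km fully wooded, east km cropland
        ev = events_df([
            (500.0, 500.0, "2010-06-01", "MODIS", "vegetation"),   # 100% wildland cell
            (1500.0, 500.0, "2010-06-01", "MODIS", "vegetation"),  # 0% wildland cell
        ])
        kept = filter_vegetation_fires(ev, lc)
        assert len(kept) == 1 and kept.loc[0, "x"] == 500.0

    def test_exactly_half_wildland_cell_dropped(self):
        lc = scene_2x2km(tree_cols=50)  # NW cell is exactly 50% tree
        ev = events_df([(500.0, 500.0, "2010-06-01", "MODIS", "vegetation")])
        assert len(filter_vegetation_fires(lc=lc, events=ev)) == 0  # strict > 50%

    def test_non_vegetation_categories_dropped(self):
        lc = scene_2x2km(tree_cols=200)
        ev = events_df([
            (500.0, 500.0, "2010-06-01", "MODIS", "static"),
            (500.0, 600.0, "2010-06-01", "VIIRS", "volcano"),
            (500.0, 700.0, "2010-06-01", "VIIRS", "vegetation"),
        ])
        kept = filter_vegetation_fires(ev, lc)
        assert kept["category"].tolist() == ["vegetation"]

    def test_out_of_scene_events_dropped(self, caplog):
        lc = scene_2x2km(tree_cols=200)
        ev = events_df([
            (-50.0, 500.0, "2010-06-01", "MODIS", "vegetation"),
            (500.0, 500.0, "2010-06-01", "MODIS", "vegetation"),
        ])
        with caplog.at_level("WARNING"):
            kept = filter_vegetation_fires(ev, lc)
        assert len(kept) == 1
        assert "1 fire event" in caplog.text

    def test_source_column_does_not_affect_filtering(self):
        lc = scene_2x2km(tree_cols=200)
        base = events_df([(500.0, 500.0, "2010-06-01", "MODIS", "vegetation")])
        viirs = base.assign(source="VIIRS")
        assert len(filter_vegetation_fires(base, lc)) == len(filter_vegetation_fires(viirs, lc))

    def test_missing_columns_rejected(self, tmp_path):
        pd.DataFrame({"x": [1.0], "y": [2.0]}).to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(ValueError, match="missing column"):
            read_fire_events(tmp_path / "bad.csv")


class TestPresenceGrid:
    def test_many_occurrences_reduce_to_one(self):
        lc = scene_2x2km()
        ev = events_df([(500.0, 500.0, "2010-06-01", "MODIS", "vegetation")] * 5)
        out = presence_grid(ev, lc.grid)
        assert out.values.sum() == 1 and out.values[1, 0] == 1

    def test_empty_events_give_empty_grid(self):
        lc = scene_2x2km()
        out = presence_grid(events_df([]), lc.grid)
        assert out.values.shape == (2, 2) and not out.values.any()

    def test_half_open_cell_boundary_convention(self):
        lc = scene_2x2km()
        # x = 1000 lies exactly on the boundary: belongs to the east cell
        ev = events_df([(1000.0, 1500.0, "2010-06-01", "MODIS", "vegetation")])
        out = presence_grid(ev, lc.grid)
        assert out.values[0, 1] == 1 and out.values[0, 0] == 0

    def test_idempotent_under_duplication(self, rng):
        lc = scene_2x2km()
        ev = events_df([
            (float(x), float(y), "2010-06-01", "MODIS", "vegetation")
            for x, y in rng.uniform(0, 2000, size=(30, 2))
        ])
        once = presence_grid(ev, lc.grid)
        doubled = presence_grid(pd.concat([ev, ev]), lc.grid)
        np.testing.assert_array_equal(once.values, doubled.values)


class TestExposure:
    def _wui(self, grid, codes):
        return Raster(grid, codes, RasterKind.CATEGORICAL)

    def _pop(self, grid10m, value):
        g = grid10m.coarsen(10)
        return Raster(g, np.full(g.shape, value, float))

    def test_disjoint_fire_and_wui(self):
        lc = scene_2x2km()
        codes = np.zeros(lc.grid.shape, np.uint8)  # all non-WUI
        fire = presence_grid(
            events_df([(500.0, 1500.0, "2010-06-01", "MODIS", "vegetation")]), lc.grid
        )
        pop = self._pop(lc.grid, 1.0)  # 100 people/cell -> 400 total, 100/fire cell
        stats = exposure_stats(fire, self._wui(lc.grid, codes), pop).set_index("statistic")
        assert stats.loc["people_affected", "total"] == 100.0
        assert stats.loc["people_affected_in_wui", "total"] == 0.0
        assert stats.loc["wildfire_area_in_wui_km2", "total"] == 0.0

    def test_area_share_attribution(self):
        lc = scene_2x2km()
        codes = np.zeros(lc.grid.shape, np.uint8)
        codes[:30, :100] = 1  # 30% of the NW 1 km cell is intermix
        fire = presence_grid(
            events_df([(500.0, 1500.0, "2010-06-01", "MODIS", "vegetation")]), lc.grid
        )
        stats = exposure_stats(
            fire, self._wui(lc.grid, codes), self._pop(lc.grid, 0.0)
        ).set_index("statistic")
        assert stats.loc["wildfire_area_km2", "total"] == pytest.approx(1.0)
        assert stats.loc["wildfire_area_in_wui_km2", "total"] == pytest.approx(0.3)
        assert stats.loc["wildfire_area_in_wui_km2", "class_1"] == pytest.approx(0.3)

    def test_saturation_all_population_in_wui_fire_cells(self):
        lc = scene_2x2km()
        codes = np.ones(lc.grid.shape, np.uint8)  # everything intermix
        ev = events_df([
            (x, y, "2010-06-01", "MODIS", "vegetation")
            for x in (500.0, 1500.0) for y in (500.0, 1500.0)
        ])
        fire = presence_grid(ev, lc.grid)
        pop = self._pop(lc.grid, 2.5)
        stats = exposure_stats(fire, self._wui(lc.grid, codes), pop).set_index("statistic")
        total = pop.values.sum()
        assert stats.loc["people_affected", "total"] == pytest.approx(total)
        assert stats.loc["people_affected_in_wui", "total"] == pytest.approx(total)

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_of_affected_people(self, seed):
        rng = np.random.default_rng(seed)
        lc = scene_2x2km()
        codes = rng.choice([0, 1, 2, 3, 4, 255], size=lc.grid.shape).astype(np.uint8)
        ev = events_df([
            (float(x), float(y), "2010-06-01", "MODIS", "vegetation")
            for x, y in rng.uniform(0, 2000, size=(6, 2))
        ])
        fire = presence_grid(ev, lc.grid)
        g100 = lc.grid.coarsen(10)
        pop = Raster(g100, rng.random(g100.shape) * 50)
        stats = exposure_stats(fire, self._wui(lc.grid, codes), pop).set_index("statistic")
        pop_class = majority_wui_class(self._wui(lc.grid, codes), g100)
        fire_fine = np.repeat(np.repeat(fire.values, 10, axis=0), 10, axis=1) == 1
        outside = pop.values[fire_fine & ~np.isin(pop_class, [1, 2, 3, 4])].sum()
        assert stats.loc["people_affected_in_wui", "total"] + outside == pytest.approx(
            stats.loc["people_affected", "total"], rel=1e-12
        )

    def test_empty_fire_grid_warns_and_zeroes(self, caplog):
        lc = scene_2x2km()
        fire = presence_grid(events_df([]), lc.grid)
        with caplog.at_level("WARNING"):
            stats = exposure_stats(
                fire, self._wui(lc.grid, np.zeros(lc.grid.shape, np.uint8)),
                self._pop(lc.grid, 1.0),
            ).set_index("statistic")
        assert (stats["total"] == 0).all()
        assert "empty fire" in caplog.text
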