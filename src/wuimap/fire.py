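"""Active-fire filtering, 1 km presence gridding and exposure statistics.

Satellite active-fire products deliver point detections of thermal
anomalies.  Only detections categorised as vegetation fires count (volcanoes
and static sources such as gas flares are excluded), and of those only
events whose enclosing 1 km cell is majority wildland — this separates
wildfires from agricultural and structural burning.  Fire frequency is then
reduced to presence: a 1 km cell with at least one detection over the
analysis window is a wildfire area, and everyone living in such a cell
counts as affected by wildfire.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import WUI_CODES
from .grid import GridSpec, Raster, RasterKind, pixel_area_km2, resample_to
from .preprocess import reclassify_wildland

__all__ = [
    "exposure_stats",
    "filter_vegetation_fires",
    "majority_wui_class",
    "presence_grid",
    "read_fire_events",
]

logger = logging.getLogger(__name__)

FIRE_COLUMNS = ["x", "y", "date", "source", "category"]


def read_fire_events(path: str | Path) -> pd.DataFrame:
    """Read a fire-event table (CSV with columns x, y, date, source, category)."""
    events = pd.read_csv(path)
    missing = set(FIRE_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"fire CSV missing column(s): {sorted(missing)}")
    return events


def _cell_grid(scene: GridSpec, cell_size_m: float) -> GridSpec:
    factor = cell_size_m / scene.pixel_size
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("cell size must be an integer multiple of the scene pixel size")
    factor = round(factor)
    if scene.n_rows % factor or scene.n_cols % factor:
        raise ValueError("scene extent is not a whole number of cells")
    return scene.coarsen(factor)


def filter_vegetation_fires(
    events: pd.DataFrame,
    lc: Raster,
    cell_size_m: float = 1000.0,
    min_wildland_share: float = 0.5,
) -> pd.DataFrame:
    """Keep vegetation-fire events in majority-wildland 1 km cells.

    An event survives iff its category is ``vegetation`` and the wildland
    share (grassland included) of the enclosing ``cell_size_m`` cell is
    strictly above ``min_wildland_share``.  Events outside the scene are
    dropped and counted in the log.
    """
    if lc.kind != RasterKind.LAND_COVER:
        raise ValueError("lc must be a land-cover raster")
    cell_grid = _cell_grid(lc.grid, cell_size_m)
    wildland = reclassify_wildland(lc, include_grassland=True)
    share = resample_to(wildland, cell_grid, "mean").values

    rows, cols = cell_grid.index_of(events["x"].to_numpy(), events["y"].to_numpy())
    inside = (rows >= 0) & (rows < cell_grid.n_rows) & (cols >= 0) & (cols < cell_grid.n_cols)
    n_out = int((~inside).sum())
    if n_out:
        logger.warning("dropping %d fire event(s) outside the scene", n_out)
    veg = events["category"].to_numpy() == "vegetation"
    keep = inside & veg
    cell_share = np.zeros(len(events))
    cell_share[inside] = np.nan_to_num(share[rows[inside], cols[inside]], nan=0.0)
    keep &= cell_share > min_wildland_share
    return events.loc[keep].reset_index(drop=True)


def presence_grid(
    events: pd.DataFrame, scene: GridSpec, cell_size_m: float = 1000.0
) -> Raster:
    """Binary 1 km fire-presence grid: cell = 1 iff ≥ 1 event falls in it.

    Cells follow the half-open convention ``[x0, x0 + cell)`` so boundary
    coordinates belong to exactly one cell.  Many detections in one cell
    still count as one.
    """
    cell_grid = _cell_grid(scene, cell_size_m)
    out = np.zeros(cell_grid.shape, dtype=np.uint8)
    if len(events):
        rows, cols = cell_grid.index_of(events["x"].to_numpy(), events["y"].to_numpy())
        inside = (rows >= 0) & (rows < cell_grid.n_rows) & (cols >= 0) & (cols < cell_grid.n_cols)
        out[rows[inside], cols[inside]] = 1
    return Raster(cell_grid, out, RasterKind.BINARY, meta={"cell_size_m": cell_size_m})


def majority_wui_class(wui: Raster, target_grid: GridSpec) -> np.ndarray:
    """Majority WUI class code per coarse cell (masked pixels excluded).

    Used to attribute population (100 m) and biomass (300 m) cells to a WUI
    class.  Cells whose pixels are all masked return 255.  Ties break toward
    the lower class code (deterministic).
    """
    factor = round(target_grid.pixel_size / wui.grid.pixel_size)
    if wui.grid.coarsen(factor).shape != target_grid.shape:
        raise ValueError("target grid does not tile the WUI grid")
    blocks = wui.values.reshape(target_grid.n_rows, factor, target_grid.n_cols, factor)
    blocks = blocks.transpose(0, 2, 1, 3).reshape(*target_grid.shape, factor * factor)
    counts = np.stack(
        [(blocks == code).sum(axis=2) for code in (0, 1, 2, 3, 4)], axis=0
    )
    best = counts.argmax(axis=0).astype(np.uint8)
    best[counts.sum(axis=0) == 0] = 255
    return best


def exposure_stats(
    fire: Raster,
    wui: Raster,
    pop: Raster,
    area_factor: Raster | None = None,
) -> pd.DataFrame:
    """Wildfire-area and people-affected summaries, split by WUI class.

    Per fire cell, the WUI pixel area inside it contributes to wildfire area
    in the WUI (area-share attribution); everyone in a fire cell is affected,
    and affected people are attributed to WUI classes by their 100 m
    population cell's majority WUI class.  Conservation holds exactly:
    affected in WUI + affected outside = total affected.
    """
    if not fire.values.any():
        logger.warning("empty fire presence grid: exposure statistics are all zero")
    cell_grid = fire.grid
    factor = round(cell_grid.pixel_size / wui.grid.pixel_size)
    if wui.grid.coarsen(factor).shape != cell_grid.shape:
        raise ValueError("fire grid does not tile the WUI grid")

    px_area = pixel_area_km2(wui.grid, area_factor)
    fire_mask_fine = np.repeat(np.repeat(fire.values, factor, axis=0), factor, axis=1) == 1

    rows = [
        {
            "statistic": "wildfire_area_km2",
            "total": float(px_area[fire_mask_fine].sum()),
        }
    ]
    wui_in_fire = {}
    for code in WUI_CODES:
        sel = fire_mask_fine & (wui.values == code)
        wui_in_fire[code] = float(px_area[sel].sum())
    rows.append(
        {"statistic": "wildfire_area_in_wui_km2", "total": sum(wui_in_fire.values()),
         **{f"class_{c}": v for c, v in wui_in_fire.items()}}
    )

    # population: attribute each pop cell to the fire cell containing it
    pfac = round(cell_grid.pixel_size / pop.grid.pixel_size)
    if pop.grid.coarsen(pfac).shape != cell_grid.shape:
        raise ValueError("fire grid does not tile the population grid")
    fire_mask_pop = np.repeat(np.repeat(fire.values, pfac, axis=0), pfac, axis=1) == 1
    pop_vals = np.nan_to_num(pop.values, nan=0.0)
    affected = float(pop_vals[fire_mask_pop].sum())
    pop_class = majority_wui_class(wui, pop.grid)
    by_class = {
        code: float(pop_vals[fire_mask_pop & (pop_class == code)].sum())
        for code in WUI_CODES
    }
    rows.append({"statistic": "people_affected", "total": affected})
    rows.append(
        {"statistic": "people_affected_in_wui", "total": sum(by_class.values()),
         **{f"class_{c}": v for c, v in by_class.items()}}
    )
    return pd.DataFrame(rows)
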