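"""Synthetic landscape generation for WUI-pipeline testing.

Two scenario families:

``random``
    A full input stack with realistic spatial structure: spatially
    autocorrelated land-cover patches (thresholded smoothed white noise,
    quantile-mapped to the configured class mixture so realized class
    fractions match the mixture almost exactly), building density decaying
    around settlement seeds, population disaggregated by building share,
    smooth biomass fields and clustered vegetation-fire points.

``analytic_strip``
    A forest strip abutting a uniformly settled cropland block.  Because
    every input varies only along the x axis, the correct WUI classification
    is computable by an independent oracle (row-wise 1-D convolutions for
    the focal shares, a KD-tree for patch distances) without running any of
    the production raster operators.  The generator emits that truth map
    alongside the inputs.

Everything is driven by one integer seed; identical configs produce
bit-identical stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .grid import GridSpec, LandCover, Raster, RasterKind, write_raster
from .pipeline import WUIParams

__all__ = [
    "LandscapeConfig",
    "LandscapeStack",
    "generate",
    "generate_analytic_strip",
]

# Default class mixture: a temperate mixed landscape with enough wildland
# for patches and enough cropland/built-up for settlements.
DEFAULT_MIXTURE: dict[LandCover, float] = {
    LandCover.TREE_COVER: 0.34,
    LandCover.SHRUBLAND: 0.10,
    LandCover.GRASSLAND: 0.16,
    LandCover.CROPLAND: 0.18,
    LandCover.BUILT_UP: 0.04,
    LandCover.BARE_SPARSE: 0.05,
    LandCover.SNOW_ICE: 0.0,
    LandCover.WATER: 0.05,
    LandCover.HERBACEOUS_WETLAND: 0.06,
    LandCover.MANGROVES: 0.01,
    LandCover.MOSS_LICHEN: 0.01,
}


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of a synthetic scene.

    The defaults describe a 6 km × 6 km scene at 10 m resolution with eight
    settlements and a moderately patchy vegetation mosaic.  Scene dimensions
    must be multiples of 300 pixels so the 100 m population, 300 m biomass
    and 1 km fire grids tile the scene exactly.
    """

    n_rows: int = 600
    n_cols: int = 600
    pixel_size: float = 10.0
    seed: int = 0
    veg_autocorr_length_m: float = 250.0
    class_weights: Mapping = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    n_settlements: int = 8
    peak_building_share: float = 85.0
    settlement_decay_m: float = 400.0
    fire_events_per_km2: float = 0.5
    scenario: str = "random"
    crs_id: str = "EQUIDISTANT-LOCAL"

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0 or self.pixel_size <= 0:
            raise ValueError("scene dimensions and pixel size must be positive")
        total = sum(self.class_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class mixture weights must sum to 1, got {total}")
        if self.veg_autocorr_length_m <= 0 or self.settlement_decay_m <= 0:
            raise ValueError("length scales must be positive")

    def grid(self) -> GridSpec:
        return GridSpec(
            origin_x=0.0,
            origin_y=self.n_rows * self.pixel_size,
            pixel_size=self.pixel_size,
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            crs_id=self.crs_id,
        )


@dataclass
class LandscapeStack:
    """The aligned synthetic input stack for one scene."""

    landcover: Raster
    building_share: Raster
    slope_deg: Raster
    water_occurrence_pct: Raster
    population: Raster
    biomass_carbon: Raster
    fires: pd.DataFrame
    truth: dict | None = None

    def write(self, out_dir: str | Path) -> dict[str, str]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, raster in (
            ("landcover", self.landcover),
            ("building_share", self.building_share),
            ("slope", self.slope_deg),
            ("water_occurrence", self.water_occurrence_pct),
            ("population", self.population),
            ("biomass_carbon", self.biomass_carbon),
        ):
            paths[name] = str(write_raster(out_dir / f"{name}.tif", raster))
        fires_path = out_dir / "fires.csv"
        self.fires.to_csv(fires_path, index=False)
        paths["fires"] = str(fires_path)
        if self.truth is not None:
            truth_raster = Raster(
                self.landcover.grid, self.truth["class_map"], RasterKind.CATEGORICAL
            )
            paths["truth_map"] = str(write_raster(out_dir / "truth_map.tif", truth_raster))
            import json

            summary = {k: v for k, v in self.truth.items() if k != "class_map"}
            (out_dir / "truth.json").write_text(json.dumps(summary, indent=2))
            paths["truth"] = str(out_dir / "truth.json")
        return paths


def _smooth_uniform_field(rng: np.random.Generator, shape, sigma_px: float) -> np.ndarray:
    """Autocorrelated field with exactly uniform margins (rank transform)."""
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_px, mode="reflect")
    ranks = stats.rankdata(smooth.ravel(), method="ordinal")
    return ((ranks - 0.5) / ranks.size).reshape(shape)


def generate(config: LandscapeConfig) -> LandscapeStack:
    """Generate the full random-scenario input stack.

    Land cover comes from quantile-mapping one autocorrelated field to the
    mixture weights, so realized class fractions equal the configured ones
    to within rounding.  Building share is a sum-of-settlements decay
    surface quantised to whole percent (zero on water), population (100 m)
    is disaggregated proportionally to built-up surface, biomass (300 m) is
    a smooth field damped where wildland is absent, and vegetation-fire
    points follow a Poisson process over majority-wildland 1 km cells.
    """
    if config.scenario == "analytic_strip":
        return generate_analytic_strip(config)
    if config.n_rows % 300 or config.n_cols % 300:
        raise ValueError("random-scenario dimensions must be multiples of 300 pixels")
    rng = np.random.default_rng(config.seed)
    grid = config.grid()
    shape = grid.shape
    px = config.pixel_size

    # -- land cover ---------------------------------------------------------
    u = _smooth_uniform_field(rng, shape, config.veg_autocorr_length_m / px)
    codes = [int(c) for c in DEFAULT_MIXTURE]  # fixed class order
    weights = np.array([config.class_weights.get(c, config.class_weights.get(int(c), 0.0))
                        for c in DEFAULT_MIXTURE])
    cum = np.cumsum(weights)
    idx = np.searchsorted(cum, u, side="left")
    idx = np.clip(idx, 0, len(codes) - 1)
    lc_values = np.array(codes, dtype=np.uint8)[idx]
    lc = Raster(grid, lc_values, RasterKind.LAND_COVER)

    # -- building share -----------------------------------------------------
    share = np.zeros(shape)
    if config.n_settlements > 0 and config.peak_building_share > 0:
        xs, ys = grid.pixel_centers()
        xx = np.repeat(xs[None, :], shape[0], axis=0)
        yy = np.repeat(ys[:, None], shape[1], axis=1)
        seeds_r = rng.uniform(0, shape[0] * px, size=config.n_settlements)
        seeds_c = rng.uniform(0, shape[1] * px, size=config.n_settlements)
        for sr, sc in zip(seeds_r, seeds_c):
            d2 = (xx - sc) ** 2 + (yy - (grid.origin_y - sr)) ** 2
            share = np.maximum(
                share,
                config.peak_building_share * np.exp(-d2 / (2 * config.settlement_decay_m**2)),
            )
    share[lc_values == int(LandCover.WATER)] = 0.0
    share = np.round(np.clip(share, 0.0, 100.0))  # whole-percent steps like the source data
    building = Raster(grid, share, RasterKind.BUILDING_SHARE)

    # -- terrain and water occurrence --------------------------------------
    slope_field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=20, mode="reflect")
    slope_field = np.abs(slope_field) / max(np.abs(slope_field).max(), 1e-12) * 45.0
    slope = Raster(grid, slope_field, RasterKind.CONTINUOUS)

    water_occ = np.where(lc_values == int(LandCover.WATER), 100.0, 0.0)
    seep = ndimage.gaussian_filter(rng.random(shape), sigma=10, mode="reflect")
    water_occ = np.maximum(water_occ, 15.0 * seep / max(seep.max(), 1e-12))
    water = Raster(grid, water_occ, RasterKind.CONTINUOUS)

    # -- population (100 m), proportional to built-up surface ---------------
    pop_grid = grid.coarsen(10)
    factor = 10
    built_km2 = (
        share.reshape(pop_grid.n_rows, factor, pop_grid.n_cols, factor).sum(axis=(1, 3))
        / 100.0 * px**2 * 1e-6
    )
    pop = Raster(pop_grid, 4000.0 * built_km2, RasterKind.CONTINUOUS)  # ~4k people / built km²

    # -- biomass carbon density (300 m, MgC/ha) -----------------------------
    bio_grid = grid.coarsen(30)
    wild = np.isin(
        lc_values,
        [int(LandCover.TREE_COVER), int(LandCover.SHRUBLAND), int(LandCover.GRASSLAND),
         int(LandCover.HERBACEOUS_WETLAND), int(LandCover.MANGROVES), int(LandCover.MOSS_LICHEN)],
    )
    wild_share = wild.reshape(bio_grid.n_rows, 30, bio_grid.n_cols, 30).mean(axis=(1, 3))
    bio_field = ndimage.gaussian_filter(rng.random(bio_grid.shape), sigma=2, mode="reflect")
    bio = Raster(
        bio_grid,
        120.0 * bio_field / max(bio_field.max(), 1e-12) * wild_share,
        RasterKind.CONTINUOUS,
    )

    # -- fire points --------------------------------------------------------
    fires = _draw_fires(rng, config, grid, wild)

    return LandscapeStack(lc, building, slope, water, pop, bio, fires)


def _draw_fires(
    rng: np.random.Generator, config: LandscapeConfig, grid: GridSpec, wild: np.ndarray
) -> pd.DataFrame:
    """Poisson vegetation fires over majority-wildland 1 km cells, plus a few
    static-source detections anywhere (negative cases for the filter)."""
    cell_px = round(1000.0 / grid.pixel_size)
    cell_grid = grid.coarsen(cell_px)
    wild_share = wild.reshape(
        cell_grid.n_rows, cell_px, cell_grid.n_cols, cell_px
    ).mean(axis=(1, 3))
    cell_area = (cell_px * grid.pixel_size) ** 2 * 1e-6
    rows = []
    for r in range(cell_grid.n_rows):
        for c in range(cell_grid.n_cols):
            if wild_share[r, c] <= 0.5:
                continue
            n = rng.poisson(config.fire_events_per_km2 * cell_area)
            for _ in range(n):
                x = grid.origin_x + (c + rng.random()) * cell_px * grid.pixel_size
                y = grid.origin_y - (r + rng.random()) * cell_px * grid.pixel_size
                rows.append((x, y, "vegetation"))
    n_static = rng.poisson(3)
    for _ in range(n_static):
        x = grid.origin_x + rng.random() * grid.n_cols * grid.pixel_size
        y = grid.origin_y - rng.random() * grid.n_rows * grid.pixel_size
        rows.append((x, y, "static"))
    years = rng.integers(2003, 2021, size=len(rows))
    days = rng.integers(1, 366, size=len(rows))
    dates = [
        (pd.Timestamp(f"{yr}-01-01") + pd.Timedelta(days=int(d) - 1)).date().isoformat()
        for yr, d in zip(years, days)
    ]
    sources = rng.choice(["MODIS", "VIIRS"], size=len(rows))
    return pd.DataFrame(
        {
            "x": [r[0] for r in rows],
            "y": [r[1] for r in rows],
            "date": dates,
            "source": sources,
            "category": [r[2] for r in rows],
        }
    )


# ---------------------------------------------------------------------------
# Analytic strip scenario


def generate_analytic_strip(
    config: LandscapeConfig,
    forest_width_m: float = 5000.0,
    building_pct: int = 30,
    params: WUIParams = WUIParams(),
    require_patch: bool = False,
) -> LandscapeStack:
    """Forest strip vs settled cropland, with machine-readable truth.

    The left ``forest_width_m`` of the scene is solid tree cover; the rest
    is cropland with a uniform built-up share of ``building_pct`` percent.
    Slope and water occurrence are zero, so the building corrections only
    zero shares of at most 20%.  The emitted truth map is computed by the
    strip oracle (see :func:`strip_truth`), not by the production pipeline.

    Raises when ``require_patch`` is set but the forest block is too small
    to qualify as a large vegetation patch.
    """
    grid = config.grid()
    forest_cols = int(round(forest_width_m / config.pixel_size))
    if not 0 <= forest_cols <= config.n_cols:
        raise ValueError("forest strip must fit inside the scene")

    col_is_forest = np.arange(config.n_cols) < forest_cols
    lc_cols = np.where(col_is_forest, int(LandCover.TREE_COVER), int(LandCover.CROPLAND))
    lc_values = np.repeat(lc_cols[None, :], config.n_rows, axis=0).astype(np.uint8)
    lc = Raster(grid, lc_values, RasterKind.LAND_COVER)

    share_cols = np.where(col_is_forest, 0.0, float(building_pct))
    share = np.repeat(share_cols[None, :], config.n_rows, axis=0)
    building = Raster(grid, share, RasterKind.BUILDING_SHARE)

    zeros = np.zeros(grid.shape)
    slope = Raster(grid, zeros.copy(), RasterKind.CONTINUOUS)
    water = Raster(grid, zeros.copy(), RasterKind.CONTINUOUS)

    pop_grid = grid.coarsen(10) if config.n_rows % 10 == 0 and config.n_cols % 10 == 0 else grid
    if pop_grid is grid:
        pop_vals = share / 100.0 * grid.pixel_size**2 * 1e-6 * 4000.0
    else:
        pop_vals = (
            share.reshape(pop_grid.n_rows, 10, pop_grid.n_cols, 10).sum(axis=(1, 3))
            / 100.0 * grid.pixel_size**2 * 1e-6 * 4000.0
        )
    pop = Raster(pop_grid, pop_vals, RasterKind.CONTINUOUS)
    biomass = Raster(grid, np.where(lc_values == int(LandCover.TREE_COVER), 80.0, 5.0),
                     RasterKind.CONTINUOUS)
    fires = pd.DataFrame(columns=["x", "y", "date", "source", "category"])

    truth = strip_truth(
        n_rows=config.n_rows,
        n_cols=config.n_cols,
        pixel_size=config.pixel_size,
        forest_cols=forest_cols,
        building_pct=building_pct,
        params=params,
    )
    if require_patch and not truth["patch_present"]:
        raise ValueError(
            f"forest block of {truth['patch_area_km2']:.3f} km² does not reach the "
            f"{params.patch_min_area_km2} km² large-patch minimum"
        )
    return LandscapeStack(lc, building, slope, water, pop, biomass, fires, truth=truth)


def _kernel_half_widths(radius_m: float, pixel_size: float) -> np.ndarray:
    """Max |dy| per dx of the disc, matching pixel-center membership."""
    k = int(radius_m // pixel_size)
    halves = np.full(2 * k + 1, -1, dtype=int)
    for i, dx in enumerate(range(-k, k + 1)):
        h = -1
        for dy in range(k + 1):
            if (dy * pixel_size) ** 2 + (dx * pixel_size) ** 2 <= radius_m**2:
                h = dy
        halves[i] = h
    return halves


def strip_truth(
    n_rows: int,
    n_cols: int,
    pixel_size: float,
    forest_cols: int,
    building_pct: int,
    params: WUIParams = WUIParams(),
) -> dict:
    """Reference WUI classification of the strip scene.

    Independent of the production operators: because every layer is constant
    along y, each focal mean reduces to a 1-D convolution per row with
    row-specific integer column weights (the disc truncated at the top and
    bottom scene edges); patch qualification is plain area arithmetic on the
    thresholded share, and the proximity band comes from KD-tree
    nearest-neighbour distances between pixel centers.
    """
    veg_cols = (np.arange(n_cols) < forest_cols).astype(float)
    crop_cols = 1.0 - veg_cols
    # corrected built-up share: zero unless strictly above the minimum
    b_eff = float(building_pct) if building_pct > params.building_min_pct else 0.0

    halves = _kernel_half_widths(params.kernel_radius_m, pixel_size)
    k = (len(halves) - 1) // 2
    dxs = np.arange(-k, k + 1)

    veg_share = np.empty((n_rows, n_cols))
    b_share = np.empty((n_rows, n_cols))
    ones = np.ones(n_cols)
    for r in range(n_rows):
        w = np.minimum(halves, r) + np.minimum(halves, n_rows - 1 - r) + 1
        w = np.where(halves >= 0, w, 0).astype(float)
        den = np.convolve(ones, w, mode="same")
        num_veg = np.convolve(veg_cols, w, mode="same")
        num_crop = np.convolve(crop_cols, w, mode="same")
        veg_share[r] = num_veg / den
        b_share[r] = (b_eff * num_crop / den) / 100.0

    patch_mask = veg_share > params.patch_share_threshold
    patch_area = float(patch_mask.sum()) * pixel_size**2 * 1e-6
    patch_present = patch_area >= params.patch_min_area_km2

    if patch_present and patch_mask.any():
        rr, cc = np.nonzero(patch_mask)
        tree = cKDTree(np.column_stack([rr, cc]) * pixel_size)
        pts = np.indices((n_rows, n_cols)).reshape(2, -1).T * pixel_size
        dist, _ = tree.query(pts, k=1)
        near = (dist.reshape(n_rows, n_cols)) <= params.interface_distance_m
    else:
        near = np.zeros((n_rows, n_cols), dtype=bool)

    cp = params.classifier()
    candidate = b_share > cp.candidate_min_building_share
    urban = b_share > cp.urban_character_share
    intermix = candidate & ~urban & (veg_share >= cp.intermix_min_veg_share)
    interface = candidate & ~intermix & near

    class_map = np.zeros((n_rows, n_cols), dtype=np.uint8)
    class_map[intermix] = 1  # F/S/W: the only wildland here is tree cover
    class_map[interface] = 3  # grassland-excluded patches exist wherever included ones do
    return {
        "class_map": class_map,
        "patch_present": bool(patch_present),
        "patch_area_km2": patch_area,
        "n_candidate": int(candidate.sum()),
        "n_intermix": int(intermix.sum()),
        "n_interface": int(interface.sum()),
        "n_wui": int(((class_map >= 1) & (class_map <= 4)).sum()),
    }
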