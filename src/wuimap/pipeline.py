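"""End-to-end WUI mapping: corrections → focal shares → patches → rule table.

The heavy per-pixel stages (wildland reclassification, focal means, the rule
table) are tileable: a tile processed with a surrounding margin of
``max(kernel radius, interface distance)`` produces exactly the same values
as a whole-scene run, so tiling is purely an execution detail.  Patch
labeling and the patch distance transform are *not* tiled — connected
components are nonlocal, and a patch can extend arbitrarily far beyond any
fixed overlap — so those two steps always see the full scene.  A
tiled-vs-untiled equality test pins this contract.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .classify import ClassifierParams, classify
from .focal import Kernel, build_kernel, focal_share
from .grid import GridSpec, LandCover, Raster, RasterKind, read_raster, write_raster
from .patches import find_large_patches, proximity_zone
from .preprocess import WILDLAND_CORE, correct_building_density, reclassify_wildland

__all__ = ["WUIParams", "map_wui", "run_pipeline"]


@dataclass(frozen=True)
class WUIParams:
    """All thresholds of the mapping pipeline, defaulting to the standard
    WUI-mapping parameter set (500 m kernel, 0.5%/15% building shares, 50%
    intermix vegetation, >75% / 5 km² patches, 2,400 m interface distance,
    25° slope and 20% water-occurrence corrections)."""

    kernel_radius_m: float = 500.0
    slope_max_deg: float = 25.0
    water_max_pct: float = 20.0
    building_min_pct: float = 20.0
    patch_share_threshold: float = 0.75
    patch_min_area_km2: float = 5.0
    interface_distance_m: float = 2400.0
    connectivity: int = 8
    candidate_min_building_share: float = 0.005
    urban_character_share: float = 0.15
    intermix_min_veg_share: float = 0.5

    def classifier(self) -> ClassifierParams:
        return ClassifierParams(
            candidate_min_building_share=self.candidate_min_building_share,
            urban_character_share=self.urban_character_share,
            intermix_min_veg_share=self.intermix_min_veg_share,
        )


def _tiles(n_rows: int, n_cols: int, tile: int, margin: int):
    for r0 in range(0, n_rows, tile):
        for c0 in range(0, n_cols, tile):
            r1, c1 = min(r0 + tile, n_rows), min(c0 + tile, n_cols)
            rr0, cc0 = max(r0 - margin, 0), max(c0 - margin, 0)
            rr1, cc1 = min(r1 + margin, n_rows), min(c1 + margin, n_cols)
            yield (r0, r1, c0, c1), (rr0, rr1, cc0, cc1)


def _focal_share_tiled(
    raster: Raster, kernel: Kernel, quantity: str, tile_size: int | None
) -> Raster:
    if tile_size is None:
        return focal_share(raster, kernel, quantity)
    margin = int(np.ceil(kernel.radius_m / raster.grid.pixel_size))
    out = np.empty(raster.grid.shape, dtype=np.float64)
    g = raster.grid
    for (r0, r1, c0, c1), (rr0, rr1, cc0, cc1) in _tiles(
        g.n_rows, g.n_cols, tile_size, margin
    ):
        sub_grid = GridSpec(
            origin_x=g.origin_x + cc0 * g.pixel_size,
            origin_y=g.origin_y - rr0 * g.pixel_size,
            pixel_size=g.pixel_size,
            n_rows=rr1 - rr0,
            n_cols=cc1 - cc0,
            crs_id=g.crs_id,
            nodata=g.nodata,
        )
        sub = Raster(sub_grid, raster.values[rr0:rr1, cc0:cc1], raster.kind)
        res = focal_share(sub, kernel, quantity)
        out[r0:r1, c0:c1] = res.values[r0 - rr0 : r1 - rr0, c0 - cc0 : c1 - cc0]
    result = Raster(raster.grid, out, RasterKind.CONTINUOUS, dict(raster.meta))
    result.meta.update({"radius_m": kernel.radius_m, "quantity": quantity})
    return result


def map_wui(
    lc: Raster,
    building: Raster,
    slope_deg: Raster,
    water_occurrence_pct: Raster,
    params: WUIParams = WUIParams(),
    area_factor: Raster | None = None,
    tile_size: int | None = None,
    return_intermediates: bool = False,
):
    """Produce the five-class WUI map from the four aligned input rasters.

    Returns the classified raster, or ``(raster, intermediates dict)`` when
    ``return_intermediates`` is set.
    """
    lc.require_aligned(building, "building raster")
    kernel = build_kernel(params.kernel_radius_m, lc.grid.pixel_size)

    corrected = correct_building_density(
        building,
        slope_deg,
        water_occurrence_pct,
        min_pixel_share=params.building_min_pct,
        max_slope=params.slope_max_deg,
        max_water=params.water_max_pct,
    )
    wl_incl = reclassify_wildland(lc, include_grassland=True)
    wl_excl = reclassify_wildland(lc, include_grassland=False)
    grass_mask = Raster(
        lc.grid, (lc.values == int(LandCover.GRASSLAND)).astype(np.uint8), RasterKind.BINARY
    )
    fsw_mask = Raster(
        lc.grid,
        np.isin(lc.values, [int(c) for c in WILDLAND_CORE]).astype(np.uint8),
        RasterKind.BINARY,
    )

    veg_incl = _focal_share_tiled(wl_incl, kernel, "vegetation_share", tile_size)
    veg_incl.meta["variant"] = "grassland_included"
    veg_excl = _focal_share_tiled(wl_excl, kernel, "vegetation_share", tile_size)
    veg_excl.meta["variant"] = "grassland_excluded"
    grass_share = _focal_share_tiled(grass_mask, kernel, "grassland_share", tile_size)
    fsw_share = _focal_share_tiled(fsw_mask, kernel, "fsw_share", tile_size)
    b_share = _focal_share_tiled(corrected, kernel, "building_share", tile_size)

    patches_incl = find_large_patches(
        veg_incl,
        share_threshold=params.patch_share_threshold,
        min_area_km2=params.patch_min_area_km2,
        area_factor=area_factor,
        connectivity=params.connectivity,
    )
    patches_excl = find_large_patches(
        veg_excl,
        share_threshold=params.patch_share_threshold,
        min_area_km2=params.patch_min_area_km2,
        area_factor=area_factor,
        connectivity=params.connectivity,
    )
    prox_incl = proximity_zone(patches_incl, params.interface_distance_m)
    prox_excl = proximity_zone(patches_excl, params.interface_distance_m)

    wui = classify(
        veg_incl, grass_share, fsw_share, b_share, prox_incl, prox_excl, lc,
        params.classifier(),
    )
    if not return_intermediates:
        return wui
    return wui, {
        "corrected_building": corrected,
        "veg_share_incl": veg_incl,
        "veg_share_excl": veg_excl,
        "grass_share": grass_share,
        "fsw_share": fsw_share,
        "building_share": b_share,
        "patches_incl": patches_incl,
        "patches_excl": patches_excl,
        "prox_incl": prox_incl,
        "prox_excl": prox_excl,
    }


# ---------------------------------------------------------------------------
# Config-driven run


_CONFIG_KEYS = {
    "landcover", "buildings", "slope", "water", "area_factor", "population",
    "biomass", "fires", "zones", "out_dir", "seed", "tile_size", "log_level",
} | set(WUIParams.__dataclass_fields__)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (unknown keys are rejected)."""

    landcover: str
    buildings: str
    slope: str
    water: str
    out_dir: str
    area_factor: str | None = None
    population: str | None = None
    biomass: str | None = None
    fires: str | None = None
    zones: str | None = None
    seed: int = 0
    tile_size: int | None = None
    log_level: str = "INFO"
    params: WUIParams = field(default_factory=WUIParams)

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        cfg = dict(cfg)
        unknown = set(cfg) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        param_kwargs = {
            k: cfg.pop(k) for k in list(cfg) if k in WUIParams.__dataclass_fields__
        }
        return cls(params=WUIParams(**param_kwargs), **cfg)


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _atomic_write_raster(path: Path, raster: Raster) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    write_raster(tmp, raster)
    os.replace(tmp, path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run preprocess → map (→ fire → summarize) from files on disk.

    Writes ``wui.tif`` plus optional ``exposure.csv`` / ``summary.csv`` and a
    ``provenance.json`` recording every parameter and input checksum.
    Outputs are written atomically (write-then-rename) so a failed stage
    leaves no truncated files.  Reruns with the same config are
    byte-identical.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs = {
        k: getattr(config, k)
        for k in ("landcover", "buildings", "slope", "water", "area_factor",
                  "population", "biomass", "fires", "zones")
        if getattr(config, k)
    }
    lc = read_raster(config.landcover, RasterKind.LAND_COVER)
    building = read_raster(config.buildings, RasterKind.BUILDING_SHARE)
    slope = read_raster(config.slope)
    water = read_raster(config.water)
    area_factor = (
        read_raster(config.area_factor, RasterKind.AREA_FACTOR)
        if config.area_factor
        else None
    )
    wui = map_wui(
        lc, building, slope, water, config.params,
        area_factor=area_factor, tile_size=config.tile_size,
    )
    wui_path = out_dir / "wui.tif"
    _atomic_write_raster(wui_path, wui)
    outputs = {"wui": str(wui_path)}

    if config.fires and config.population:
        from . import fire as fire_mod

        events = fire_mod.read_fire_events(config.fires)
        pop = read_raster(config.population)
        kept = fire_mod.filter_vegetation_fires(events, lc)
        presence = fire_mod.presence_grid(kept, lc.grid)
        stats = fire_mod.exposure_stats(presence, wui, pop, area_factor=area_factor)
        tmp = out_dir / "exposure.csv.tmp"
        stats.to_csv(tmp, index=False)
        os.replace(tmp, out_dir / "exposure.csv")
        outputs["exposure"] = str(out_dir / "exposure.csv")

    provenance = {
        "params": asdict(config.params),
        "seed": config.seed,
        "tile_size": config.tile_size,
        "inputs": {k: {"path": v, "sha256": _checksum(v)} for k, v in inputs.items()},
        "outputs": outputs,
    }
    tmp = out_dir / "provenance.json.tmp"
    tmp.write_text(json.dumps(provenance, indent=2, sort_keys=True))
    os.replace(tmp, out_dir / "provenance.json")
    return provenance
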