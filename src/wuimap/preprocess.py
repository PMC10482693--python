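"""Land-cover reclassification and building-density corrections.

Wildland vegetation comprises tree cover, shrubland, herbaceous wetland,
mangroves and moss/lichen — and, in one variant, grassland.  Grassland is
handled both ways because it ranges from wild steppe to intensively managed
pasture, so downstream maps carry two wildland masks.

Built-up surface share is corrected before any WUI logic: pixels on steep
slopes or with frequent surface water are set to zero (both are common
sources of false building detections), as are pixels whose own share is too
low for the source data to be reliable.
"""

from __future__ import annotations

import numpy as np

from .grid import CATEGORICAL_NODATA, LandCover, Raster, RasterKind

__all__ = ["WILDLAND_CORE", "correct_building_density", "reclassify_wildland"]

# Wildland classes common to both variants; grassland is the switchable one.
WILDLAND_CORE = frozenset(
    {
        LandCover.TREE_COVER,
        LandCover.SHRUBLAND,
        LandCover.HERBACEOUS_WETLAND,
        LandCover.MANGROVES,
        LandCover.MOSS_LICHEN,
    }
)


def reclassify_wildland(lc: Raster, include_grassland: bool) -> Raster:
    """Binary wildland (1) vs non-wildland (0) mask from land cover.

    Non-wildland is cropland, built-up, bare/sparse, snow/ice and water.
    Nodata pixels stay nodata.  The chosen variant is recorded in the
    raster's metadata.
    """
    if lc.kind != RasterKind.LAND_COVER:
        raise ValueError(f"expected a land-cover raster, got kind {lc.kind}")
    codes = {int(c) for c in WILDLAND_CORE}
    if include_grassland:
        codes.add(int(LandCover.GRASSLAND))
    mask = np.isin(lc.values, sorted(codes)).astype(np.uint8)
    mask[lc.values == CATEGORICAL_NODATA] = CATEGORICAL_NODATA
    variant = "grassland_included" if include_grassland else "grassland_excluded"
    return Raster(lc.grid, mask, RasterKind.BINARY, meta={"variant": variant})


def correct_building_density(
    building: Raster,
    slope_deg: Raster,
    water_occurrence_pct: Raster,
    min_pixel_share: float = 20.0,
    max_slope: float = 25.0,
    max_water: float = 20.0,
) -> Raster:
    """Zero out unreliable built-up share pixels.

    Share is set to zero wherever slope exceeds ``max_slope`` degrees, water
    occurrence exceeds ``max_water`` percent of the year, or the pixel's own
    share is not above ``min_pixel_share`` percent.  All comparisons are
    strict.  The three rules are independent pixel-wise zeroings, so their
    order is immaterial and the operation is idempotent.
    """
    building.require_aligned(slope_deg, "slope raster")
    building.require_aligned(water_occurrence_pct, "water-occurrence raster")
    zero = (
        (slope_deg.values > max_slope)
        | (water_occurrence_pct.values > max_water)
        | (building.values <= min_pixel_share)
    )
    out = np.where(zero, 0.0, building.values)
    out = np.where(np.isnan(building.values), np.nan, out)
    meta = dict(building.meta)
    meta["corrections"] = {
        "min_pixel_share": min_pixel_share,
        "max_slope": max_slope,
        "max_water": max_water,
    }
    return Raster(building.grid, out, RasterKind.BUILDING_SHARE, meta=meta)
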