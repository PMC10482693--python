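"""Per-pixel WUI classification rule table.

Given the precomputed focal shares and patch-proximity masks, each pixel
receives exactly one of six codes:

====  =========================================
code  class
====  =========================================
0     non-WUI
1     intermix, forest/shrubland/wetland (F/S/W)
2     intermix, grassland-dominated
3     interface, F/S/W
4     interface, grassland-dominated
255   masked (open water / missing land cover)
====  =========================================

A pixel is a WUI *candidate* when the built-up share aggregated over the
500 m kernel exceeds 0.5%.  Candidates embedded in ≥ 50% wildland
vegetation (grassland included) are *intermix*, unless the aggregated
built-up share exceeds 15% — such "urban character" neighbourhoods keep
managed vegetation and fire control and are excluded from intermix, though
they may still be interface.  Remaining candidates near a large vegetation
patch are *interface*.  Intermix splits F/S/W vs grassland by the larger
kernel share of the two groups (ties to F/S/W); interface splits by which
patch variant is nearby, F/S/W (grassland-excluded patches) taking
precedence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import CATEGORICAL_NODATA, LandCover, Raster, RasterKind

__all__ = ["ClassifierParams", "WUI_CLASS_NAMES", "classify"]

WUI_CLASS_NAMES = {
    0: "non_wui",
    1: "intermix_fsw",
    2: "intermix_grassland",
    3: "interface_fsw",
    4: "interface_grassland",
    255: "masked",
}

WUI_CODES = (1, 2, 3, 4)


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the WUI rule table (shares as fractions of 1).

    candidate_min_building_share
        Kernel built-up share above which a pixel is a WUI candidate
        (default 0.5% = 0.005).
    urban_character_share
        Kernel built-up share above which the neighbourhood counts as urban
        and is barred from intermix (default 15% = 0.15).
    intermix_min_veg_share
        Minimum kernel wildland share (grassland included) for intermix
        (default 50% = 0.5, inclusive).
    """

    candidate_min_building_share: float = 0.005
    urban_character_share: float = 0.15
    intermix_min_veg_share: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.candidate_min_building_share < self.urban_character_share <= 1):
            raise ValueError(
                "need 0 < candidate_min_building_share < urban_character_share <= 1"
            )


def _check_share(r: Raster, quantity: str, radius_m: float | None) -> None:
    q = r.meta.get("quantity")
    if q is not None and q != quantity:
        raise ValueError(f"expected a {quantity} raster, got {q}")
    rm = r.meta.get("radius_m")
    if radius_m is not None and rm is not None and rm != radius_m:
        raise ValueError(f"focal radius mismatch: {rm} m vs {radius_m} m")


def classify(
    veg_share_incl: Raster,
    grass_share: Raster,
    fsw_share: Raster,
    building_share: Raster,
    prox_incl: Raster,
    prox_excl: Raster,
    lc: Raster,
    params: ClassifierParams = ClassifierParams(),
) -> Raster:
    """Apply the WUI rule table pixel-wise.

    All inputs must be aligned and carry consistent kernel radii.  The
    vegetation share used for the 50% intermix split is the
    grassland-included one; the two patch variants only steer interface
    subclassing.  Output is masked (255) over open water and missing land
    cover.
    """
    radius = veg_share_incl.meta.get("radius_m")
    for r, what in (
        (grass_share, "grass share"),
        (fsw_share, "F/S/W share"),
        (building_share, "building share"),
        (prox_incl, "proximity (grassland incl.)"),
        (prox_excl, "proximity (grassland excl.)"),
        (lc, "land cover"),
    ):
        veg_share_incl.require_aligned(r, what)
    _check_share(veg_share_incl, "vegetation_share", radius)
    _check_share(building_share, "building_share", radius)
    _check_share(grass_share, "grassland_share", radius)
    _check_share(fsw_share, "fsw_share", radius)
    if lc.kind != RasterKind.LAND_COVER:
        raise ValueError("lc must be a land-cover raster")

    b = np.nan_to_num(building_share.values, nan=0.0)
    veg = np.nan_to_num(veg_share_incl.values, nan=0.0)
    grass = np.nan_to_num(grass_share.values, nan=0.0)
    fsw = np.nan_to_num(fsw_share.values, nan=0.0)
    near_incl = prox_incl.values == 1
    near_excl = prox_excl.values == 1

    candidate = b > params.candidate_min_building_share
    urban = b > params.urban_character_share
    intermix = candidate & ~urban & (veg >= params.intermix_min_veg_share)
    interface = candidate & ~intermix & (near_excl | near_incl)

    out = np.zeros(lc.grid.shape, dtype=np.uint8)
    out[intermix & (fsw >= grass)] = 1
    out[intermix & (fsw < grass)] = 2
    out[interface & near_excl] = 3
    out[interface & ~near_excl] = 4
    masked = (lc.values == int(LandCover.WATER)) | (lc.values == CATEGORICAL_NODATA)
    out[masked] = CATEGORICAL_NODATA
    return Raster(
        lc.grid,
        out,
        RasterKind.CATEGORICAL,
        meta={"classes": WUI_CLASS_NAMES, "params": params.__dict__.copy()},
    )
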