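"""Large wildland-vegetation patches and the interface proximity zone.

Interface WUI requires a nearby *large* block of wildland vegetation: a
connected region of high focal vegetation share (> 75% by default) whose
(area-corrected) extent reaches 5 km².  The minimum size keeps small urban
parks from qualifying.  Settled pixels within 2,400 m of such a patch — the
distance embers can travel in a wildfire — fall in the proximity zone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import GridSpec, Raster, RasterKind, pixel_area_km2

__all__ = ["PatchSet", "find_large_patches", "proximity_zone"]


@dataclass
class PatchSet:
    """Labeled large-vegetation patches on a grid.

    ``labels`` is 0 for background and 1..k for retained patches (contiguous
    ids); ``areas`` maps patch id to area in km².
    """

    grid: GridSpec
    labels: np.ndarray
    areas: pd.Series
    variant: str
    share_threshold: float
    min_area_km2: float

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def __len__(self) -> int:
        return len(self.areas)


def find_large_patches(
    veg_share: Raster,
    share_threshold: float = 0.75,
    min_area_km2: float = 5.0,
    area_factor: Raster | None = None,
    connectivity: int = 8,
    min_area_strict: bool = False,
) -> PatchSet:
    """Connected high-vegetation-share regions above the minimum area.

    The focal vegetation share is binarised at ``> share_threshold``,
    labeled (8-connectivity by default, so diagonally touching blobs merge),
    and components whose summed pixel area reaches ``min_area_km2`` are
    retained (``>=`` comparator unless ``min_area_strict``).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    fg = np.nan_to_num(veg_share.values, nan=0.0) > share_threshold
    labels, n = ndimage.label(fg, structure=structure)
    if area_factor is None:
        counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
        areas = counts * (veg_share.grid.pixel_size**2 * 1e-6)
    else:
        px_area = pixel_area_km2(veg_share.grid, area_factor)
        areas = np.bincount(labels.ravel(), weights=px_area.ravel(), minlength=n + 1)[1:]
    keep = areas > min_area_km2 if min_area_strict else areas >= min_area_km2
    # relabel retained patches 1..k in original label order
    remap = np.zeros(n + 1, dtype=np.int32)
    kept_ids = np.flatnonzero(keep) + 1
    remap[kept_ids] = np.arange(1, kept_ids.size + 1)
    out_labels = remap[labels]
    out_areas = pd.Series(
        areas[keep], index=pd.RangeIndex(1, kept_ids.size + 1, name="patch_id"), name="area_km2"
    )
    return PatchSet(
        grid=veg_share.grid,
        labels=out_labels,
        areas=out_areas,
        variant=str(veg_share.meta.get("variant", "unknown")),
        share_threshold=share_threshold,
        min_area_km2=min_area_km2,
    )


def proximity_zone(patches: PatchSet, max_distance_m: float = 2400.0) -> Raster:
    """Binary mask of pixels within ``max_distance_m`` of a retained patch.

    Distance is pixel-center to pixel-center Euclidean, computed with an
    exact distance transform.  An empty patch set yields an all-zero mask.
    """
    if not patches.mask.any():
        mask = np.zeros(patches.grid.shape, dtype=np.uint8)
    else:
        px = patches.grid.pixel_size
        dist = ndimage.distance_transform_edt(~patches.mask, sampling=(px, px))
        mask = (dist <= max_distance_m).astype(np.uint8)
    return Raster(
        patches.grid,
        mask,
        RasterKind.BINARY,
        meta={"max_distance_m": max_distance_m, "variant": patches.variant},
    )
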