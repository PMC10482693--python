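"""Zonal WUI summaries, biomass conversion and hotspot-country selection.

Summaries accumulate (area-corrected) pixel areas by WUI class within each
zone, population by the 100 m cell's majority WUI class and aboveground
biomass — converted from carbon density to dry-matter mass with a factor of
two — by the 300 m cell's majority WUI class.  Masked (water) pixels are
excluded from land area.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .classify import WUI_CODES
from .fire import majority_wui_class
from .grid import Raster, RasterKind, ZoneSet, pixel_area_km2

__all__ = ["convert_biomass", "select_hotspots", "summarize"]

logger = logging.getLogger(__name__)

CARBON_TO_DRY_MATTER = 2.0


def convert_biomass(carbon_density: Raster, area_factor: Raster | None = None) -> Raster:
    """Aboveground carbon density (MgC/ha) → dry-matter mass (kg) per pixel.

    mass = density × pixel area (ha) × 1000 kg/Mg × 2 (carbon → dry matter).
    """
    vals = carbon_density.values
    if vals.size and np.nanmin(vals) < 0:
        raise ValueError("biomass carbon density must be non-negative")
    area_ha = pixel_area_km2(carbon_density.grid, area_factor) * 100.0
    mass = np.nan_to_num(vals, nan=0.0) * area_ha * 1000.0 * CARBON_TO_DRY_MATTER
    return Raster(carbon_density.grid, mass, RasterKind.CONTINUOUS, meta={"unit": "kg_dry_matter"})


def _class_areas(wui: Raster, sel: np.ndarray, px_area: np.ndarray) -> dict[int, float]:
    return {c: float(px_area[sel & (wui.values == c)].sum()) for c in WUI_CODES}


def summarize(
    zones: ZoneSet,
    wui: Raster,
    pop: Raster | None = None,
    biomass_mass: Raster | None = None,
    exposure: pd.DataFrame | None = None,
    area_factor: Raster | None = None,
    fire: Raster | None = None,
) -> pd.DataFrame:
    """Per-zone land/WUI area, population, biomass and fire statistics.

    Zone membership is by pixel-center-in-polygon.  Shares of zones with
    zero land area are NaN rather than a division error.  When a fire
    presence grid is given, per-zone wildfire exposure is computed
    (fire cells assigned to zones by cell center).
    """
    member = zones.membership(wui.grid)
    px_area = pixel_area_km2(wui.grid, area_factor)
    land = wui.values != 255

    pop_class = pop_vals = None
    if pop is not None:
        pop_class = majority_wui_class(wui, pop.grid)
        pop_vals = np.nan_to_num(pop.values, nan=0.0)
        pop_member = zones.membership(pop.grid)
    if biomass_mass is not None:
        bio_class = majority_wui_class(wui, biomass_mass.grid)
        bio_member = zones.membership(biomass_mass.grid)
    if fire is not None:
        fire_member = zones.membership(fire.grid)
        ffac = round(fire.grid.pixel_size / wui.grid.pixel_size)
        fire_fine = np.repeat(np.repeat(fire.values, ffac, axis=0), ffac, axis=1) == 1

    records = []
    for idx, (zid, _, kind, name) in enumerate(zones):
        in_zone = member == idx
        land_area = float(px_area[in_zone & land].sum())
        class_areas = _class_areas(wui, in_zone, px_area)
        wui_area = sum(class_areas.values())
        rec: dict = {
            "zone_id": zid,
            "kind": kind,
            "name": name,
            "land_area_km2": land_area,
            "wui_area_km2": wui_area,
            **{f"wui_area_km2_class_{c}": a for c, a in class_areas.items()},
            "wui_area_share_pct": 100.0 * wui_area / land_area if land_area > 0 else np.nan,
        }
        if pop is not None:
            zp = pop_member == idx
            total_pop = float(pop_vals[zp].sum())
            pop_by_class = {
                c: float(pop_vals[zp & (pop_class == c)].sum()) for c in WUI_CODES
            }
            pop_wui = sum(pop_by_class.values())
            rec.update(
                population=total_pop,
                population_in_wui=pop_wui,
                **{f"population_class_{c}": v for c, v in pop_by_class.items()},
                population_share_in_wui_pct=(
                    100.0 * pop_wui / total_pop if total_pop > 0 else np.nan
                ),
            )
        if biomass_mass is not None:
            zb = bio_member == idx
            bio_vals = biomass_mass.values
            total_bio = float(bio_vals[zb].sum())
            bio_wui = float(bio_vals[zb & np.isin(bio_class, WUI_CODES)].sum())
            rec.update(
                biomass_kg=total_bio,
                biomass_in_wui_kg=bio_wui,
                biomass_share_in_wui_pct=(
                    100.0 * bio_wui / total_bio if total_bio > 0 else np.nan
                ),
            )
        if fire is not None:
            zf_fine = np.repeat(
                np.repeat(fire_member == idx, ffac, axis=0), ffac, axis=1
            )
            fire_area = float(px_area[zf_fine & fire_fine].sum())
            fire_wui = float(
                px_area[zf_fine & fire_fine & np.isin(wui.values, WUI_CODES)].sum()
            )
            rec.update(
                wildfire_area_km2=fire_area,
                wildfire_area_in_wui_km2=fire_wui,
                wildfire_wui_share_pct=(
                    100.0 * fire_wui / fire_area if fire_area > 0 else np.nan
                ),
            )
            if pop is not None:
                zfp = np.repeat(
                    np.repeat(
                        (fire_member == idx) & (fire.values == 1),
                        round(fire.grid.pixel_size / pop.grid.pixel_size),
                        axis=0,
                    ),
                    round(fire.grid.pixel_size / pop.grid.pixel_size),
                    axis=1,
                )
                affected = float(pop_vals[zfp & zp].sum())
                affected_wui = float(
                    pop_vals[zfp & zp & np.isin(pop_class, WUI_CODES)].sum()
                )
                rec.update(
                    people_affected=affected, people_affected_in_wui=affected_wui
                )
        records.append(rec)
    if exposure is not None:
        # scene-level exposure table attached as attrs for provenance
        out = pd.DataFrame.from_records(records)
        out.attrs["scene_exposure"] = exposure
        return out
    return pd.DataFrame.from_records(records)


def select_hotspots(
    country_table: pd.DataFrame,
    border_distance_km: pd.DataFrame,
    top_n: int = 10,
    min_fire_wui_share_pct: float = 20.0,
    min_size_km2: float = 10000.0,
    min_border_distance_km: float = 200.0,
) -> pd.DataFrame:
    """Pick per-region hotspot country pairs.

    Candidates per region: the ``top_n`` countries by WUI area share among
    those with more than ``min_fire_wui_share_pct`` of their wildfire area in
    the WUI and more than ``min_size_km2`` land area.  Of these, the two with
    the most people affected by wildfire in the WUI are chosen; while the
    pair's borders are within ``min_border_distance_km``, the second is
    replaced by the next-ranked candidate.  Deterministic and invariant to
    input row order.

    ``country_table`` needs columns zone_id, region, land_area_km2,
    wui_area_share_pct, wildfire_wui_share_pct, people_affected_in_wui.
    ``border_distance_km`` is a symmetric zone_id × zone_id matrix.
    """
    required = {
        "zone_id", "region", "land_area_km2", "wui_area_share_pct",
        "wildfire_wui_share_pct", "people_affected_in_wui",
    }
    missing = required - set(country_table.columns)
    if missing:
        raise ValueError(f"country table missing column(s): {sorted(missing)}")
    out = []
    table = country_table.sort_values("zone_id")  # order-invariance
    for region, grp in table.groupby("region", sort=True):
        qual = grp[
            (grp["wildfire_wui_share_pct"] > min_fire_wui_share_pct)
            & (grp["land_area_km2"] > min_size_km2)
        ]
        candidates = qual.sort_values(
            ["wui_area_share_pct", "zone_id"], ascending=[False, True]
        ).head(top_n)
        ranked = candidates.sort_values(
            ["people_affected_in_wui", "zone_id"], ascending=[False, True]
        )
        ids = ranked["zone_id"].tolist()
        if len(ids) < 2:
            logger.warning("region %s has %d qualifying country(ies)", region, len(ids))
            for zid in ids:
                out.append({"region": region, "zone_id": zid, "rank": 1})
            continue
        first = ids[0]
        second = None
        for cand in ids[1:]:
            if float(border_distance_km.loc[first, cand]) > min_border_distance_km:
                second = cand
                break
        pair = [first] + ([second] if second is not None else [])
        if second is None:
            logger.warning(
                "region %s: no second hotspot beyond %g km of %s",
                region, min_border_distance_km, first,
            )
        for rank, zid in enumerate(pair, start=1):
            out.append({"region": region, "zone_id": zid, "rank": rank})
    return pd.DataFrame(out, columns=["region", "zone_id", "rank"])
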