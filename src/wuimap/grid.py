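"""Georeferenced grid data model and raster I/O.

All rasters in a scene live on square-pixel grids in one projected,
equidistant-style CRS.  The grid origin is the *upper-left corner* of pixel
(0, 0); row 0 is the northernmost row.  A pixel value refers to the full
pixel footprint.  Two rasters are "aligned" iff their :class:`GridSpec`
fields match exactly.

GeoTIFF files are read and written through :mod:`tifffile`, carrying the
standard GeoTIFF ``ModelPixelScale`` / ``ModelTiepoint`` tags plus the GDAL
nodata tag.  Categorical rasters are stored as unsigned 8-bit with nodata
255; continuous rasters as 32-bit float with nodata NaN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum, IntEnum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import tifffile

__all__ = [
    "GridSpec",
    "LandCover",
    "Raster",
    "RasterKind",
    "ZoneSet",
    "pixel_area_km2",
    "read_raster",
    "resample_to",
    "write_raster",
]

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

CATEGORICAL_NODATA = 255


class LandCover(IntEnum):
    """Land-cover classes with their on-disk numeric codes.

    The code dialect follows the ESA WorldCover convention
    (10, 20, ..., 100); internal logic always goes through this enum so the
    codes stay decoupled from the rules.
    """

    TREE_COVER = 10
    SHRUBLAND = 20
    GRASSLAND = 30
    CROPLAND = 40
    BUILT_UP = 50
    BARE_SPARSE = 60
    SNOW_ICE = 70
    WATER = 80
    HERBACEOUS_WETLAND = 90
    MANGROVES = 95
    MOSS_LICHEN = 100


LAND_COVER_CODES = frozenset(int(c) for c in LandCover)


class RasterKind(str, Enum):
    LAND_COVER = "land_cover"
    BUILDING_SHARE = "building_share"
    CONTINUOUS = "continuous"
    CATEGORICAL = "categorical"
    BINARY = "binary"
    AREA_FACTOR = "area_factor"


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up, square-pixel raster grid.

    Parameters
    ----------
    origin_x, origin_y
        Map coordinates (metres) of the upper-left corner of pixel (0, 0).
    pixel_size
        Edge length of a pixel in metres; must be positive.
    n_rows, n_cols
        Grid dimensions; positive integers.
    crs_id
        Free-text identifier of the projected CRS the scene lives in.
    nodata
        Sentinel for missing values (NaN for float rasters, 255 for
        categorical ones).
    """

    origin_x: float
    origin_y: float
    pixel_size: float
    n_rows: int
    n_cols: int
    crs_id: str = "LOCAL"
    nodata: float = float("nan")

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError(
                f"grid dimensions must be positive, got {self.n_rows}x{self.n_cols}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def aligned_with(self, other: "GridSpec") -> bool:
        """Exact alignment: every geometry field matches (nodata excluded)."""
        return (
            self.origin_x == other.origin_x
            and self.origin_y == other.origin_y
            and self.pixel_size == other.pixel_size
            and self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and self.crs_id == other.crs_id
        )

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) 1-D arrays of pixel-center coordinates."""
        x = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.pixel_size
        y = self.origin_y - (np.arange(self.n_rows) + 0.5) * self.pixel_size
        return x, y

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates -> (row, col) by the half-open pixel convention.

        A point with ``x == origin_x + j * pixel_size`` falls in column ``j``
        (cells own their west and north edges).
        """
        col = np.floor((np.asarray(x, float) - self.origin_x) / self.pixel_size)
        row = np.floor((self.origin_y - np.asarray(y, float)) / self.pixel_size)
        return row.astype(np.int64), col.astype(np.int64)

    def coarsen(self, factor: int) -> "GridSpec":
        """Grid with ``factor``-times larger pixels covering the same origin."""
        if factor < 1 or self.n_rows % factor or self.n_cols % factor:
            raise ValueError(
                f"cannot coarsen {self.n_rows}x{self.n_cols} grid by factor {factor}"
            )
        return replace(
            self,
            pixel_size=self.pixel_size * factor,
            n_rows=self.n_rows // factor,
            n_cols=self.n_cols // factor,
        )


@dataclass
class Raster:
    """A typed single-band raster: a :class:`GridSpec` plus a value array.

    ``kind`` drives validation and on-disk dtype.  Continuous rasters use NaN
    as nodata; categorical ones use 255.
    """

    grid: GridSpec
    values: np.ndarray
    kind: RasterKind = RasterKind.CONTINUOUS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"value array shape {self.values.shape} does not match grid "
                f"{self.grid.shape}"
            )
        if self.kind in (RasterKind.LAND_COVER, RasterKind.CATEGORICAL, RasterKind.BINARY):
            self.values = self.values.astype(np.uint8, copy=False)
        else:
            self.values = self.values.astype(np.float64, copy=False)
        _validate_values(self.kind, self.values)

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of non-nodata pixels."""
        if self.values.dtype == np.uint8:
            return self.values != CATEGORICAL_NODATA
        return ~np.isnan(self.values)

    def require_aligned(self, other: "Raster | GridSpec", what: str = "raster") -> None:
        grid = other.grid if isinstance(other, Raster) else other
        if not self.grid.aligned_with(grid):
            raise ValueError(f"misaligned {what}: {grid} vs {self.grid}")


def _validate_values(kind: RasterKind, values: np.ndarray) -> None:
    if kind == RasterKind.LAND_COVER:
        codes = np.unique(values)
        bad = [int(c) for c in codes if c != CATEGORICAL_NODATA and int(c) not in LAND_COVER_CODES]
        if bad:
            raise ValueError(f"unknown land-cover code(s): {bad}")
    elif kind == RasterKind.BINARY:
        codes = set(np.unique(values).tolist()) - {CATEGORICAL_NODATA}
        if not codes <= {0, 1}:
            raise ValueError(f"binary raster contains non-binary values: {sorted(codes)}")
    elif kind == RasterKind.BUILDING_SHARE:
        v = values[~np.isnan(values)]
        if v.size and (v.min() < 0 or v.max() > 100):
            raise ValueError("building share must lie in [0, 100] percent")
    elif kind == RasterKind.AREA_FACTOR:
        v = values[~np.isnan(values)]
        if v.size and v.min() <= 0:
            raise ValueError("area-correction factors must be > 0")


# ---------------------------------------------------------------------------
# GeoTIFF I/O


def write_raster(path: str | Path, raster: Raster) -> Path:
    """Write a single-band GeoTIFF with georeferencing tags.

    Categorical/binary kinds are written as uint8 (nodata 255), continuous
    kinds as float32 (nodata NaN).  The :class:`GridSpec` CRS id and the
    raster kind travel in the ImageDescription tag as JSON, so a round trip
    restores the typed raster exactly.
    """
    path = Path(path)
    g = raster.grid
    if raster.values.dtype == np.uint8:
        data = raster.values
        nodata = str(CATEGORICAL_NODATA)
    else:
        data = raster.values.astype(np.float32)
        nodata = "nan"
    desc = json.dumps({"crs_id": g.crs_id, "kind": raster.kind.value, "meta": raster.meta})
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (g.pixel_size, g.pixel_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.origin_x, g.origin_y, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, nodata),
    ]
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, data, description=desc, extratags=extratags)
    return path


def read_raster(path: str | Path, expected_kind: RasterKind | str | None = None) -> Raster:
    """Read a single-band GeoTIFF written by :func:`write_raster`.

    Raises if georeferencing tags are missing, or if a land-cover raster
    contains a code outside the 11-class set.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing georeferencing (GeoTIFF model tags)")
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value
        tiepoint = tags[_TAG_MODEL_TIEPOINT].value
        desc = {}
        if "ImageDescription" in tags:
            try:
                desc = json.loads(tags["ImageDescription"].value)
            except (TypeError, json.JSONDecodeError):
                desc = {}
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster, got shape {data.shape}")
    kind = RasterKind(expected_kind) if expected_kind else RasterKind(desc.get("kind", "continuous"))
    if abs(scale[0] - scale[1]) > 1e-9:
        raise ValueError(f"{path}: pixels are not square ({scale[0]} x {scale[1]})")
    is_int = np.issubdtype(data.dtype, np.integer)
    grid = GridSpec(
        origin_x=float(tiepoint[3]),
        origin_y=float(tiepoint[4]),
        pixel_size=float(scale[0]),
        n_rows=data.shape[0],
        n_cols=data.shape[1],
        crs_id=desc.get("crs_id", "LOCAL"),
        nodata=float(CATEGORICAL_NODATA) if is_int else float("nan"),
    )
    values = data if is_int else data.astype(np.float64)
    return Raster(grid, values, kind, meta=desc.get("meta", {}))


# ---------------------------------------------------------------------------
# Resampling and area


def _block_factor(source: GridSpec, target: GridSpec) -> int:
    ratio = target.pixel_size / source.pixel_size
    factor = round(ratio)
    if factor < 1 or abs(ratio - factor) > 1e-9:
        raise ValueError(
            f"target pixel size {target.pixel_size} is not an integer multiple of "
            f"source {source.pixel_size}"
        )
    if (source.origin_x, source.origin_y) != (target.origin_x, target.origin_y):
        raise ValueError("block resampling requires a shared grid origin")
    if source.n_rows != target.n_rows * factor or source.n_cols != target.n_cols * factor:
        raise ValueError("target grid does not tile the source grid")
    return factor


def resample_to(raster: Raster, target_grid: GridSpec, method: str) -> Raster:
    """Resample onto an aligned grid of different resolution.

    ``nearest`` samples the source at target pixel centers (categorical);
    ``mean`` block-averages non-nodata source pixels (continuous, nodata
    renormalised); ``sum`` block-sums, conserving the global total exactly
    (population-style counts, nodata treated as zero contribution).
    """
    src = raster.grid
    if method == "nearest":
        xs, ys = target_grid.pixel_centers()
        rows, cols = src.index_of(
            np.repeat(xs[None, :], target_grid.n_rows, axis=0).ravel(),
            np.repeat(ys[:, None], target_grid.n_cols, axis=1).ravel(),
        )
        rows = np.clip(rows, 0, src.n_rows - 1).reshape(target_grid.shape)
        cols = np.clip(cols, 0, src.n_cols - 1).reshape(target_grid.shape)
        return Raster(target_grid, raster.values[rows, cols], raster.kind, dict(raster.meta))

    if raster.values.dtype == np.uint8 and raster.kind != RasterKind.BINARY:
        raise ValueError(f"method {method!r} is invalid for categorical rasters")
    factor = _block_factor(src, target_grid)
    vals = raster.values.astype(np.float64)
    if raster.values.dtype == np.uint8:
        valid = raster.values != CATEGORICAL_NODATA
        vals = np.where(valid, vals, 0.0)
    else:
        valid = ~np.isnan(vals)
        vals = np.nan_to_num(vals, nan=0.0)
    blocks = vals.reshape(target_grid.n_rows, factor, target_grid.n_cols, factor)
    counts = valid.reshape(target_grid.n_rows, factor, target_grid.n_cols, factor).sum(axis=(1, 3))
    sums = blocks.sum(axis=(1, 3))
    if method == "sum":
        out = sums
    elif method == "mean":
        with np.errstate(invalid="ignore"):
            out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    kind = RasterKind.CONTINUOUS if raster.values.dtype == np.uint8 else raster.kind
    return Raster(target_grid, out, kind, dict(raster.meta))


def pixel_area_km2(grid: GridSpec, area_factor: Raster | None = None) -> np.ndarray:
    """Per-pixel ground area in km².

    Nominal area is ``pixel_size² × 1e-6``; an optional aligned
    area-correction raster multiplies it per pixel to undo projection
    distortion.  Factor ≡ 1 reproduces nominal-area statistics exactly.
    """
    nominal = grid.pixel_size**2 * 1e-6
    if area_factor is None:
        return np.full(grid.shape, nominal)
    if not area_factor.grid.aligned_with(grid):
        raise ValueError("area-factor raster is not aligned with the grid")
    return nominal * area_factor.values


# ---------------------------------------------------------------------------
# Zones


@dataclass
class ZoneSet:
    """Polygons used for zonal summaries (countries, regions, biomes).

    A thin wrapper over shapely geometries; read/written as GeoJSON
    FeatureCollections with ``zone_id``, ``kind`` and ``name`` properties.
    """

    zone_ids: list
    geometries: list
    kinds: list
    names: list

    def __post_init__(self) -> None:
        if len(set(self.zone_ids)) != len(self.zone_ids):
            raise ValueError("zone ids must be unique")
        from shapely.validation import make_valid

        self.geometries = [g if g.is_valid else make_valid(g) for g in self.geometries]

    def __len__(self) -> int:
        return len(self.zone_ids)

    def __iter__(self):
        return iter(zip(self.zone_ids, self.geometries, self.kinds, self.names))

    @classmethod
    def from_features(cls, features: Iterable[Mapping]) -> "ZoneSet":
        from shapely.geometry import shape

        ids, geoms, kinds, names = [], [], [], []
        for feat in features:
            props = feat.get("properties", {})
            ids.append(props["zone_id"])
            kinds.append(props.get("kind", "region"))
            names.append(props.get("name", str(props["zone_id"])))
            geoms.append(shape(feat["geometry"]))
        return cls(ids, geoms, kinds, names)

    @classmethod
    def read_geojson(cls, path: str | Path) -> "ZoneSet":
        with open(path) as fh:
            collection = json.load(fh)
        return cls.from_features(collection["features"])

    def write_geojson(self, path: str | Path) -> Path:
        from shapely.geometry import mapping

        features = [
            {
                "type": "Feature",
                "properties": {"zone_id": zid, "kind": kind, "name": name},
                "geometry": mapping(geom),
            }
            for zid, geom, kind, name in self
        ]
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)
        return path

    def membership(self, grid: GridSpec) -> np.ndarray:
        """Zone index per pixel by pixel-center-in-polygon (-1 = no zone)."""
        import shapely

        xs, ys = grid.pixel_centers()
        xx = np.repeat(xs[None, :], grid.n_rows, axis=0)
        yy = np.repeat(ys[:, None], grid.n_cols, axis=1)
        out = np.full(grid.shape, -1, dtype=np.int32)
        for idx, (_, geom, _, _) in enumerate(self):
            inside = shapely.contains_xy(geom, xx.ravel(), yy.ravel()).reshape(grid.shape)
            out[inside] = idx
        return out
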