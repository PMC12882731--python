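"""Raster data model and GeoTIFF I/O.

A :class:`Grid2D` is one single-band georeferenced field on a regular
geographic (lon/lat degree) grid: origin at the top-left pixel *corner*,
row-major storage, rows running south (decreasing latitude). Pixel-center
coordinates are used whenever cells are converted to point locations.

GeoTIFF files are read and written through :mod:`tifffile`, carrying the
standard georeferencing tags (ModelPixelScale, ModelTiepoint, a minimal
geographic-WGS84 GeoKeyDirectory) and the GDAL nodata convention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import tifffile

__all__ = [
    "Grid2D",
    "MonthStack",
    "ClimateCube",
    "LandUseGrid",
    "LANDUSE_CLASSES",
    "read_raster",
    "write_raster",
    "resample_to",
    "stack_align",
    "month_range",
    "solar_flux_to_monthly_mj",
]

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# Minimal GeoKeyDirectory: geographic model, WGS84 (EPSG:4326)
_GEOKEYS_WGS84 = (
    1, 1, 0, 3,
    1024, 0, 1, 2,      # GTModelTypeGeoKey = geographic
    1025, 0, 1, 1,      # GTRasterTypeGeoKey = pixel-is-area
    2048, 0, 1, 4326,   # GeographicTypeGeoKey = WGS84
)

#: Canonical six-class land-use legend (code -> name).
LANDUSE_CLASSES: dict[int, str] = {
    1: "grassland",
    2: "urban",
    3: "cropland",
    4: "forest",
    5: "water",
    6: "barren",
}


class RasterFormatError(ValueError):
    """Unreadable, multi-band or otherwise malformed raster file."""


class AlignmentError(ValueError):
    """Grids that must share a geotransform/shape do not."""


@dataclass(frozen=True)
class Grid2D:
    """One single-band raster field.

    Parameters
    ----------
    values
        2-D float or integer array, row-major, row 0 at the northern edge.
    origin_lon, origin_lat
        Longitude/latitude of the top-left pixel *corner*, degrees.
    pixel_size
        Square pixel size in degrees (positive).
    nodata
        Sentinel value marking missing pixels, or None.
    crs
        CRS identifier; geographic lon/lat only.
    """

    values: np.ndarray
    origin_lon: float = 0.0
    origin_lat: float = 0.0
    pixel_size: float = 0.011305581
    nodata: float | None = None
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"values must be a non-empty 2-D array, got shape {arr.shape}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "values", arr)

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def geotransform(self) -> tuple[float, float, float]:
        return (self.origin_lon, self.origin_lat, self.pixel_size)

    def same_grid(self, other: "Grid2D", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.origin_lon - other.origin_lon) <= tol
            and abs(self.origin_lat - other.origin_lat) <= tol
            and abs(self.pixel_size - other.pixel_size) <= tol
        )

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of pixel-center coordinates, each shaped like values."""
        rows, cols = self.shape
        lon = self.origin_lon + (np.arange(cols) + 0.5) * self.pixel_size
        lat = self.origin_lat - (np.arange(rows) + 0.5) * self.pixel_size
        return np.meshgrid(lon, lat)

    # -- masking ------------------------------------------------------------
    def mask(self) -> np.ndarray:
        """Boolean mask, True where the pixel holds data."""
        v = self.values
        if self.nodata is None:
            if np.issubdtype(v.dtype, np.floating):
                return ~np.isnan(v)
            return np.ones(v.shape, dtype=bool)
        if np.issubdtype(v.dtype, np.floating) and math.isnan(self.nodata):
            return ~np.isnan(v)
        return v != self.nodata

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask()]

    def with_values(self, values: np.ndarray, nodata: float | None = None) -> "Grid2D":
        """Same georeferencing, new array (and optionally new nodata)."""
        return replace(self, values=np.asarray(values),
                       nodata=self.nodata if nodata is None else nodata)


def _months_between(start: tuple[int, int], end: tuple[int, int]) -> list[tuple[int, int]]:
    (y0, m0), (y1, m1) = start, end
    out = []
    y, m = y0, m0
    while (y, m) <= (y1, m1):
        out.append((y, m))
        m += 1
        if m == 13:
            y, m = y + 1, 1
    return out


def month_range(start_year: int, end_year: int) -> list[tuple[int, int]]:
    """All (year, month) pairs covering the closed year interval."""
    return _months_between((start_year, 1), (end_year, 12))


class MonthStack:
    """Ordered map (year, month) -> Grid2D over a contiguous month sequence.

    All member grids must share shape and geotransform.
    """

    def __init__(self, grids: Mapping[tuple[int, int], Grid2D]):
        if not grids:
            raise ValueError("MonthStack needs at least one month")
        keys = sorted(grids)
        expected = _months_between(keys[0], keys[-1])
        if keys != expected:
            raise ValueError("months must form a contiguous sequence")
        ref = grids[keys[0]]
        for k in keys:
            if not grids[k].same_grid(ref):
                raise AlignmentError(f"grid for {k} not aligned with {keys[0]}")
        self._grids: dict[tuple[int, int], Grid2D] = {k: grids[k] for k in keys}

    # Mapping-ish surface
    def __getitem__(self, key: tuple[int, int]) -> Grid2D:
        return self._grids[key]

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(self._grids)

    def __len__(self) -> int:
        return len(self._grids)

    def __contains__(self, key: object) -> bool:
        return key in self._grids

    def keys(self) -> Sequence[tuple[int, int]]:
        return list(self._grids)

    def items(self):
        return self._grids.items()

    @property
    def first(self) -> Grid2D:
        return next(iter(self._grids.values()))

    @property
    def years(self) -> list[int]:
        return sorted({y for (y, _) in self._grids})

    def year(self, y: int) -> "MonthStack":
        sub = {k: g for k, g in self._grids.items() if k[0] == y}
        if len(sub) != 12:
            raise ValueError(f"year {y} incomplete: {len(sub)} months present")
        return MonthStack(sub)

    def to_array(self) -> np.ndarray:
        """(n_months, rows, cols) array in chronological order."""
        return np.stack([g.values for g in self._grids.values()])

    def aligned_with(self, other: "MonthStack") -> bool:
        return self.keys() == other.keys() and self.first.same_grid(other.first)


#: The six climate driver names, in canonical order.
CLIMATE_VARS = (
    "temperature",        # degC
    "precipitation",      # mm / month
    "relative_humidity",  # %
    "soil_temperature",   # degC
    "soil_moisture",      # volumetric fraction
    "solar_radiation",    # MJ m-2 month-1
)


class ClimateCube:
    """Six aligned monthly climate stacks (see :data:`CLIMATE_VARS`)."""

    def __init__(self, stacks: Mapping[str, MonthStack],
                 units: Mapping[str, str] | None = None):
        missing = set(CLIMATE_VARS) - set(stacks)
        if missing:
            raise ValueError(f"missing climate variables: {sorted(missing)}")
        ref = stacks[CLIMATE_VARS[0]]
        for name in CLIMATE_VARS:
            if not stacks[name].aligned_with(ref):
                raise AlignmentError(f"stack {name!r} not aligned with reference")
        self.stacks = {name: stacks[name] for name in CLIMATE_VARS}
        self.units = dict(units or {})

    def __getitem__(self, name: str) -> MonthStack:
        return self.stacks[name]

    @property
    def months(self) -> Sequence[tuple[int, int]]:
        return self.stacks[CLIMATE_VARS[0]].keys()

    @property
    def template(self) -> Grid2D:
        return self.stacks[CLIMATE_VARS[0]].first


@dataclass(frozen=True)
class LandUseGrid:
    """Categorical raster of integer class codes with a legend."""

    grid: Grid2D
    legend: Mapping[int, str] = field(default_factory=lambda: dict(LANDUSE_CLASSES))

    def __post_init__(self) -> None:
        codes = np.unique(self.grid.values[self.grid.mask()])
        unknown = [int(c) for c in codes if int(c) not in self.legend]
        if unknown:
            raise ValueError(f"codes without legend entry: {unknown}")

    @property
    def values(self) -> np.ndarray:
        return self.grid.values

    def code_of(self, name: str) -> int:
        for code, nm in self.legend.items():
            if nm == name:
                return code
        raise KeyError(f"class {name!r} not in legend")


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def write_raster(grid: Grid2D, path: str | Path) -> None:
    """Write a Grid2D as a single-band GeoTIFF (roundtrip-stable)."""
    path = Path(path)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.pixel_size, grid.pixel_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, grid.origin_lon, grid.origin_lat, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(_GEOKEYS_WGS84), _GEOKEYS_WGS84),
    ]
    if grid.nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, repr(float(grid.nodata))))
    try:
        tifffile.imwrite(path, grid.values, extratags=extratags)
    except (OSError, PermissionError) as exc:
        raise OSError(f"cannot write raster to {path}: {exc}") from exc


def read_raster(path: str | Path) -> Grid2D:
    """Read a single-band GeoTIFF written by :func:`write_raster` (or alike)."""
    path = Path(path)
    if not path.exists():
        raise RasterFormatError(f"no such raster file: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            if len(tif.pages) != 1:
                raise RasterFormatError(f"{path}: expected single band, got {len(tif.pages)} pages")
            page = tif.pages[0]
            values = page.asarray()
            if values.ndim != 2:
                raise RasterFormatError(f"{path}: expected single band, got shape {values.shape}")
            tags = page.tags
            pixel = 0.011305581
            olon = olat = 0.0
            if _TAG_MODEL_PIXEL_SCALE in tags:
                pixel = float(tags[_TAG_MODEL_PIXEL_SCALE].value[0])
            if _TAG_MODEL_TIEPOINT in tags:
                tp = tags[_TAG_MODEL_TIEPOINT].value
                olon, olat = float(tp[3]), float(tp[4])
            nodata = None
            if _TAG_GDAL_NODATA in tags:
                nodata = float(str(tags[_TAG_GDAL_NODATA].value))
    except RasterFormatError:
        raise
    except Exception as exc:  # malformed TIFF
        raise RasterFormatError(f"cannot read raster {path}: {exc}") from exc
    return Grid2D(values=values, origin_lon=olon, origin_lat=olat,
                  pixel_size=pixel, nodata=nodata)


def write_landuse(lu: LandUseGrid, path: str | Path) -> None:
    """LandUseGrid as GeoTIFF plus a JSON legend sidecar."""
    write_raster(lu.grid, path)
    sidecar = Path(path).with_suffix(".legend.json")
    sidecar.write_text(json.dumps({str(k): v for k, v in lu.legend.items()}, indent=1))


def read_landuse(path: str | Path) -> LandUseGrid:
    grid = read_raster(path)
    sidecar = Path(path).with_suffix(".legend.json")
    if sidecar.exists():
        legend = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    else:
        legend = dict(LANDUSE_CLASSES)
    return LandUseGrid(grid=grid, legend=legend)


# ---------------------------------------------------------------------------
# Resampling and alignment
# ---------------------------------------------------------------------------

def _is_categorical(grid: Grid2D) -> bool:
    return np.issubdtype(grid.values.dtype, np.integer)


def resample_to(grid: Grid2D,
                target_geotransform: tuple[float, float, float],
                target_shape: tuple[int, int],
                method: str = "bilinear") -> Grid2D:
    """Resample onto a target grid by nearest-neighbour or bilinear.

    Nearest never invents class codes; bilinear is refused for integer
    (categorical) grids. A constant field resamples to that constant.
    Target pixels whose source support is nodata (or outside the source
    extent) come out as nodata.
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown method {method!r}")
    if method == "bilinear" and _is_categorical(grid):
        raise ValueError("bilinear resampling is invalid for categorical grids")

    t_lon, t_lat, t_pix = target_geotransform
    t_rows, t_cols = target_shape
    if grid.geotransform == (t_lon, t_lat, t_pix) and grid.shape == (t_rows, t_cols):
        return grid

    # target pixel centers in source fractional index space
    lon = t_lon + (np.arange(t_cols) + 0.5) * t_pix
    lat = t_lat - (np.arange(t_rows) + 0.5) * t_pix
    fx = (lon - grid.origin_lon) / grid.pixel_size - 0.5   # source col index
    fy = (grid.origin_lat - lat) / grid.pixel_size - 0.5   # source row index
    FX, FY = np.meshgrid(fx, fy)

    rows, cols = grid.shape
    src = grid.values
    if method == "nearest":
        ix = np.clip(np.round(FX).astype(int), 0, cols - 1)
        iy = np.clip(np.round(FY).astype(int), 0, rows - 1)
        inside = (FX >= -0.5) & (FX <= cols - 0.5) & (FY >= -0.5) & (FY <= rows - 0.5)
        out = src[iy, ix]
        if grid.nodata is not None and not inside.all():
            out = np.where(inside, out, np.asarray(grid.nodata, dtype=src.dtype))
        nodata = grid.nodata
    else:
        x0 = np.clip(np.floor(FX).astype(int), 0, cols - 1)
        y0 = np.clip(np.floor(FY).astype(int), 0, rows - 1)
        x1 = np.clip(x0 + 1, 0, cols - 1)
        y1 = np.clip(y0 + 1, 0, rows - 1)
        wx = np.clip(FX - x0, 0.0, 1.0)
        wy = np.clip(FY - y0, 0.0, 1.0)
        srcf = src.astype(float)
        m = grid.mask()
        if not m.all():
            srcf = np.where(m, srcf, np.nan)
        out = ((1 - wy) * ((1 - wx) * srcf[y0, x0] + wx * srcf[y0, x1])
               + wy * ((1 - wx) * srcf[y1, x0] + wx * srcf[y1, x1]))
        inside = (FX >= -0.5) & (FX <= cols - 0.5) & (FY >= -0.5) & (FY <= rows - 0.5)
        out = np.where(inside, out, np.nan)
        nodata = grid.nodata
        if nodata is not None:
            out = np.where(np.isnan(out), nodata, out)
        elif np.isnan(out).any():
            nodata = float("nan")
    return Grid2D(values=out, origin_lon=t_lon, origin_lat=t_lat,
                  pixel_size=t_pix, nodata=nodata, crs=grid.crs)


def stack_align(stacks: Sequence[MonthStack], reference: MonthStack,
                methods: Sequence[str] | None = None) -> list[MonthStack]:
    """Resample every stack onto the reference geotransform/shape.

    ``methods`` gives one resampling method per stack (default: nearest for
    integer-valued stacks, bilinear otherwise). Stacks whose extent does not
    overlap the reference raise :class:`AlignmentError`.
    """
    ref = reference.first
    out: list[MonthStack] = []
    for idx, stack in enumerate(stacks):
        g0 = stack.first
        # overlap check on outer bounds
        lon0, lon1 = g0.origin_lon, g0.origin_lon + g0.shape[1] * g0.pixel_size
        rlon0, rlon1 = ref.origin_lon, ref.origin_lon + ref.shape[1] * ref.pixel_size
        lat1, lat0 = g0.origin_lat, g0.origin_lat - g0.shape[0] * g0.pixel_size
        rlat1, rlat0 = ref.origin_lat, ref.origin_lat - ref.shape[0] * ref.pixel_size
        if lon1 <= rlon0 or rlon1 <= lon0 or lat1 <= rlat0 or rlat1 <= lat0:
            raise AlignmentError(f"stack {idx} extent disjoint from reference")
        method = (methods[idx] if methods is not None
                  else ("nearest" if _is_categorical(g0) else "bilinear"))
        out.append(MonthStack({
            k: resample_to(g, ref.geotransform, ref.shape, method)
            for k, g in stack.items()
        }))
    return out


_DAYS_IN_MONTH = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)


def solar_flux_to_monthly_mj(flux_wm2: Grid2D, month: int) -> Grid2D:
    """Convert mean W/m2 flux to the MJ m-2 month-1 total CASA expects.

    Uses a fixed 365-day calendar (no leap years).
    """
    if not 1 <= month <= 12:
        raise ValueError("month must be in 1..12")
    seconds = _DAYS_IN_MONTH[month - 1] * 86400.0
    return flux_wm2.with_values(flux_wm2.values * seconds * 1e-6)
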