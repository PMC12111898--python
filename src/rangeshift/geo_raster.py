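"""Raster grid model, GeoTIFF I/O, resampling, and latitude-corrected areas.

Every spatial layer in the pipeline — monthly climate, bioclim variables,
habitat-suitability maps, binary ranges — is carried by :class:`RasterGrid`,
a plain 2D array on a north-up geographic (lon/lat, EPSG:4326) grid with an
explicit nodata mask.  Areas are computed on a spherical Earth so that
"million km²" style summaries respect the shrinking of lon/lat pixels
toward the poles.

GeoTIFF files are read and written through :mod:`tifffile` with the
standard georeferencing tags (ModelPixelScale, ModelTiepoint,
GeoKeyDirectory, GDAL_NODATA); only single-band, geographic-CRS rasters
are supported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import tifffile

EARTH_RADIUS_KM = 6371.0

# GeoTIFF tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids
_KEY_MODEL_TYPE = 1024
_KEY_RASTER_TYPE = 1025
_KEY_GEOGRAPHIC_TYPE = 2048
_MODEL_TYPE_PROJECTED = 1
_MODEL_TYPE_GEOGRAPHIC = 2
_EPSG_WGS84 = 4326

DEFAULT_NODATA = -9999.0


class RasterError(ValueError):
    """Raised for invalid raster inputs (CRS, grid mismatch, bad files)."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up lon/lat raster grid.

    ``lon_origin``/``lat_origin`` are the west and north *edges* of cell
    (0, 0); ``cell_size`` is in degrees and pixels are square.  Row 0 is the
    northernmost row.  Point-to-cell mapping uses half-open intervals
    ``[edge, edge + cell_size)``.
    """

    n_rows: int
    n_cols: int
    lon_origin: float
    lat_origin: float
    cell_size: float

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise RasterError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise RasterError("cell_size must be positive")
        if self.lat_origin - self.n_rows * self.cell_size < -90.0 - 1e-9:
            raise RasterError("grid extends south of -90 degrees latitude")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lat_centers(self) -> np.ndarray:
        """Cell-center latitudes, north to south (length n_rows)."""
        return self.lat_origin - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def lon_centers(self) -> np.ndarray:
        """Cell-center longitudes, west to east (length n_cols)."""
        return self.lon_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def cell_of(self, lon: float | np.ndarray, lat: float | np.ndarray):
        """Map point(s) to (row, col); points outside the grid get -1."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_origin) / self.cell_size).astype(int)
        row = np.floor((self.lat_origin - lat) / self.cell_size).astype(int)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        row = np.where(bad, -1, row)
        col = np.where(bad, -1, col)
        if row.ndim == 0:
            return int(row), int(col)
        return row, col


@dataclass
class RasterGrid:
    """A single-band raster: values + nodata mask on a :class:`GridSpec`.

    ``nodata_mask`` is True where the cell carries no data.  All statistics
    ignore masked cells, and arithmetic between rasters masks the union of
    the operand masks (nodata is never silently treated as zero).
    """

    grid: GridSpec
    values: np.ndarray
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.shape != self.grid.shape:
            raise RasterError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.nodata_mask.shape != self.grid.shape:
            raise RasterError("nodata_mask shape does not match grid")

    # -- convenience -------------------------------------------------------
    def copy(self, values: np.ndarray | None = None, name: str | None = None) -> "RasterGrid":
        return RasterGrid(
            grid=self.grid,
            values=self.values.copy() if values is None else values,
            nodata_mask=self.nodata_mask.copy(),
            name=self.name if name is None else name,
        )

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.MaskedArray(self.values, mask=self.nodata_mask)

    def unmasked_values(self) -> np.ndarray:
        return self.values[~self.nodata_mask]

    def _binary_op(self, other, op, name: str) -> "RasterGrid":
        if isinstance(other, RasterGrid):
            if other.grid != self.grid:
                raise RasterError("grid mismatch in raster arithmetic")
            vals = op(self.values, other.values)
            mask = self.nodata_mask | other.nodata_mask
        else:
            vals = op(self.values, other)
            mask = self.nodata_mask.copy()
        return RasterGrid(grid=self.grid, values=vals, nodata_mask=mask, name=name)

    def __add__(self, other):
        return self._binary_op(other, np.add, f"({self.name}+)")

    def __sub__(self, other):
        return self._binary_op(other, np.subtract, f"({self.name}-)")

    def __mul__(self, other):
        return self._binary_op(other, np.multiply, f"({self.name}*)")


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def _geokey_directory() -> tuple[int, ...]:
    # version 1.1.0, 3 keys: geographic model, pixel-is-area, WGS84
    return (
        1, 1, 0, 3,
        _KEY_MODEL_TYPE, 0, 1, _MODEL_TYPE_GEOGRAPHIC,
        _KEY_RASTER_TYPE, 0, 1, 1,
        _KEY_GEOGRAPHIC_TYPE, 0, 1, _EPSG_WGS84,
    )


def write_raster(r: RasterGrid, path, nodata: float = DEFAULT_NODATA,
                 dtype: str = "float32") -> str:
    """Write a single-band GeoTIFF with explicit nodata encoding.

    Finite values round-trip bit-faithfully at the stored precision;
    masked cells are written as the nodata value.
    """
    path = str(path)
    vals = np.where(r.nodata_mask, float(nodata),
                    np.where(np.isfinite(r.values), r.values, float(nodata)))
    vals = vals.astype(dtype)
    geokeys = _geokey_directory()
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (r.grid.cell_size, r.grid.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, r.grid.lon_origin, r.grid.lat_origin, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(path, vals, photometric="minisblack", extratags=extratags)
    return path


def read_raster(path, name: str | None = None) -> RasterGrid:
    """Read a single-band georeferenced GeoTIFF into a :class:`RasterGrid`.

    Rejects projected coordinate systems: the pipeline works exclusively on
    geographic (lon/lat) grids.
    """
    path = str(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        tags = page.tags
        vals = page.asarray()
        if vals.ndim != 2:
            raise RasterError(f"{path}: expected a single-band raster")

        if _TAG_GEO_KEY_DIRECTORY in tags:
            keys = tuple(int(v) for v in np.atleast_1d(tags[_TAG_GEO_KEY_DIRECTORY].value))
            model_type = None
            for i in range(4, len(keys), 4):
                if keys[i] == _KEY_MODEL_TYPE:
                    model_type = keys[i + 3]
            if model_type == _MODEL_TYPE_PROJECTED:
                raise RasterError(
                    f"{path}: projected coordinate system; only geographic "
                    "(lon/lat, EPSG:4326) rasters are supported"
                )
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise RasterError(f"{path}: missing georeferencing tags")
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value
        tiepoint = tags[_TAG_MODEL_TIEPOINT].value
        sx, sy = float(scale[0]), float(scale[1])
        if not math.isclose(sx, sy, rel_tol=1e-9):
            raise RasterError(f"{path}: non-square pixels are not supported")
        # tiepoint maps raster (i, j, k) -> model (x, y, z)
        px, py = float(tiepoint[0]), float(tiepoint[1])
        mx, my = float(tiepoint[3]), float(tiepoint[4])
        lon_origin = mx - px * sx
        lat_origin = my + py * sy

        nodata = None
        if _TAG_GDAL_NODATA in tags:
            try:
                nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 "))
            except ValueError:
                nodata = None

    vals = np.asarray(vals, dtype=float)
    mask = ~np.isfinite(vals)
    if nodata is not None:
        mask |= vals == nodata
    spec = GridSpec(
        n_rows=vals.shape[0], n_cols=vals.shape[1],
        lon_origin=lon_origin, lat_origin=lat_origin, cell_size=sx,
    )
    return RasterGrid(grid=spec, values=vals, nodata_mask=mask,
                      name=name if name is not None else path)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample(r: RasterGrid, target: GridSpec,
             method: str = "bilinear") -> RasterGrid:
    """Resample a raster onto ``target``.

    ``bilinear`` (default for continuous layers) interpolates between the
    four nearest source cell centers with mask-aware weight renormalisation;
    ``nearest`` picks the closest source cell (categorical layers);
    ``mean_aggregate`` averages all source cells whose centers fall inside
    each target cell (fraction layers coarsened from finer grids).  Target
    cells with no usable source data are masked.
    """
    src, tgt = r.grid, target
    src_lon_min = src.lon_origin
    src_lon_max = src.lon_origin + src.n_cols * src.cell_size
    src_lat_max = src.lat_origin
    src_lat_min = src.lat_origin - src.n_rows * src.cell_size
    tgt_lon_min = tgt.lon_origin
    tgt_lon_max = tgt.lon_origin + tgt.n_cols * tgt.cell_size
    tgt_lat_max = tgt.lat_origin
    tgt_lat_min = tgt.lat_origin - tgt.n_rows * tgt.cell_size
    if (tgt_lon_min >= src_lon_max or tgt_lon_max <= src_lon_min
            or tgt_lat_min >= src_lat_max or tgt_lat_max <= src_lat_min):
        raise RasterError("source and target grids do not overlap")

    if method == "mean_aggregate":
        return _resample_mean_aggregate(r, target)
    if method not in ("bilinear", "nearest"):
        raise RasterError(f"unknown resampling method {method!r}")

    # fractional source indices of target cell centers (index space where
    # integer k is the center of source cell k)
    tlon = tgt.lon_centers()
    tlat = tgt.lat_centers()
    fx = (tlon - (src.lon_origin + 0.5 * src.cell_size)) / src.cell_size
    fy = ((src.lat_origin - 0.5 * src.cell_size) - tlat) / src.cell_size
    fx2, fy2 = np.meshgrid(fx, fy)

    if method == "nearest":
        ix = np.rint(fx2).astype(int)
        iy = np.rint(fy2).astype(int)
        oob = (ix < 0) | (ix >= src.n_cols) | (iy < 0) | (iy >= src.n_rows)
        ixc = np.clip(ix, 0, src.n_cols - 1)
        iyc = np.clip(iy, 0, src.n_rows - 1)
        vals = r.values[iyc, ixc]
        mask = oob | r.nodata_mask[iyc, ixc]
        return RasterGrid(grid=tgt, values=np.where(mask, np.nan, vals),
                          nodata_mask=mask, name=r.name)

    # bilinear with mask-aware renormalisation over the valid corners
    x0 = np.floor(fx2).astype(int)
    y0 = np.floor(fy2).astype(int)
    wx = fx2 - x0
    wy = fy2 - y0
    vals = np.zeros(tgt.shape)
    wsum = np.zeros(tgt.shape)
    for dy, dx, w in (
        (0, 0, (1 - wx) * (1 - wy)),
        (0, 1, wx * (1 - wy)),
        (1, 0, (1 - wx) * wy),
        (1, 1, wx * wy),
    ):
        ix = x0 + dx
        iy = y0 + dy
        inb = (ix >= 0) & (ix < src.n_cols) & (iy >= 0) & (iy < src.n_rows)
        ixc = np.clip(ix, 0, src.n_cols - 1)
        iyc = np.clip(iy, 0, src.n_rows - 1)
        valid = inb & ~r.nodata_mask[iyc, ixc]
        wv = np.where(valid, w, 0.0)
        vals += wv * np.where(valid, r.values[iyc, ixc], 0.0)
        wsum += wv
    mask = wsum <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(mask, np.nan, vals / np.where(wsum > 0, wsum, 1.0))
    return RasterGrid(grid=tgt, values=out, nodata_mask=mask, name=r.name)


def _resample_mean_aggregate(r: RasterGrid, target: GridSpec) -> RasterGrid:
    src, tgt = r.grid, target
    slon = src.lon_centers()
    slat = src.lat_centers()
    col = np.floor((slon - tgt.lon_origin) / tgt.cell_size).astype(int)
    row = np.floor((tgt.lat_origin - slat) / tgt.cell_size).astype(int)
    col2, row2 = np.meshgrid(col, row)
    ok = ((col2 >= 0) & (col2 < tgt.n_cols) & (row2 >= 0) & (row2 < tgt.n_rows)
          & ~r.nodata_mask)
    flat = row2[ok] * tgt.n_cols + col2[ok]
    sums = np.bincount(flat, weights=r.values[ok], minlength=tgt.n_rows * tgt.n_cols)
    counts = np.bincount(flat, minlength=tgt.n_rows * tgt.n_cols)
    counts2 = counts.reshape(tgt.shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = sums.reshape(tgt.shape) / np.where(counts2 > 0, counts2, 1)
    mask = counts2 == 0
    return RasterGrid(grid=tgt, values=np.where(mask, np.nan, vals),
                      nodata_mask=mask, name=r.name)


# ---------------------------------------------------------------------------
# Areas
# ---------------------------------------------------------------------------

def cell_area_km2(lat_center: float | np.ndarray, cell_size: float) -> float | np.ndarray:
    """Spherical-Earth area (km²) of a lon/lat cell centered at ``lat_center``.

    A = R² · Δλ · (sin φ_n − sin φ_s) with R = 6371 km; positive everywhere,
    decreasing toward the poles, symmetric in the sign of the latitude.
    """
    lat = np.asarray(lat_center, dtype=float)
    if np.any(np.abs(lat) > 90.0 + 1e-9):
        raise RasterError("|lat_center| must be <= 90")
    half = cell_size / 2.0
    phi_n = np.minimum(lat + half, 90.0)
    phi_s = np.maximum(lat - half, -90.0)
    dlam = math.radians(cell_size)
    area = (EARTH_RADIUS_KM ** 2) * dlam * (
        np.sin(np.radians(phi_n)) - np.sin(np.radians(phi_s))
    )
    if np.ndim(lat_center) == 0:
        return float(area)
    return area


def cell_areas(grid: GridSpec) -> np.ndarray:
    """Per-cell areas (km²) for a whole grid, shape (n_rows, n_cols)."""
    row_areas = cell_area_km2(grid.lat_centers(), grid.cell_size)
    return np.repeat(np.asarray(row_areas)[:, None], grid.n_cols, axis=1)


def masked_area_sum(r: RasterGrid, predicate=None) -> float:
    """Total area (km²) of unmasked cells where ``predicate(values)`` holds.

    ``predicate`` receives the value array and returns a boolean array;
    ``None`` selects every unmasked cell.
    """
    sel = ~r.nodata_mask
    if predicate is not None:
        with np.errstate(invalid="ignore"):
            sel = sel & np.asarray(predicate(r.values), dtype=bool)
    if not sel.any():
        return 0.0
    return float(cell_areas(r.grid)[sel].sum())
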