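"""Bioclimatic, terrain and land-use predictor derivation.

Implements the 19 standard bioclimatic variables (bio1–bio19, the
WorldClim/ANUCLIM definitions) from monthly minimum/maximum temperature and
precipitation rasters, Horn-method slope/aspect from a DEM, and category-
tagged predictor stacks (climate / landuse / topography) shared by all
modelling stages.

Conventions (documented because several competing ones exist in the wild):

* monthly mean temperature is (tmin + tmax) / 2;
* bio4 is 100 × the population standard deviation of monthly means;
* bio15 uses the ANUCLIM denominator 1 + bio12/12, so deserts with zero
  rainfall get bio15 = 0 rather than a division by zero;
* "quarters" are the 12 windows of 3 consecutive months with December→
  January wraparound; ties between equally warm/wet quarters are broken by
  the earliest starting month.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geo_raster import GridSpec, RasterGrid, RasterError

BIOCLIM_NAMES = [f"bio{i}" for i in range(1, 20)]

CATEGORY_CLIMATE = "climate"
CATEGORY_LANDUSE = "landuse"
CATEGORY_TOPOGRAPHY = "topography"

#: metres per degree of latitude (spherical Earth, R = 6371 km)
METRES_PER_DEGREE = 111194.9

FLAT_ASPECT = -1.0


@dataclass
class MonthlyClimate:
    """Twelve monthly tmin/tmax (°C) and precipitation (mm) rasters."""

    tmin: list[RasterGrid]
    tmax: list[RasterGrid]
    prec: list[RasterGrid]
    scenario_id: str = "current"

    def __post_init__(self) -> None:
        for name, layers in (("tmin", self.tmin), ("tmax", self.tmax),
                             ("prec", self.prec)):
            if len(layers) != 12:
                raise RasterError(f"{name} must have 12 monthly layers")
        grids = {lyr.grid for lyr in self.tmin + self.tmax + self.prec}
        if len(grids) != 1:
            raise RasterError("monthly layers must share one GridSpec")

    @property
    def grid(self) -> GridSpec:
        return self.tmin[0].grid

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(tmin, tmax, prec) stacked (12, rows, cols) plus the union mask."""
        tn = np.stack([r.values for r in self.tmin])
        tx = np.stack([r.values for r in self.tmax])
        pr = np.stack([r.values for r in self.prec])
        mask = np.zeros(self.grid.shape, dtype=bool)
        for r in self.tmin + self.tmax + self.prec:
            mask |= r.nodata_mask
        return tn, tx, pr, mask


def _quarter_stats(tmean: np.ndarray, prec: np.ndarray):
    """Per-window quarter means/sums over the 12 wrapped 3-month windows.

    Returns (qt, qp) with shape (12, rows, cols): qt[k] is the mean
    temperature and qp[k] the precipitation sum of the window starting at
    month k (0-based), wrapping across the year boundary.
    """
    idx = np.arange(12)
    windows = (idx[:, None] + np.arange(3)[None, :]) % 12
    qt = tmean[windows].mean(axis=1)
    qp = prec[windows].sum(axis=1)
    return qt, qp


def compute_bioclim(mc: MonthlyClimate) -> dict[str, RasterGrid]:
    """Derive bio1…bio19 from monthly climate.

    Raises if tmax < tmin anywhere unmasked, listing the offending cells.
    """
    tn, tx, pr, mask = mc.arrays()
    bad = (tx < tn).any(axis=0) & ~mask
    if bad.any():
        cells = list(zip(*np.nonzero(bad)))
        raise RasterError(
            f"tmax < tmin at {len(cells)} cells, e.g. {cells[:5]}"
        )
    tm = (tn + tx) / 2.0

    out: dict[str, np.ndarray] = {}
    out["bio1"] = tm.mean(axis=0)
    out["bio2"] = (tx - tn).mean(axis=0)
    out["bio4"] = 100.0 * tm.std(axis=0)  # population sd
    out["bio5"] = tx.max(axis=0)
    out["bio6"] = tn.min(axis=0)
    out["bio7"] = out["bio5"] - out["bio6"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["bio3"] = np.where(out["bio7"] != 0,
                               100.0 * out["bio2"] / out["bio7"], 0.0)
    out["bio12"] = pr.sum(axis=0)
    out["bio13"] = pr.max(axis=0)
    out["bio14"] = pr.min(axis=0)
    out["bio15"] = 100.0 * pr.std(axis=0) / (1.0 + out["bio12"] / 12.0)

    qt, qp = _quarter_stats(tm, pr)
    # argmax/argmin return the first (earliest-starting) optimum: the
    # documented tie-break.
    wettest = qp.argmax(axis=0)
    driest = qp.argmin(axis=0)
    warmest = qt.argmax(axis=0)
    coldest = qt.argmin(axis=0)
    rr, cc = np.meshgrid(np.arange(qt.shape[1]), np.arange(qt.shape[2]),
                         indexing="ij")
    out["bio8"] = qt[wettest, rr, cc]
    out["bio9"] = qt[driest, rr, cc]
    out["bio10"] = qt[warmest, rr, cc]
    out["bio11"] = qt[coldest, rr, cc]
    out["bio16"] = qp[wettest, rr, cc]
    out["bio17"] = qp[driest, rr, cc]
    out["bio18"] = qp[warmest, rr, cc]
    out["bio19"] = qp[coldest, rr, cc]

    return {
        name: RasterGrid(grid=mc.grid, values=np.where(mask, np.nan, out[name]),
                         nodata_mask=mask.copy(), name=name)
        for name in BIOCLIM_NAMES
    }


def compute_terrain(dem: RasterGrid) -> dict[str, RasterGrid]:
    """Elevation, slope (degrees) and aspect (degrees from north) from a DEM.

    Slope and aspect use Horn's 3×3 finite differences with lon spacing
    scaled by cos(latitude) so gradients are in metres/metre.  Flat cells
    get the aspect sentinel -1.  Border cells use edge-replicated padding.
    """
    if dem.grid.n_rows < 3 or dem.grid.n_cols < 3:
        raise RasterError("DEM must be at least 3x3 for slope/aspect")
    # masked (ocean) neighbours enter the stencil at sea level so coastal
    # land cells still get finite gradients
    filled = np.where(dem.nodata_mask | ~np.isfinite(dem.values), 0.0,
                      dem.values)
    z = np.pad(filled, 1, mode="edge")
    # Horn kernel weights over the 3x3 neighbourhood
    dz_dx = ((z[:-2, 2:] + 2 * z[1:-1, 2:] + z[2:, 2:])
             - (z[:-2, :-2] + 2 * z[1:-1, :-2] + z[2:, :-2]))
    dz_dy = ((z[2:, :-2] + 2 * z[2:, 1:-1] + z[2:, 2:])
             - (z[:-2, :-2] + 2 * z[:-2, 1:-1] + z[:-2, 2:]))
    lat = dem.grid.lat_centers()
    dy_m = dem.grid.cell_size * METRES_PER_DEGREE
    dx_m = dy_m * np.maximum(np.cos(np.radians(lat)), 1e-6)[:, None]
    gx = dz_dx / (8.0 * dx_m)
    gy = dz_dy / (8.0 * dy_m)  # positive toward south

    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    # downslope direction, clockwise from north: the gradient points
    # (gx east, -gy north), so downslope is (-gx, gy)
    aspect = np.degrees(np.arctan2(-gx, gy)) % 360.0
    flat = (gx == 0) & (gy == 0)
    aspect = np.where(flat, FLAT_ASPECT, aspect)

    mask = dem.nodata_mask.copy()
    return {
        "elevation": dem.copy(name="elevation"),
        "slope": RasterGrid(grid=dem.grid, values=np.where(mask, np.nan, slope),
                            nodata_mask=mask.copy(), name="slope"),
        "aspect": RasterGrid(grid=dem.grid, values=np.where(mask, np.nan, aspect),
                             nodata_mask=mask.copy(), name="aspect"),
    }


@dataclass
class PredictorStack:
    """Ordered, category-tagged set of co-registered predictor rasters."""

    layers: dict[str, RasterGrid]
    category: dict[str, str]
    scenario_id: str = "current"
    _mask: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.layers:
            raise RasterError("empty predictor stack")
        grids = {r.grid for r in self.layers.values()}
        if len(grids) != 1:
            raise RasterError("all stack layers must share one GridSpec")
        missing = set(self.layers) - set(self.category)
        if missing:
            raise RasterError(f"layers without category: {sorted(missing)}")
        mask = np.zeros(self.grid.shape, dtype=bool)
        for r in self.layers.values():
            mask |= r.nodata_mask
        self._mask = mask

    @property
    def grid(self) -> GridSpec:
        return next(iter(self.layers.values())).grid

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def combined_mask(self) -> np.ndarray:
        """True where any layer is nodata — the cell is unusable."""
        return self._mask

    def land_indices(self) -> np.ndarray:
        """Flat indices of fully-valid (land) cells."""
        return np.flatnonzero(~self._mask.ravel())

    def feature_matrix(self, flat_indices: np.ndarray,
                       names: list[str] | None = None) -> np.ndarray:
        """Per-cell feature vectors for the given flat cell indices.

        Rejects indices that fall on masked cells.
        """
        flat_indices = np.asarray(flat_indices)
        if self._mask.ravel()[flat_indices].any():
            raise RasterError("feature extraction requested at masked cells")
        names = names if names is not None else self.names
        return np.column_stack(
            [self.layers[n].values.ravel()[flat_indices] for n in names]
        )

    def subset(self, names: list[str]) -> "PredictorStack":
        return PredictorStack(
            layers={n: self.layers[n] for n in names},
            category={n: self.category[n] for n in names},
            scenario_id=self.scenario_id,
        )


def assemble_stack(bio: dict[str, RasterGrid],
                   landuse: dict[str, RasterGrid],
                   terrain: dict[str, RasterGrid],
                   scenario_id: str = "current") -> PredictorStack:
    """Assemble the climate + landuse + topography stack for one scenario."""
    layers: dict[str, RasterGrid] = {}
    category: dict[str, str] = {}
    for group, cat in ((bio, CATEGORY_CLIMATE), (landuse, CATEGORY_LANDUSE),
                       (terrain, CATEGORY_TOPOGRAPHY)):
        for name, r in group.items():
            if name in layers:
                raise RasterError(f"duplicate predictor name {name!r}")
            layers[name] = r
            category[name] = cat
    return PredictorStack(layers=layers, category=category,
                          scenario_id=scenario_id)
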