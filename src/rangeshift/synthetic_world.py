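"""Synthetic worlds and virtual species with known truth.

The generator produces everything the real pipeline would consume —
monthly climate under multiple scenarios, compositional land-use
fractions, a rough DEM, and occurrence samples — from seeded, spatially
autocorrelated random fields, so the whole modelling chain can be
exercised against species whose true environmental responses (and hence
true range dynamics) are known by construction.

What it emulates: a latitudinal mean-temperature gradient with smooth
regional anomalies; a seasonal cycle whose amplitude grows away from the
equator (opposite phase in the two hemispheres); log-normal-ish smooth
precipitation fields with a seasonal modulation; warming scenarios as a
uniform temperature offset plus a precipitation scale factor and a shift
of land-use fractions toward the urban class; an ocean mask so land is a
proper subset of the grid.  What it does not emulate: circulation-model
physics, interannual variability, topographically forced climate, or any
dispersal limitation — virtual species occupy their full climate envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geo_raster import GridSpec, RasterGrid, cell_areas
from .occurrences import OccurrenceRecord, OccurrenceSet
from .predictors import (MonthlyClimate, PredictorStack, assemble_stack,
                         compute_bioclim, compute_terrain)
from .seeding import derive_seed

LANDUSE_NAMES = ["urban", "crop", "pasture", "rangeland", "primary_forest",
                 "secondary_forest", "primary_nonforest", "secondary_nonforest"]

#: the default predictor subset used by the virtual-species suite:
#: four climate summaries, two terrain variables, four land-use fractions,
#: chosen to be reasonably decorrelated in the synthetic world.
SUITE_PREDICTORS = ["bio1", "bio4", "bio12", "bio15", "elevation", "slope",
                    "urban", "crop", "pasture", "primary_forest"]


@dataclass(frozen=True)
class ScenarioConfig:
    id: str
    delta_t: float = 0.0        # °C added to monthly tmin/tmax
    precip_scale: float = 1.0   # multiplicative on monthly precipitation
    landuse_shift: float = 0.0  # fraction of non-urban land converted to urban


@dataclass
class WorldConfig:
    """Configuration of a synthetic world.

    Defaults give a 120×240 global grid (1.5° cells), a 0.55 °C/°lat
    equator-to-pole gradient, smooth anomalies with a 3-cell correlation
    length, and an optimistic (+1 °C) and a pessimistic (+4 °C) future
    scenario alongside the current one.
    """

    grid: GridSpec = dc_field(default_factory=lambda: GridSpec(
        n_rows=120, n_cols=240, lon_origin=-180.0, lat_origin=90.0,
        cell_size=1.5))
    seed: int = 0
    gradient: float = 0.55          # °C per degree latitude
    t_equator: float = 27.0         # annual-mean °C at the equator
    roughness: float = 3.0          # correlation length, cells
    anomaly_sd: float = 3.0         # °C, sd of the smooth regional anomaly
    amplitude: float = 16.0         # °C, max seasonal half-swing at the poles
    half_range_base: float = 4.0    # °C, (tmax - tmin)/2 baseline
    prec_base: float = 80.0         # mm/month
    prec_var: float = 0.7           # log-scale sd of the moisture field
    land_fraction: float = 0.7
    scenarios: list[ScenarioConfig] = dc_field(default_factory=lambda: [
        ScenarioConfig("current"),
        ScenarioConfig("ssp126", delta_t=1.0, precip_scale=1.02,
                       landuse_shift=0.03),
        ScenarioConfig("ssp585", delta_t=4.0, precip_scale=1.08,
                       landuse_shift=0.10),
    ])

    def __post_init__(self) -> None:
        ids = [s.id for s in self.scenarios]
        if len(set(ids)) != len(ids):
            raise ValueError("scenario ids must be unique")
        if "current" not in ids:
            raise ValueError('scenario set must include "current"')
        if self.roughness < 1:
            raise ValueError("correlation length must be >= 1 cell")
        for s in self.scenarios:
            if s.precip_scale <= 0:
                raise ValueError("precip_scale must be positive")


@dataclass
class WorldScenario:
    climate: MonthlyClimate
    landuse: dict[str, RasterGrid]
    dem: RasterGrid


def _smooth_field(shape, rng: np.random.Generator, sigma: float) -> np.ndarray:
    """Unit-variance, zero-mean smoothed white noise (the autocorrelated
    anomaly building block)."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma,
                                mode="wrap")
    return (f - f.mean()) / f.std()


def _raster(grid: GridSpec, values: np.ndarray, mask: np.ndarray,
            name: str) -> RasterGrid:
    return RasterGrid(grid=grid, values=np.where(mask, np.nan, values),
                      nodata_mask=mask.copy(), name=name)


def gen_world(cfg: WorldConfig) -> dict[str, WorldScenario]:
    """Generate all scenario layer sets; fully deterministic from cfg.seed."""
    grid = cfg.grid
    shape = grid.shape
    lat = np.repeat(grid.lat_centers()[:, None], grid.n_cols, axis=1)
    latfrac = lat / 90.0

    def fld(stage: str) -> np.ndarray:
        rng = np.random.default_rng(derive_seed(cfg.seed, "world", stage))
        return _smooth_field(shape, rng, cfg.roughness)

    # ocean mask: smooth field threshold at the requested land fraction
    land_field = fld("landmask")
    mask = land_field < np.quantile(land_field, 1.0 - cfg.land_fraction)

    annual = cfg.t_equator - cfg.gradient * np.abs(lat) + cfg.anomaly_sd * fld("tmean")
    # seasonal amplitude: half latitude-driven, half regional, so
    # temperature level and seasonality are not collinear by construction
    amp_unit = 1.0 / (1.0 + np.exp(-fld("amp")))
    amp = cfg.amplitude * np.abs(latfrac) * (0.5 + 0.5 * amp_unit)
    half_range = np.maximum(0.5, cfg.half_range_base * (1.0 + 0.4 * fld("diurnal")))
    moisture = np.exp(cfg.prec_var * fld("moisture"))
    prec_season_amp = np.clip(0.5 * np.abs(latfrac) + 0.2, 0.0, 0.9)

    dem_vals = np.maximum(0.0, 500.0 + 700.0 * fld("dem") + 250.0 * fld("dem2"))
    dem = _raster(grid, dem_vals, mask, "dem")

    lu_fields = np.stack([1.5 * fld(f"landuse_{n}") for n in LANDUSE_NAMES])
    lu_fields -= lu_fields.max(axis=0, keepdims=True)
    lu = np.exp(lu_fields)
    lu /= lu.sum(axis=0, keepdims=True)  # softmax: fractions sum to 1

    worlds: dict[str, WorldScenario] = {}
    months = np.arange(1, 13)
    season = np.cos(2.0 * np.pi * (months - 7) / 12.0)  # +1 in July
    for scen in cfg.scenarios:
        tmin, tmax, prec = [], [], []
        for m, s in zip(months, season):
            tmean_m = annual + amp * np.sign(latfrac + 1e-12) * s + scen.delta_t
            prec_m = (cfg.prec_base * moisture
                      * (1.0 + prec_season_amp * np.sign(latfrac + 1e-12) * s)
                      * scen.precip_scale)
            tmin.append(_raster(grid, tmean_m - half_range, mask, f"tmin{m:02d}"))
            tmax.append(_raster(grid, tmean_m + half_range, mask, f"tmax{m:02d}"))
            prec.append(_raster(grid, np.maximum(prec_m, 0.0), mask, f"prec{m:02d}"))
        climate = MonthlyClimate(tmin=tmin, tmax=tmax, prec=prec,
                                 scenario_id=scen.id)
        urban = lu[0] + scen.landuse_shift * (1.0 - lu[0])
        others = lu[1:] * (1.0 - scen.landuse_shift)
        lu_scen = np.concatenate([urban[None], others])
        landuse = {n: _raster(grid, lu_scen[i], mask, n)
                   for i, n in enumerate(LANDUSE_NAMES)}
        worlds[scen.id] = WorldScenario(climate=climate, landuse=landuse, dem=dem)
    return worlds


def build_stack(ws: WorldScenario, scenario_id: str,
                predictor_subset: list[str] | None = None) -> PredictorStack:
    """Bioclim + terrain + land-use stack for one generated scenario."""
    bio = compute_bioclim(ws.climate)
    terrain = compute_terrain(ws.dem)
    stack = assemble_stack(bio, ws.landuse, terrain, scenario_id=scenario_id)
    if predictor_subset is not None:
        stack = stack.subset(predictor_subset)
    return stack


# ---------------------------------------------------------------------------
# Virtual species
# ---------------------------------------------------------------------------

@dataclass
class UncertaintyModel:
    """How coordinate-uncertainty metadata is attached to sampled records.

    ``frac_high`` of records get uncertainty in ``high_km`` (these must be
    removed by the <5 km filter), ``frac_missing`` get no metadata (also
    dropped by the filter), the rest get uncertainty in ``low_km``.
    """

    frac_high: float = 0.2
    frac_missing: float = 0.05
    high_km: tuple[float, float] = (5.0, 50.0)
    low_km: tuple[float, float] = (0.0, 4.9)


@dataclass
class VirtualSpecies:
    species: str
    responses: dict[str, tuple[float, float]]  # predictor -> (mu, sigma)
    prevalence_target: float = 0.1
    n_occurrences: int = 800
    uncertainty_model: UncertaintyModel = dc_field(default_factory=UncertaintyModel)

    def __post_init__(self) -> None:
        if not self.responses:
            raise ValueError("a virtual species needs at least one response")
        for name, (_, sigma) in self.responses.items():
            if sigma <= 0:
                raise ValueError(f"sigma must be positive ({name})")


#: raw-suitability cut defining the species' true range: the 1-sigma
#: iso-surface of the product kernel, exp(-1) for a two-predictor species.
TRUE_RANGE_CUT = np.exp(-1.0)


def raw_suitability(vs: VirtualSpecies, stack: PredictorStack) -> RasterGrid:
    """Product of per-predictor Gaussian kernels, unrescaled (max <= 1)."""
    missing = set(vs.responses) - set(stack.names)
    if missing:
        raise ValueError(f"response predictors absent from stack: {sorted(missing)}")
    logp = np.zeros(stack.grid.shape)
    for name, (mu, sigma) in vs.responses.items():
        x = stack.layers[name].values
        logp = logp - (x - mu) ** 2 / (2.0 * sigma ** 2)
    mask = stack.combined_mask()
    vals = np.where(mask, np.nan, np.exp(np.where(mask, 0.0, logp)))
    return RasterGrid(grid=stack.grid, values=vals, nodata_mask=mask.copy(),
                      name=f"truth_raw_{vs.species}")


def true_suitability(vs: VirtualSpecies, stack: PredictorStack) -> RasterGrid:
    """Raw kernel product rescaled to max 1 on unmasked land — the
    generator's record of truth for suitability-recovery tests."""
    raw = raw_suitability(vs, stack)
    top = raw.unmasked_values().max()
    if top <= 0:
        raise ValueError("true suitability is zero everywhere on land")
    out = raw.copy(values=raw.values / top, name=f"truth_{vs.species}")
    return out


def true_range_area_km2(vs: VirtualSpecies, stack: PredictorStack,
                        cut: float = TRUE_RANGE_CUT) -> float:
    """Area of the species' true range (raw suitability above the cut)."""
    raw = raw_suitability(vs, stack)
    sel = ~raw.nodata_mask & (raw.values > cut)
    return float(cell_areas(stack.grid)[sel].sum())


def sample_occurrences(vs: VirtualSpecies, truth: RasterGrid,
                       seed: int = 0) -> OccurrenceSet:
    """Draw occurrence records with probability proportional to truth.

    Cells are drawn with replacement (revisited sites are what the spatial
    rarefaction step exists to thin), points are jittered uniformly within
    their cell, and coordinate-uncertainty metadata follows the species'
    uncertainty model.  Deterministic given (vs, truth, seed).
    """
    rng = np.random.default_rng(derive_seed(seed, "occ", vs.species))
    grid = truth.grid
    p = np.where(truth.nodata_mask, 0.0, np.maximum(truth.values, 0.0)).ravel()
    if p.sum() <= 0:
        raise ValueError("truth raster has no positive suitability")
    p = p / p.sum()
    cells = rng.choice(len(p), size=vs.n_occurrences, p=p, replace=True)
    rows, cols = np.unravel_index(cells, grid.shape)
    lon = grid.lon_origin + (cols + rng.random(len(cols))) * grid.cell_size
    lat = grid.lat_origin - (rows + rng.random(len(rows))) * grid.cell_size
    lon = np.clip(lon, -180.0, 180.0 - 1e-9)
    lat = np.clip(lat, -90.0, 90.0)

    um = vs.uncertainty_model
    u = rng.random(vs.n_occurrences)
    records = []
    for i in range(vs.n_occurrences):
        if u[i] < um.frac_missing:
            unc = None
        elif u[i] < um.frac_missing + um.frac_high:
            unc = float(rng.uniform(*um.high_km))
        else:
            unc = float(rng.uniform(*um.low_km))
        records.append(OccurrenceRecord(species=vs.species, lon=float(lon[i]),
                                        lat=float(lat[i]), uncertainty_km=unc))
    return OccurrenceSet(species=vs.species, records=records,
                         provenance=[f"simulated: {len(records)} records"])


# ---------------------------------------------------------------------------
# Expanding-species suite
# ---------------------------------------------------------------------------

@dataclass
class ExpandingSuite:
    """Virtual species constructed so their true suitable area strictly
    expands under the warming scenario, with the generator's truth record."""

    species: list[VirtualSpecies]
    truth: pd.DataFrame  # species, true_current_km2, true_future_km2, true_rri
    warming_scenario: str


def make_expanding_species_suite(n_species: int, cfg: WorldConfig,
                                 seed: int = 0,
                                 worlds: dict[str, WorldScenario] | None = None
                                 ) -> ExpandingSuite:
    """Build species whose thermal optima sit just beyond the warm edge of
    the current climate, so warming strictly enlarges their true range.

    Each species responds to exactly two predictors: annual mean
    temperature (bio1, the strong niche axis) and annual precipitation
    (bio12, a broad secondary axis).  Expansion is verified against the
    generated fields; optima are nudged warmer (bounded retries) if a
    species' true future area does not strictly exceed its current one.
    """
    warming = [s for s in cfg.scenarios if s.delta_t > 0]
    if not warming:
        raise ValueError("cfg needs at least one warming scenario")
    warm_id = max(warming, key=lambda s: s.delta_t).id
    if worlds is None:
        worlds = gen_world(cfg)
    cur = build_stack(worlds["current"], "current", SUITE_PREDICTORS)
    fut = build_stack(worlds[warm_id], warm_id, SUITE_PREDICTORS)

    bio1 = cur.layers["bio1"].unmasked_values()
    bio12 = cur.layers["bio12"].unmasked_values()
    t_edge = float(np.quantile(bio1, 0.995))
    # precipitation optimum taken over the warmest decile so the two niche
    # axes intersect; breadth narrow enough that the axis genuinely shapes
    # the species' distribution
    warm = bio1 >= np.quantile(bio1, 0.9)
    p_med = float(np.quantile(bio12[warm], 0.5))
    p_sd = float(np.std(bio12))

    rng = np.random.default_rng(derive_seed(seed, "suite"))
    species: list[VirtualSpecies] = []
    rows = []
    for i in range(n_species):
        # broad thermal niche clipped at the warm edge: temperature alone
        # does not separate suitable from unsuitable within the warm band,
        # so the narrow precipitation axis must carry real weight too
        margin = 0.3 + 0.4 * float(rng.random())
        sigma_t = 2.5 + 1.0 * float(rng.random())
        mu_p = p_med * (0.9 + 0.2 * float(rng.random()))
        sigma_p = (0.2 + 0.1 * float(rng.random())) * p_sd
        vs = None
        for _attempt in range(8):
            cand = VirtualSpecies(
                species=f"vs{i + 1:02d}",
                responses={"bio1": (t_edge + margin, sigma_t),
                           "bio12": (mu_p, sigma_p)},
            )
            a_cur = true_range_area_km2(cand, cur)
            a_fut = true_range_area_km2(cand, fut)
            if a_cur > 0 and a_fut > a_cur:
                vs = cand
                break
            margin += 0.5 if a_fut <= a_cur else -0.5
        if vs is None:
            raise ValueError(
                f"could not construct an expanding species #{i + 1} on this world"
            )
        species.append(vs)
        rows.append({"species": vs.species, "true_current_km2": a_cur,
                     "true_future_km2": a_fut, "true_rri": a_fut / a_cur})
    return ExpandingSuite(species=species, truth=pd.DataFrame(rows),
                          warming_scenario=warm_id)
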