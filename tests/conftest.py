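import numpy as np
import pytest

from rangeshift.geo_raster import GridSpec, RasterGrid
from rangeshift.predictors import MonthlyClimate


def make_raster(values, lon_origin=0.0, lat_origin=10.0, cell_size=1.0,
                mask=None, name="r") -> RasterGrid:
    values = np.asarray(values, dtype=float)
    spec = GridSpec(n_rows=values.shape[0], n_cols=values.shape[1],
                    lon_origin=lon_origin, lat_origin=lat_origin,
                    cell_size=cell_size)
    return RasterGrid(grid=spec, values=values, nodata_mask=mask, name=name)


def constant_climate(grid: GridSpec, tmin=5.0, tmax=15.0, prec=100.0):
    def mk(v, n):
        return RasterGrid(grid=grid, values=np.full(grid.shape, float(v)), name=n)
    return MonthlyClimate(
        tmin=[mk(tmin, f"tmin{m:02d}") for m in range(1, 13)],
        tmax=[mk(tmax, f"tmax{m:02d}") for m in range(1, 13)],
        prec=[mk(prec, f"prec{m:02d}") for m in range(1, 13)],
    )


def random_climate(grid: GridSpec, rng: np.random.Generator):
    """Unstructured random monthly climate with tmax >= tmin and prec >= 0."""
    def mk(vals, n):
        return RasterGrid(grid=grid, values=vals, name=n)
    tmin, tmax, prec = [], [], []
    for m in range(12):
        lo = rng.uniform(-20, 25, grid.shape)
        hi = lo + rng.uniform(0, 15, grid.shape)
        tmin.append(mk(lo, f"tmin{m + 1:02d}"))
        tmax.append(mk(hi, f"tmax{m + 1:02d}"))
        prec.append(mk(rng.uniform(0, 300, grid.shape), f"prec{m + 1:02d}"))
    return MonthlyClimate(tmin=tmin, tmax=tmax, prec=prec)


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture(scope="session")
def small_world():
    """A small (60x120) synthetic world with two virtual species, shared by
    the slower pipeline-level tests."""
    from rangeshift.synthetic_world import (SUITE_PREDICTORS, WorldConfig,
                                            build_stack, gen_world,
                                            make_expanding_species_suite,
                                            sample_occurrences,
                                            true_suitability)
    from rangeshift.geo_raster import GridSpec

    cfg = WorldConfig(
        grid=GridSpec(n_rows=60, n_cols=120, lon_origin=-180.0,
                      lat_origin=90.0, cell_size=3.0),
        seed=11,
    )
    worlds = gen_world(cfg)
    stacks = {sid: build_stack(ws, sid, SUITE_PREDICTORS)
              for sid, ws in worlds.items()}
    suite = make_expanding_species_suite(2, cfg, seed=11, worlds=worlds)
    occ_sets = {
        vs.species: sample_occurrences(
            vs, true_suitability(vs, stacks["current"]), seed=11)
        for vs in suite.species
    }
    return {"cfg": cfg, "worlds": worlds, "stacks": stacks, "suite": suite,
            "occ_sets": occ_sets}
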