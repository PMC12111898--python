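"""Range maps and range-dynamics indices.

The continuous habitat-suitability index (HSI) is binarized at the
threshold maximizing sensitivity + specificity on the species' presence
and pseudo-absence scores; cells with HSI strictly above the threshold
form the potential range.  From current/future range pairs the module
computes, with latitude-corrected areas:

* RRI (range ratio index)      = future area / current area; >1 = expansion
* RSI (range similarity index) = 2·shared area / (current + future area),
  a Sørensen-type positional similarity: 1 for identical ranges, 0 for
  disjoint ones, >0.5 read as "similar range positions"

and the cross-species overlap products: OIHS (cell-wise sum of the
per-species HSI maps), the pixel overlap count (how many species' ranges
cover a cell), their future−current deltas, and the area/fraction-of-land
accounting of cells where the overlap increases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo_raster import RasterGrid, RasterError, masked_area_sum
from .sdm_core import best_sss_threshold


def max_sss_threshold(hsi_at_presences, hsi_at_absences) -> float:
    """The max sensitivity+specificity threshold (exhaustive midpoint scan,
    smallest optimum on ties)."""
    return best_sss_threshold(hsi_at_presences, hsi_at_absences)


@dataclass
class RangeMap:
    """Binary potential-range raster for one species × scenario."""

    species: str
    scenario_id: str
    cells: RasterGrid
    threshold_used: float

    def area_km2(self) -> float:
        return masked_area_sum(self.cells, lambda v: v > 0.5)


def binarize(hsi: RasterGrid, threshold: float, species: str = "",
             scenario_id: str = "") -> RangeMap:
    """Cell = 1 iff HSI strictly above the threshold; masks propagate."""
    if not (0.0 <= threshold <= 1.0):
        raise RasterError(f"threshold {threshold} outside [0, 1]")
    vals = np.where(hsi.nodata_mask, np.nan,
                    (hsi.values > threshold).astype(float))
    cells = RasterGrid(grid=hsi.grid, values=vals,
                       nodata_mask=hsi.nodata_mask.copy(),
                       name=f"range_{species}_{scenario_id}")
    return RangeMap(species=species, scenario_id=scenario_id,
                    cells=cells, threshold_used=float(threshold))


def rri(rcs_km2: float, rfs_km2: float) -> float:
    """Range ratio index: future range area over current range area."""
    if rcs_km2 <= 0:
        raise ValueError("RRI undefined: current range area is zero")
    return rfs_km2 / rcs_km2


def rsi(rcs_km2: float, rfs_km2: float, sr_km2: float) -> float:
    """Range similarity index: 2·SR/(RCS+RFS) ∈ [0, 1]."""
    if rcs_km2 + rfs_km2 <= 0:
        raise ValueError("RSI undefined: both ranges empty")
    if sr_km2 > min(rcs_km2, rfs_km2) + 1e-6 * max(rcs_km2, rfs_km2, 1.0):
        raise ValueError("shared area exceeds one of the ranges")
    return 2.0 * sr_km2 / (rcs_km2 + rfs_km2)


@dataclass
class RangeDynamics:
    species: str
    scenario_id: str           # the future scenario of the current→future pair
    rcs_km2: float
    rfs_km2: float
    sr_km2: float
    rri: float
    rsi: float
    threshold_current: float
    threshold_future: float


def range_dynamics(current: RangeMap, future: RangeMap) -> RangeDynamics:
    """Areas and indices for one current→future range pair."""
    if current.cells.grid != future.cells.grid:
        raise RasterError("range maps on different grids")
    rcs = current.area_km2()
    rfs = future.area_km2()
    inter = current.cells * future.cells  # mask-union propagating AND
    sr = masked_area_sum(inter, lambda v: v > 0.5)
    return RangeDynamics(
        species=current.species, scenario_id=future.scenario_id,
        rcs_km2=rcs, rfs_km2=rfs, sr_km2=sr,
        rri=rri(rcs, rfs), rsi=rsi(rcs, rfs, sr),
        threshold_current=current.threshold_used,
        threshold_future=future.threshold_used,
    )


def hsi_delta(future_hsi: RasterGrid, current_hsi: RasterGrid) -> RasterGrid:
    """Future − current HSI, in [−1, 1], mask union propagated."""
    if future_hsi.grid != current_hsi.grid:
        raise RasterError("HSI maps on different grids")
    out = future_hsi - current_hsi
    out.name = "hsi_delta"
    return out


def oihs(hsi_maps: list[RasterGrid]) -> RasterGrid:
    """Overlap index of habitat suitability: cell-wise sum of per-species
    HSI maps, in [0, n_species]."""
    if not hsi_maps:
        raise ValueError("oihs requires at least one HSI map")
    total = hsi_maps[0].copy(name="oihs")
    for m in hsi_maps[1:]:
        total = total + m
    total.name = "oihs"
    return total


def oihs_mean(hsi_maps: list[RasterGrid]) -> RasterGrid:
    """Mean-aggregation variant of the overlap index (non-default)."""
    total = oihs(hsi_maps)
    total.values = total.values / len(hsi_maps)
    total.name = "oihs_mean"
    return total


def overlap_count(ranges: list[RangeMap]) -> RasterGrid:
    """Cell-wise count of species whose potential range covers the cell."""
    if not ranges:
        raise ValueError("overlap_count requires at least one range map")
    total = ranges[0].cells.copy(name="overlap_count")
    for r in ranges[1:]:
        total = total + r.cells
    total.name = "overlap_count"
    return total


def delta_and_area_summary(future: RasterGrid, current: RasterGrid) -> dict:
    """Future−current delta plus the paper-style increase accounting:
    the area (km²) of cells where the delta is positive and that area as a
    percentage of the total unmasked land."""
    delta = future - current
    delta.name = "delta"
    area_increase = masked_area_sum(delta, lambda v: v > 0)
    land = masked_area_sum(delta)
    fraction = 100.0 * area_increase / land if land > 0 else 0.0
    return {"delta": delta, "area_increase_km2": area_increase,
            "fraction_of_land": fraction}


def dynamics_table(rows: list[RangeDynamics]) -> pd.DataFrame:
    return pd.DataFrame([
        {"species": d.species, "scenario": d.scenario_id,
         "rcs_km2": d.rcs_km2, "rfs_km2": d.rfs_km2, "sr_km2": d.sr_km2,
         "rri": d.rri, "rsi": d.rsi,
         "threshold_current": d.threshold_current,
         "threshold_future": d.threshold_future}
        for d in rows
    ])
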