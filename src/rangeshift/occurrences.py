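"""Occurrence ingestion, uncertainty filtering, spatial rarefaction, gating.

The cleaning protocol: keep records with coordinate uncertainty strictly
below 5 km (records with no uncertainty metadata are dropped — the
conservative reading), thin to one record per 10×10 km grid cell, and
retain only species with at least 100 rarefied records.  Every step appends
a before/after line to the set's provenance trail.

The rarefaction lattice is a latitude-corrected degree lattice: latitude
rows of height cell_km/111.32°, longitude columns widened by 1/cos(lat) so
cells stay approximately cell_km wide on the ground (error <1% below 60°
latitude, adequate for sampling-bias thinning).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

KM_PER_DEGREE = 111.32


@dataclass(frozen=True)
class OccurrenceRecord:
    species: str
    lon: float
    lat: float
    uncertainty_km: float | None = None

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon < 180.0):
            raise ValueError(f"lon {self.lon} outside [-180, 180)")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"lat {self.lat} outside [-90, 90]")
        if self.uncertainty_km is not None and self.uncertainty_km < 0:
            raise ValueError("uncertainty_km must be non-negative")


@dataclass
class OccurrenceSet:
    species: str
    records: list[OccurrenceRecord] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.species != self.species:
                raise ValueError(
                    f"record species {rec.species!r} != set species {self.species!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def lonlat(self) -> np.ndarray:
        """(n, 2) array of lon, lat."""
        return np.array([[r.lon, r.lat] for r in self.records]).reshape(-1, 2)

    def with_records(self, records: list[OccurrenceRecord],
                     note: str) -> "OccurrenceSet":
        return OccurrenceSet(
            species=self.species,
            records=records,
            provenance=self.provenance + [f"{note}: {len(self)} -> {len(records)}"],
        )


def read_occurrences(path) -> dict[str, OccurrenceSet]:
    """Parse an occurrence CSV (species, lon, lat, uncertainty_km).

    Malformed rows (bad coordinates, unparseable numbers) are logged with
    their line number and skipped; a missing uncertainty is kept as None.
    """
    df = pd.read_csv(path)
    required = {"species", "lon", "lat"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"occurrence CSV must have columns {sorted(required)}; "
            f"found {list(df.columns)}"
        )
    has_unc = "uncertainty_km" in df.columns
    sets: dict[str, OccurrenceSet] = {}
    n_bad = 0
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after header
        try:
            unc = getattr(row, "uncertainty_km", None) if has_unc else None
            if unc is not None and (isinstance(unc, float) and math.isnan(unc)):
                unc = None
            rec = OccurrenceRecord(
                species=str(row.species),
                lon=float(row.lon),
                lat=float(row.lat),
                uncertainty_km=None if unc is None else float(unc),
            )
        except (ValueError, TypeError) as exc:
            log.warning("skipping line %d: %s", line, exc)
            n_bad += 1
            continue
        sets.setdefault(rec.species, OccurrenceSet(species=rec.species)) \
            .records.append(rec)
    for s in sets.values():
        s.provenance.append(f"read: {len(s)} records ({n_bad} rejected rows in file)")
    return sets


def filter_uncertainty(s: OccurrenceSet, max_km: float = 5.0) -> OccurrenceSet:
    """Keep records with uncertainty strictly below ``max_km``.

    Records with missing uncertainty are dropped.
    """
    kept = [r for r in s.records
            if r.uncertainty_km is not None and r.uncertainty_km < max_km]
    return s.with_records(kept, f"filter_uncertainty(<{max_km} km)")


def _rarefaction_cell(lon: np.ndarray, lat: np.ndarray,
                      cell_km: float) -> list[tuple[int, int]]:
    """Assign points to (lat_band, lon_cell) on the thinning lattice."""
    dlat = cell_km / KM_PER_DEGREE
    band = np.floor((lat + 90.0) / dlat).astype(int)
    band_center = -90.0 + (band + 0.5) * dlat
    coslat = np.maximum(np.cos(np.radians(np.clip(band_center, -89.9, 89.9))),
                        1e-3)
    dlon = dlat / coslat
    col = np.floor((lon + 180.0) / dlon).astype(int)
    return list(zip(band.tolist(), col.tolist()))


def rarefy(s: OccurrenceSet, cell_km: float = 10.0,
           seed: int = 0) -> OccurrenceSet:
    """Spatial rarefaction: keep exactly one record per occupied lattice cell.

    The kept record is chosen uniformly at random within each cell with the
    given seed; the result is deterministic given (records, seed) and
    idempotent for a fixed lattice.
    """
    if cell_km <= 0:
        raise ValueError("cell_km must be positive")
    if not s.records:
        return s.with_records([], f"rarefy({cell_km} km)")
    pts = s.lonlat()
    keys = _rarefaction_cell(pts[:, 0], pts[:, 1], cell_km)
    by_cell: dict[tuple[int, int], list[int]] = {}
    for i, key in enumerate(keys):
        by_cell.setdefault(key, []).append(i)
    rng = np.random.default_rng(seed)
    kept_idx = [members[rng.integers(len(members))]
                for _, members in sorted(by_cell.items())]
    kept = [s.records[i] for i in sorted(kept_idx)]
    return s.with_records(kept, f"rarefy({cell_km} km)")


def gate_species(sets: dict[str, OccurrenceSet],
                 min_records: int = 100) -> dict[str, OccurrenceSet]:
    """Retain species with at least ``min_records`` (rarefied) records."""
    out: dict[str, OccurrenceSet] = {}
    for name, s in sets.items():
        if len(s) >= min_records:
            s.provenance.append(f"gate(>= {min_records}): retained with {len(s)}")
            out[name] = s
        else:
            log.info("species %s excluded: %d < %d records",
                     name, len(s), min_records)
    return out


def to_dataframe(sets: dict[str, OccurrenceSet]) -> pd.DataFrame:
    rows = [
        {"species": r.species, "lon": r.lon, "lat": r.lat,
         "uncertainty_km": r.uncertainty_km}
        for s in sets.values() for r in s.records
    ]
    return pd.DataFrame(rows, columns=["species", "lon", "lat", "uncertainty_km"])
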