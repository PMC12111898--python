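"""End-to-end orchestration: per-species SDMs, projections, range indices.

The per-species chain mirrors the modelling protocol: uncertainty filter →
spatial rarefaction → minimum-record gate → initial model on the full
stack for permutation importance → collinearity pruning → three
pseudo-absence rounds × five 70/30 cross-repetitions × the learner
families → gated TSS-weighted ensemble → per-scenario HSI projection →
max-SSS threshold → binary range.  Cross-species products (OIHS, overlap
counts, deltas, area summaries) follow once every species is fitted.

Species are fitted independently; a failure in one is recorded and does
not abort the others.  All artifacts can be persisted to a directory tree
(GeoTIFF rasters, tidy CSVs, JSON summaries) with a hash-complete run
manifest so that a rerun with the same config and seed is verifiably
identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geo_raster import RasterGrid, read_raster, write_raster
from .occurrences import (OccurrenceSet, filter_uncertainty, gate_species,
                          rarefy, read_occurrences, to_dataframe)
from .predictors import PredictorStack
from .range_dynamics import (RangeDynamics, RangeMap, binarize,
                             delta_and_area_summary, dynamics_table,
                             hsi_delta, max_sss_threshold, oihs,
                             overlap_count, range_dynamics)
from .sdm_core import (DEFAULT_ALGORITHMS, EnsembleResult, SdmError,
                       aggregate_importance, build_ensemble, fit_members,
                       generate_pseudo_absences, members_table,
                       prune_collinear)
from .seeding import derive_seed
from .synthetic_world import WorldScenario, build_stack, gen_world

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; defaults are the protocol's values."""

    max_uncertainty_km: float = 5.0
    rarefy_cell_km: float = 10.0
    min_records: int = 100
    algorithms: list[str] = field(default_factory=lambda: list(DEFAULT_ALGORITHMS))
    n_rounds: int = 3
    n_cv: int = 5
    initial_n_cv: int = 2     # cross-repetitions of the screening model
    train_frac: float = 0.7
    gate_tss: float = 0.6
    gate_auc: float = 0.8
    r_threshold: float = 0.7
    n_shuffles: int = 1
    per_scenario_thresholds: bool = True
    predictor_subset: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_frac < 1):
            raise ValueError("train_frac must be in (0, 1)")
        for name in ("gate_tss", "gate_auc", "r_threshold"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} out of range")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SpeciesResult:
    species: str
    occurrences: OccurrenceSet
    members: pd.DataFrame
    importance: pd.DataFrame
    retained: list[str]
    ensembles: dict[str, EnsembleResult]
    thresholds: dict[str, float]
    ranges: dict[str, RangeMap]
    dynamics: list[RangeDynamics]

    @property
    def mean_auc(self) -> float:
        return float(self.members["auc"].mean())

    @property
    def mean_tss(self) -> float:
        return float(self.members["tss"].mean())


@dataclass
class PipelineResult:
    config: PipelineConfig
    species: dict[str, SpeciesResult]
    failed: dict[str, str]
    oihs_maps: dict[str, RasterGrid]
    overlap_maps: dict[str, RasterGrid]
    summaries: dict[str, dict]        # per future scenario: OIHS-increase accounting
    dynamics: pd.DataFrame

    @property
    def scenario_ids(self) -> list[str]:
        return list(self.oihs_maps)


def clean_occurrences(sets: dict[str, OccurrenceSet],
                      cfg: PipelineConfig) -> dict[str, OccurrenceSet]:
    """Uncertainty filter → rarefaction → minimum-record gate."""
    cleaned = {}
    for name, s in sets.items():
        s = filter_uncertainty(s, cfg.max_uncertainty_km)
        s = rarefy(s, cfg.rarefy_cell_km,
                   seed=derive_seed(cfg.seed, "rarefy", name))
        cleaned[name] = s
    return gate_species(cleaned, cfg.min_records)


def fit_species(occ: OccurrenceSet, stacks: dict[str, PredictorStack],
                cfg: PipelineConfig) -> SpeciesResult:
    """Fit one species' ensemble and project it onto every scenario.

    ``occ`` must already be cleaned (filtered, rarefied, gated);
    ``stacks`` must contain the key "current".
    """
    current = stacks["current"]
    seed = derive_seed(cfg.seed, "species", occ.species)

    # screening model on the full stack -> importance -> pruning
    tt_full = generate_pseudo_absences(occ, current, cfg.n_rounds,
                                       seed=derive_seed(seed, "pa_init"))
    initial = fit_members(tt_full, cfg.algorithms, n_cv=cfg.initial_n_cv,
                          train_frac=cfg.train_frac,
                          seed=derive_seed(seed, "fit_init"))
    importance = aggregate_importance(initial, tt_full,
                                      n_shuffles=cfg.n_shuffles,
                                      seed=derive_seed(seed, "importance"))
    retained = prune_collinear(tt_full, importance, cfg.r_threshold)
    log.info("%s: retained %d/%d predictors", occ.species, len(retained),
             len(tt_full.feature_names))

    # baseline ensemble on the pruned predictor set
    tt = tt_full.subset_features(retained)
    members = fit_members(tt, cfg.algorithms, n_cv=cfg.n_cv,
                          train_frac=cfg.train_frac,
                          seed=derive_seed(seed, "fit"))

    ensembles: dict[str, EnsembleResult] = {}
    thresholds: dict[str, float] = {}
    ranges: dict[str, RangeMap] = {}
    pres = tt.response == 1
    for sid, stack in stacks.items():
        ens = build_ensemble(members, stack, species=occ.species,
                             gate_tss=cfg.gate_tss, gate_auc=cfg.gate_auc,
                             feature_names=retained)
        ensembles[sid] = ens
        scores = ens.hsi.values.ravel()[tt.cell_index]
        if sid == "current" or cfg.per_scenario_thresholds:
            thr = max_sss_threshold(scores[pres], scores[~pres])
        else:
            thr = thresholds["current"]
        thresholds[sid] = thr
        ranges[sid] = binarize(ens.hsi, thr, species=occ.species,
                               scenario_id=sid)
    if not cfg.per_scenario_thresholds:
        # "current" may not be the first key; recompute dependent ranges
        for sid in stacks:
            if sid != "current":
                thresholds[sid] = thresholds["current"]
                ranges[sid] = binarize(ensembles[sid].hsi, thresholds[sid],
                                       species=occ.species, scenario_id=sid)

    dyn = [range_dynamics(ranges["current"], ranges[sid])
           for sid in stacks if sid != "current"]
    return SpeciesResult(
        species=occ.species, occurrences=occ,
        members=members_table(members), importance=importance,
        retained=retained, ensembles=ensembles, thresholds=thresholds,
        ranges=ranges, dynamics=dyn,
    )


def run_pipeline_on_stacks(occ_sets: dict[str, OccurrenceSet],
                           stacks: dict[str, PredictorStack],
                           cfg: PipelineConfig,
                           clean: bool = True) -> PipelineResult:
    """The full analysis on in-memory inputs.

    Per species: the fit/project chain of :func:`fit_species`; then the
    cross-species OIHS, overlap-count and delta/area products.
    """
    if "current" not in stacks:
        raise ValueError('stacks must include the "current" scenario')
    if clean:
        occ_sets = clean_occurrences(occ_sets, cfg)
    results: dict[str, SpeciesResult] = {}
    failed: dict[str, str] = {}
    for name, occ in occ_sets.items():
        try:
            results[name] = fit_species(occ, stacks, cfg)
        except SdmError as exc:
            log.error("species %s failed: %s", name, exc)
            failed[name] = str(exc)
    if not results:
        raise SdmError("every species failed; nothing to aggregate")

    oihs_maps = {sid: oihs([r.ensembles[sid].hsi for r in results.values()])
                 for sid in stacks}
    overlap_maps = {sid: overlap_count([r.ranges[sid] for r in results.values()])
                    for sid in stacks}
    summaries = {}
    for sid in stacks:
        if sid == "current":
            continue
        s = delta_and_area_summary(oihs_maps[sid], oihs_maps["current"])
        ov = delta_and_area_summary(overlap_maps[sid], overlap_maps["current"])
        summaries[sid] = {
            "oihs_area_increase_km2": s["area_increase_km2"],
            "oihs_fraction_of_land": s["fraction_of_land"],
            "overlap_area_increase_km2": ov["area_increase_km2"],
            "overlap_fraction_of_land": ov["fraction_of_land"],
        }
    dyn = dynamics_table([d for r in results.values() for d in r.dynamics])
    return PipelineResult(config=cfg, species=results, failed=failed,
                          oihs_maps=oihs_maps, overlap_maps=overlap_maps,
                          summaries=summaries, dynamics=dyn)


# ---------------------------------------------------------------------------
# Persistence: world directories, artifacts, manifest
# ---------------------------------------------------------------------------

def write_world(worlds: dict[str, WorldScenario], outdir,
                occ_sets: dict[str, OccurrenceSet] | None = None,
                truth: pd.DataFrame | None = None) -> None:
    """Persist a generated world as the directory tree the pipeline reads:
    monthly GeoTIFFs per scenario, land-use GeoTIFFs, the DEM, the
    occurrence CSV and the truth manifest."""
    outdir = Path(outdir)
    for sid, ws in worlds.items():
        sdir = outdir / "world" / sid
        sdir.mkdir(parents=True, exist_ok=True)
        for group in (ws.climate.tmin, ws.climate.tmax, ws.climate.prec):
            for r in group:
                write_raster(r, sdir / f"{r.name}.tif")
        for name, r in ws.landuse.items():
            write_raster(r, sdir / f"landuse_{name}.tif")
    write_raster(next(iter(worlds.values())).dem, outdir / "world" / "dem.tif")
    if occ_sets is not None:
        to_dataframe(occ_sets).to_csv(outdir / "occurrences.csv", index=False)
    if truth is not None:
        (outdir / "truth.json").write_text(
            json.dumps(truth.to_dict(orient="records"), indent=2))


def read_world(indir) -> dict[str, WorldScenario]:
    """Load a world directory written by :func:`write_world`."""
    from .predictors import MonthlyClimate
    indir = Path(indir)
    dem = read_raster(indir / "world" / "dem.tif", name="dem")
    worlds = {}
    for sdir in sorted((indir / "world").iterdir()):
        if not sdir.is_dir():
            continue
        tmin = [read_raster(sdir / f"tmin{m:02d}.tif", name=f"tmin{m:02d}")
                for m in range(1, 13)]
        tmax = [read_raster(sdir / f"tmax{m:02d}.tif", name=f"tmax{m:02d}")
                for m in range(1, 13)]
        prec = [read_raster(sdir / f"prec{m:02d}.tif", name=f"prec{m:02d}")
                for m in range(1, 13)]
        landuse = {}
        for p in sorted(sdir.glob("landuse_*.tif")):
            name = p.stem.removeprefix("landuse_")
            landuse[name] = read_raster(p, name=name)
        worlds[sdir.name] = WorldScenario(
            climate=MonthlyClimate(tmin=tmin, tmax=tmax, prec=prec,
                                   scenario_id=sdir.name),
            landuse=landuse, dem=dem)
    if not worlds:
        raise FileNotFoundError(f"no scenario directories under {indir}/world")
    return worlds


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_artifacts(result: PipelineResult, outdir) -> dict:
    """Persist every pipeline product and return the hash-complete manifest."""
    outdir = Path(outdir)
    for sub in ("hsi", "ranges", "models", "dynamics"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    for name, r in result.species.items():
        mdir = outdir / "models" / name
        mdir.mkdir(exist_ok=True)
        r.members.to_csv(mdir / "members.csv", index=False)
        r.importance.to_csv(mdir / "importance.csv")
        (mdir / "retained.txt").write_text("\n".join(r.retained) + "\n")
        files += [mdir / "members.csv", mdir / "importance.csv",
                  mdir / "retained.txt"]
        for sid, ens in r.ensembles.items():
            p = outdir / "hsi" / f"{name}_{sid}.tif"
            write_raster(ens.hsi, p)
            files.append(p)
        for sid, rng_map in r.ranges.items():
            p = outdir / "ranges" / f"{name}_{sid}.tif"
            write_raster(rng_map.cells, p, dtype="uint8", nodata=255)
            files.append(p)

    ddir = outdir / "dynamics"
    result.dynamics.to_csv(ddir / "range_dynamics.csv", index=False)
    files.append(ddir / "range_dynamics.csv")
    for sid, m in result.oihs_maps.items():
        p = ddir / f"oihs_{sid}.tif"
        write_raster(m, p)
        files.append(p)
    for sid, m in result.overlap_maps.items():
        p = ddir / f"overlap_{sid}.tif"
        write_raster(m, p, dtype="uint16", nodata=65535)
        files.append(p)
    (ddir / "summary.json").write_text(json.dumps(result.summaries, indent=2))
    files.append(ddir / "summary.json")

    manifest = {
        "version": __version__,
        "config": result.config.to_dict(),
        "failed_species": result.failed,
        "n_species": len(result.species),
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def run_pipeline(world_dir, outdir, cfg: PipelineConfig) -> dict:
    """File-based end-to-end run: read a world directory (occurrences CSV +
    scenario rasters), execute the analysis, persist artifacts, return the
    run manifest."""
    world_dir = Path(world_dir)
    worlds = read_world(world_dir)
    occ_sets = read_occurrences(world_dir / "occurrences.csv")
    stacks = {sid: build_stack(ws, sid, cfg.predictor_subset)
              for sid, ws in worlds.items()}
    result = run_pipeline_on_stacks(occ_sets, stacks, cfg)
    return write_artifacts(result, outdir)


def report(outdir) -> list[str]:
    """Render quick-look maps (OIHS, overlap counts, per-species HSI) from
    a persisted run; returns the image paths written."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    rdir = outdir / "report"
    rdir.mkdir(exist_ok=True)
    written = []
    for rel in sorted(manifest["files"]):
        if not rel.endswith(".tif") or not (
                rel.startswith("dynamics/oihs") or rel.startswith("hsi/")):
            continue
        r = read_raster(outdir / rel)
        fig, ax = plt.subplots(figsize=(7, 4))
        im = ax.imshow(np.where(r.nodata_mask, np.nan, r.values),
                       extent=(r.grid.lon_origin,
                               r.grid.lon_origin + r.grid.n_cols * r.grid.cell_size,
                               r.grid.lat_origin - r.grid.n_rows * r.grid.cell_size,
                               r.grid.lat_origin),
                       cmap="viridis")
        ax.set_title(Path(rel).stem)
        fig.colorbar(im, ax=ax, shrink=0.8)
        p = rdir / (Path(rel).stem + ".png")
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(str(p))
    return written


def simulate_world(cfg, outdir, suite_size: int = 3) -> pd.DataFrame:
    """Generate a synthetic world + expanding-species suite and persist it
    as a pipeline-ready input directory.  Returns the truth table."""
    from .synthetic_world import (SUITE_PREDICTORS, make_expanding_species_suite,
                                  sample_occurrences, true_suitability)
    worlds = gen_world(cfg)
    suite = make_expanding_species_suite(suite_size, cfg, seed=cfg.seed,
                                         worlds=worlds)
    cur = build_stack(worlds["current"], "current", SUITE_PREDICTORS)
    occ_sets = {}
    for vs in suite.species:
        truth = true_suitability(vs, cur)
        occ_sets[vs.species] = sample_occurrences(vs, truth, seed=cfg.seed)
    write_world(worlds, outdir, occ_sets=occ_sets, truth=suite.truth)
    return suite.truth
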