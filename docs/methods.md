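# Methods

This note documents the modelling choices in `rangeshift`: the procedure,
its assumptions, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical conventions that
make results exactly reproducible.

## Occurrence cleaning

Records pass three ordered filters, each appending a before/after line to
the set's provenance trail:

1. **Coordinate uncertainty < 5 km**, read strictly (a record at exactly
   5 km is dropped). Records with *missing* uncertainty metadata are also
   dropped — the conservative reading; treating unknown precision as
   acceptable would silently admit coarse records.
2. **Spatial rarefaction to one record per 10×10 km cell.** The thinning
   lattice is a latitude-corrected degree lattice: latitude bands of
   height `cell_km / 111.32°`, longitude columns widened by `1 / cos(lat)`
   (cosine clamped near the poles). This avoids an equal-area projection
   dependency at the cost of < 1 % cell-size error below 60° latitude,
   which is immaterial for sampling-bias thinning. The record kept within
   a cell is chosen uniformly at random from a seeded stream, so the
   operation is deterministic given (records, seed) and idempotent.
3. **Species gate at ≥ 100 rarefied records**, inclusive at the boundary.

## Predictors

The stack per scenario is 19 bioclim + 8 land-use fractions + 3 terrain
layers, all co-registered on one lon/lat grid (resample first; bilinear
for continuous fields, nearest or mean-aggregate for categorical/fraction
layers). Conventions for the bioclim derivation, where several competing
ones circulate:

* monthly mean temperature = (tmin + tmax) / 2;
* BIO4 = 100 × *population* standard deviation of monthly means;
* BIO15 uses the ANUCLIM denominator `1 + BIO12/12` so rainless cells get
  0 rather than a division by zero;
* quarters are all 12 windows of 3 consecutive months with December →
  January wraparound; ties between equally warm/wet quarters break to the
  earliest starting month (deterministic).

Terrain slope/aspect use Horn's 3×3 finite differences with the
east–west spacing scaled by cos(latitude); aspect is the downslope
azimuth clockwise from north, with −1 as the sentinel for flat cells.
Masked (ocean) DEM neighbours enter the stencil at sea level so coastal
cells keep finite gradients. Terrain is identical across scenarios.

## The ensemble SDM

* **Pseudo-absences**: three independent rounds of uniform draws from
  unmasked non-presence cells, without replacement within a round;
  1000 per round, or one per presence once a species has ≥ 1000 presence
  cells. Presences are excluded but not buffered (plain random selection).
* **Members**: one per (learner family × round × cross-repetition), the
  default grid being {logistic regression, random forest, gradient-boosted
  trees} × 3 × 5. Each repetition takes a stratified random 70/30 split of
  its round's table; class-balancing sample weights make presences and
  pseudo-absences contribute equally. Learner families are pluggable; the
  defaults are deliberately small (80 trees / 80 boosting iterations) so a
  full multi-species experiment runs in minutes on one CPU, and member
  quality is gated downstream anyway.
* **Evaluation**: AUC in the Mann–Whitney mid-rank form (exact under
  ties), and TSS = sensitivity + specificity − 1 at the hold-out's
  max-sens+spec threshold. Sensitivity counts scores strictly above the
  threshold, specificity scores at or below it.
* **Gate and combination**: members with TSS > 0.6 *or* AUC > 0.8 enter
  the ensemble; the HSI is their TSS-weighted mean (weights ∝ max(TSS, 0),
  equal weights if all passing TSS ≤ 0). A species with no passing member
  fails loudly rather than producing an empty map.
* **Variable screening**: a cheaper initial model (2 repetitions instead
  of 5, a deliberate cost/fidelity trade-off) on the full stack yields
  permutation importances: IS = 1 − Pearson correlation between
  predictions before and after shuffling one column, averaged over seeded
  shuffles and members; an unused predictor scores 0, the upper bound
  is 2, and zero-variance prediction vectors score 0 with a logged flag.
  Collinear pairs (|r| > 0.7; Pearson when both columns pass Shapiro–Wilk
  at α = 0.05 on ≤ 5000-point subsamples, Spearman otherwise) are resolved
  greedily — worst pair first, ties by name, drop the lower-IS member —
  and the retained set is audited to contain no offending pair.

## Thresholding and indices

The max-sens+spec threshold is found by exhaustive scan over midpoints of
consecutive sorted unique scores plus the extremes {0, 1}; ties resolve to
the smallest optimal threshold. Binarization is strict (HSI > threshold).
Thresholds are recomputed per scenario against the same presence/PA cells'
projected scores by default (`per_scenario_thresholds=True`), since the
optimal cut genuinely moves with the projected score distribution; the
fixed-current-threshold mode is available and recorded in provenance.

Areas are spherical-Earth cell areas, R = 6371 km (the WGS84 ellipsoid
correction is < 0.5 % and irrelevant to ratio indices):
`A = R²·Δλ·(sin φ_n − sin φ_s)`. RRI = RFS/RCS and
RSI = 2·SR/(RCS + RFS) with SR the cell-wise intersection area. OIHS is
the cell-wise **sum** of per-species HSI — consistent with the overlap
count, where a pixel covered by eight ranges is assigned eight; a mean
variant exists but is not the default. All raster arithmetic masks the
union of operand masks, so nodata is never treated as zero, and the land
domain is simply the predictor stack's unmasked cells.

## Randomness

Every stage derives its own 31-bit seed by hashing (master seed, stage
path), so reruns are bit-identical, stages are independently
reproducible, and adding a stage never perturbs the draws of another.

## The synthetic world and virtual species

The generator emulates the statistical shape of real inputs, not their
physics: a 0.55 °C/°lat equator-to-pole gradient with smooth regional
anomalies (seeded white noise, Gaussian-smoothed at a 3-cell correlation
length), a seasonal cycle whose amplitude grows poleward with opposite
phase per hemisphere and a regional component (so temperature level and
seasonality are not collinear by construction), log-normal smooth
precipitation with latitudinal seasonality, softmax-composed land-use
fractions (compositionally valid by construction), a rough DEM, and an
ocean mask covering 30 % of the grid. Scenarios are a uniform temperature
offset (+1 °C "optimistic", +4 °C "pessimistic" by default), a
precipitation scale factor, and a land-use shift toward the urban class.
The default grid is 120×240 cells (1.5°), sized so a five-species,
ten-seed experiment completes in minutes.

Virtual species are products of Gaussian response kernels over named
predictors; the true range is the kernel product above exp(−1) (the
1-sigma iso-surface for a two-axis species). The expanding-species suite
places each species' thermal optimum just beyond the warm edge of the
current climate with a broad thermal breadth and a narrow precipitation
niche, so that (a) warming strictly enlarges the true range — verified
against the generated fields, with bounded warm-ward retries — and
(b) both axes genuinely shape the distribution, making
importance-recovery a meaningful test rather than a one-variable
giveaway. Occurrences are drawn proportional to (rescaled) truth with
within-cell jitter and configurable uncertainty metadata (20 % coarse,
5 % missing by default) so the cleaning stages have real work to do.

What passing on this world does **not** show: robustness to dispersal
limits, biotic interactions, spatially biased sampling effort, label
noise in occurrence identifications, or non-Gaussian/multimodal niches.
Estimated RRIs are systematically closer to 1 than the true ones because
tree ensembles extrapolate conservatively beyond the training envelope —
the direction of change is recovered, its magnitude is compressed.

## Degenerate inputs and edge cases

* All-identical scores: the threshold scan returns a cut below the common
  score (sensitivity 1, specificity 0) — defined, flagged by its TSS of 0.
* RRI with an empty current range is an explicit error, as is an RSI
  whose shared area exceeds either range.
* Constant predictor columns are dropped before correlation pruning
  (undefined r), with a warning.
* Cells at the exact pole get ~0 area; grids may not extend past ±90°.

## Known limitations

GeoTIFF support is single-band, geographic-CRS (EPSG:4326) only — no
projected rasters, multi-band files, or antimeridian-spanning grids.
Rarefaction uses the degree lattice described above, not an equal-area
tessellation. The pipeline models species independently; no competition
or joint-distribution structure is represented.
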