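# rangeshift

An ensemble species-distribution-modelling (SDM) pipeline for projecting
climate-driven range shifts of disease-vector mosquitoes (or any terrestrial
taxon) and quantifying them with range-dynamics indices — built as a single,
reusable framework so projections are comparable across species, and
validated end to end on synthetic worlds with virtual species whose true
ranges are known by construction.

## Who this is for

Spatial ecologists and epidemiological modellers who need, from occurrence
points and gridded environmental layers:

* per-species habitat-suitability maps under current and future climate
  scenarios,
* binary potential ranges and how they shift,
* cross-species overlap hotspots (where many vector species could co-occur),

and who want every step of that chain — occurrence cleaning, bioclimatic
variable derivation, pseudo-absence sampling, model gating, thresholding,
index computation — to be tested against independent oracles rather than
trusted on faith.

## The model and the indices

Occurrences are cleaned (coordinate uncertainty < 5 km, one record per
10×10 km cell, species kept only with ≥ 100 thinned records) and modelled
against a 30-layer predictor stack: the 19 bioclimatic variables BIO1–BIO19
derived from monthly temperature and precipitation, 8 land-use fractions,
and elevation/slope/aspect. After permutation-importance screening,
predictor pairs with |r| > 0.7 (Pearson or Spearman) are resolved by
dropping the lower-importance variable.

The ensemble fits one member per learner family × pseudo-absence round ×
cross-repetition (3 × 3 × 5 by default; regularized logistic regression,
random forest, gradient-boosted trees). Pseudo-absences follow the
1000-or-`n_presences` rule per round; each member is evaluated on a
held-out stratified 30% split; members with TSS > 0.6 **or** AUC > 0.8
enter the ensemble, whose habitat-suitability index (HSI) is their
TSS-weighted mean prediction. HSI is binarized at the threshold maximizing
sensitivity + specificity.

For a species with current range area *RCS*, future range area *RFS* and
shared area *SR* (all latitude-corrected km² on a spherical Earth):

```
RRI = RFS / RCS                  range ratio index   (> 1 ⇒ expansion)
RSI = 2·SR / (RCS + RFS)         range similarity index ∈ [0, 1]
```

Across species, the overlap index of habitat suitability (OIHS) is the
cell-wise sum of per-species HSI, and the overlap count is the number of
species whose binary range covers a cell; future − current deltas of both
are summarized as the area (and % of land) with increases.

## Worked example

```python
from rangeshift.range_dynamics import rri, rsi
print(f"RRI = {rri(1.13, 2.20):.3f}")     # current → future area ratio
print(f"RSI = {rsi(10.0, 20.0, 8.0):.4f}")
```

```
RRI = 1.947
RSI = 0.5333
```

An RRI of 1.947 means the future range is nearly twice the current one; an
RSI of 0.53 means the two ranges overlap over about half their combined
extent (RSI > 0.5 reads as "similar range positions"). A full synthetic
experiment — generate a world, sample two virtual species, fit, project
onto a +4 °C scenario, and measure the dynamics:

```python
from rangeshift.geo_raster import GridSpec
from rangeshift.pipeline import PipelineConfig, run_pipeline_on_stacks
from rangeshift.synthetic_world import (SUITE_PREDICTORS, WorldConfig,
                                        build_stack, gen_world,
                                        make_expanding_species_suite,
                                        sample_occurrences, true_suitability)

cfg = WorldConfig(grid=GridSpec(60, 120, -180.0, 90.0, 3.0), seed=7)
worlds = gen_world(cfg)
suite = make_expanding_species_suite(2, cfg, seed=7, worlds=worlds)
stacks = {sid: build_stack(worlds[sid], sid, SUITE_PREDICTORS)
          for sid in ("current", "ssp585")}
occ = {vs.species: sample_occurrences(
           vs, true_suitability(vs, stacks["current"]), seed=7)
       for vs in suite.species}
result = run_pipeline_on_stacks(occ, stacks, PipelineConfig(seed=7))
print(result.dynamics[["species", "rcs_km2", "rfs_km2", "rri", "rsi"]]
      .round(3).to_string(index=False))
print(f"OIHS increase: "
      f"{result.summaries['ssp585']['oihs_fraction_of_land']:.1f}% of land")
```

```
species      rcs_km2      rfs_km2   rri   rsi
   vs01 46693364.791 67761845.888 1.451 0.773
   vs02 43175734.929 55618067.356 1.288 0.827
OIHS increase: 80.8% of land
```

Both virtual species were constructed so their true suitable area expands
under warming; the fitted pipeline recovers that (RRI > 1 for both) and
reports that the summed habitat suitability rises over ~81 % of the
synthetic land surface.

The same pipeline is scriptable from the shell:

```bash
rangeshift simulate --outdir world --seed 7 --n-species 3
rangeshift run --world world --outdir results --seed 7
rangeshift report --outdir results
```

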