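# islandsdm

Climate-change impact assessment for island faunas from presence-only
occurrence records, built around the **Ensemble of Small Models (ESM)**
strategy for rare species, with a fully synthetic archipelago test-bed
whose ground truth is known at every stage.

## Who this is for

Ecologists and conservation analysts who need the full chain from raw
occurrence records + monthly climate + a DEM to per-species range-change
forecasts, diversity-hotspot maps and protected-area gap numbers — and who
want every stage testable against data with known answers. The package was
written for archipelago-scale pollinator assessments (hundreds of species,
most with only a handful of records), but nothing in it is taxon-specific.

## What it computes

1. **Occurrence prep** — cell-level deduplication, spatial thinning to a
   minimum pairwise great-circle distance, a minimum-record filter
   (species with < 3 thinned records are dropped), and a sampbias-style
   Poisson accessibility model (sampling rate q·e^(−w·d) against distance
   to settlements).
2. **Predictors** — the 19 standard bioclimatic variables, a Hargreaves
   PET family (annual PET, quarter PETs, Thornthwaite aridity, moisture
   index, continentality, degree-days), five topographic variables (Horn
   slope/aspect, TPI, TRI, McCune–Keon heat-load index), reduced to a
   non-collinear subset (pairwise |Spearman ρ| < 0.7, VIF < 10).
3. **ESMs** — per species: pseudo-absence sets ≥ 5.5 km from presences,
   spatial-block cross-validation (blocks sized by the median variogram
   range of the predictors), one Random-Forest classifier per predictor
   pair, TSS-weighted ensembling with low-skill pairs excluded, AUC /
   AUC-PR / TSS / continuous Boyce / ECE evaluation, null-model p-values,
   and a TSS ≥ 0.8 admission gate.
4. **Projection** — ensemble suitability under baseline and (GCM, RCP,
   time-slice) scenario climates, clamping outside the training ranges,
   maxSSS binarization, range change under a configurable dispersal rule,
   ExDet (NT1/NT2) extrapolation diagnostics with %N, and a niche
   truncation index.
5. **Hotspots & protection** — species richness (SR), weighted endemism
   (WE = Σ 1/range size), corrected weighted endemism (CWE = WE/SR), L1
   hotspots (top 1% of cells), Kruskal–Wallis altitudinal and Watson U²
   directional shift tests, human-modification class contrasts, and the
   percent of hotspot cells inside protected-area polygons.

The synthetic landscape (module `islandsdm.synth`) generates the whole
study system — multi-island DEM, Mediterranean monthly climate,
warming/drying scenarios, 12 virtual species with known Gaussian niches,
settlement-biased sampling, a human-modification surface and protected
areas — so recovery of niches, range-change directions and protection
fractions can be checked against truth. See `docs/methods.md` for the
model details and design choices.

## Worked example

```python
from islandsdm import recovery_config, run_pipeline

cfg = recovery_config()          # 150x150-cell archipelago, 12 virtual species
cfg.fit_species = ("vs_cold_narrow", "vs_montane_sunny", "vs_warm_generalist")
pipe = run_pipeline(cfg, "runs/demo")
print(pipe.state["eval_table"][["species", "n_presences", "ensemble_tss", "admitted"]])
```

```
              species  n_presences  ensemble_tss  admitted
0      vs_cold_narrow          120      0.928147      True
1    vs_montane_sunny          231      0.796083     False
2  vs_warm_generalist          234      0.184979     False
```

The narrow-niche cold-adapted species is modelled with a cross-validated
ensemble TSS of 0.93 and passes the 0.8 admission gate; the broad warm
generalist is (correctly) barely distinguishable from background and is
excluded. Its projected range change under the severe scenario,

```python
rc = pipe.state["range_change"]
print(rc[(rc.species == "vs_cold_narrow") & (rc.rcp == "8.5")][["slice", "change_pct"]])
```

```
   slice  change_pct
   2020s       -44.3
   2050s       -72.8
   2080s       -85.4
```

shows the expected monotone contraction as warming pushes its thermal
niche uphill. The analogue-climate fraction falls from 95.9% (mild
scenario, 2020s) to 26.2% (severe, 2080s) — a uniform +3.6 °C shift
exhausts the thermal range of a 150-km archipelago — and the
protected-area overlap of the L1 richness hotspots sits near the ~37%
mark in the current period (`pipe.state["overlap_table"]`).

A smaller smoke run is `islandsdm run --demo --run-dir runs/smoke` on the
command line (verbs: `synth`, `predictors`, `occurrences`, `fit`,
`project`, `hotspots`, `overlap`, `run`, `report`; all accept `--config`,
`--seed`, `--force`).

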