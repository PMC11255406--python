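# bftb-sdm

Stacked species-distribution modelling (S-SDM) of the bamboo-feeding true
bugs (BFTBs) of China — the Heteroptera that feed predominantly on
Bambusoideae — as a reusable, tested pipeline. The package covers the
whole workflow from raw occurrence records to a richness map, biodiversity
hotspots and an environmental driver-importance analysis, and ships a
machine-readable checklist of the 69 Chinese BFTB species plus a
synthetic-data generator with known truth so every stage is testable
without external downloads.

## What it computes

**Tiered range estimation.** Species are routed by the number of cleaned,
spatially thinned occurrence records *n*:

* *n* ≥ 5 — a presence-background **maximum-entropy SDM** (MaxEnt-style):
  a Gibbs distribution over background cells
  `P(x) = exp(λ·f(x)) / Z`, fitted by maximizing the L1-penalized
  log-likelihood
  `mean_presence[λ·f] − log Z(λ) − Σ_j β_j |λ_j|`
  with feature classes L/Q/H/P/T and the published per-class
  regularization tables. Feature class and regularization multiplier are
  selected by minimum AICc over the 6 × 8 grid
  {L, H, LQ, LQH, LQHP, LQHPT} × {0.5, 1, …, 4}; ten bootstrap-style
  80/20 replicates give a mean test AUC (rank-based), and models with
  mean AUC < 0.8 are deemed unsuccessful. Binary ranges use the
  10th-percentile training-presence (P10) threshold; a three-class map
  (unsuitable / moderate / high) uses MTP and P10.
* 2 ≤ *n* ≤ 4, and MaxEnt failures — **MCP-AT**: the 20-km-buffered
  minimum convex polygon of the occurrences, intersected with the
  inclusive annual-temperature range observed at the occurrence cells.
* *n* = 1 — **point-to-grid**: the single grid cell containing the record.

**Diversity pattern.** Binary ranges are stacked cellwise into a species
richness surface; **hotspots** are the top 5% of land cells by richness
(deterministic tie rule).

**Drivers.** Over a 13-variable registry (temperature, precipitation,
habitat heterogeneity, LGM climate anomalies TANO/PANO, human
interference), richness is analysed three ways: random-forest hotspot
classification (mtry = 7, ntree = 1000; importance = mean decrease Gini),
random-forest richness regression (mtry = 8, ntree = 1000; importance =
increase in node purity), and single-variable Gaussian GLMs (importance =
adjusted R²).

Supporting steps: record cleaning and 20-km spatial thinning (spThin-style
randomized heuristic), per-species calibration regions (MCP + 400 km), and
collinearity pruning (|Pearson r| ≥ 0.8 resolved by single-variable
jackknife AUC).

## Worked example

Generate a six-species synthetic study and run the full pipeline:

```bash
bftb-sdm simulate demo --preset tiny --seed 11
bftb-sdm run-all demo/config.yaml
```

which prints:

```
run complete: demo/run
  maxent: 3 species
  mcp_at: 2 species
  point: 1 species
  hotspot cells: 18 (cutoff richness 3)
```

Three well-sampled virtual species passed the AUC gate and kept their
MaxEnt ranges, the two sparse species fell to MCP-AT, the singleton to
point-to-grid; of the 360 land cells, the 18 richest (5%) form the
hotspot mask, and every cell in it holds at least 3 of the 6 species.
`demo/run/` then contains per-species ranges, `richness.asc`,
`hotspots.asc`, `drivers_importance.csv` (MDG/INP/adjusted-R² ranks) and a
`manifest.json` recording methods, seeds and checksums.

The checklist ships with the package:

```bash
bftb-sdm checklist-summary --level superfamily
```

```
        group  n_species  n_genera
    Coreoidea         32        12
Pentatomoidea         20        11
   Lygaeoidea         13         9
     Miroidea          4         3
total: 69 species, 35 genera
```

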