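# Methods

This note documents the models, algorithmic conventions, default
parameters and synthetic-data design of `bftb-sdm`, and what the test
suite does and does not establish.

## Occurrence handling

Cleaning drops rows with missing or out-of-range coordinates, exact
duplicate coordinates within a species, and points off the land mask;
every point keeps a provenance flag. Distances are great-circle
(haversine) on a sphere of radius 6371.0088 km — the 20-km thinning radius
and the 400-km calibration buffer are metric requirements, and a study
spanning tens of degrees of latitude makes Euclidean degrees unacceptable.

Spatial thinning enforces a minimum nearest-neighbour distance (default
20 km) with the classic randomized heuristic: repeatedly delete a point
with the most neighbours closer than the threshold, ties broken uniformly
at random; the whole procedure is repeated (default 10 runs) with seeds
derived from one input seed and a largest retained set is kept, making the
result deterministic per seed. The heuristic is not an exact
maximum-independent-set solver; the suite checks it against an exhaustive
subset oracle on instances of ≤ 12 points, where it has matched the
optimum on every random instance tried. The repetition count and tie rule
are this package's choices — published descriptions of the procedure leave
them open.

Species with zero retained points are dropped from modelling with a
logged warning.

## Calibration regions and predictor pruning

A species' calibration (background) extent is the convex hull of its
occurrences buffered by 400 km, intersected with land; degenerate hulls
(one point, collinear points) buffer to discs/stadia naturally. The
"within 400 km of the polygon" test uses a local equirectangular metric
per cell (longitude scaled by cos latitude), accurate to well under 1% at
these scales; the unit tests compare it cell-by-cell against brute force.

Collinearity pruning computes Pearson correlations over all region land
cells (background-driven screening, standard SDM practice, rather than
occurrence cells only). Each candidate gets an exploratory jackknife AUC
from a single-variable model with default settings (feature class LQ,
RM 1) — the single-variable reading is the only one that yields a
per-variable AUC to compare. Pairs with |r| ≥ 0.8 are resolved greedily
from the largest |r| down, dropping the lower-AUC member; AUC ties drop
the alphabetically later name (logged), so selection is order-invariant
up to that rule.

## The maximum-entropy engine

The engine is a from-scratch implementation of the penalized
maximum-entropy estimator, not a wrapper around the Java reference
program; small numeric differences from that program are expected and
acceptable. Conventions:

* **Features.** Variables are min-max standardized on the background and
  clamped to [0, 1] (clamping also applies when projecting outside the
  training range). L = z, Q = z², P = all pairwise products, T = step
  indicators and H = forward+reverse hinge pairs at knots placed on
  uniform background quantiles; 10 knots per variable by default (the
  reference program's 50 is unnecessary at desk scale; configurable).
  Variables constant on the background contribute no features (warning).
* **Penalty.** β_j = RM × β_class(m) × sd_j/√m with m = number of
  presences, β_class interpolated from the published per-class sample-size
  tables, and sd_j the presence standard deviation of the feature floored
  at 0.05 so rarely-varying features stay penalized.
* **Optimization.** The convex objective is maximized with L-BFGS-B on the
  split λ = λ⁺ − λ⁻ (both ≥ 0), gradient tolerance 1e-6, at most 500
  iterations; non-convergence flags the fit as a failed replicate. On 1-2
  feature instances the optimum is verified against dense grid search of
  the same objective.
* **Outputs.** Raw scores normalize to 1 over the background; logistic
  output uses the entropy-based transform `c·raw/(1 + c·raw)`,
  c = exp(H).
* **Model selection.** AICc with the raw likelihood renormalized over the
  study cells and k = the number of nonzero coefficients
  (ENMeval/Warren-Seifert convention), over the full 6 × 8 feature-class ×
  RM grid; ties go to fewer parameters, then lower RM, then simpler
  feature class. At desk scale the background is all region cells (the
  10,000-cell cap never binds), so "study cells" and background coincide.
* **Replicates.** "Bootstrap" evaluation is implemented as ten seeded
  random 80/20 presence splits (the published description does not define
  it further); test AUC is the rank-based (Mann-Whitney) statistic with
  ties counting one half. The final suitability map is the cellwise mean
  of replicate logistic maps; MTP/P10 thresholds are computed from the
  pooled per-replicate training-presence suitabilities, with P10 as the
  ceil(0.1 n)-th smallest value (order-statistic convention, no
  interpolation).

## Fallback estimators and dispatch

MCP-AT buffers the occurrence hull by 20 km and keeps land cells whose
annual-temperature value lies in the inclusive [min, max] observed at
occurrence cells — inclusive so every occurrence remains inside its own
predicted range; "AT" is read as the annual mean temperature layer.
Point-to-grid marks exactly the cell containing the record, with the
half-open convention that edge points belong to the east/north cell.
Everything shares one grid; "pixel" means one grid cell.

Species with ≥ 5 occurrences whose tuning fails or whose mean test AUC
falls below 0.8 re-enter MCP-AT with **all** their occurrences (the
natural reading of the fallback rule). Because MaxEnt-tier binary maps are
thresholded at P10, up to 10% of a species' own training presences can
legitimately fall outside its binary range; the occurrence-containment
invariant is therefore asserted for the MCP-AT and point tiers only.

## Stacking, hotspots, drivers

Richness is the cellwise count of binary ranges (MCP-AT and point species
contribute their binary maps directly; no suitability exists for them).
Hotspots are the top `round(0.05 × n_land)` cells by richness, ranked with
row-major cell index as a deterministic tie-break; per-cell counting is
used (no latitude weighting — cell areas vary by only a few percent across
the default synthetic window; a cos-latitude weighting switch would be the
first addition for continental real-data use). The 5% is taken of all
land cells, not of modelled cells.

Random forests come from scikit-learn (`max_features` = mtry 7/8,
`n_estimators` = 1000, out-of-bag scoring); importances are the Gini /
node-purity impurity measures corresponding to MDG and INP. The hotspot
classifier uses a stratified 80/20 split and leaves the ~5% class
imbalance unbalanced. The per-variable GLM is Gaussian with identity link
— adjusted R² is well-defined there, and with one regressor equals
1 − (1 − R²)(n − 1)/(n − 2); negative values are reported as computed, and
a Poisson log-link option (importance 1 − deviance/null deviance) sits
behind a flag. The 13-variable registry is a configurable reconstruction
grouped into temperature, precipitation, habitat heterogeneity, historical
anomaly (TANO/PANO) and human interference; temperature and precipitation
variables are flagged as the SDM-modelling block in ranked reports.

## Synthetic data

The generator exists so every stage can be tested against known truth.
Layers are smooth latitudinal/longitudinal gradients plus Gaussian-filtered
noise with a requested correlation length (default 150 km), on a default
60 × 60-cell window at 15 arc-min over 100-115°E / 15-30°N. The window is
deliberately low-latitude and coarse: adjacent cell centers are > 20 km
apart, so the 20-km thinning removes only genuinely clustered records, and
the full pipeline runs in minutes. An optional exact-correlation control
regenerates one layer as a mixture with another to exercise the |r| ≥ 0.8
pruning. The land mask thresholds an independent smooth field at 88% land.

Virtual species have logistic niches over standardized layers; the
intercept is calibrated so a chosen fraction of land (the prevalence) has
suitability ≥ 0.5, which defines the true range. Presences are sampled
without replacement, one per cell, proportional to suitability, and
jittered within the cell — duplicates that thinning would immediately
remove cannot occur, which keeps tier counts controllable.

Community generation fixes the tier mix (defaults 30/28/11 species with
≥ 5, 2-4 and 1 occurrences). Because presences are drawn in proportion to
suitability and backgrounds are restricted to each species' calibration
region, the achievable test AUC is capped by within-region prevalence and
niche steepness; the defaults — niche coefficients U(6, 9) on the
coldest-month-minimum and annual-precipitation analogues, prevalence
U(0.05, 0.10), 20-40 occurrences in the MaxEnt tier — are chosen so that
ranges are strongly climate-determined and the MaxEnt tier clears its 0.8
AUC gate, i.e. so the community realizes the method mix it is asked to
emulate. Niches default to those two layers, planting a two-variable
ground truth that the driver analysis should recover; the driver-analysis
tests also use a direct planted response (Poisson richness with a logistic
mean in the two dominant layers).

What passing tests therefore show: the estimators recover planted truth
under clean, stationary, two-driver conditions at desk scale. What they do
not show: behaviour under real-data pathologies — sampling bias, spatially
autocorrelated errors, niche truncation at study borders, mixed-resolution
layers, taxonomic noise — none of which the generator emulates, and no
attempt is made to mimic real Chinese geography or real climate values.

## Reproducibility and sizes

All randomness flows from one master seed; stages and species derive
31-bit seeds as CRC32("master:stage:name"), recorded in the run manifest
together with per-stage counts, method assignments and output checksums.
Problem sizes used by the acceptance script — 60 × 60 landscape, 69-species
community, 2000-cell driver tables, 200 thinning instances, 500-presence
recovery fits — keep a full from-scratch run within a few minutes on one
CPU while leaving every estimator's signal clearly above its acceptance
threshold.

## Known limitations

* The MaxEnt engine omits cloglog output, MESS/extrapolation diagnostics
  and projection to other climates (out of scope here).
* Hinge/threshold knot counts and the sd floor in the penalty are desk-
  scale conventions; coefficients are not numerically identical to the
  Java reference program.
* The checklist fixture transcribes the published China table verbatim;
  its internal genus-count discrepancies (35 by table headers vs 36 in
  running text) are preserved, not resolved — summaries count what the
  rows contain.
* Hotspot delineation is per-cell, not area-weighted.
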