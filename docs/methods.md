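# Methods

This note documents the models, parameters, numerical choices and known
limitations of the package. It states no empirical result that the test
suite does not itself compute.

## Problem setting

Narrow-range montane endemics (the motivating case is high-elevation
conifers of biodiversity hotspots) are assessed for climate-change
extinction risk by (1) modelling current habitat suitability from presence
records and bioclimatic predictors, (2) projecting suitability under
future climate, (3) converting both maps to occupied-area estimates inside
the species' extent of occurrence, and (4) translating the projected loss
of occupied area into a Red List category under criterion A3(C), which
treats projected habitat loss as a proxy for future population reduction.

## Simulated world (what the generator emulates, and what it does not)

Real inputs for this workflow are herbarium/GBIF occurrence records and
bioclim raster stacks. The generator replaces them with a *virtual
species*: every downstream quantity then has a known ground truth.

* **Climate layers** are Gaussian-smoothed white noise (kernel s.d. =
  `correlation_range` cells, default 8) min–max rescaled to realistic
  bioclim ranges — by default a temperature-annual-range layer spanning
  21.75–33.65 °C, an isothermality layer (34.44–45.62), and two
  precipitation layers (573.5–987 mm and 295–419.2 mm). The four layers
  are generated independently: the strong inter-variable covariance of
  real bioclim data is deliberately *not* emulated (the collinearity
  filter is instead exercised on constructed tables in tests).
* **Niche**: per-driver Gaussian (`exp(-((x-opt)/breadth)²/2)`, peak 1 at
  the optimum) or logistic responses, combined by product. The default
  species responds only to the temperature layer (optimum 23.5 °C,
  breadth 0.6 °C), occupying roughly a tenth of the 100×100-cell region —
  chosen once as a realistic footprint for a narrow-range endemic.
* **Presences** are drawn without replacement at the cell level with
  probability proportional to suitability, and returned as cell centers —
  mirroring the deduplication that leaves real datasets with at most one
  record per grid cell. Default n = 41, a study-scale sample size.
  An optional uniform contamination rate emulates georeferencing error;
  no default error rate is claimed (default 0).
* **Futures** are per-layer affine deltas (`x·factor + offset`), default
  +3 °C (moderate) and +5 °C (high emission) on the niche driver. Real
  GCM fields have spatial structure in the deltas; an additive shift is
  sufficient to create known contraction fractions for recovery tests,
  which is all the downstream stages consume.
* **Land cover** is an iid categorical map (classes: 1 forest, 2
  grassland, 3 water, 4 urban) with a controllable forest fraction
  (default 0.7). It has no spatial autocorrelation; it exists to exercise
  the masking and occurrence-cleaning paths.
* **Grid**: 100×100 cells of 60 arc-seconds (nominally 2 km), the
  resolution required for AOO counting; cell area is fixed at 4 km²
  rather than latitude-corrected, because the assessment counts cells.

A green recovery test therefore establishes that the pipeline recovers
niches and contractions *under these idealized conditions* — smooth
independent predictors, presence sampling exactly proportional to
suitability, no observation bias. It does not establish robustness to
sampling bias, predictor covariance shift, or spatially structured error.

## Model members and evaluation

* GLM: logistic regression on linear + quadratic terms per predictor
  (standardized; effectively unpenalized, C = 1e4).
* GAM: logistic model on a cubic B-spline basis per predictor (6 knots ≈ 8
  basis functions), ridge-penalized (C = 1) as the smoother.
* RF: 500 trees; BRT: 1000 trees, learning rate 0.01, depth 3, subsample
  0.75 — conventional SDM settings, all overridable per model spec.
* One replicate per family by default (4 members); a `replicates` knob
  multiplies that.
* Evaluation uses the stratified 30% held-out split: AUC by the
  Mann–Whitney pair-counting estimator (ties = 0.5) and TSS at the MTSS
  threshold. Member TSS for ensemble weighting comes from the same split;
  negative-TSS members are floored to zero weight, and if all members are
  skill-free the ensemble falls back to equal weights with a warning.
  Both member and ensemble scores are reported, the ensemble score being
  primary.
* Non-convergent members are retried once with stronger shrinkage, then
  excluded with a warning.
* MTP and MTSS thresholds are computed from ensemble predictions on the
  *training* split (they are training-data rules by definition) and
  applied unchanged to future surfaces, the standard practice.

## Variable importance

Permutation importance on the ensemble (not per member): raw importance =
1 − Pearson r between predictions on the original table and on the table
with one column permuted, averaged over 10 seeded permutations, floored at
zero, then normalized to percentages summing to 100. Constant predictions
make the correlation undefined; such variables are flagged zero with a
warning. An AUC-drop variant was considered and rejected as the default
because the correlation-drop scheme is what the widely used SDM tooling
reports as "% contribution".

## Collinearity filtering

Correlation rule first, then VIF rule (the conventional composition):
while any pair exceeds |r| = 0.75, drop the pair member with the larger
VIF; then while any VIF exceeds 5, drop the largest; VIFs recomputed after
each removal. Ties drop the lexicographically later name — determinism
over faithfulness to unspecified behaviour. Perfect collinearity reports
VIF = +inf (numerical floor: residual variance ≤ ~1e-12 of total). VIF is
computed by least-squares regression of each variable on the rest; tests
cross-check it against the inverse-correlation-matrix closed form.

## Range geometry

* **Alpha hull**: Delaunay triangulation, discard triangles with
  circumradius > α (the classical alpha-shape criterion; the R tooling
  this emulates does not document its internal parameterization, so the
  textbook definition is used). Default α = 2 × median nearest-neighbour
  distance, logged per species and config-overridable. Occurrences
  covered by no kept triangle are retained as isolated parts so the
  buffered EOO contains every record — they become small discs, i.e.
  disjunct range fragments. Fewer than 3 or collinear points fall back to
  buffered points with a warning.
* **Buffer**: Euclidean, in degree units, default 0.1° (≈ 12 km at the
  equator) — deliberately *not* done in projected metres.
* **Masking**: cell-center-in-polygon, boundary cells resolved by the
  same half-open convention ([x0, x0+w) × (y0−h, y0]) used for point
  extraction and deduplication, so extraction and AOO counting can never
  disagree about cell membership. Land-cover and EOO masks are
  intersections, hence commutative and idempotent (asserted by test).
* **AOO is counted inside the buffered EOO for both current and future
  maps.** This is the accounting that makes off-EOO habitat gains
  irrelevant to the AOO trend, and the worked full-loss example depends
  on it.

## Risk categories

The classifier implements the assessment scheme's printed constants
verbatim: LC below 15% loss, NT from 15%, VU above 30%, EN above 50%, CR
above 80%, EX at exactly 100%. Two deliberate choices:

* **Boundary semantics.** The scheme's strict inequalities leave the
  boundary points ambiguous; the precautionary reading assigns a boundary
  value to the more threatened category where a "≥" reading supports it
  (15 → NT), leaving 30 → NT, 50 → VU, 80 → EN under the strict ">" of
  the next category. The mapping is monotone and total, and overridable.
* These cut-offs differ from the canonical IUCN A3 thresholds (30/50/80
  for VU/EN/CR); the printed scheme is implemented as given, and "EX" is
  a projected-status label under A3(C), not a formal extinction
  declaration — the report carries that caveat string.

Gains clamp to LC (there is no reward category).

## Numerical and procedural choices

* **Raster I/O** uses the ESRI ASCII grid text format with a `.prj`
  sidecar for the CRS (GDAL's DX/DY header extension for rectangular
  cells); values are written at 17 significant digits so round-trips are
  bit-exact. Affine nearest/bilinear resampling between aligned
  geographic grids only; bilinear refuses categorical layers.
* **Thresholding convention**: score ≥ threshold is suitable, so the MTP
  rule's defining guarantee (every training presence classified suitable
  at its own minimum) holds by construction. MTSS candidates are the
  unique observed scores (exact optimum, cheap at these sizes); ties take
  the smallest threshold. MTP ≤ MTSS is *not* assumed — either order
  occurs in practice.
* **Deduplication tie-break**: first record in input order after a
  lexicographic (lon, lat) pre-sort — order-independent and idempotent.
* **Seeding**: one master seed; per-stage, per-species seeds are derived
  by hashing `master:stage:species` (SHA-256, reduced below 2³¹), so
  adding a stage does not reshuffle the others. Full runs are
  bit-reproducible (asserted by test).
* **Contraction-recovery check**: the ±10-point criterion is evaluated on
  the MTSS rule (the conservative headline rule) and on the mean over the
  5 seeded replicates; the delta for a target loss is found by bisection
  on the true-suitability area inside the EOO (step function, 60
  iterations, smallest offset reaching the target).

## Limitations

* No MaxEnt member, no spatial block cross-validation, no calibration of
  member probabilities beyond their native outputs.
* No reprojection engine; all coordinates are WGS84 decimal degrees and
  cell areas are nominal, not latitude-corrected.
* No IUCN criterion B (EOO-area) computation, no generation-length
  scaling of the A3 window, no landscape-connectivity metrics, no
  land-use-change projection.
* Real-data headline numbers from the motivating study (per-species AUC,
  variable-importance percentages, VIF values) depend on proprietary-ish
  occurrence and climate downloads and are out of scope; the suite
  validates the *rules* and the *recovery behaviour*, not those data.
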