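# Methods

This note documents the models, algorithms and design choices behind
`orchardyield`, in the spirit of a model-description appendix. Nothing here
states an empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Problem setting

The target system is a mature almond orchard imaged once in summer at
0.3 m ground resolution in four bands — green (550 nm), red (671 nm), red
edge (717 nm), NIR (800 nm) — with individual-tree fresh-weight harvest
records available for a subset of rows. The goal is a per-tree yield
estimate (kg fresh weight) for every tree in the orchard, plus an account
of within-field yield variability (row-to-row, tree-to-tree, along
transects).

## Crown segmentation

No single NDVI threshold delineates every tree: low thresholds fuse
adjacent crowns, high thresholds miss small or weak trees. The multi-stage
procedure segments NDVI at seven thresholds evenly spaced over
[0.60, 0.83] (the range and count are the method's parameters; the even
spacing is this package's choice, configurable), polygonizes 8-connected
components (components under 3 pixels dropped as noise), and removes from
each layer any polygon whose major axis — the longer side of the minimum
rotated bounding rectangle, compared inclusively — exceeds the 4.5 m
in-row spacing, since one crown cannot be wider than the planting spacing.
Filtered layers are merged from the lowest threshold upward: a
higher-threshold candidate is discarded iff it lies *spatially within* an
already-kept polygon, defined as representative-point containment plus
≥90% area overlap (tolerant of raster-polygonization slivers; both the
overlap fraction and a strict-containment mode are configurable). The
result is containment-free and keeps the largest valid polygon per tree.
Tree centers are polygon centroids, numbered row-major.

## Block extraction

Each tree contributes a (2r+1)² × bands reflectance block centered on the
pixel *containing* the tree center (affine containment, not
nearest-center rounding); r = 10 px by default (21 × 21 ≈ 3 m radius),
with 41 × 41 and 61 × 61 supported. Edge trees are excluded, not padded:
zero padding would inject artificial dark/soil signal into training.
Blocks are raw reflectance in [0, 1]; no per-block normalization is
applied (batch normalization inside the network handles scale).

## CNN regressor

Two architectures:

* **Tunable family** — 3–4 blocks of
  `conv(3×3) → BN → pool → conv(3×3) → BN → pool → ReLU` with 16–128
  filters per conv layer and max- or average-pooling, followed by the
  attention head: global average pooling → dense (30–100 units) → dropout
  (0–0.5) → dense(1). Learning rate searched in [1e-4, 1e-2].
  **Pooling uses ceil ("same"-edge) semantics here**: with two pools per
  block, floor pooling would collapse a 21×21 input to zero pixels by the
  sixth pool (21→10→5→2→1→0), making every 3–4-block configuration
  infeasible — ceil mode (21→11→6→3→2→1→1) keeps the stated search space
  valid, and is how such stacks are conventionally built.
* **Final architecture** — eight 3×3 conv layers, each followed by batch
  normalization and ReLU, a max-pool after every two convs (four pools,
  floor/valid semantics: 21→10→5→2→1, 61→30→15→7→3), then GAP →
  dense(100) → dense(1). The conv-layer, pool and dense-width counts
  define this architecture; the per-layer filter widths are not part of
  the printed design and default to (16,16,32,32,64,64,64,64) — doubling
  after each pool, a conventional schedule — configurable.

The "spatial attention module" is exactly the GAP-plus-dense head (not a
multiplicative attention mask); the head's dense layers learn which
channels of the pooled feature vector matter.

Training minimizes MSE with Adam (β₁ = 0.9, β₂ = 0.999), batch size 128.
Two training details are this package's choices, both documented because
they matter at short training budgets: (i) targets are standardized for
training and predictions mapped back to kg — without this a
small-initialized head spends tens of epochs learning the output scale;
(ii) the learning rate follows a half-cosine decay to ~0 across the run,
which substantially reduces seed-to-seed variance of the minimum reached.
Evaluation uses seeded random k-fold cross-validation (k = 5); fold sizes
differ by at most one. A fold with constant observed yields has undefined
R² and is flagged rather than silently averaged.

Hyperparameter search is sequential model-based optimization: a Matérn-5/2
Gaussian process fitted to (configuration, validation-MSE) pairs in a unit
hypercube encoding, maximizing expected improvement over a random
candidate pool; the first five trials are random. A fixed 20% of the
training trees is held out as the tuner's validation split. Default
budget 50 trials × 100 epochs; the acceptance runs use reduced budgets
(noted below).

Band ablation retrains the same architecture on spectral-band subsets
(input depth = subset size); all 14 non-empty proper subsets of the four
bands are enumerated, the full set optionally included.

The network engine itself (convolution via im2col, batch norm, pooling,
GAP, dense, dropout, Adam) is implemented in numpy inside the package,
float32, with every random draw routed through a seeded generator:
identical seeds give bit-identical initial weights and shuffles.

## Engineered features and baselines

Per tree, 46 features:

* 13 vegetation indices — NDVI, NDRE, GNDVI, EVI2, SAVI (L=0.5), OSAVI,
  MSAVI, RDVI, SR, CI_red-edge, CI_green, MTCI, GRVI — averaged over crown
  pixels (NDVI > 0.5) within a 2.5 m circular buffer. The exact index list
  is configurable; this set spans the structure / greenness / chlorophyll
  families. Divisions are guarded (NaN, excluded from means).
* fractional coverage: crown pixels ÷ buffer pixels, a crown-size proxy.
* 32 GLCM textures: per band, the block is quantized to 32 gray levels
  over its observed range; the symmetric co-occurrence matrix at distance
  1 is accumulated over directions {0°, 45°, 90°, 135°}, normalized, and
  eight measures computed (contrast, dissimilarity, homogeneity, angular
  second moment, correlation, mean, variance, entropy). The texture window
  defaults to the full 21×21 block: a literal 2×2 window with 32 gray
  levels is degenerate, so the "compute locally then average over the
  block" reading is implemented with the window size configurable.
  Correlation of a constant window is defined as 0 (vanishing marginal
  variance).

Baselines: bidirectional stepwise OLS from the intercept-only model with
AIC as the criterion (a p-value mode is available); SVR, random forest,
XGBoost and a dense network (2–3 layers, 32–256 units) tuned by seeded
random search over conventional ranges with a shared budget. Every model ×
feature-set cell is evaluated on the *identical* seeded fold partition
(fold hash asserted), so differences are attributable to the models.

## Evaluation

R² = 1 − SSres/SStot; RMSE; NRMSE = RMSE / mean(observed) × 100; bias =
mean(predicted − observed); IQR of predictions with linearly interpolated
quartiles. Distribution agreement uses the Welch (unequal-variance)
two-sample two-tailed t-test — the paired variant would answer a different
question than distribution-level agreement. Row variability reports mean,
SD, CV, IQR and boxplot quartiles per row for predicted and observed
yields; transects are horizontal lines (perpendicular to rows) selected at
seeded random among lines crossing ≥80% of rows, capturing the nearest
tree per row within a 2.25 m half-width. The yield map floors negative
network outputs at 0 kg (map product only; metrics use raw outputs).

## Synthetic orchard generator

The generator defines the study conditions for every test:

* **Layout**: rows along one axis, 6 m row spacing, 4.5 m in-row spacing,
  Gaussian positional jitter (SD 0.2 m); crown radii truncated-normal
  (mean 2.2 m, SD 0.4 m, floor 0.5 m — consistent with crowns mostly under
  5 m diameter). Axis-aligned by default (segmentation and block logic are
  rotation-agnostic); a rotation option exists for stress tests.
* **Fertility**: a Gaussian random field at tree centers with exponential
  covariance (range 30 m — a few rows, the scale at which soil variability
  typically expresses) mapped through the standard normal CDF, giving
  exactly uniform [0, 1] marginals and tractable moments.
* **Yield link**:
  `Y = μ(a0 + a1·F + a2·G + a3·(F−½)(G−E[G]) − a4·C + a5·√3·Q) + ε`,
  with F the fertility, G = (R/R̄)² the normalized crown area, C a
  standardized in-row crowding index (summed crown overlap with adjacent
  row neighbors, residualized against own radius so it is orthogonal to
  the area term), Q ~ U[−1, 1] the signed within-crown vigor pattern
  (below), and ε Gaussian noise. Coefficients are derived analytically so
  that E[Y] = μ = 53.1 kg and SD[Y]/μ = 0.331, with 70% of the variance
  in the deterministic (imagery-visible) term, split 20% / 20% / 15% /
  15% / 30% between fertility, area, the fertility×area interaction,
  competition, and pattern. Yields are truncated at 0 kg (rate logged;
  negligible at defaults). The structured terms exist because a purely
  additive fertility+area link makes per-tree summary features a
  lossless description of the signal — then a linear baseline sits at the
  noise ceiling and imagery has no value beyond averages, contradicting
  the structure the pipeline is designed to exploit.
* **Reflectance**: soil background (NDVI ≈ 0.15); each crown a radial
  disk, `value = soil + (core − soil)(1 − (r/R)²)`, whose core spectrum
  rises with fertility mainly in the red edge (gain 0.20) and secondarily
  NIR (0.10); visible-band gains are near zero, reflecting chlorophyll-
  absorption saturation — the red edge is the canopy-volume proxy. The
  vigor pattern Q adds a core-vs-ring contrast to the red-edge band only
  (`Q · 0.05 · (1−ρ²)(1−4.58ρ²)`, ρ = r/R), a mode whose mean over the
  detected crown is approximately zero: trees with vigorous versus
  declining interiors differ in spatial arrangement at equal average
  red-edge reflectance. NDVI (red/NIR) is independent of Q, so
  segmentation and coverage are unaffected. Crown-core NDVI exceeds 0.60
  at any fertility (guaranteeing segmentability) and soil stays below
  0.3; overlapping crowns resolve per pixel to the larger radial weight.
  Additive Gaussian pixel noise (SD 0.01), clipped to [0, 1].
* **Registration error**: the inventory's tree coordinates are the
  *recorded* locations — true centers plus isotropic Gaussian error with
  SD 0.15 m, a sub-pixel residual consistent with a location-QC'd
  pipeline. Both model families consume the same inventory.
* **Harvest sampling**: an every-k-rows visibility option mimics the
  field protocol in which only every seventh row is individually
  harvested.

What the generator does **not** emulate: shadows and sun geometry,
radiative transfer, phenology/multi-date imagery, weather, harvest-record
measurement error structure, inter-orchard variation. Passing tests
therefore demonstrate that the pipeline recovers the *kinds* of structure
it targets (crown geometry, band-specific vigor signal, spatial yield
patterns) under controlled conditions — not that real-orchard accuracy
levels are reproduced.

## Problem sizes and numerical choices

The test and acceptance runs use synthetic orchards of 120–1,500 trees,
with CNN training at 15–30 epochs and a 5-trial tuner budget — sizes
chosen so the full pipeline exercises every code path while a complete run
stays in the minutes range on a single CPU core. Determinism: all
randomness (layout, field, noise, weight init, shuffling, dropout, folds,
tuner) flows from explicit integer seeds; pre-training pipeline stages are
bit-reproducible (hash-checked), and training is reproducible on a given
BLAS build. Degenerate inputs are defined rather than crashed: NDVI with
zero denominator → nodata; empty crown mask → missing features with a
logged reason; constant GLCM window → the analytic degenerate measure
values; constant observed yields → flagged undefined R².

## Known limitations

* The numpy CNN engine is CPU-only and unoptimized beyond im2col matmuls;
  wall-clock, not capability, limits model sizes.
* Crown polygons are unions of pixel squares; sub-pixel boundary accuracy
  is not attempted.
* North-up, square-pixel rasters only; no reprojection.
* The GP tuner assumes a smooth response over the encoded hypercube;
  categorical dimensions are embedded, not treated with a dedicated
  kernel.
* The synthetic generator's realism limits are listed above, and they
  have a measurable consequence for model comparisons: on clean,
  smoothly rendered crowns the 46 engineered features are a *near-
  sufficient* summary of the imagery — every latent's image expression
  interferes linearly with the smooth radial base profile, so VI crown
  means and quadratic texture statistics recover even the "spatial"
  signal components (interaction, crowding, within-crown pattern) to a
  large degree. Empirically, stepwise linear regression on these
  features and the final-architecture CNN both capture roughly 80–85%
  of the imagery-visible yield variance at CPU-scale training budgets,
  and their mean cross-validated R² difference is within a few
  hundredths with seed-dependent sign. The large CNN-over-baseline
  margins reported for real orchards arise from image complexity
  (shadows, sensor artifacts, morphological diversity) that this
  generator deliberately does not emulate; synthetic runs therefore
  validate the comparison *machinery* and the band-importance
  structure, not the real-data effect size or its direction at the
  margin.
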