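# Methods

## The estimation problem

Given collar fixes of grazing sheep at a 2-minute interval, estimate
the spatial distribution of forage removal (grazing intensity, g/m²)
over a fenced semi-arid paddock, and identify which covariates carry
the signal. The package implements the full chain — preprocessing,
allocation, regression — plus a synthetic-data generator that stands
in for field data, which are not publicly deposited.

## Constant-rate intake model

Assumptions:

* A sheep's daily fresh intake IZ depends on body weight only:
  IZ = f·W with f = 0.076 by default. This is consistent with
  dry-matter intake of 2–4 % of body weight (default 0.03) at a
  dry-to-fresh mass ratio of 0.39 (0.03/0.39 ≈ 0.0769); both
  parameterisations are exposed (`daily_intake(mode="fresh"|"derived")`)
  and agree within 5 % at the defaults.
* Intake accrues at a constant rate over the grazing day. With
  effective grazing time TZ, the literal average rate is IZ/TZ (g/s).
  Only a fraction a of grazing time is actual feeding (a = 0.86;
  plausible range 0.85–0.90), so a segment of duration Tᵢ removes
  Iᵢ = (IZ/TZ)·Tᵢ·a, and a full day's segments sum to IZ·a.
  `average_grazing_rate(corrected=True)` separately reports the
  *rate while feeding*, IZ/(TZ·a). These two conventions cannot be
  composed into one formula without the correction cancelling; the
  allocator uses the first so that the feeding-time fraction visibly
  scales the map total.
* In the end-to-end pipeline the rate is calibrated on the nominal
  full grazing day (day_end − day_start, 12 h by default) rather than
  on each day's retained time. A season with shorter days or more
  excluded dwell time therefore removes proportionally less forage,
  which is what makes seasonal map totals comparable.

### Allocation modes

* `conservative` (default): each segment's intake is spread over the
  cells intersecting its buffer footprint — the segment line dilated
  by the 3-m half-width with square end caps (a zero-length segment
  yields a 6-m square) — with weights proportional to overlap area.
  Σ F·S equals the summed segment intakes to machine precision as
  long as footprints stay inside the grid; the synthetic paddock's
  grid pads one cell beyond the fence for exactly this reason.
* `literal_eq5`: the published closed form F = IZ·Tᵢ·Cᵢ/(ΣCᵢ·TZ·S),
  with Cᵢ the count of segment midpoints in cell i and Tᵢ their
  summed dwell time. Because it weights by both dwell time and point
  count it double-counts occupancy and does not conserve IZ in
  general; it is retained verbatim for comparability. Whether the
  per-cell time should be summed dwell or the raw fix interval is
  ambiguous in the source; summed dwell is used. In the single-cell
  limit both modes concentrate IZ in one cell (F = IZ/S).

Grid geometry: 13-m square cells, origin snapped to a multiple of the
cell size, 0-based half-open cells, row 0 northernmost.

## Preprocessing

* One trajectory = one animal × one local day. Rows with unparseable
  time or coordinates are dropped and counted; duplicate timestamps
  keep the first record.
* Segment length is haversine on lon/lat (R = 6371 km) or Euclidean
  on planar input. Segments implying speed > 3 m/s are GPS glitches
  (a sheep cannot sustain more between 2-min fixes) and are removed,
  counted, and logged. Segmentation never bridges a time gap larger
  than 1.5× the median fix interval, so runs split by zone exclusion
  stay independent.
* Kernel density: truncated (4h) Gaussian kernel on the analysis
  grid, rescaled to integrate to the fix count; bandwidth defaults to
  Silverman's rule on the fix coordinates. Grading into five classes
  (1 = extremely low … 5 = extremely high) uses quantiles by default;
  natural-breaks (1-D k-means) and equal intervals are offered. Zero
  cells are grade 1, and grading is monotone in density.
* Zone classification: connected components of grade ≥ 4 are
  candidate clusters. A cluster containing the configured water point
  is *drinking* — this rule runs first, because a drinking
  aggregation is also near-stationary; then a cluster whose
  within-cluster mean fix speed is < 0.05 m/s with ≥ 30 min dwell is
  *rest*; anything else is *grazing*. Explicit override polygons win
  over the rules (the original zones were labelled by inspection, so
  manual override is a first-class path). Exclusion removes fixes
  inside rest/drinking polygons and is idempotent.

## Terrain and vegetation covariates

* NDVI = (ρNIR − ρR)/(ρNIR + ρR), zero-denominator cells → nodata.
  Negative values (bare soil, water) are clamped to 0 with a logged
  count, keeping the working range in [0, 1]; the unclamped value is
  available with `clamp_negative=False`.
* Slope/aspect by Horn's 3×3 finite differences (the GIS standard for
  30-m DEM products; the source names no algorithm). Aspect is the
  compass bearing of the downslope direction, 0° = north, clockwise;
  flats get nodata. Borders are padded by odd reflection — linear
  extrapolation — so an inclined plane keeps its exact slope up to
  the edge (plain edge replication would halve border gradients).
* Raster I/O is ESRI ASCII grid (plain text, float32 round-trip).
  Planar ↔ geographic conversion is an equirectangular projection
  about a configurable anchor (default 39.0° N, 107.6° E); over a
  ~1.5 km paddock the distortion is negligible and the mapping is
  exactly invertible.

## Regression

Features per retained segment: duration T (s), walking distance C
(m), slope P (°), elevation E (m), aspect D (°), NDVI, weight S (kg),
temperature (°C); target = F of the cell containing the segment
midpoint. Aspect is circular, so it is encoded as (sin D, cos D) by
default, with a `raw` fallback matching the source's flat treatment.
Features are z-scored with the sample standard deviation (n−1);
constant columns are a hard error in `standardize` but are dropped
with a log message in the combination screen (at a fixed fix interval
T is constant by construction and carries no information).

The network: one tanh hidden layer (default 10 units), linear output,
full-batch gradient descent with momentum 0.9, learning rate 0.05,
early stopping on validation MSE (patience 20, min-delta 1e-6), all
seeded. The source used a MATLAB toolbox whose default optimiser is
Levenberg–Marquardt; plain momentum descent was chosen for
dependency-free reproducibility, which is adequate because the
screening question is relative ranking, not absolute benchmark speed.
Targets are standardized on the training partition internally and
metrics are reported in original units.

Split: train/validation sizes are rounded half-up from 70 %/15 %, the
test set takes the remainder — 780 samples give 546/117/117.

Metrics: R² = 1 − Σ(Wᵢ−Wᵢ₁)²/Σ(Wᵢ−Wᵢ₂)² with Wᵢ the prediction, Wᵢ₁
the actual value and Wᵢ₂ the **mean of the predictions**. This
denominator is nonstandard — it coincides with the conventional
coefficient of determination only when the predictor's spread matches
its error structure appropriately — and the package implements it
verbatim, with `conventional_r_squared` provided for comparison and a
constructed counterexample in the test suite documenting the
divergence. MSE = (1/N)Σ(Tᵢ−Yᵢ)². Screening trains one network per
combination X1–X9 with seeds derived from a shared schedule; the best
model is the highest R², ties broken by lowest MSE then lowest
combination index.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical shape* the pipeline relies
on: 06:00–18:00 days at 120-s fixes (361 fixes), dawn departure from
and dusk return to the pen (within 20 m), a midday rest dwell (60
min) and a drinking visit (15 min) as low-speed jitter (σ = 1 m), and
grazing loops as a correlated random walk (von Mises turning angles,
κ = 4) whose steps are accepted Metropolis-style in proportion to
exp(ΔNDVI/0.05). Walking speeds (grazing ≈ 0.45 m/s, transit 1 m/s)
are declared assumptions — no published values exist for this flock.
Flock weights use exact largest-remainder class counts (15/70/15 %
below 40 / 40–60 / above 60 kg, drawn uniformly within 30–40, 40–60,
60–75 kg), so 200 head give exactly 30/140/30. The DEM is a sum of
low-frequency sinusoids (30-m cells); reflectance bands are
constructed so NDVI is smooth with patch peaks drawn in [0.58, 0.90];
temperature is a sinusoid peaking at 14:00 with seasonal means 24 °C
(summer) / 10 °C (autumn).

Ground truth plants per-segment intakes (summing exactly to IZ) and
the implied intensity field, enabling conservation and recovery
tests. What passing these tests shows: the pipeline's arithmetic,
geometry and training are correct under known generative conditions.
What it does not show: behavioural realism (no social interaction, no
forage depletion or regrowth, no weather response), GPS error
structure beyond speed glitches, or the field accuracy of the
published model — the original field data are not deposited, so the
published headline metrics are explicitly out of reach.

`planted_feature_table` generates regression samples whose target
depends only on the five-variable subset {NDVI, S, T, temperature, C}
plus Gaussian noise; terrain features are pure distractors. Recovery
tests require test R² ≥ 0.95 at n = 780, σ = 0.05 and that this
subset outranks both the trajectory-only and terrain-only
combinations in the screen.

## Numerical choices and degenerate inputs

* Kernel density truncation at 4 bandwidths loses < 1e-4 of kernel
  mass; the surface is rescaled to integrate exactly to n.
* Quantile grading on constant positive density yields a single
  grade; an all-zero surface is all grade 1 with a warning.
* Buffer weights sum to 1 ± 1e-9 inside the grid; clipped footprint
  fractions are logged.
* Zero-length segments get a square footprint about the point.
* Training aborts with a diagnostic (reporting the learning rate) if
  the loss goes non-finite.
* All stochastic components flow from explicit integer seeds;
  identical seeds give byte-identical trajectories, rasters, splits
  and fits.

## Problem sizes

Default test-suite and acceptance-script runs use one to a few
simulated collar days (hundreds of fixes each), a ≤ 50×50 oracle grid
for the kernel-density check, 10⁵ Monte-Carlo points per buffer
check, and n = 780 regression samples — the modelling sample size of
the study — which keeps every check exact or tightly seeded while
running in seconds.

## Known limitations

* The equirectangular projection is paddock-scale only; no CRS
  handling or reprojection.
* GeoTIFF is not read or written; ESRI ASCII grid is the raster
  interchange format.
* The literal closed-form allocation is non-conservative by
  construction; use it for comparability, not for budgeting forage.
* Zone classification is rule-based with manual override; it is not
  a behavioural classifier (grazing vs ruminating vs walking), and
  only the aggregate feeding-time fraction a enters the intake model.
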