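# Methods

## Model overview

`lulcsim` forecasts a categorical land-use/land-cover (LULC) raster forward
in time by combining three independently parameterised sources of
information — per-class environmental suitability, per-class demand, and
binary transition rules — in an iterative allocation step.  The design
assumes: (i) a regular, north-up grid in a projected CRS that never changes
during a simulation (no resampling, no reprojection); (ii) a fixed class
codebook partitioned into *modelled* classes, which compete for cells, and
*static* classes (water bodies, transport infrastructure), which are held
fixed and excluded from the dynamic universe; (iii) change is rare per
time-step, so the classifier must be trained on a deliberately rebalanced
sample.

## Suitability classifier

Each dynamic cell is described by: its class at t−2, t−1 and t0 (three
nominal features), the focal proportion of every modelled class in an odd
`window_cells` × `window_cells` neighbourhood at t0, the modal class in
that window (nominal), and the predictor stack (continuous and categorical
layers).  Focal windows are truncated at the map edge — the denominator is
the number of valid in-window cells — and a physical window extent is
discretised to the nearest odd cell count (5 km at 100 m cells → 51).

Feature processing, fitted once on the training sample and frozen:

- **Correlation filter** (continuous columns only): columns are visited in
  descending |point-biserial correlation| with the cell-changed indicator;
  a column is dropped when its absolute Pearson correlation with an
  already-retained column reaches the threshold (default 0.7).  The
  ranking criterion is this package's own transparent stand-in for embedded
  selection procedures whose internals vary between tools.  Zero-variance
  columns are dropped with a warning.
- **Standardisation** by training mean and sample standard deviation.
- **One-hot encoding** of nominal features with the level set frozen at
  training; a projection-time level unseen at fit time is an error, since
  the classifier's input dimension must stay constant across steps.
  Indicator columns bypass both the filter (it handles continuous
  variables only) and standardisation.

The default classifier is a feed-forward network: five densely connected
ReLU hidden layers (256-128-64-32-16, configurable) and a softmax output
over the K modelled classes, trained by an adaptive-moment optimiser with
batch size 256, a 0.2 validation split, and early stopping (patience 10)
within at most 200 epochs — training accuracy plateaus well before that on
the synthetic landscape.  The scikit-learn backend has no dropout layers;
the `dropout_rate` field documents the nominal reference architecture and
regularisation is carried by the L2 penalty (`alpha`, default 1e-4) plus
early stopping.  The model interface is deliberately an abstraction: any
estimator with `fit`/`predict_proba` satisfying the per-cell simplex
contract can be plugged in, and a multinomial-logistic backend is provided
for fast tests.  Training is seed-reproducible.

### Sampling and augmentation

The training universe is all valid cells whose class is modelled at both t0
and the response step.  Every changing cell (class at response ≠ class at
t0) is included, plus an equal-size simple random sample of non-changing
cells (all of them, with a warning, if fewer exist).  Within the changing
subset only, each class is oversampled to the size of the most prevalent
class using SMOTE-NC: the distance between rows is the Euclidean distance
on continuous features plus `med²` per categorical mismatch, `med` being
the median of the continuous features' standard deviations; a synthetic row
interpolates continuous values between a seed row and one of its k = 5
nearest same-class neighbours at u ~ Uniform(0,1) and takes each nominal
feature's mode among the k neighbours.  Interpolation happens in the raw
(pre-one-hot) space so nominal attributes stay atomic; rows are re-encoded
afterwards.  A one-row class cannot be interpolated and is duplicated with
a warning.  Original rows are never modified.

## Demand

Demand is kept in cell counts internally (fractions of the dynamic area at
the file interfaces; the dynamic total is fixed, so conversion is exact).
Future steps continue the straight line through the last two observed
steps.  Negative projections are clamped to zero and each step is rescaled
proportionally over unconstrained classes so it sums exactly to the dynamic
total.  Policy overrides constrain future steps: `freeze` pins a class to
its reference-step value, `replacement-only` caps it there (the class may
shrink but only regain its losses).  Overrides are idempotent; an
all-classes-constrained step whose counts cannot sum to the dynamic total
raises an infeasibility error rather than silently rescaling.

## Transition rules

One binary matrix per simulation period, rows = current class, columns =
future class, diagonal forced to 1 (persistence is always legal).  The
package ships a default pair of matrices for the 14 modelled classes of the
Swiss 17-class codebook encoding a baseline scenario: urban land is never
taken over; arable and grassland may be urbanised in the first forecast
period only, after which urban columns close entirely; agricultural classes
interconvert; vegetation succession (alpine grassland → brush/trees →
forest) is one-way; trees are the only forested class allowed onto
grassland; horticulture replaces losses only; and glacier retreat follows
glacier → bare land → unproductive vegetation.  Every narrative rule is
asserted against the shipped matrices in the test suite.

## CLUE-S allocation

The allocator maintains one additive iteration parameter λ_c per class
(zero-initialised).  Each pass assigns every free dynamic cell to
argmax_c (s_c + λ_c) over the classes its transition row allows, with
deterministic tie-breaking (lowest class id, then row-major cell order),
then updates λ_c ← λ_c + η·(demanded_c − allocated_c)/N with η = 0.5 and
multiplicative damping (×0.9) whenever a class's deviation changes sign
without shrinking.  Iteration stops when max_c |allocated_c − demanded_c| ≤
tolerance (default max(1 cell, 0.05% of the dynamic area)) or after
`max_iter` = 1000 passes; the assignment with the smallest maximum
deviation seen is returned, flagged `converged` accordingly.  This is the
classic dual-ascent view of demand-constrained allocation: at the fixed
point, cells are filled from the highest suitability downwards for each
class while the λs price the competition between classes.

Numerical choices: forbidden destinations are −∞ (never an additive
identity), so no λ can resurrect an illegal transition; cells whose rules
allow only persistence are pre-assigned and removed from competition, and
demand feasibility is checked after this reduction (demand below the locked
count, or above the number of cells allowed to convert, raises an error
naming the class); fractional demand is rounded to integers summing exactly
to the dynamic total by largest remainder; non-simplex suitability inputs
are rejected.

On exactly satisfiable, rule-unconstrained instances small enough to
enumerate, the converged allocation coincides with the maximum-total-
suitability assignment (verified against brute force in the tests).  With
near-degenerate (tied) suitabilities the dual ascent can stall above a zero
tolerance; the default one-cell tolerance absorbs this.

## Autoregressive projection and post-processing

To project step t+1, the LULC-derived features are recomputed from the
(t−2, t−1, t0) history — observed maps or previously allocated forecasts —
time-varying predictor layers (e.g. climate) may be substituted by name,
and all other features stay fixed.  After each allocation the map can be
post-processed: modelled glacier recoded to bare land, external glacier and
lake masks stamped on (lake wins over glacier on overlap, as new lakes form
in deglaciated terrain; the mechanistic source model resolves the physics,
the package only needs a deterministic precedence), and static aggregate
codes resolved to fine thematic codes with validation that each fine code
belongs to its aggregate.

## Validation metrics

Overall accuracy with a binomial confidence interval (symmetric normal
approximation by default, Wilson by flag); the quantity/allocation
decomposition of disagreement computed from the confusion-matrix
proportions (q_g = |p₊g − pg₊|, a_g = 2·min(pg₊ − pgg, p₊g − pgg), halved
sums), which satisfies Q + A = 1 − OA exactly; one-vs-rest sensitivity,
specificity and balanced accuracy per class, with classes absent from the
reference reported as missing (never zero) and excluded from averages with
a warning; and a demand audit reporting, per class and step, the obtained
minus the requested prevalence change relative to a baseline map, as a
fraction of the dynamic area.  Full precision is kept throughout;
rounding happens only at presentation.

## Synthetic landscape generator

The generator emulates the statistical structure of national
land-statistics series: K imbalanced classes on a 100 m grid, few cells
changing per step, transitions driven by environmental gradients and
neighbourhood contagion, and a static class.  Defaults (the reference
conditions used across the test suite): 100×100 cells, 6 classes, 4
time-steps, 5% of dynamic cells changing per step, drift
(+0.004, +0.002, 0, −0.002, −0.004, 0) of the dynamic-area share per step,
predictor effects ±1.5 on three continuous fields, neighbourhood
coefficient 2.0, and one static class occupying the highest 8% of the
elevation field.

Continuous predictors are an elevation-like gradient with smoothed relief
and two spatially autocorrelated Gaussian fields; one categorical predictor
tiles the map into five contiguous regions.  At each step, dynamic cells
are drawn as changing with probability `change_rate`; a changing cell must
change, drawing its destination from a multinomial logit over the other
modelled classes with linear predictor
`intercept_c + adj_c(t) + effects_c·x + 2.0·focal_c`.  The drift term
`adj_c(t)` is a proportional feedback — gain `drift_strength` (default 200)
times the gap between the class's target share (initial share + drift·t)
and its current share — so realized prevalences track the configured linear
trend instead of relaxing to the logit's own equilibrium; with the default
gain the regression slope of a drifting class's prevalence has the
configured sign in essentially every seed.  All randomness flows through a
single seeded generator; equal seeds give bit-identical series.

What the generator does *not* emulate: real geography, spatially
heterogeneous survey error, the hundreds of socio-economic predictors of
operational runs, or climate trajectories.  Passing tests therefore
demonstrate the correctness of the machinery (sampling, augmentation,
training contracts, demand accounting, allocation, audits) on a recoverable
signal — not forecast skill on real landscapes.

## Problem sizes

The test suite and the acceptance script run the reference 100×100-cell
landscape (≈9200 dynamic cells) for training, projection and allocation,
40×40 grids for the multi-seed drift checks, and ≤10-cell instances for
exhaustive allocation enumeration — sizes chosen so the full pipeline,
including network training, completes in seconds while every contract is
exercised end to end.

## Known limitations

- The dual-ascent allocator has no optimality guarantee under restrictive
  transition rules; the enumeration check covers the unconstrained case.
- Demand rebalancing spreads clamped/overridden residuals proportionally,
  one plausible convention among several.
- The network backend approximates the reference dropout architecture with
  L2 + early stopping (see above).
- Per-class elasticities and region-specific demand, present in some
  CLUE-S variants, are out of scope.
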