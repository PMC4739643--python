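# Methods

`energyscape` reconstructs an animal's *energy landscape* — the spatial
surface of movement-related energy expenditure inside its home range — from
collar biologging data: GPS fixes plus short tri-axial accelerometer bursts.
This note documents the models, the defaults and why they were chosen, what
the synthetic world does and does not emulate, and the numerical choices that
matter.

## From raw counts to ODBA

Collar accelerometers report integer counts per axis. Calibration follows the
manufacturer form `a_i = (n_i − n_zerog) · c_i · g`, with `n_zerog = 2048`
counts, slope `c_i` = 0.001 (high sensitivity) or 0.00269 (low sensitivity)
g/count, and `g = 9.81 m/s²`. Overall dynamic body acceleration per burst `j`
is

    ODBA_j = (1/n) Σ_i ( |x_i − x̄| + |y_i − ȳ| + |z_i − z̄| ),

the mean over the burst's `n` samples of the summed per-axis absolute
deviations from the per-axis burst mean. Mean-centering removes the static
(gravity/posture) component, so ODBA is invariant to adding a constant to any
axis and scales linearly with the calibration slope. Because sensitivity
settings differ between collars, ODBA is min–max standardized to [0, 1]
within each individual (`ODBA′`); standardization happens **after** resting
bouts are excluded, over active records only — the resting floor would
otherwise pin the minimum at a value with no behavioral meaning.

Bursts are associated to the GPS fix nearest in time; ties go to the earlier
fix (deterministic, order-stable), and bursts farther than `max_gap = 60 s`
from any fix are dropped rather than extrapolated.

## Track processing

Dynamic GPS schedules (2/10/60 min keyed to activity) over-represent active
behavior; tracks are regularized to a common ≥10-minute resolution by greedy
thinning (keep the first fix, then the next fix ≥10 min later) and by filling
stationary inactive gaps with synthetic fixes repeating the last coordinate
every 10 min (an inserted fix is only created if it leaves ≥10 min clearance
to the next real fix).

Resting bouts are contiguous runs of low-variability bursts lasting more than
4 h that intersect a daylight window (default 06:00–18:00); qualifying runs
that extend into the night are also excluded. The per-burst activity score is
the standard deviation of the calibrated samples summed over axes — a
documented stand-in for the collar's proprietary activity measure. The
default threshold separating "low" from "high" scores is an Otsu split of the
per-individual log-score distribution: a fixed low quantile (e.g. the 10th
percentile) cannot flag a resting fraction that is ~25–30% of all bursts, and
the score distribution is strongly bimodal, for which the two-class
variance-maximizing split is the natural deterministic choice. A quantile
threshold remains available (`threshold=("quantile", q)`), as does an
absolute score. The first 48 h after collaring are always excluded
(capture/handling effects).

Per-day activity metrics (active-bout count, bout durations, cumulative
Euclidean distance) use a configurable day boundary in seconds-of-day
(default 18:00) standing in for sunset-to-sunset days — the synthetic world
has no solar geometry.

## Utilization distributions (dBBMM)

The dynamic Brownian bridge movement model conditions on consecutive fixes
and a time-varying Brownian motion variance σ²ₘ (m²/s). In a sliding window
(default 31 fixes, margin 11), every odd-indexed fix is left out and
predicted from its neighbours; σ²ₘ maximizes the product of bridge densities
N(μ(α), α(1−α)Tσ²ₘ + (1−α)²δ² + α²δ²) with δ the telemetry error (default
20 m). Candidate breakpoints outside the margins are screened and a
two-variance split replaces the single estimate when BIC (one extra
parameter, n = held-out fixes) favours it; per-segment σ²ₘ averages the
window estimates covering it. The likelihood carries only the endpoint
location errors (the cited method's printed form); when δ² is comparable to
Tσ²ₘ this inflates σ̂²ₘ, so recovery checks run in the δ = 0 regime where the
estimator is exact. Windows, margins and grid resolution are not stated by
the source analysis; the defaults mirror the cited method's conventions.

The UD integrates the bridge density over time (midpoint rule, default 60 s
spacing) on a 30 m grid and normalizes to total mass 1 (enforced to 1e-6).
The home range is the 95% contour: the smallest set of highest-density cells
reaching the level, with ties resolved deterministically in flat-index order.
UD values at burst locations use nearest-cell lookup (raster extraction
semantics).

## Landscape covariates

On a shared planar 30 m grid: distance to the forest edge (unsigned,
cell-center to nearest opposite-class cell center — brute-force verifiable),
proportion of urban area (developed classes or roads) within a 240 m radius
disc (cell-center inclusion; edge cells normalize by the in-grid disc area),
landscape heterogeneity within the same disc, and distance to roads. The
heterogeneity metric is Shannon diversity H = −Σ p_k ln p_k of land-cover
classes; the source analysis does not pin the metric down, so it is
documented as substitutable. Distance maps are 1-Lipschitz and focal
statistics translation-equivariant; both properties are tested.

## Energy-landscape models

Per individual, `(ODBA′)^(1/3)` (the cube root makes Gaussian residuals
tenable for a [0, 1]-bounded response) is modeled with mgcv-backed penalized
regression: a thin-plate spatial smooth `s(x, y, k=100)`, a cyclic cubic
smooth of time of day (period 86 400 s, `k=10`), REML smoothing-parameter
selection, and double-penalty shrinkage (`select=TRUE`) so any term can leave
the model. Planar (x, y) replaces geographic coordinates — the synthetic
world is metric. The environmental candidate set is all 2⁵ subsets of {land
cover, distance to forest edge, heterogeneity, proportion urban, distance to
roads} on top of the fixed spatio-temporal base; models are ranked by

    AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1),   k = (total edf) + 1 (scale),

the ΔAICc < 4 subset forms the confidence set, and per-cell predictions are
Akaike-weight averaged. Mapped predictions exclude the (centered) cyclic
time-of-day term — maps are time-marginal — and are reported on the cube-root
scale (no back-transform bias correction is attempted; `pred**3` is a naive
option left to the caller). Prediction cells whose land-cover class was not
seen in training are predicted at the modal training class. Adjusted R² is
mgcv's standard report. Cross-individual couplings (UD value, habitat
suitability) use the same smooths plus the linear covariate and a
per-individual random-intercept smooth (`bs="re"`).

A degenerate exactly-constant response admits no REML fit (zero scale); the
trivial intercept fit is returned explicitly with all smooths at zero
effective df.

## Step-selection habitat suitability

Observed steps (consecutive regularized fixes) are contrasted with K = 5
random steps per stratum: (speed, turning angle) pairs drawn from a bivariate
normal fitted to the observed joint distribution, lengths converted with the
observed step's duration, endpoints placed relative to the previous bearing.
Negative drawn speeds are resampled (not truncated: truncation would put an
atom at zero and distort the covariance target); angles are wrapped to
(−π, π]. Conditional logistic regression on endpoint attributes (land cover
vs a reference class — `developed_high` when present — four continuous
covariates, plus raw step length and turning angle as movement controls)
maximizes Σ [x_obs β − log Σ_j exp(x_j β)]. The design is unit-scaled
internally for optimizer conditioning and coefficients are back-transformed;
a Newton step with BFGS fallback gives convergence tight enough to match
brute-force grid search on toy problems. Covariates constant within every
stratum are conditioned out and dropped with a warning.

Suitability maps evaluate the linear predictor per cell with step length and
angle fixed at one seeded kernel draw (a cell-constant offset) and min–max
normalize within the home range — the [0, 1] scale is otherwise undefined.
Validation fits on the chronological first 75% of fixes (chronological, not
random: avoids temporal leakage between train and test) and compares
suitability at held-out locations against an equal number of uniform random
in-home-range points (Welch t).

## ODBA valleys and peaks

Valleys (peaks) are home-range cells at or below (above) the 5% (95%)
quantile of the averaged prediction surface, ties included on the hot-spot
side, grouped by 8-connectivity. Each hot spot carries its area, its summed
UD probability ("time spent" is read from the UD, not from raw fix counts),
and an environmental profile (continuous covariate means + land-cover
fractions). Time budgets: OLS of time share on type + area + individual.
Composition: McArdle–Anderson distance-based pseudo-F on Euclidean distances
of z-scored profiles, with the area covariate partialled out and type labels
permuted within individuals only (999 permutations;
p = (1 + #{F* ≥ F}) / (1 + n_perm)). The pseudo-F reduces exactly to the
standard permutational MANOVA statistic in the unstratified single-factor
case (cross-checked against an independent implementation in the tests).

## The synthetic world

The generator emulates the study conditions of a ~20-day deployment on 12
nocturnal, forest-associated individuals along an urbanization gradient:

* a patchy landscape (smoothed-noise fields thresholded into two developed
  and four natural classes, straight-line roads) whose developed fraction is
  drawn from a configurable range, with urbanization increasing west→east so
  individuals placed along x span a gradient of % urban home ranges;
* a "true" standardized ODBA surface, the min–max normalized linear
  combination of z-scored covariate layers with configurable signed
  coefficients (defaults: urban +0.9, forest-edge distance −0.4,
  heterogeneity +0.2, road distance −0.2), and a "true" suitability surface
  favouring forest and penalizing urban;
* habitat-biased correlated random walks at 1-min resolution (candidate
  headings weighted by exp(3 × suitability) with a weak home-center pull);
  speeds 0 / 0.4 / 1.2 m/s for rest / moderate / high states;
* one diurnal resting bout per day (09:00 onset ± 30 min, 6.5 h > the 4 h
  exclusion threshold) with *exactly* zero dynamic acceleration — clean rest
  blocks, by design;
* GPS fixes on a 2/10/60-min dynamic schedule (or fixed 10/15 min; the
  default population mixes schedules as the emulated study did), and bursts
  of 54 samples (nominal 18.74 Hz × 3.5 s, kept as metadata; the 54-sample
  analyzed unit is authoritative) every 180 s;
* bursts encoded as alternating ±A square waves per axis with A = ODBA/3 and
  the 1-g offset on z, counts obtained by inverting the calibration — the
  decoded ODBA round-trips within one count per sample per axis
  (3 · c · g ≈ 0.03 m/s²).

What the generator does **not** emulate: GPS error by default (configurable,
default 0 so degenerate contracts hold exactly), behavioral sub-structure
beyond a two-state active Markov chain, seasonal or weather effects,
autocorrelated within-burst waveforms, or any particular species' movement
parameters.
Passing tests therefore demonstrate that the estimators recover *planted*
structure under idealized noise, not that they would behave identically on
field data with location error, irregular sampling and behavioral
complexity.

For step-selection parameter recovery a separate generator emits independent
choice situations (random start points and bearings, selection ∝
exp(β·forest) among kernel draws); sequential tracks confound the fitted
movement kernel with habitat autocorrelation and are used for the validation
power checks instead.

## Problem sizes and numerics

Multi-seed recovery checks run at n ≈ 1500–2500 observations with spatial
basis dimensions k = 30–50 (20 seeds); single-fit examples use k up to 100.
The bundled end-to-end configuration uses 3 individuals × 6 days on a 64²
grid with a one-variable candidate set and 99 permutations. σ²ₘ is optimized
on the log scale within [1e-10, 1e8] m²/s (bounded scalar minimization,
xatol 1e-6); UD normalization is enforced to 1e-6; all randomness descends
from explicit `numpy.random.SeedSequence` seeds and the mgcv bridge pins
single-threaded BLAS, so reruns are byte-identical.

## Known limitations

* The GAM/GAMM stage shells out to R (mgcv) — an R installation with mgcv
  and jsonlite is required.
* The σ²ₘ likelihood omits the left-out fix's own location error (faithful to
  the printed form); with large δ it overestimates σ²ₘ.
* Suitability is a min–max normalized linear predictor, not a calibrated
  probability; comparisons are rank-based.
* The compositional test assumes exchangeability of hot spots within
  individuals under the null; spatially overlapping hot spots violate this
  mildly.
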