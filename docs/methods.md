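# Methods

## The estimation problem

A mycophagous mammal eats a fungal fruiting body at some point in its home
range; the spores leave the gut over the following days and are deposited
wherever the animal then is.  The dispersal distance kernel — the
probability that a spore ends up a given distance from the ingestion
point — is the composition of two measurable processes:

1. **gut retention**: the distribution of time between ingestion and
   defecation, measured in feeding trials with marker spores;
2. **movement**: the animal's displacement over that time, measured by GPS
   telemetry.

`sporekernel` estimates the kernel nonparametrically on the movement side
and parametrically on the gut side.

## Gut-passage model

Feeding trials record marker-spore amounts per scat-collection interval on
a staged schedule (by default 4-hourly to 48 h, 6-hourly to 84 h, then
12-hourly to 108 h post-dosing).  `build_curve` converts these to a
cumulative excretion curve: the running marker total over the grand total,
indexed by interval midpoints (the conventional point estimate of the
individual excretion times).  The curve is fitted with the logistic

    C(t) = A / (1 + exp(-(t - t50) / s)),    A = 1 by default,

by nonlinear least squares (`scipy.optimize.least_squares`, TRF with
bounds t50 >= 0, s > 0, 0 < A <= 1).  Initial values come from the curve
itself: t50 from the linearly interpolated crossing of 0.5, and
s = (t75 - t25) / (2 ln 3) from the interpolated quartile crossings (the
exact relation for a logistic).  On a failed solve, up to five jittered
restarts are tried; persistent failure raises an error carrying the best
parameters and RSS found.  Standard errors are the usual asymptotic
Jacobian-based estimates.

**Fit abscissa.**  The cumulative count through interval k is, in
expectation, C evaluated at the interval's *end*, not at its midpoint.
Evaluating the model at midpoints while plotting the full running sum
there — the classical presentation — biases t50 low by about half an
interval width (~2 h, i.e. ~8% at t50 = 24 h, verified by simulation).
Curves built from interval observations therefore retain the interval ends
and the fit evaluates the model there by default (`time_basis="auto"`);
midpoints remain the reporting convention, and `time_basis="midpoint"`
reproduces the classical fit exactly.  Curves supplied as bare
(time, proportion) points are fitted at the given times.  With interval-end
fitting, simulated trials with 10,000 spores recover t50 and s with mean
relative bias below 1% and 2% respectively; the residual bias on s comes
from fitting an untruncated logistic to schedule-truncated data and
shrinks with larger t50/s ratios.

**Defecation weights.**  For a sequence of fix offsets t_0 < t_1 < ... in
[0, W], the probability that the spores leave the gut in the interval
ending at t_i is the increment C(t_i) − C(t_{i−1}), with the value before
t_0 taken as C(0).  By default weights are renormalised to sum to 1 within
the window (all recovered spore mass attributed to observed fix times);
`residual="assign_endpoints"` instead adds the pre-window and post-window
tail mass to the first and last fix.  If a window carries no increment
mass at all (a single offset at 0, or a degenerate parameter set) the unit
mass is spread uniformly over the offsets, so a single-fix window is a
point mass.  A diagnostic `weighting="cumulative"` mode uses C(t_i) itself
as the (renormalised) weight — the literal reading of "probability of
defecation at that time" — for comparison; it is not a probability mass
over the window and is not the default.

## Telemetry processing

Tracks are read from delimited text with configurable column names,
grouped by (animal, tracking period) and sorted by timestamp, making the
reader invariant to row order.  When a satellite-count column is present,
fixes with fewer than 4 satellites (non-3D fixes) are dropped; duplicate
timestamps keep the first record; periods with fewer than two valid fixes
are skipped.  All of these log what they removed.

The first 60 min of each period are discarded (return to normal movement
after handling); a fix exactly on the boundary is kept.  The cut is
anchored at the period's deployment start (carried on the Track), not at
the current first fix, so cleaning is idempotent.

Distances are great-circle (haversine, R = 6,371 km) for geographic input
and Euclidean for projected-metre input; offsets are exact timestamp
differences in hours, with no resampling or interpolation (observed fix
gaps in such datasets range from minutes to a day, and no interpolation
rule is defensible across that range).

Every fix with at least `min_span_fraction × 69` h of track remaining
(default fraction 1.0) anchors one ingestion window containing all fixes
within 69 h; there is no partial trailing window by default.

## Kernel construction and aggregation

A window kernel has the window's displacements as support and the
defecation weights as mass.  Aggregation is by finite mixture: the trial
animals' gut models get equal weight within each window, windows get equal
weight within each animal, and animals get equal weight (1/n, regardless
of how much tracking data each contributed) in the overall kernel.
Mixtures are exact (concatenated supports, scaled masses), so mass is
conserved to floating-point accuracy (validated to 1e-9) at every level.
The mixture-of-distributions reading of the aggregation is the package's
central interpretive decision: the output object is a probability
distribution over distance, which a literal "mean displacement at each
time" curve is not.  That literal per-animal mean is still available as a
diagnostic (`mean_displacement_curve`).

Summaries:

- **quantiles** — lower weighted-empirical convention: the smallest
  support value whose cumulative mass reaches q (with a 1e-9 slack on the
  comparison to absorb accumulated rounding);
- **maximum** — the largest support distance carrying mass above a
  configurable floor (default 0: any positive mass counts), taken across
  window kernels;
- **binned density** — mass summed into half-open bins [kw, (k+1)w),
  default width 25 m;
- **across-animal band** — per-animal binned densities on a shared grid;
  at each bin the mean and an outward-rounded central interquantile
  envelope (lower/higher empirical quantile methods, so two animals' band
  spans both values).  The envelope is additionally widened to include the
  mean, which an interquantile range of skewed values need not otherwise
  cover.

## Synthetic data

The generator produces studies with the structure the pipeline assumes:

- **movement** — per-axis discrete-time Ornstein–Uhlenbeck motion with the
  exact transition `x' = x e^(-dt/tau) + sigma sqrt(1 - e^(-2 dt/tau)) z`,
  started from the stationary law, converted to lat/lon on a local tangent
  plane (111,194.93 m per degree latitude, × cos(lat) per degree
  longitude, consistent with the haversine radius).  Defaults sigma =
  300 m, tau = 12 h give a stationary home range a few hundred metres
  across.  Constant-velocity and stationary models provide analytic edge
  cases.  Optional independent fix dropout emulates missed fixes.
- **gut passage** — each spore's excretion time is logistic(t50, s)
  truncated to the collection schedule (inverse-CDF sampling), tallied per
  interval; the law matches the fitted family so parameter recovery is
  well-posed.
- **study** — six animals over nine tracking periods (spans 85–544 h
  totalling ~1,807 h, two animals retracked, fixes every 15 or 30 min) and
  two feeding trials with distinct retention curves (t50 = 24 h, s = 5 h
  and t50 = 40 h, s = 7 h — one faster, one slower passage, spanning the
  6–69 h range over which marker spores are typically recovered).

What the generator does **not** emulate: GPS positional error,
habitat-driven or behaviourally switching movement, spatially non-uniform
defecation, spore viability.  Passing tests therefore demonstrate the
estimator's correctness under its stated assumptions (uniform ingestion
and defecation over the home range, retention time independent of
movement), not robustness to their violation in field data.

The constant-velocity scenario admits a closed form: the q-quantile of the
kernel is `v · C̃⁻¹(q)` with `C̃(t) = (C(t) − C(0)) / (C(W) − C(0))`,
inverted by bisection to 1e-9 h.  The pipeline agrees with it to within
one fix interval of travel (v × Δt), the discretisation limit of a
weighted empirical distribution on fix times.

## Numerical choices

- Logistic evaluated via tanh for tail stability.
- Window admission and truncation use a 1e-9 h tolerance on hour
  arithmetic derived from nanosecond timestamps.
- Probability-mass invariants (kernel construction, quantile comparisons)
  use a 1e-9 absolute tolerance.
- All simulators take explicit integer seeds (numpy `default_rng`) and are
  bit-reproducible; study sub-seeds are spawned from a `SeedSequence`.

## Problem sizes

The default test and validation runs use six 200-h OU tracks at 15-min
fixes (~3,100 ingestion windows), 200 replicate feeding trials of 10,000
spores for recovery checks, and the nine-period synthetic study (~4,600
positions, ~3,100 windows) for the end-to-end summary — sizes chosen to
mirror the scale of a real single-species tracking campaign while keeping
a full validation run in the low seconds.

## Known limitations

- The 69-h window and the 60-min warm-up are empirical constants of the
  motivating system; both are configurable.
- Equal per-animal weighting makes the overall kernel sensitive to animals
  with very little tracking data (few windows); a per-window-weighted
  mixture is available through `mix_kernels` weights.
- The logistic retention family is symmetric on the logit scale; strongly
  skewed retention would need a different family, which the fitting
  machinery does not currently provide.
- Real deposited datasets may use their own column names and projections;
  the reader's `column_map` and projected-metre mode cover this, but no
  datum transformations are performed.
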