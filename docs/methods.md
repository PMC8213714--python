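# Methods

## Model

The package treats heat failure as the accumulation of a dose of injury.
At a constant temperature T the injury rate is exponential in T with rate
constant k (per °C); the animal fails when the cumulative dose reaches a
fixed lethal amount.  Only the ratio of lethal dose to rate scale is
observable (it is the tolerance time), so all bookkeeping is done in
normalized units — dose as a *fraction of the lethal dose*, failure at 1.
The three absolute constants of the underlying rate law (basal rate,
lethal dose, and their ratio) therefore have no representation in the
code; a curve is fully specified by

* `z` — thermal sensitivity, °C per tenfold change of tolerance time
  (k = ln(10)/z is always derived, never stored);
* `ct_ref` at `t_ref` — one anchor point on the line, by default the
  temperature tolerated for 60 min (sCT_max(1 h));
* optionally `tc_star` — a baseline temperature below which ramp formulas
  book no injury.

Assumptions inherited from the model: injury is additive and carries no
memory of exposure order; there is no repair and no hardening, so rates
are non-negative everywhere and the simplified rate law is (negligibly)
positive even at benign temperatures; one curve describes one endpoint at
one mortality level.  Families of curves across mortality percentiles,
cold-side tolerance, and repair dynamics below the incipient lethal
temperature are out of scope.

## Rate law: simplified vs exact

The default injury rate is `1 / predict_time(curve, T)` — the simplified
exponential law.  Passing `exact_tc` to `injury_rate`/`integrate_profile`
restores the exact form, which multiplies the rate by
`1 − e^{−k(T − T_c)}` above the floor and zeroes it at or below.  The two
differ by 1% at T − T_c = 2z and by <0.1% at ≥3z, which is why the
simplified law is the default: the floor temperature of real species is
rarely known, and under genuinely stressful exposures it is irrelevant.
Using `exact_tc` is a documented departure from the default convention.

## Fitting

* **Static** (`StaticTDTModel`): OLS of log10(time) on temperature
  (delegated to statsmodels). z = −1/slope; the anchor is where the line
  predicts `t_ref`.  A non-negative slope raises `FitInvalidError` —
  tolerance time cannot increase with heat.  Replicates are regressed as
  supplied by default; `aggregate="median"` collapses them to
  per-temperature medians first (the CLI default, matching the
  conventional reduction of group assays).  Whether replicates should
  weight the regression is genuinely open; the median policy is the
  package's choice and is stated on the fit.
* **Dynamic, two ramps** (`DynamicTDTModel`): each ramp's observed
  dCT_max implies, for any trial z, a static anchor via the inverted ramp
  formula; the fit is the z at which both ramps imply the same anchor.
  The root is bracketed by a scan of 200 log-spaced points on
  z ∈ [0.1, 50] °C and polished by Brent's method (xtol 1e−12) —
  guaranteed convergence on the bracket, no starting guess needed.
* **Dynamic, three or more ramps**: least squares on predicted minus
  observed dCT_max (°C) over (z, ct_ref), initialized from the median of
  all pairwise exact solutions; fully deterministic, no random restarts.
  The squared-error-in-dCT_max loss is the package's choice.  A fitted z
  outside [0.1, 50] °C flags the result rather than failing it.
* **Single measurement + assumed z** (`SingleMeasurementModel`): pins the
  line of slope −1/z through the one observed point (static) or inverts
  the ramp formula at the assumed z (dynamic).  Always flagged
  `assumed-z` and `extrapolation-sensitive`.

Every fit records the time- and temperature-span of its input; any
prediction leaving that span emits an `ExtrapolationWarning` (threshold =
the span itself, no grace margin).  The ±50% z perturbation example in
the acceptance script shows why: 40-fold extrapolation in time turns a
1-minute truth into anything from 1.5 s to 3.4 min.

## Dose integration

`integrate_profile` uses first-order quadrature with a default step of
10 s (1/6 min), the resolution at which the model has been validated
against fluctuating-temperature assays; `dt` is configurable and a
coarser step than the finest profile interval triggers a
`RefinementWarning`.  Temperature within a step is the linear interpolant
of the profile sampled at the step midpoint — endpoint sampling is biased
under an exponential rate, midpoint halves that bias at no cost.  The
trajectory is not truncated at dose 1; supra-unity doses are reported
as-is.  `DoseTrajectory.t_failure` is the first grid time at which the
dose reaches 1; `time_to_dose` refines the crossing by linear
interpolation between grid points (and raises `DoseNotReached`, carrying
the final dose, if the target is never met).  Profiles dipping more than
2z below `ct_ref` are flagged with a `BelowRangeWarning`: the linear TDT
relation is unvalidated that far below the tolerated range and real
animals may repair or harden there.

Verified integrator contracts: halving dt moves the failure time by less
than dt (first order); at the default step, constant and linear-ramp
profiles agree with their closed forms to well within 0.5% across
z ∈ [1, 10], ct_ref ∈ [30, 45] and rates 0.01–1 °C/min.

## Synthetic experiments

The generator emulates the standard experimental designs:

* static series — tolerance times on a known curve at chosen assay
  temperatures, with additive Gaussian noise on log10(time) (default
  sd 0 — noiseless; recovery tests use sd 0.05, about ±12% in time, with
  5 replicates at 6 temperatures spanning the stress range);
* ramp series — dCT_max from the closed form at chosen (start, rate)
  pairs (the canonical design uses rates 0.05/0.1/0.25 °C/min from a
  benign start), with Gaussian noise in °C;
* fluctuating profiles — alternating heat/cool legs with exponentially
  distributed durations and uniformly drawn rates, reflected at the band
  edges and sampled every 10 s; the default band in tests (34.5–42.5 °C)
  keeps the whole exposure stressful, matching the regime in which the
  no-repair assumption is defensible.

Noise spaces (log10-time for static, °C for dynamic) are the spaces the
respective fits operate in.  The log-normal time noise is a stand-in, not
a biological model of inter-individual variation; real assays also share
bath/block effects and censoring that the generator does not emulate, so
passing recovery tests demonstrate correctness of the estimators under
the model, not field realism.  All generation is bit-reproducible from a
single seeded generator per call.

## Numerical choices and degenerate inputs

* Canonical units °C and minutes everywhere; profile files may use
  `time_s` (converted on read).
* With `tc_star` unset, ramp formulas take T_c* = T₀, making the baseline
  exponential exactly 1 — the recommended regime of starting ramps near
  the threshold of net injury accumulation.  The true incipient lethal
  temperature is exposed as a parameter and never inferred.
* Two-ramp fits with a duplicated condition and conflicting dCT_max raise
  an unsolvable-input error; a single condition is insufficient data.
* `segment_fractions` allows at most one open-ended segment, last; closed
  segments overshooting dose 1 report the exact crossing time rather than
  erroring; an open segment after the budget is spent is an error.
* Exit codes of the CLI: 0 success, 2 validation/parse, 3 convergence.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data:
Monte-Carlo recovery uses 200 seeds (static) and 100 seeds (dynamic);
the integrator cross-check uses 25 randomized curve/rate draws; profiles
span minutes to a day at 10-s resolution.  These sizes make the full
suite run in a few seconds while leaving the Monte-Carlo standard errors
far below the tolerances being asserted.

## Known limitations

No repair or hardening dynamics; no thermal-tolerance landscapes across
mortality levels; no cold tolerance; no confidence intervals on z (the
fitting routes report R² and residuals only); no weighted or robust
regression; predictions under profiles that spend long periods below the
(unknown) true incipient lethal temperature are computed but flagged, and
should be trusted only where that regime has been validated empirically.
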