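# Methods

## Model

Occupancy in the ED is treated as a birth–death population process: patients
arrive at a deterministic weekly flux f(t) (patients/hour, piecewise constant
over hourly bins, periodic with period 168 h) and each patient present leaves
independently with hazard β(t) (1/hour).  β is piecewise constant over four
day groups — Sunday, Monday–Thursday, Friday, Saturday — switching at the
07:00 day boundaries; 1/β is the typical length of stay.  Three views of the
process are implemented:

1. **Mean field.**  dn̄/dt = f − βn̄ has an exact closed-form solution for
   piecewise-constant rates; within each hour n̄ relaxes exponentially toward
   f/β and hours are chained analytically, so the deterministic trajectory
   carries no integration error.  For constant rates the stable fixed point
   is n* = f/β.
2. **Exact birth–death.**  An event-driven simulation of the master equation
   (gain–loss equation for Pₙ(t)).  Rates are constant within each hour, so
   waiting times are exponential and the memoryless clock is simply redrawn
   at hour boundaries.  This simulator carries demographic noise only and
   serves as the brute-force oracle for the diffusion approximation: for
   constant f, β its stationary law is Poisson with mean f/β.
3. **Langevin diffusion.**  dn = [f − β(1+ξ₂)n] dt + √(f+βn) ξ₁, with ξ₁, ξ₂
   independent zero-mean white noises of magnitude σ₁ (demographic:
   discreteness/heterogeneity of individuals, √rate-scaled) and σ₂
   (systematic: environment-level fluctuations multiplying everyone's exit
   rate).  This is the workhorse for ensemble statistics and tail estimates.

Assumptions worth stating: stays are exponential given the day group (no
aging of stays in progress beyond the β(t) schedule); noise is white (an
hourly-correlated variant of ξ₂ is what the synthetic generator actually
realizes, see below); no annual trend, seasonality, or exogenous
catastrophes; staff size is not a dynamic variable.

## Parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| β (Sunday, Midweek, Friday, Saturday) | per-patient exit rate | 1/h | 0.224, 0.244, 0.280, 0.304 |
| σ₁ | demographic noise magnitude | — | 1.1 |
| σ₂ | systematic noise magnitude | — | 0.36 |
| f(t) | weekly arrival flux | patients/h | calibrated profile, mean ≈ 14 |
| dt | Euler–Maruyama step | h | 0.01 |
| thresholds | severe / dangerous overcrowding | patients | 120 / 140 |

The default β and σ values are the rates estimated from a five-year visit
record of a large Israeli hospital ED; they imply a day-weighted mean exit
rate β̄ ≈ 0.255/h, a typical stay 1/β̄ ≈ 3.9 h and a long-run mean occupancy
f̄/β̄ ≈ 55 patients.  σ₁ ≈ 1.1 is consistent with the value 1 implied by the
diffusion approximation of a pure birth–death process, with a little extra
population heterogeneity.

## Numerical choices

- **Itô convention, Euler–Maruyama.**  The Langevin equation is derived as a
  diffusion approximation, for which Itô is the standard reading.  Noise
  increments are Gaussian with standard deviation σᵢ√dt; the demographic and
  systematic increments are mutually independent.
- **Boundary at n = 0.**  The square-root argument is clamped at
  max(f + βn, 0) and any post-step negative state is reflected to |n|.  At a
  typical occupancy of ~55 the reflection is essentially never active and
  introduces negligible bias.
- **Step size.**  dt = 0.01 h by default; dt is snapped to an integer number
  of steps per hour.  Halving dt changes hourly ensemble means by well under
  0.5% (tested).
- **float32 noise increments.**  Gaussian increments are generated in
  float32 (integrator state stays float64): the quantization (~10⁻⁸ patients
  per step) is orders of magnitude below Monte-Carlo resolution and halves
  the generation cost.
- **Sampling convention.**  Occupancy is recorded *on the hour* ("as
  recorded hourly"), both for model ensembles and for visit logs; hourly
  bins and shift windows are half-open; a patient is present on
  [arrival, departure).
- **Burn-in and initial state.**  Week ensembles start from the periodic
  mean-field state 48 h before the sampled week; with a relaxation time
  1/β ≈ 4 h this leaves no visible transient.
- **KL divergence.**  Count histograms are aligned on the union support and
  both get add-one-half smoothing (`pseudocount=0.5`) before normalizing;
  exact probability vectors are compared without smoothing.

## Synthetic visit-log generator

The generator produces agent-level records (arrival and departure timestamps
at minute resolution), so every downstream stage runs on the same data
structure as real hospital records.

- **Arrivals.**  Counts per hour are Poisson with the hour's intensity
  (equivalent to thinning a homogeneous majorant for piecewise-constant
  intensity), with event times uniform within the hour.  For σ₁ > 1, pure
  Poisson arrivals cannot carry the extra demographic noise, so arrival
  events carry batch sizes 1 + Poisson(λ_b(t)); λ_b is chosen hour by hour
  so the arrival Fano factor equals σ₁² + (σ₁²−1)·βn̄(t)/f(t), which makes
  the total injected demographic noise match the Langevin intensity
  σ₁²(f + βn̄) at every hour (n̄ from the mean-field solution).  At σ₁ = 1
  the batches degenerate to single patients.  σ₁ < 1 (sub-Poisson arrivals)
  is not representable by batching and is clamped to the Poisson level.
- **Exits.**  Each patient's hazard is β(t)·max(1 + ε_k + β σ₂²/2, 0), where
  ε_k ~ N(0, σ₂) is refreshed every hour and shared by everyone present —
  the agent-level counterpart of systematic white noise at 1-hour
  resolution.  The β σ₂²/2 mean shift removes the Jensen bias of a
  multiplier held constant over an hour (E[e^{−β(1+ε)Δ}] > e^{−βΔ}),
  aligning the generator's mean occupancy with the Itô Langevin model;
  without it the generated occupancy runs ~1.5% high.  Exit times are drawn
  by inverting the piecewise-linear cumulative hazard at a unit-exponential
  deviate.
- **Truncation.**  Stays in progress at the period end run to completion
  (within a 240-hour buffer); the metadata records how many, if any, had to
  be truncated at the buffer end (in practice none).

What the generator emulates: the weekly/daily arrival cycle, exponential
day-group stays, both noise channels, and the printed crowding moments.
What it does **not** emulate: patient covariates, revisits, the
hospitalization/discharge split, sub-exponential stay durations (real stay
STDs are below the mean; an exponential has STD = mean), annual trends,
seasonality, and catastrophe bursts.  Tests passing on synthetic data
therefore validate the pipeline's statistics and inference machinery, not
the model's adequacy for any particular real ED.

## Profile calibration

The reference weekly profile is drawn from a three-knob trapezoid family: a
night level shared by all days, a daytime trapezoid bump on weekdays, and a
weekend scale applied to the daytime component only (overnight emergencies
do not follow the workweek).  The day shape follows the typical ED arrival
curve — steep rise from 08:00, peak 10:00–16:00, decline through the evening
to an 01:00–07:00 trough; peak timing is a realism choice of this package,
not an estimate.  Calibration targets four pooled moments: hourly flux mean
14 (±2%) and STD 8 (±10%) across the 168 weekly hours, and hourly occupancy
mean 55 (±3%) and STD 27 (±10%) under the Langevin model with the reference
parameters.  The flux moments are solved analytically (base and amplitude);
the weekend scale is found by bisection on the simulated occupancy STD —
more weekend contrast moves flux variance to low frequencies that the
exit-rate filter (cutoff β ≈ 0.25/h) passes, raising the occupancy STD — and
a final uniform rescale, confined to the flux-mean band, centres the
occupancy mean.  Common random numbers make the whole search deterministic
given a seed; unreachable targets raise a calibration error carrying the
best residuals.

## Estimation

Stage I fits the four β's simultaneously by least squares between the
closed-form periodic mean-field week (driven by the empirical arrival flux)
and the observed per-weekly-hour occupancy means; 1-STD intervals come from
the Gauss–Newton curvature of the squared-error surface.  The first week of
a log is dropped from cross-week statistics as warm-up (the log starts from
an empty ED).

Stage II estimates (σ₁, σ₂) by grid search: each grid point simulates an
ensemble of weeks and scores the model's hour-by-hour STD S(σ, tᵢ) against
the data's Sᵢ (STD across weeks, per weekly hour).  Under the assumption
that the observed Sᵢ carry additional white Gaussian observation noise of
variance p², maximizing the likelihood is equivalent to minimizing
MSE(σ) = Σᵢ(Sᵢ − S(σ, tᵢ))²/n, and p² = MSE(σ*) at the optimum.  The search
is coarse-to-fine: a coarse pass over σ₁ ∈ [0.5, 2.0] × σ₂ ∈ [0, 1]
(steps 0.1/0.05) followed by one refinement pass of ±1 coarse step around
the argmin at steps 0.025/0.02.  All grid points share one vectorized
Euler–Maruyama sweep and one stream of Gaussian increments (σ only scales
the increments), so common random numbers are exact and the MSE surface is
smooth; the coarse pass uses a quarter of the realizations of the fine pass.
An argmin on the requested rectangle's boundary raises an error rather than
returning a clipped estimate.

Uncertainty: the 1-D likelihood profile along each axis,
L(σᵢ) = C·exp[−(n/2)·MSE(σᵢ)/MSE(σ*)], is fitted to a Gaussian — performed
as a likelihood-weighted parabola fit to log L over the points within ~5σ of
the peak, which is exact for a quadratic MSE profile (width w/√n for
MSE = MSE*(1 + (σ−σ*)²/w²)) and robust when the profile collapses onto a
few grid points.

The (σ₁, σ₂) objective has a shallow trade-off valley (both magnitudes
inflate S; they are separated only by the different time profiles of
√(f+βn) versus βn), so at ~200 weeks of data the argmin wanders by roughly
±0.075 in σ₁ from seed to seed.  This is a property of the experiment size,
not of the optimizer.

## Overcrowding analysis

Tail probabilities pool hourly samples over the whole week (an optional
shift filter restricts them) and quote binomial standard errors.  Elasticity
scans perturb one knob — uniform flux scale, minutes added to 1/β in all day
groups, or a proportional σ₂ change — and report the ratio of tail
probabilities against the unperturbed baseline, with common random numbers
across deltas.  The severe threshold (120 patients) is the default scan
target; thresholds are configurable.  Relative-crowding tails P(x > 1+δ)
are computed over the ten most crowded weekly shifts (Sunday–Thursday,
morning and afternoon), with per-shift patient hours obtained by trapezoid
integration of the hourly samples.

## Problem sizes

Defaults chosen for a single CPU: 10⁴ week realizations for tails and
elasticities (≈1.7 M pooled hourly samples; the dangerous tail of ~0.09%
then carries a ~3% relative standard error); 200-week synthetic studies for
estimation; 6000 realizations per refined grid point in the σ MLE (coarse
pass 1500); 1000 realizations per calibration step.  The test suite uses
smaller ensembles where the assertion tolerances allow it.

## Known limitations

- The systematic-noise channel in the generator is hourly-correlated rather
  than white; its filtered variance differs from the white-noise value by
  <1% at β ≈ 0.25/h, but the equivalence degrades if β approaches 1/h.
- Elasticity standard errors propagate independent binomial errors and are
  conservative under common random numbers.
- The calibrated profile matches pooled moments, not the hour-by-hour shape
  of any particular ED; quantities dominated by the profile's peak (the
  absolute tail probabilities) inherit a corresponding model uncertainty.
- β intervals from the Gauss–Newton curvature assume independent hourly
  residuals; residual autocorrelation within days makes them optimistic.
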