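# edcrowd

Stochastic population modelling of emergency-department (ED) crowding.

Hospital EDs are volatile environments: occupancy swings across hours and
days and produces sudden overcrowding "spikes" that average-behaviour models
miss.  `edcrowd` implements a compact stochastic population model for the
momentary patient count *n(t)*: patients arrive at a time-dependent flux
*f(t)* (patients/hour) and each independently leaves at a per-patient exit
rate *β(t)* (1/hour, so 1/β is the typical length of stay).  On top of the
mean-field dynamics

    dn̄/dt = f(t) − β(t) n̄(t)

the model carries two white-noise channels in a Langevin equation

    dn/dt = f(t) − β(t) [1 + ξ₂(t)] n(t) + √(f(t) + β(t) n(t)) · ξ₁(t)

with ⟨ξᵢ(t) ξᵢ(t+τ)⟩ = σᵢ² δ(τ): a **demographic** term ξ₁ (discreteness and
heterogeneity of individuals, √rate-scaled, magnitude σ₁) and a
**systematic** term ξ₂ (facility-level fluctuations that multiply everyone's
exit rate at once, magnitude σ₂).  Despite having only a handful of
parameters the model reproduces the full hourly occupancy distribution,
including rare overcrowding events, and — because it is mechanistic — it
answers "what-if" questions: how does the overcrowding probability respond
to more arrivals, shorter stays, or steadier operations?

The package is aimed at researchers in patient-flow modelling and
quantitatively minded ED operations analysts.  It provides:

- **`edcrowd.model`** — forward simulators: the exact closed-form mean-field
  solution, an event-driven exact birth–death simulator (the master-equation
  oracle), and a vectorized Euler–Maruyama integrator for the Langevin
  equation.
- **`edcrowd.synth`** — a synthetic visit-log generator (agent-level arrival
  and departure timestamps at minute resolution) plus calibration of a
  trapezoid weekly arrival profile to printed crowding moments, so the whole
  pipeline runs without access to protected hospital records.
- **`edcrowd.metrics`** — crowding metrics from any visit log: hourly
  arrival/exit flux, momentary occupancy, patient hours C = ∫ n dt per
  shift, relative crowding x = C_shift/⟨C⟩, cohort survival curves, and
  goodness-of-fit measures (R², Kullback–Leibler divergence).
- **`edcrowd.estimation`** — the two-stage fit: day-group exit rates β from
  the mean-field solution, then (σ₁, σ₂) by grid maximum likelihood against
  the hour-by-hour occupancy STD, with Gaussian-profile uncertainties.
- **`edcrowd.analysis`** — overcrowding tail probabilities at the severe
  (120 patients) and dangerous (140 patients) thresholds, and parameter
  elasticity scans with common random numbers.

Week conventions follow the Israeli workweek: weeks start Sunday 07:00,
days are grouped {Sunday, Monday–Thursday, Friday, Saturday} with one β
each, and shifts are morning 07–15, afternoon 15–23, night 23–07.

## Worked example

```python
import numpy as np
from edcrowd import (reference_params, calibrate_profile, generate_visit_log,
                     hourly_occupancy, tail_probability,
                     weekly_hourly_samples, elasticity_scan)

params = reference_params()                  # fitted β per day group, σ₁=1.1, σ₂=0.36
profile = calibrate_profile(params, seed=0)  # weekly arrival flux, mean 14/h

log = generate_visit_log(profile, params, n_weeks=20, seed=1)
print(f"{len(log)} visits, mean stay "
      f"{(log.departures_h - log.arrivals_h).mean():.2f} h")

_, occ = hourly_occupancy(log, skip_weeks=1)
pooled = np.sqrt((occ.std**2 + (occ.mean - occ.mean.mean())**2).mean())
print(f"hourly occupancy: mean {occ.mean.mean():.1f}, pooled STD {pooled:.1f}")

samples = weekly_hourly_samples(profile, params, n_realizations=10_000, seed=2)
p, se = tail_probability(samples, 140)
print(f"P(n > 140) = {100*p:.3f}% +/- {100*se:.3f}%")

curve = elasticity_scan(params, profile, "arrival_flux", [0.0, 0.10],
                        n_realizations=10_000, seed=2)
print(f"+10% arrivals multiplies P(n > 120) by {curve.ratio[1]:.2f}")
```

Output:

```
46051 visits, mean stay 3.99 h
hourly occupancy: mean 54.6, pooled STD 26.9
P(n > 140) = 0.086% +/- 0.002%
+10% arrivals multiplies P(n > 120) by 2.95
```

Reading the numbers: 20 synthetic weeks contain ~46k visits with a ~4-hour
typical stay; occupancy recorded on the hour averages ~55 patients with a
pooled STD of ~27 (daily/weekly cycle plus noise).  Dangerous overcrowding
(more than 140 patients present) occurs in roughly 0.09% of hours — about 7
hours per year — and, although the *mean* occupancy is linear in the arrival
flux, a 10% flux increase roughly **triples** the probability of severe
overcrowding.  That nonlinearity of the tail is the model's central
operational message.

A CLI wraps the same functionality for shell use:

```sh
edcrowd synth --weeks 20 --seed 1 --out visits.csv
edcrowd metrics visits.csv --outdir metrics/
edcrowd fit visits.csv --realizations 4000 --outdir fit/
edcrowd elasticity --knob length_of_stay --deltas 0,-10,-20 --out curve.csv
edcrowd report --out report.json
```

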