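# pinkfoot

Wintering-strategy dynamics of individually marked migratory geese.

Flyway populations of Arctic-breeding geese winter across a chain of
staging regions — here Jutland (Denmark), Friesland (the Netherlands) and
Flanders (Belgium).  For a neck-collared bird observed repeatedly within a
winter, the annual subset of regions it uses is its **wintering strategy**;
three regions give exactly seven strategies (Ju, Fr, Fl, Ju-Fr, Ju-Fl,
Fr-Fl, Ju-Fr-Fl).  `pinkfoot` turns raw resighting streams into strategy
tables and then asks the population-ecology questions that follow: how have
strategy proportions shifted over 25 winters, where did switching birds go,
how faithful are individuals to their strategy, and which environmental
factors (hunting pressure, winter temperature, agricultural land use) track
region use.  It is written for movement ecologists and biostatisticians
working with mark–resight data.

Because the underlying field resightings are not publicly deposited, the
package includes a first-class individual-based simulator that generates
populations with known ground truth and the same statistical structure,
so every estimator ships with parameter-recovery and calibration evidence.

## Models

* **Strategy classification.** For bird *i* and season *t* (labelled by its
  starting year; the season spans Sep 20 – May 10), the strategy is the set
  of regions with ≥ 1 in-window sighting.  Ringing-season winters and the
  low-sample first season are excluded.
* **Segmented trends.** Each strategy's annual share *p_s(t)* is fitted by
  continuous piecewise-linear least squares; the number of breakpoints is
  chosen by BIC, slope changes are tested with the Davies bound (the
  breakpoint vanishes under the null), and breakpoint CIs come from a
  residual bootstrap.  Pooled breakpoints define study periods.
* **Net exchange.** Within a period, net(a→b) = (c(a→b) − c(b→a)) / (all
  changes); flows below 2.5 % are filtered for display.
* **Switching GLMMs.** The change/no-change indicator for consecutive-season
  pairs is modelled as logit P(change) = x′β + u_bird (+ u_year), with
  crossed Gaussian random intercepts fitted by Laplace approximation
  (adaptive Gauss–Hermite optional for single-factor models) and Wald
  inference.  Fixed effects: year; sex/age group (3rd-winter M/F vs adult
  M/F); breeding-status transition (pair-deduplicated); previous-year
  change.
* **Driver GLMs.** Proportions staying in Jutland / using each region are
  regressed on range-scaled covariates, x′ = (x − mean) / (range/2), with
  joint crop models per region, single-covariate harvest and temperature
  models, and a screen for quadratic effects.

## Worked example

```python
from pinkfoot import (SimConfig, simulate_dataset, assign_strategies,
                      change_events, model_change_by_year)

cfg = SimConfig(seed=4)   # default study-scale conditions, 1990-2015
birds, resightings, covariates, truth = simulate_dataset(cfg)
table = assign_strategies(resightings, birds, excluded_seasons=(1990,))
events = change_events(table, birds)
print(f"{len(birds)} marked birds, {len(resightings)} resightings")
print(f"{len(table)} bird-seasons classified, {len(events)} year-on-year events")

fit = model_change_by_year(events)
print(fit.params.round(4))
print("random-intercept variance (bird):", round(fit.variances["bird_id"], 3))
print(fit.predictions.round(3))
```

prints

```
4160 marked birds, 424077 resightings
15772 bird-seasons classified, 12435 year-on-year events
             estimate      se        z    p
(Intercept)    0.1248  0.0253   4.9307  0.0
year           0.0380  0.0036  10.4386  0.0
random-intercept variance (bird): 0.502
   year   prob     lo     hi
0  1991  0.407  0.381  0.433
1  2014  0.622  0.602  0.642
```

The positive year coefficient (logit scale, per year) means the annual
probability that a bird changes its wintering strategy rose over the study
span — here from 0.41 in 1991 to 0.62 in 2014 for an average bird — while
the bird-level variance (0.50) says individuals differ substantially in
their switching propensity.

The same stages are available from a shell:

```bash
pinkfoot run-all --seed 4 --out-dir out/
```

writes `resightings.csv`, `strategy_table.csv`, `change_events.csv`,
`proportions.csv`, `trendfits.json`, per-period `net_exchange_*.csv`,
`fits.json`, `driver_fits.json` and a checksummed `manifest.json`.

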