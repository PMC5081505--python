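# icuforecast

Forecasting intensive-care-unit bed occupancy from daily SOFA scores with
random survival forests.

## The problem

ICU planners need to know how many beds the *current* patient population
will still occupy one, two, ... ten days from now. Individual length-of-stay
prediction is notoriously hard; this package instead treats the unit as a
group: it estimates, for each admitted patient, the probability of still
being in the ICU on each future day, and sums those probabilities into an
expected occupancy curve. It is aimed at researchers in clinical
informatics and operations who have daily organ-failure scores (or raw
physiology to compute them from) and want a reproducible group-level
forecasting pipeline, including baselines and an evaluation protocol.

## The model

Daily physiology is condensed into the six SOFA subscores (coagulation,
renal, liver, CNS, respiratory, cardiovascular; each 0–4) and their total.
For every patient-day from day 4 of a 3–16-day stay, a dataset entry holds
19 predictors — the six subscores for each of the previous three days plus
the number of days already admitted — and the remaining stay in days.
Discharge is the event of interest; in-ICU death right-censors it.

A **random survival forest** is grown on bootstrap samples: nodes are split
on the cut maximizing the absolute standardized two-sample **log-rank
statistic**, and each terminal node *h* of tree *b* stores the
**Nelson–Aalen** cumulative hazard of its in-bag cases,

    N_{b,h}(t) = Σ_{t_l ≤ t} d_l / I_l ,

the sum over distinct event times of deaths-over-at-risk. Dropping a
patient x down all B trees and averaging the reached terminal hazards gives
the ensemble cumulative hazard H(t, x); the survival function

    S(t, x) = exp(−H(t, x))

is the probability of still occupying a bed t days after the prediction
morning. For a unit with patients x_1..x_m, the expected occupancy at day t
is `load_pred(t) = Σ_i S(t, x_i)`.

Comparators: a random-forest regression of remaining stay (RSS splits,
terminal means, predictions turned into 0/1 occupancy curves), and a
baseline that predicts each patient's stay by sampling a random training
entry's remaining stay. Methods are scored with the error measure **E**:
per test fold, 100 times a group of 25 entries is drawn without
replacement, predicted and actual occupancy curves are truncated at day 10,
and their mean absolute error (in beds) is averaged. A bundled synthetic
cohort simulator — raw physiology with a SOFA-dependent discharge hazard —
makes the whole pipeline runnable without hospital data.

## Worked example

`examples/` holds one short script per capability. Forecasting a 25-patient
unit (`python examples/05_forecast_occupancy.py`) trains a forest on ~1,200
sliding-window entries and prints:

```
day | expected beds | actual beds
  0 |          25.0 |          25
  1 |          19.5 |          21
  2 |          15.0 |          16
  3 |          11.8 |          11
  4 |           8.9 |           9
  5 |           6.7 |           5
 ...
mean absolute error over days 0-10: 1.02 beds
```

The expected curve tracks the true emptying of the unit to about one bed.
Comparing methods (`python examples/06_evaluate_methods.py`) prints per-fold
E values; on the bundled simulator the survival forest attains the lowest
median E (≈1.5 beds), the sampling baseline ≈1.8, and the pointwise RF
regression is worst (≈3.8) — individual point predictions aggregate poorly
into group curves, which is precisely the motivation for the group-based
approach.

A thin CLI mirrors the pipeline stages:

```bash
icuforecast simulate --config cfg.yaml --out cohort.csv
icuforecast score --in cohort.csv --out sofa.csv
icuforecast build --sofa sofa.csv --stays cohort_stays.csv --out dataset.csv
icuforecast train rsf --data dataset.csv --out model.json --trees 200
icuforecast predict --model model.json --group dataset.csv --out curve.csv
```

## Layout

- `src/icuforecast/` — library: `sofa`, `synthetic`, `dataset`,
  `survival_forest`, `baselines`, `occupancy`, `evaluation`, `io`, `cli`,
  `pipeline`
- `examples/` — narrative scripts, one per capability
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
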