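# Methods

This note records the modelling assumptions, parameter choices and known
limitations of `icuforecast`, in the order the pipeline runs.

## SOFA scoring

Each of the six organ systems maps the day's worst measurement(s) to an
integer 0–4 through fixed clinical cut points (see `sofa.py` docstrings for
the tables). The printed cut-point tables overlap when read literally, so
every subscore is evaluated most-severe-first (4 down to 0) — the standard
convention and the only ordering that makes the pieces exhaustive and
mutually exclusive. Vasoactive-drug intervals are read as half-open (a, b]:
dopamine (0,5] → 2, (5,15] → 3, >15 → 4; epinephrine/norepinephrine
(0,0.1] → 3, >0.1 → 4. An absent measurement contributes 0: in routine
practice an organ judged healthy is simply not monitored, so missingness is
informative of health and is imputed at scoring time, not earlier. For
sedated patients the Glasgow coma score field is defined to carry the last
pre-sedation value; the scorer uses it directly.

## Cohort filters and the sliding window

Stays with LOS < 3 days carry too little history for a 3-day feature window
and are clinically easy to plan for; stays over 16 days are the province of
prolonged-stay models. Both are dropped, with counts logged.

Day convention: a stay of `los` days occupies a bed on days 1..los and the
patient leaves on the morning of day los+1. An entry is created on each
morning from day 4 through day los; the entry at `index_day` reads the
subscores of days index_day−3..index_day−1 (named lags d1..d3, d3 most
recent) plus days admitted (= index_day − 1). The target,
`remaining_los = los − index_day + 1`, is therefore ≥ 1: an entry with a
zero-day remaining stay would be degenerate for occupancy and is not
created. A 3-day stay passes the filter but contributes no entries.
Entries from stays ending in death keep their observed remaining time and
carry `event=False` (right-censored discharge).

## Random survival forest

- **Splitting.** At each node, `mtry` predictors are drawn; every midpoint
  between consecutive distinct values present in the node is a candidate
  cut, scored by the absolute standardized two-sample log-rank statistic.
  Candidate-cut enumeration is exhaustive rather than randomized because
  the 19 predictors have at most ~14 distinct values each. Ties break to
  the lowest variable index, then the lowest cut value, making trees
  invariant to row order.
- **Stopping.** A split is admitted only if each daughter would hold more
  than `min_unique_deaths` (d0, default 3) distinct event times *and* at
  least `min_node_size` (default 15) cases. The second condition matters
  because exit times are whole days and heavily tied: a node can hold four
  distinct event times yet only six cases, and the Nelson–Aalen estimate of
  such a tiny risk set saturates near a cumulative hazard of ~3, leaving
  exp(−CHF) ≈ 0.05 as a floor on late-horizon survival and biasing the
  summed occupancy curve upward. A minimum terminal size of 15 — the
  survival default of mainstream RSF software — keeps terminal hazards
  stable; both knobs are configurable.
- **Terminal estimates and prediction.** Terminal nodes store the
  Nelson–Aalen cumulative hazard of their in-bag cases (bootstrap
  multiplicity included); censored cases leave the risk set after their
  time, and cases censored exactly at an event time are still at risk at
  that time. Prediction averages the B reached terminal hazards as a
  right-continuous step function (no interpolation) and sets
  S(t) = exp(−CHF(t)). S is reported as the probability of *still being
  admitted* at t, i.e. P(T > t).
- **Defaults.** B = 1000 trees, mtry = ⌈√p⌉ (5 for 19 predictors), seeds
  explicit everywhere. Evaluation runs use B = 200, which is past the point
  where the cross-validated error stabilizes on datasets of a few thousand
  entries.
- **OOB error.** 1 − Harrell concordance of ensemble out-of-bag mortality
  (the per-case CHF summed over the training event-time grid) against the
  censored targets. Comparable pairs require the earlier time to be an
  observed event; risk ties count one half.

## Comparators

The RF regression mirrors a standard remaining-LOS regressor: bootstrap,
RSS-optimal splits over mtry = ⌈p/3⌉ candidates, terminal means (a
single-case node predicts that case's target), ensemble = mean over trees.
It receives no censoring mechanism by design — censored entries' observed
times are used as-is — because that is how a plain regression comparator
treats such data. Its point predictions become occupancy curves by the
counting rule `curve(t) = #{i : L_i > t}`.

The sampling baseline predicts each patient's remaining stay by drawing a
training *entry* uniformly (not a unique patient: the evaluation protocol
operates on entries). It is marginally perfectly calibrated but ignores
covariates, which makes it a genuinely competitive group-level reference.

## Occupancy curves and the error measure E

Curves live on integer days 0..horizon inclusive (default horizon 10, so 11
grid points, and the MAE denominator is 11); day 0 is the prediction
morning, on which everyone still occupies a bed. Actual occupancy uses time
to *physical* exit — a death frees a bed exactly as a discharge does — even
though the model treats death as censoring.

E for one method on one test fold: 100 times, 25 entries are sampled
without replacement from a canonicalized ordering of the fold (sorted by
patient and index day, so E is invariant to row order); predicted and
actual curves are truncated to days 0..10 and their MAE taken; E is the
mean over rounds, in beds. Cross-validation uses k = 10 folds grouped by
patient, so one patient's sliding-window entries never straddle train and
test (a `by_entry` mode reproduces the literal per-entry reading). The
sampled groups are shared across methods within a fold, pairing the
comparison; method pairs are tested with the two-sided Wilcoxon rank-sum
test with continuity correction (scipy's asymptotic Mann–Whitney U) on the
k per-fold E values, treated as unpaired samples.

## Permutation importance

Breiman–Cutler: per tree, each feature is permuted among that tree's OOB
cases only, and the increase in the tree-level OOB error (1 − concordance
for the survival forest, MSE for the regression forest) is averaged over
trees. Normalized scores clip negatives to zero and divide by the total; if
every raw importance is ≤ 0 the normalized scores fall back to uniform. A
feature constant in the OOB data is unchanged by permutation and scores 0.

## The synthetic cohort generator

The generator emulates the *structure* of an ICU information-system export:
per-day raw physiology, a stays table, discharge/death labels. Each patient
draws a latent severity ~ Normal(1.0, 0.9); every channel follows a
stationary AR(1) (autocorrelation 0.7) in a latent scale, mapped
monotonically to physiologic ranges so higher severity always means a worse
subscore. Each morning after day 1, discharge fires with probability
expit(logit(0.42) − 0.20 × yesterday's total SOFA) and death independently
with 0.004 × max(0, SOFA − 8); death wins same-morning ties; stays are
truncated at day 60 as discharges. Channels are independently unrecorded
with probability 0.05 per day. Per-patient RNG substreams derive from
(seed, patient index), so cohorts are reproducible and stable under
reordering.

These defaults were chosen to produce a realistic general-ICU case mix —
median stay ≈ 3 days, about half of stays in the modelled 3–16-day band,
deaths a small minority — with a deliberately strong dependence of the
discharge hazard on recent SOFA (Spearman ≈ 0.4 between day-3 total SOFA
and remaining stay among survivors), since the point of the simulator is to
let the downstream pipeline demonstrate signal recovery. What the simulator
does *not* emulate: readmissions, inter-ward transfers, arrival processes,
measurement-device artefacts, correlated missingness, or calibration to any
real hospital's distributions. Passing tests therefore show the pipeline
recovers structure it is designed to detect, not that it matches any
particular hospital's numbers.

`simulate_signal_dataset` is a second, feature-level generator: i.i.d.
subscore features with a geometric remaining stay whose exit probability
depends only on the most recent respiratory and CNS subscores — used to
verify that importance machinery attributes signal to exactly the features
that carry it.

## Numerical and design choices

- All randomness flows through `numpy` `SeedSequence` substreams keyed by
  (seed, stream id, ...); identical configs give byte-identical artifacts.
- The node scan bins each predictor onto its global grid of distinct values
  once per fit and scores all cuts of all candidate features with
  cumulative sums; a numba-compiled scan is used when available, with a
  vectorized numpy fallback verified equivalent in the tests.
- Step functions are right-continuous with an explicit pre-first-knot
  baseline (0 for hazards, 1 for survival).
- Degenerate cases: a forest with `max_depth=0` grows root-only trees
  (useful as an estimator oracle); an all-censored node has an identically
  zero hazard; the log-rank statistic raises on one-group or zero-variance
  input rather than returning a value.
- Problem sizes in the test-suite evaluations (2,000 simulated patients,
  ~3,000 entries, B = 200, 10 folds) were chosen as the smallest at which
  fold-level comparisons are stable.
- Provenance: file writers drop a `<path>.meta.json` sidecar with a sha256
  hash of the generating configuration rather than embedding comments in
  the CSVs, keeping the tabular artifacts strictly standard.

## Known limitations

- exp(−Nelson–Aalen) exceeds the Kaplan–Meier survival estimate in small
  risk sets; the minimum-node-size rule mitigates but does not remove the
  late-horizon optimism of the summed occupancy curve.
- Death is right censoring for the model but frees a bed in reality; in
  populations with high ICU mortality the forecast will overestimate
  occupancy, since the model only learns time-to-discharge.
- New admissions are out of scope by design: the forecast conditions on the
  current population only.
- The Wilcoxon rank-sum comparison treats per-fold E values as independent
  samples; with k = 10 folds its power is limited, and cross-validated
  folds are not strictly independent.
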