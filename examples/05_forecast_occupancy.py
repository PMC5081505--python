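"""Forecast the bed occupancy of a 25-patient unit over the next 10 days.

Summing the per-patient survival probabilities gives the expected number of
occupied beds per day; the actual curve counts who really was still there.
"""

import numpy as np

from icuforecast import (
    RsfParams,
    SimulationConfig,
    assemble_dataset,
    filter_cohort,
    fit_rsf,
    generate_cohort,
    predict_occupancy_rsf,
    real_occupancy,
    score_day,
)

stays = generate_cohort(SimulationConfig(n_patients=900, seed=33))
kept, log = filter_cohort(stays)
scored = {s.patient_id: [score_day(r) for r in s.physiology] for s in kept}
dataset = assemble_dataset(kept, scored, filter_log=log)

# hold out 25 entries as "the unit this morning"; train on the rest
rng = np.random.default_rng(1)
unit = rng.choice(len(dataset), size=25, replace=False)
rest = np.setdiff1d(np.arange(len(dataset)), unit)
model = fit_rsf(dataset.subset(rest), RsfParams(n_trees=150, seed=9))

group = dataset.subset(unit)
forecast = predict_occupancy_rsf(model, group.X, horizon=10)
actual = real_occupancy(group.remaining_los, horizon=10)

print("day | expected beds | actual beds")
for day, pred, real in zip(forecast.days, forecast.values, actual.values):
    print(f" {day:2d} | {pred:13.1f} | {real:11.0f}")
mae = np.abs(forecast.values - actual.values).mean()
print(f"mean absolute error over days 0-10: {mae:.2f} beds")
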