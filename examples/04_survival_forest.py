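"""Fit a random survival forest and read off per-patient survival curves.

The forest bootstraps the dataset entries, splits nodes by the log-rank
statistic, and stores Nelson-Aalen cumulative hazards in the terminal
nodes; S(t) = exp(-CHF(t)) is the probability a patient still occupies a
bed t days after the prediction morning.
"""

import numpy as np

from icuforecast import (
    RsfParams,
    SimulationConfig,
    assemble_dataset,
    filter_cohort,
    fit_rsf,
    generate_cohort,
    oob_concordance_error,
    score_day,
)

stays = generate_cohort(SimulationConfig(n_patients=800, seed=21))
kept, log = filter_cohort(stays)
scored = {s.patient_id: [score_day(r) for r in s.physiology] for s in kept}
dataset = assemble_dataset(kept, scored, filter_log=log)

model = fit_rsf(dataset, RsfParams(n_trees=150, seed=3))
print(f"fitted {model.n_trees} survival trees on {len(dataset)} entries")
print(f"out-of-bag error (1 - concordance): "
      f"{oob_concordance_error(model, dataset):.3f}  (0.5 = chance)")

days = np.arange(6.0)
totals = dataset.X[:, :18].sum(axis=1)
low, high = int(np.argmin(totals)), int(np.argmax(totals))
S = model.predict_survival_matrix(dataset.X[[low, high]], days)
print("P(still in the ICU) at days 0-5:")
print(f"  lowest-SOFA entry : {np.round(S[0], 2)}")
print(f"  highest-SOFA entry: {np.round(S[1], 2)}")
print("The sicker patient's curve decays more slowly: a longer expected stay.")
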