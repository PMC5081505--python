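import numpy as np
import pytest

import icuforecast as icf


@pytest.fixture(scope="session")
def small_cohort():
    """300 synthetic stays, enough for filter/window/IO round-trip tests."""
    return icf.generate_cohort(icf.SimulationConfig(n_patients=300, seed=11))


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    kept, log = icf.filter_cohort(small_cohort)
    scored = {
        s.patient_id: [icf.score_day(r) for r in s.physiology] for s in kept
    }
    return icf.assemble_dataset(kept, scored, filter_log=log)


@pytest.fixture(scope="session")
def signal_dataset():
    """Dataset where only resp-d3 and cns-d3 drive the exit hazard."""
    return icf.simulate_signal_dataset(1200, seed=4)


def random_survival_sample(rng, n):
    """Random small right-censored sample on a day grid."""
    times = rng.integers(1, 12, size=n).astype(float)
    events = rng.random(n) < 0.7
    if not events.any():
        events[rng.integers(0, n)] = True
    return times, events
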