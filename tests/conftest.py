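import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from flyfae import ApproachEvent, SimulationConfig, simulate_cohort


def make_events(spec_rows):
    """Events from (fly_id, day, onset, duration[, label[, retained]]) rows."""
    out = []
    for row in spec_rows:
        fly, day, onset, dur = row[:4]
        label = row[4] if len(row) > 4 else "unlabeled"
        retained = row[5] if len(row) > 5 else True
        out.append(ApproachEvent(fly, day, onset, dur, label, retained))
    return out


@pytest.fixture(scope="session")
def small_cohort():
    """A small seeded cohort shared by read-only tests."""
    cfg = SimulationConfig(seed=11, n_flies=6, n_days=2)
    plate, truth = simulate_cohort(cfg)
    return cfg, plate, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
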