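import numpy as np
import pytest

import timecourt as tc


def tuned_population(gain: float = 18.0, baseline: float = 4.0):
    """2 neurons per preferred duration + 4 tiling time fields + 2 untuned."""
    pop = []
    for d in (1500, 3000, 6000):
        for _ in range(2):
            pop.append(
                tc.RateProfileSpec("duration_tuned", baseline=baseline, duration_gain={d: gain})
            )
    for c in (100, 400, 700, 1000):
        pop.append(
            tc.RateProfileSpec("time_field", baseline=3.0, gain=25.0, center_ms=c, width_ms=150.0)
        )
    pop += [tc.RateProfileSpec("untuned", baseline=5.0) for _ in range(2)]
    return pop


@pytest.fixture(scope="session")
def task_small():
    return tc.TaskConfig(n_correct_trials_per_cue=10)


@pytest.fixture(scope="session")
def behavior_model():
    return tc.BehaviorModel(weber_fraction=0.15, mean_offset_fraction=0.1, optout_prob=0.2, lapse_prob=0.08)


@pytest.fixture(scope="session")
def tuned_session(task_small, behavior_model):
    """A small mixed-archetype synthetic session shared across tests."""
    return tc.generate_session(task_small, behavior_model, tuned_population(), seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
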