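"""Generate a synthetic timing session and write it to disk.

Builds a small population of ground-truth neuron archetypes, simulates a
cued duration-estimation session (two cue protocols x three durations),
and saves trials.csv / spikes.csv / neurons.json.
"""

import numpy as np

import timecourt as tc

task = tc.TaskConfig(n_correct_trials_per_cue=12)
model = tc.BehaviorModel(weber_fraction=0.2, mean_offset_fraction=0.1, optout_prob=0.3, lapse_prob=0.05)
population = (
    [tc.RateProfileSpec("duration_tuned", baseline=4, duration_gain={d: 15}) for d in (1500, 3000, 6000)]
    + [tc.RateProfileSpec("time_field", baseline=3, gain=25, center_ms=c, width_ms=150) for c in (200, 600, 1000)]
    + [tc.RateProfileSpec("ramp_linear", baseline=2, gain=20), tc.RateProfileSpec("untuned", baseline=5)]
)

session = tc.generate_session(task, model, population, seed=7)
session.validate()
session.to_dir("scratch/example_session")

trials = session.trials
print(f"{len(trials)} trials, {len(session.spikes)} spikes from {len(population)} neurons")
print(trials.outcome.value_counts().to_string())
print(f"outcome counts above; correct trials per cue = {task.n_correct_trials_per_cue} by design.")
print("Session written to scratch/example_session (trials.csv, spikes.csv, neurons.json).")
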