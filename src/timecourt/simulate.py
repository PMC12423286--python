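"""Synthetic session generator with ground-truth neuron archetypes.

Emulates a cued duration-estimation task: two cue protocols (colored
squares, white shapes) x three target durations (1500/3000/6000 ms), a
delayed-retry trial engine, scalar (Weber-like) response-time variability,
strategic opt-outs on the longest duration, and inhomogeneous-Poisson spike
trains from parameterized firing-rate archetypes (duration-tuned,
time-field/sequence, ramping, temporally scaling, protocol-sensitive,
untuned).  Every generated quantity carries its ground truth so downstream
analyses can be recovery-tested.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import label_trial

ARCHETYPES = (
    "duration_tuned",
    "time_field",
    "ramp_linear",
    "ramp_exponential",
    "ramp_sigmoidal",
    "scaled_template",
    "protocol_modulated",
    "untuned",
)

#: Default cue identities: one cue per (protocol, duration).
DEFAULT_PROTOCOLS = {
    "color": {1500: "red", 3000: "blue", 6000: "green"},
    "shape": {1500: "ring", 3000: "triangle", 6000: "plus"},
}


class GenerationError(RuntimeError):
    """Raised when a session request cannot be satisfied."""


@dataclass
class TaskConfig:
    """Structure of the timing task.

    All times in ms.  The trial timeline, relative to cue onset, is:
    ready period (``ready_ms``), pre-cue gap (``pre_cue_ms``), cue
    (``cue_ms``), then a wait of the cued duration and a response ("go")
    window of equal length.  The earliest response counted as correct is
    ``correct_fraction_threshold * duration`` after cue offset.
    """

    durations: tuple[int, ...] = (1500, 3000, 6000)
    protocols: dict[str, dict[int, str]] = field(
        default_factory=lambda: {p: dict(d) for p, d in DEFAULT_PROTOCOLS.items()}
    )
    pre_cue_ms: float = 300.0
    cue_ms: float = 600.0
    ready_ms: float = 600.0
    correct_fraction_threshold: float = 0.8
    n_correct_trials_per_cue: int = 20
    seed: int | None = None

    def __post_init__(self) -> None:
        d = tuple(self.durations)
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("durations must be strictly increasing")
        self.durations = d
        for proto, cues in self.protocols.items():
            if set(cues) != set(d):
                raise ValueError(f"protocol {proto!r} must define one cue per duration")

    @property
    def t_ready(self) -> float:
        """Ready-period entry time, ms relative to cue onset."""
        return -(self.ready_ms + self.pre_cue_ms)

    def earliest_correct(self, duration: float) -> float:
        return self.correct_fraction_threshold * duration

    def response_window(self, duration: float) -> float:
        """Length of the go period (equals the wait duration)."""
        return float(duration)


@dataclass
class BehaviorModel:
    """Stochastic response-time model.

    Non-opt-out response times for target ``d`` are Gaussian with mean
    ``d * (1 + mean_offset_fraction)`` and SD ``weber_fraction * mean``
    (scalar timing by construction), truncated at 0 by resampling.  With
    probability ``optout_prob`` a longest-duration trial is aborted within
    the first 400 ms of the wait; with probability ``lapse_prob`` any trial
    ends as a late error (no response within the go window).
    """

    weber_fraction: float = 0.2
    mean_offset_fraction: float = 0.1
    optout_prob: float = 0.3
    lapse_prob: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.weber_fraction < 0:
            raise ValueError("weber_fraction must be >= 0")
        for name in ("optout_prob", "lapse_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class RateProfileSpec:
    """Ground-truth firing-rate archetype for one synthetic neuron.

    ``baseline`` and gains are in Hz.  Time-locked shape parameters
    (``center_ms``, ``width_ms``, ``onset_ms``) live in wait-period
    coordinates (ms after cue offset).  ``duration_gain`` maps target
    duration -> Hz for duration-tuned cells; ``protocol_gain`` maps
    protocol -> Hz for protocol-sensitive cells.  A ``protocol_filter``
    restricts duration tuning to one protocol (used to build populations
    whose duration code does not generalize across cue sets).
    """

    archetype: str = "untuned"
    baseline: float = 5.0
    gain: float = 10.0
    duration_gain: dict[int, float] | None = None
    protocol_gain: dict[str, float] | None = None
    center_ms: float = 600.0
    width_ms: float = 200.0
    onset_ms: float = 0.0
    curvature: float = 3.0
    midpoint_frac: float = 0.5
    steepness: float = 10.0
    template: np.ndarray | None = None
    template_dt_ms: float = 10.0
    d_reference: float = 1500.0
    protocol_filter: str | None = None
    preferred_ms: int | None = None

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype: {self.archetype!r}")
        if self.baseline < 0:
            raise ValueError("baseline rate must be >= 0")
        if self.archetype == "duration_tuned" and self.duration_gain is None:
            raise ValueError("duration_tuned requires duration_gain")
        if self.archetype == "protocol_modulated" and self.protocol_gain is None:
            raise ValueError("protocol_modulated requires protocol_gain")
        if self.archetype == "scaled_template" and self.template is None:
            raise ValueError("scaled_template requires a template")
        if self.template is not None:
            self.template = np.asarray(self.template, dtype=float)
        if self.preferred_ms is None and self.duration_gain:
            self.preferred_ms = max(self.duration_gain, key=self.duration_gain.__getitem__)


def _ramp_shape(u: np.ndarray, archetype: str, spec: RateProfileSpec) -> np.ndarray:
    """Normalized monotone ramp on u in [0, 1] with f(0)=0, f(1)=1."""
    if archetype == "ramp_linear":
        return u
    if archetype == "ramp_exponential":
        c = spec.curvature
        return (np.expm1(c * u)) / np.expm1(c)
    # sigmoidal
    k, m = spec.steepness, spec.midpoint_frac
    s = 1.0 / (1.0 + np.exp(-k * (u - m)))
    s0 = 1.0 / (1.0 + np.exp(k * m))
    s1 = 1.0 / (1.0 + np.exp(-k * (1.0 - m)))
    return (s - s0) / (s1 - s0)


def make_rate_profile(
    spec: RateProfileSpec,
    duration: float,
    protocol: str | None = None,
    *,
    cue_ms: float = 600.0,
    t_start: float = -900.0,
    t_stop: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a neuron's ground-truth rate function on a 1 ms grid.

    Returns ``(t, rate_hz)`` with ``t`` in ms relative to cue onset, from
    ``t_start`` to ``t_stop`` (default: end of the wait period).  Condition
    information becomes available at cue onset, so duration- and
    protocol-dependent gains apply from t=0 onward; wait-anchored shapes
    (time fields, ramps, scaled templates) unfold from cue offset.
    Negative composed rates are clipped to 0 with a warning.
    """
    if t_stop is None:
        t_stop = cue_ms + duration
    t = np.arange(t_start, t_stop, 1.0)
    rate = np.full(t.shape, float(spec.baseline))
    post_cue = t >= 0.0  # condition known from cue onset
    tau = t - cue_ms  # wait-period clock
    a = spec.archetype

    if a == "duration_tuned":
        g = float(spec.duration_gain.get(int(duration), 0.0))
        if spec.protocol_filter is not None and protocol != spec.protocol_filter:
            g = 0.0
        rate[post_cue] += g
    elif a == "protocol_modulated":
        g = float(spec.protocol_gain.get(protocol, 0.0)) if protocol is not None else 0.0
        rate[post_cue] += g
    elif a == "time_field":
        rate += spec.gain * np.exp(-0.5 * ((tau - spec.center_ms) / spec.width_ms) ** 2)
    elif a in ("ramp_linear", "ramp_exponential", "ramp_sigmoidal"):
        onset, top = spec.onset_ms, float(duration)
        u = np.clip((tau - onset) / (top - onset), 0.0, 1.0)
        rate += spec.gain * _ramp_shape(u, a, spec)
    elif a == "scaled_template":
        stretch = duration / spec.d_reference
        t_template = np.arange(len(spec.template)) * spec.template_dt_ms
        inside = (tau >= 0) & (tau <= t_template[-1] * stretch)
        rate[inside] += np.interp(tau[inside] / stretch, t_template, spec.template)
    # untuned: baseline only

    if np.any(rate < 0):
        warnings.warn("negative composed rates clipped to 0", stacklevel=2)
        rate = np.clip(rate, 0.0, None)
    return t, rate


def sample_spikes(
    t: np.ndarray,
    rate_hz: np.ndarray,
    n_trials: int,
    seed=None,
    *,
    t_end: float | None = None,
) -> list[np.ndarray]:
    """Draw spike trains from an inhomogeneous Poisson process by thinning.

    ``t``/``rate_hz`` sample the rate function (ms / Hz).  Returns one
    sorted spike-time array per trial; the expected count per trial equals
    the integral of the rate over the span.  ``t_end`` optionally truncates
    the sampling span (used for per-trial response-dependent cutoffs).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.asarray(t, dtype=float)
    rate_hz = np.asarray(rate_hz, dtype=float)
    t0 = t[0]
    t1 = t[-1] if t_end is None else min(float(t_end), t[-1])
    if t1 <= t0:
        return [np.empty(0) for _ in range(n_trials)]
    mask = t <= t1
    rmax = float(rate_hz[mask].max(initial=0.0))
    out = []
    span_s = (t1 - t0) / 1000.0
    for _ in range(n_trials):
        if rmax <= 0:
            out.append(np.empty(0))
            continue
        n = rng.poisson(rmax * span_s)
        cand = rng.uniform(t0, t1, size=n)
        accept = rng.uniform(0.0, rmax, size=n) < np.interp(cand, t, rate_hz)
        out.append(np.sort(cand[accept]))
    return out


def generate_behavioral_rts(
    task: TaskConfig,
    model: BehaviorModel,
    n: int,
    seed=None,
) -> pd.DataFrame:
    """Generate ``n`` response times per target duration.

    Returns a DataFrame with columns ``duration``, ``rt_ms`` (ms from cue
    offset; NaN for late-error lapses) and ``outcome``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    longest = max(task.durations)
    for d in task.durations:
        for _ in range(n):
            rt = _draw_rt(d, d == longest, model, rng)
            outcome = label_trial(rt, d, correct_fraction=task.correct_fraction_threshold)
            rows.append((d, rt, outcome))
    return pd.DataFrame(rows, columns=["duration", "rt_ms", "outcome"])


def _draw_rt(duration: float, is_longest: bool, model: BehaviorModel, rng) -> float | None:
    if rng.uniform() < model.lapse_prob:
        return None
    if is_longest and rng.uniform() < model.optout_prob:
        return float(rng.uniform(0.0, 400.0))
    mean = duration * (1.0 + model.mean_offset_fraction)
    sd = model.weber_fraction * mean
    rt = rng.normal(mean, sd) if sd > 0 else mean
    while rt <= 0:  # truncate at 0 by resampling (keeps the mode intact)
        rt = rng.normal(mean, sd)
    return float(rt)


@dataclass
class SessionRecording:
    """One recording session: trial table, spike table, neuron ground truth.

    ``trials`` columns: trial_id, cue, protocol, duration_ms, t_ready,
    t_cue_on, t_cue_off, t_response (all ms relative to cue onset;
    t_response is NaN for late errors), rt_ms (ms from cue offset), outcome.
    ``spikes`` columns: neuron_id, trial_id, t_ms (ms relative to cue
    onset).  ``specs`` maps neuron_id -> :class:`RateProfileSpec` when the
    session is synthetic.
    """

    trials: pd.DataFrame
    spikes: pd.DataFrame
    neurons: pd.DataFrame
    specs: dict[int, RateProfileSpec] = field(default_factory=dict)
    task: TaskConfig | None = None

    @property
    def neuron_ids(self) -> np.ndarray:
        return self.neurons["neuron_id"].to_numpy()

    def validate(self) -> None:
        """Check the structural invariants of the recording."""
        known = set(self.trials["trial_id"])
        if not set(self.spikes["trial_id"]).issubset(known):
            raise ValueError("spike table references unknown trial ids")
        merged = self.spikes.merge(self.trials, on="trial_id")
        end = np.where(
            np.isnan(merged["t_response"]),
            np.inf,
            merged["t_response"] + 500.0,
        )
        if ((merged["t_ms"] < merged["t_ready"]) | (merged["t_ms"] > end)).any():
            raise ValueError("spike outside its trial's time span")
        if not self.trials["outcome"].isin(OUTCOME_SET).all():
            raise ValueError("unknown outcome label")

    def to_dir(self, path) -> None:
        """Write trials.csv, spikes.csv and neurons.json to ``path``."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(path / "trials.csv", index=False)
        self.spikes.to_csv(path / "spikes.csv", index=False)
        payload = {}
        for nid, spec in self.specs.items():
            d = asdict(spec)
            if d.get("template") is not None:
                d["template"] = np.asarray(d["template"]).tolist()
            payload[str(nid)] = d
        (path / "neurons.json").write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_dir(cls, path, task: TaskConfig | None = None) -> "SessionRecording":
        path = Path(path)
        trials = pd.read_csv(path / "trials.csv")
        spikes = pd.read_csv(path / "spikes.csv")
        specs: dict[int, RateProfileSpec] = {}
        f = path / "neurons.json"
        if f.exists():
            for nid, d in json.loads(f.read_text()).items():
                if d.get("template") is not None:
                    d["template"] = np.asarray(d["template"], dtype=float)
                if d.get("duration_gain"):
                    d["duration_gain"] = {int(k): v for k, v in d["duration_gain"].items()}
                specs[int(nid)] = RateProfileSpec(**d)
        neurons = pd.DataFrame(
            {
                "neuron_id": sorted(specs) if specs else sorted(spikes["neuron_id"].unique()),
            }
        )
        neurons["archetype"] = [
            specs[n].archetype if n in specs else "unknown" for n in neurons["neuron_id"]
        ]
        return cls(trials, spikes, neurons, specs, task)


OUTCOME_SET = {"correct", "early_error", "late_error", "aborted"}


def generate_session(
    task: TaskConfig,
    behavior: BehaviorModel,
    population: list[RateProfileSpec],
    seed=None,
    *,
    late_error_mode: str = "veridical",
    max_attempts_factor: int = 200,
) -> SessionRecording:
    """Simulate a full session: trials, outcomes, and spikes for all neurons.

    Trials are generated per cue with a delayed-retry engine (errors are
    kept and the cue repeats later) until ``task.n_correct_trials_per_cue``
    correct trials exist per cue, then randomly interleaved.  Every neuron
    fires on every trial according to its archetype profile for the trial's
    duration and protocol.

    ``late_error_mode`` controls the rate profile used on late-error
    trials: "veridical" (the cued duration's profile), "swapped" (a wrong
    duration's profile — models timing failures whose population state
    resembles a different target), or "untuned" (baseline only).
    """
    if not population:
        raise ValueError("population must be non-empty")
    if late_error_mode not in ("veridical", "swapped", "untuned"):
        raise ValueError(f"unknown late_error_mode: {late_error_mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    longest = max(task.durations)

    rows = []
    for protocol in sorted(task.protocols):
        for d in task.durations:
            cue = task.protocols[protocol][d]
            n_corr = 0
            attempts = 0
            limit = max_attempts_factor * task.n_correct_trials_per_cue
            while n_corr < task.n_correct_trials_per_cue:
                attempts += 1
                if attempts > limit:
                    raise GenerationError(
                        f"could not reach {task.n_correct_trials_per_cue} correct "
                        f"trials for cue {cue!r} within {limit} attempts"
                    )
                rt = _draw_rt(d, d == longest, behavior, rng)
                outcome = label_trial(rt, d, correct_fraction=task.correct_fraction_threshold)
                if outcome == "correct":
                    n_corr += 1
                rows.append((cue, protocol, d, rt, outcome))

    order = rng.permutation(len(rows))
    trials = pd.DataFrame(
        [rows[i] for i in order],
        columns=["cue", "protocol", "duration_ms", "rt_ms", "outcome"],
    )
    trials.insert(0, "trial_id", np.arange(len(trials)))
    trials["t_ready"] = task.t_ready
    trials["t_cue_on"] = 0.0
    trials["t_cue_off"] = task.cue_ms
    trials["t_response"] = task.cue_ms + trials["rt_ms"]

    # spike emission: cache one profile per (neuron, duration, protocol)
    swap = {d: task.durations[(i + 1) % len(task.durations)] for i, d in enumerate(task.durations)}
    spike_rows = {"neuron_id": [], "trial_id": [], "t_ms": []}
    for nid, spec in enumerate(population):
        profiles = {}
        for protocol in task.protocols:
            for d in task.durations:
                stop = task.cue_ms + 2.0 * d + 500.0
                profiles[(d, protocol)] = make_rate_profile(
                    spec, d, protocol, cue_ms=task.cue_ms, t_start=task.t_ready, t_stop=stop
                )
        untuned_profiles = None
        if late_error_mode == "untuned":
            flat = RateProfileSpec(archetype="untuned", baseline=spec.baseline)
            untuned_profiles = {
                k: make_rate_profile(
                    flat, k[0], k[1], cue_ms=task.cue_ms, t_start=task.t_ready,
                    t_stop=task.cue_ms + 2.0 * k[0] + 500.0,
                )
                for k in profiles
            }
        for trial in trials.itertuples(index=False):
            d, protocol = int(trial.duration_ms), trial.protocol
            key = (d, protocol)
            if trial.outcome == "late_error":
                if late_error_mode == "swapped":
                    t_prof, r_prof = profiles[(swap[d], protocol)]
                elif late_error_mode == "untuned":
                    t_prof, r_prof = untuned_profiles[key]
                else:
                    t_prof, r_prof = profiles[key]
                t_end = task.cue_ms + 2.0 * d
            else:
                t_prof, r_prof = profiles[key]
                t_end = min(trial.t_response + 500.0, task.cue_ms + 2.0 * d + 500.0)
            (spk,) = sample_spikes(t_prof, r_prof, 1, rng, t_end=t_end)
            spike_rows["neuron_id"].append(np.full(len(spk), nid))
            spike_rows["trial_id"].append(np.full(len(spk), trial.trial_id))
            spike_rows["t_ms"].append(spk)

    spikes = pd.DataFrame(
        {
            "neuron_id": np.concatenate(spike_rows["neuron_id"]).astype(int)
            if spike_rows["neuron_id"]
            else np.empty(0, int),
            "trial_id": np.concatenate(spike_rows["trial_id"]).astype(int)
            if spike_rows["trial_id"]
            else np.empty(0, int),
            "t_ms": np.concatenate(spike_rows["t_ms"]) if spike_rows["t_ms"] else np.empty(0),
        }
    )
    neurons = pd.DataFrame(
        {
            "neuron_id": np.arange(len(population)),
            "archetype": [s.archetype for s in population],
        }
    )
    return SessionRecording(trials, spikes, neurons, dict(enumerate(population)), task)
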