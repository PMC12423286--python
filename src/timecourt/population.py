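"""Population-level information timecourses and state-space geometry.

Sliding-window omega-squared percent-explained-variance (PEV) for target
duration, cue protocol and their interaction, and PCA state-space
trajectories with Euclidean distance, amplitude and velocity descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from . import preprocessing
from ._stats import FACTORS, balanced_anova_ss, omega_squared

__all__ = [
    "PevTimecourse",
    "pev_timecourse",
    "TrajectorySet",
    "build_trajectories",
    "trajectory_distances",
    "trajectory_kinematics",
]


# ---------------------------------------------------------------------------
# omega-squared PEV timecourse


@dataclass
class PevTimecourse:
    """Time-resolved population PEV with a shuffled-label baseline.

    ``omega2[factor]`` is the mean-over-neurons, mean-over-resamples
    percent explained variance per window; ``baseline`` the same quantity
    under label shuffling (``n_resamples * n_shuffles_per_resample``
    reshuffles in total).
    """

    times: np.ndarray  # window centers, ms relative to cue onset
    omega2: dict[str, np.ndarray]
    sem: dict[str, np.ndarray]
    baseline: dict[str, np.ndarray]
    n_resamples: int
    n_shuffles_per_resample: int
    excluded: list[tuple[int, str]] = field(default_factory=list)

    @property
    def total_shuffles(self) -> int:
        return self.n_resamples * self.n_shuffles_per_resample


def pev_timecourse(
    session,
    neuron_ids=None,
    *,
    window_ms: float = 200.0,
    step_ms: float = 20.0,
    span: tuple[float, float] = (-300.0, 2400.0),
    min_trials: int = 15,
    n_resamples: int = 20,
    n_shuffles: int = 50,
    seed=None,
) -> PevTimecourse:
    """Sliding-window two-way ANOVA omega-squared timecourse.

    ``span`` is in ms relative to cue onset (the default runs from pre-cue
    onset to 1800 ms after cue offset).  Neurons need ``min_trials``
    correct trials per duration x protocol cell; each resample draws
    exactly that many per cell per neuron (a balanced design, so the
    closed-form decomposition applies) and omega-squared is averaged
    across neurons.  The baseline repeats each resample with
    ``n_shuffles`` label shuffles (the default 20 x 50 = 1000 reshuffles).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # window-binned rates relative to cue onset: shift to cue-offset frame
    task = session.task
    cue_ms = task.cue_ms if task is not None else 600.0
    off_span = (span[0] - cue_ms, span[1] - cue_ms)
    aligned = preprocessing.extract_window_rates(
        session, "cue_offset", off_span, step_ms, neuron_ids=neuron_ids
    )
    k = int(round(window_ms / step_ms))
    csum = np.cumsum(aligned.rates, axis=-1)
    csum = np.concatenate([np.zeros(csum.shape[:-1] + (1,)), csum], axis=-1)
    win = (csum[..., k:] - csum[..., :-k]) / k  # (trials, neurons, windows)
    centers = span[0] + step_ms * np.arange(win.shape[-1]) + window_ms / 2.0

    tinfo = session.trials.set_index("trial_id").loc[aligned.trial_ids]
    durs = np.array(sorted(tinfo["duration_ms"].unique()))
    prots = np.array(sorted(tinfo["protocol"].unique()))
    ia_all = np.searchsorted(durs, tinfo["duration_ms"].to_numpy())
    ib_all = np.searchsorted(prots, tinfo["protocol"].to_numpy())

    cells = [
        np.where((ia_all == a) & (ib_all == b))[0]
        for a in range(len(durs))
        for b in range(len(prots))
    ]
    excluded = []
    if min(len(c) for c in cells) < min_trials:
        raise ValueError(f"need >= {min_trials} correct trials per duration x protocol cell")

    n_neu = win.shape[1]
    n_win = win.shape[2]
    ia = np.repeat(np.arange(len(durs)), min_trials * len(prots))
    ib = np.tile(np.repeat(np.arange(len(prots)), min_trials), len(durs))

    true_series = {f: np.empty((n_resamples, n_win)) for f in FACTORS}
    base_sum = {f: np.zeros(n_win) for f in FACTORS}
    for r in range(n_resamples):
        # independent per-neuron trial draws (pseudopopulation convention)
        y = np.empty((n_neu, n_win, len(ia)))
        col = 0
        for a in range(len(durs)):
            for b in range(len(prots)):
                pool = cells[a * len(prots) + b]
                for i in range(n_neu):
                    idx = rng.choice(pool, size=min_trials, replace=False)
                    y[i, :, col : col + min_trials] = win[idx, i, :].T
                col += min_trials
        res = balanced_anova_ss(y, ia, ib, len(durs), len(prots))
        om = omega_squared(res)
        for f in FACTORS:
            true_series[f][r] = om[f].mean(axis=0)
        for _ in range(n_shuffles):
            perm = rng.permutation(len(ia))
            res_s = balanced_anova_ss(y[..., perm], ia, ib, len(durs), len(prots))
            om_s = omega_squared(res_s)
            for f in FACTORS:
                base_sum[f] += om_s[f].mean(axis=0)

    omega2 = {f: true_series[f].mean(axis=0) for f in FACTORS}
    sem = {f: true_series[f].std(axis=0, ddof=1) / np.sqrt(n_resamples) for f in FACTORS}
    total = n_resamples * n_shuffles
    baseline = {f: base_sum[f] / total if total else np.zeros(n_win) for f in FACTORS}
    return PevTimecourse(centers, omega2, sem, baseline, n_resamples, n_shuffles, excluded)


# ---------------------------------------------------------------------------
# state-space trajectories


@dataclass
class TrajectorySet:
    """Per-duration 3-D PCA trajectories on a common basis.

    ``trajectories[d]`` is (time x 3); ``times[d]`` the matching ms axis
    relative to cue onset.  Event markers give cue onset/offset and the
    1200/2400 ms wait milestones in the same frame.
    """

    durations: np.ndarray
    times: dict[float, np.ndarray]
    trajectories: dict[float, np.ndarray]
    explained_variance_ratio: np.ndarray
    event_markers: dict[str, float]
    step_ms: float


def build_trajectories(
    session,
    neuron_ids=None,
    *,
    sigma_ms: float = 200.0,
    step_ms: float = 20.0,
    min_trials: int = 30,
    n_components: int = 3,
    pre_ms: float = 900.0,
) -> TrajectorySet:
    """Condition-averaged population trajectories in a shared PCA space.

    For each duration the window runs from ``-pre_ms`` before cue onset to
    the earliest-correct point of the wait (spans 2700/3900/6300 ms for
    the standard task).  Per neuron: trial-average at ``step_ms``
    resolution, Gaussian-smooth (``sigma_ms``), then z-score using the
    concatenation across durations.  PCA is fit on that concatenation (a
    common basis, so between-condition distances are meaningful) and each
    duration's segment is projected onto the first ``n_components``
    components.  Component signs are fixed by making each component's
    largest-magnitude loading positive.
    """
    task = session.task
    cue_ms = task.cue_ms if task is not None else 600.0
    frac = task.correct_fraction_threshold if task is not None else 0.8
    trials = session.trials
    durations = np.array(sorted(trials["duration_ms"].unique()), dtype=float)

    segments = {}
    times = {}
    n_neu = None
    for d in durations:
        span = (-(pre_ms + cue_ms), frac * d)  # relative to cue offset
        tids = trials[(trials["outcome"] == "correct") & (trials["duration_ms"] == d)]["trial_id"]
        a = preprocessing.extract_window_rates(
            session, "cue_offset", span, step_ms, trial_ids=tids, neuron_ids=neuron_ids
        )
        if a.rates.shape[0] < min_trials:
            raise ValueError(f"need >= {min_trials} correct trials for duration {d}")
        mean = a.rates.mean(axis=0)  # neurons x time
        sm = preprocessing.gaussian_smooth(mean, sigma_ms, step_ms, axis=-1)
        segments[d] = sm
        times[d] = a.bin_centers + cue_ms  # back to cue-onset frame
        n_neu = sm.shape[0]
    if n_neu is None or n_neu < 4:
        raise ValueError("need at least 4 neurons")

    concat = np.concatenate([segments[d] for d in durations], axis=1)  # neurons x total_time
    mu = concat.mean(axis=1, keepdims=True)
    sd = concat.std(axis=1, keepdims=True)
    if int((sd.ravel() > 0).sum()) < 3:
        raise ValueError("need at least 3 neurons with nonzero variance")
    z = np.zeros_like(concat)
    np.divide(concat - mu, sd, out=z, where=sd > 0)

    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(z.T)  # total_time x comps
    # deterministic sign: largest-|loading| positive per component
    for c in range(n_components):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, c] *= -1.0

    trajectories = {}
    k = 0
    for d in durations:
        n_t = segments[d].shape[1]
        trajectories[d] = scores[k : k + n_t]
        k += n_t
    markers = {
        "cue_on": 0.0,
        "cue_off": cue_ms,
        "wait_1200": cue_ms + 1200.0,
        "wait_2400": cue_ms + 2400.0,
    }
    return TrajectorySet(
        durations, times, trajectories, pca.explained_variance_ratio_, markers, step_ms
    )


def trajectory_distances(ts: TrajectorySet) -> dict[tuple[float, float], np.ndarray]:
    """Pairwise Euclidean distance series between duration trajectories.

    Each pair is compared over the overlap of their time spans (the
    trajectories share a grid by construction).  Returns
    ``{(d1, d2): (times, distances)}`` for the three distinct pairs.
    """
    out = {}
    ds = ts.durations
    for i in range(len(ds)):
        for j in range(i + 1, len(ds)):
            a, b = ts.trajectories[ds[i]], ts.trajectories[ds[j]]
            n = min(len(a), len(b))
            dist = np.linalg.norm(a[:n] - b[:n], axis=1)
            out[(float(ds[i]), float(ds[j]))] = (ts.times[ds[i]][:n], dist)
    return out


def trajectory_kinematics(
    trajectory: np.ndarray,
    times: np.ndarray,
    *,
    reference_time: float = 0.0,
    boxcar_bins: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude and velocity series of one state-space trajectory.

    Amplitude(t) is the Euclidean distance from the state at t to the
    state at ``reference_time`` (cue onset by default, so the reference
    amplitude is exactly 0).  Velocity is the distance between consecutive
    states divided by the time step in seconds, boxcar-smoothed over
    ``boxcar_bins`` (edge-renormalized); it has one fewer sample than the
    trajectory.
    """
    trajectory = np.asarray(trajectory, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(trajectory) < 6:
        raise ValueError("need at least 6 time points")
    ref = trajectory[int(np.argmin(np.abs(times - reference_time)))]
    amplitude = np.linalg.norm(trajectory - ref, axis=1)
    steps = np.diff(times) / 1000.0
    speed = np.linalg.norm(np.diff(trajectory, axis=0), axis=1) / steps
    kernel = np.ones(boxcar_bins)
    norm = np.convolve(np.ones(len(speed)), kernel, mode="same")
    velocity = np.convolve(speed, kernel, mode="same") / norm
    return amplitude, velocity
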