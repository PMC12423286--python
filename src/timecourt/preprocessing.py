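"""Trial labeling, neuron inclusion, event-aligned rate extraction, scaling.

Conventions used throughout the package:

* all times are in milliseconds relative to **cue onset** unless a function
  says otherwise (behavioral response times are measured from cue offset,
  i.e. from wait-period onset, matching how the task defines them);
* all bins and analysis windows are half-open ``[start, end)``, so a spike
  exactly at a window end is excluded and never double-counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Possible trial outcomes.  "aborted" covers responses made before the
#: earliest band that the task treats as a genuine estimate (< 1200 ms into
#: the wait), including strategic opt-outs on the longest duration.
OUTCOMES = ("correct", "early_error", "late_error", "aborted")

#: Earliest wait time treated as a genuine timing response (ms from cue
#: offset).  Responses before this are aborts regardless of cued duration.
EARLY_FLOOR_MS = 1200.0


def label_trial(
    response_ms: float | None,
    duration: float,
    *,
    correct_fraction: float = 0.8,
    early_floor_ms: float = EARLY_FLOOR_MS,
) -> str:
    """Classify a trial outcome from its response time.

    Parameters
    ----------
    response_ms
        Response time in ms measured from cue offset (wait onset), or
        ``None``/NaN if the subject never left the light barrier within the
        response window.
    duration
        Cued target duration in ms.

    Returns
    -------
    str
        One of :data:`OUTCOMES`.  "correct" means the response fell at or
        after ``correct_fraction * duration`` (the earliest response the
        task rewards-or-tolerates as a genuine estimate) and within the
        response window (which has the same length as the wait, i.e. ends
        at ``2 * duration``).  Responses in ``[early_floor_ms,
        correct_fraction * duration)`` are early errors; responses after
        the window (or absent) are late errors; anything earlier than
        ``early_floor_ms`` is an abort.
    """
    if response_ms is None or (isinstance(response_ms, float) and np.isnan(response_ms)):
        return "late_error"
    if response_ms < 0:
        raise ValueError(f"negative response time: {response_ms}")
    earliest_correct = correct_fraction * duration
    window_end = 2.0 * duration
    if earliest_correct <= response_ms <= window_end:
        return "correct"
    if early_floor_ms <= response_ms < earliest_correct:
        return "early_error"
    if response_ms > window_end:
        return "late_error"
    return "aborted"


@dataclass
class InclusionResult:
    """Outcome of the neuron inclusion filter with failure reasons."""

    included: bool
    reasons: list[str] = field(default_factory=list)
    correct_per_cue: dict[str, int] = field(default_factory=dict)
    mean_rate_hz: float = float("nan")

    def __bool__(self) -> bool:  # allows `if neuron_inclusion(...)`
        return self.included


def neuron_inclusion(
    session,
    neuron_id: int,
    *,
    min_correct_per_cue: int = 8,
    min_rate_hz: float = 0.5,
    wait_span_ms: float = 1200.0,
) -> InclusionResult:
    """Apply the analysis inclusion filter to one neuron.

    A neuron is included iff it has at least ``min_correct_per_cue`` correct
    trials for *each* cue identity and an average firing rate of at least
    ``min_rate_hz`` over the composite pre-cue + cue + first
    ``wait_span_ms`` of the wait period (2100 ms by default), computed on
    correct trials.  Both thresholds are inclusive.
    """
    trials = session.trials
    correct = trials[trials["outcome"] == "correct"]
    counts = correct.groupby("cue").size().to_dict()
    all_cues = sorted(trials["cue"].unique())
    reasons: list[str] = []
    per_cue = {c: int(counts.get(c, 0)) for c in all_cues}
    if any(v < min_correct_per_cue for v in per_cue.values()):
        reasons.append("trials")

    task = getattr(session, "task", None)
    pre_cue = task.pre_cue_ms if task is not None else 300.0
    cue = task.cue_ms if task is not None else 600.0
    start, end = -float(pre_cue), float(cue) + float(wait_span_ms)
    spk = session.spikes
    spk = spk[(spk["neuron_id"] == neuron_id) & spk["trial_id"].isin(correct["trial_id"])]
    n_spikes = int(((spk["t_ms"] >= start) & (spk["t_ms"] < end)).sum())
    span_s = (end - start) / 1000.0
    n_trials = len(correct)
    rate = n_spikes / (n_trials * span_s) if n_trials else 0.0
    if rate < min_rate_hz:
        reasons.append("rate")
    return InclusionResult(not reasons, reasons, per_cue, rate)


@dataclass
class AlignedRates:
    """Event-aligned binned firing rates for a set of trials and neurons.

    ``rates`` has shape (trials, neurons, bins) in Hz; ``bin_edges`` are ms
    relative to the alignment event and tile ``window`` exactly.
    """

    neuron_ids: np.ndarray
    trial_ids: np.ndarray
    alignment: str
    window: tuple[float, float]
    bin_edges: np.ndarray
    rates: np.ndarray
    skipped_trials: list[int] = field(default_factory=list)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def extract_window_rates(
    session,
    alignment: str = "cue_offset",
    window: tuple[float, float] = (0.0, 1200.0),
    bin_width: float | None = None,
    *,
    outcomes: tuple[str, ...] = ("correct",),
    trial_ids=None,
    neuron_ids=None,
) -> AlignedRates:
    """Extract per-trial binned rates aligned to cue offset or response onset.

    ``window`` is (start, end) in ms relative to the alignment event; with
    ``bin_width=None`` the whole window is a single bin.  Counts in each
    half-open bin are divided by the bin width in seconds.  Response-aligned
    extraction skips (with a warning) trials lacking a response event.
    """
    if alignment not in ("cue_offset", "response_onset"):
        raise ValueError(f"unknown alignment: {alignment!r}")
    start, end = float(window[0]), float(window[1])
    if bin_width is None:
        bin_width = end - start
    span = end - start
    n_bins = span / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("window length must be divisible by bin_width")
    n_bins = int(round(n_bins))

    trials = session.trials
    if outcomes is not None:
        trials = trials[trials["outcome"].isin(outcomes)]
    if trial_ids is not None:
        trials = trials[trials["trial_id"].isin(trial_ids)]
    if alignment == "cue_offset":
        event = trials["t_cue_off"].to_numpy(dtype=float)
    else:
        event = trials["t_response"].to_numpy(dtype=float)
    keep = ~np.isnan(event)
    skipped = trials["trial_id"].to_numpy()[~keep].tolist()
    if skipped:
        warnings.warn(
            f"{len(skipped)} trial(s) lack the {alignment} event and were skipped",
            stacklevel=2,
        )
    trials = trials[keep]
    event = event[keep]
    tids = trials["trial_id"].to_numpy()

    if neuron_ids is None:
        neuron_ids = np.asarray(sorted(session.spikes["neuron_id"].unique()))
    else:
        neuron_ids = np.asarray(list(neuron_ids))
    trial_pos = {t: i for i, t in enumerate(tids)}
    neuron_pos = {n: i for i, n in enumerate(neuron_ids)}

    counts = np.zeros((len(tids), len(neuron_ids), n_bins))
    spk = session.spikes
    spk = spk[spk["trial_id"].isin(trial_pos) & spk["neuron_id"].isin(neuron_pos)]
    if len(spk):
        ti = spk["trial_id"].map(trial_pos).to_numpy()
        ni = spk["neuron_id"].map(neuron_pos).to_numpy()
        t_rel = spk["t_ms"].to_numpy(dtype=float) - event[ti]
        inside = (t_rel >= start) & (t_rel < end)
        bi = np.floor((t_rel[inside] - start) / bin_width).astype(int)
        np.add.at(counts, (ti[inside], ni[inside], bi), 1.0)

    rates = counts / (bin_width / 1000.0)
    edges = start + bin_width * np.arange(n_bins + 1)
    return AlignedRates(neuron_ids, tids, alignment, (start, end), edges, rates, skipped)


# ---------------------------------------------------------------------------
# smoothing and scaling


def gaussian_smooth(x: np.ndarray, sigma_ms: float, dt_ms: float, axis: int = -1) -> np.ndarray:
    """Smooth along ``axis`` with a Gaussian kernel of SD ``sigma_ms``.

    The kernel is truncated at 5 SD and edge-renormalized: each output
    sample is divided by the kernel mass that fell inside the window, so a
    unit impulse integrates to ~1 even in short windows and edges do not
    droop.
    """
    x = np.asarray(x, dtype=float)
    sigma_bins = sigma_ms / dt_ms
    radius = max(1, int(np.ceil(5 * sigma_bins)))
    k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma_bins) ** 2)
    k /= k.sum()
    x_moved = np.moveaxis(x, axis, -1)
    n = x_moved.shape[-1]
    flat = x_moved.reshape(-1, n)
    out = np.empty_like(flat)
    norm = np.convolve(np.ones(n), k, mode="full")[radius : radius + n]
    for i in range(flat.shape[0]):
        out[i] = np.convolve(flat[i], k, mode="full")[radius : radius + n] / norm
    return np.moveaxis(out.reshape(x_moved.shape), -1, axis)


def minmax_scale(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Map each slice along ``axis`` to [0, 1]; constant slices map to 0."""
    x = np.asarray(x, dtype=float)
    lo = x.min(axis=axis, keepdims=True)
    hi = x.max(axis=axis, keepdims=True)
    rng = hi - lo
    out = np.zeros_like(x)
    np.divide(x - lo, rng, out=out, where=rng > 0)
    return out


def zscore_by_train(x: np.ndarray, train_idx, axis: int = 0) -> np.ndarray:
    """z-score features using mean/SD computed on the training rows only.

    Statistics use the population SD (ddof=0).  Zero-variance features map
    to 0 everywhere, keeping silent neurons neutral for linear classifiers.
    This is the leakage-free scaling contract every decoder in the package
    uses.
    """
    x = np.asarray(x, dtype=float)
    train = np.take(x, np.asarray(train_idx), axis=axis)
    mu = train.mean(axis=axis, keepdims=True)
    sd = train.std(axis=axis, keepdims=True)
    out = np.zeros_like(x)
    np.divide(x - mu, sd, out=out, where=sd > 0)
    return out


def smooth_and_scale(matrix: np.ndarray, method: str, **kwargs) -> np.ndarray:
    """Dispatch to :func:`gaussian_smooth` / :func:`minmax_scale` /
    :func:`zscore_by_train` by name ("gaussian_kernel", "minmax",
    "zscore_by_train")."""
    if method == "gaussian_kernel":
        return gaussian_smooth(matrix, kwargs["sigma_ms"], kwargs["dt_ms"], kwargs.get("axis", -1))
    if method == "minmax":
        return minmax_scale(matrix, kwargs.get("axis", -1))
    if method == "zscore_by_train":
        return zscore_by_train(matrix, kwargs["train_idx"], kwargs.get("axis", 0))
    raise ValueError(f"unknown method: {method!r}")
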