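"""Linear SVM population decoding with permutation-based significance.

Pseudopopulation assembly from non-simultaneously recorded neurons,
within/cross-protocol duration decoding, elapsed-time decoding,
correct-vs-late-error decoding, cross-temporal generalization with a
cluster permutation test, and wait-period bin-stability decoding.

All decoders share the same core: a linear one-vs-one SVM (C = 1 by
default), stratified cross-validation, and train-only z-scoring through
:func:`timecourt.preprocessing.zscore_by_train` so no test statistics ever
leak into the scaler.  Accuracies are reported in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import preprocessing

# ---------------------------------------------------------------------------
# pseudopopulation assembly


@dataclass
class PseudoPopulation:
    """Per-class trial pools per neuron, ready for resampled assembly.

    ``pools[c][i]`` is a (n_trials, n_features) array of neuron i's
    features on class-c trials.  Each :meth:`draw` samples ``n_per_class``
    trials per neuron per class *without replacement* and pairs them by
    position into pseudotrials, so every neuron contributes exactly one
    trial per pseudotrial and class counts are balanced.
    """

    neuron_ids: np.ndarray
    classes: np.ndarray
    pools: dict
    n_per_class: int
    excluded: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    @classmethod
    def from_pools(cls, pools: dict, neuron_ids, min_trials: int) -> "PseudoPopulation":
        """Build from explicit per-neuron pools, applying per-neuron exclusion.

        ``pools[c][i]`` may have different trial counts per neuron (the
        multi-session case); neurons below ``min_trials`` in any class are
        excluded with a recorded reason.
        """
        neuron_ids = np.asarray(list(neuron_ids))
        classes = np.array(sorted(pools))
        keep, excluded = [], []
        for i, nid in enumerate(neuron_ids):
            bad = [c for c in classes if len(pools[c][i]) < min_trials]
            if bad:
                excluded.append((int(nid), f"min_trials: classes {bad} below {min_trials}"))
            else:
                keep.append(i)
        if not keep:
            raise ValueError("no neuron satisfies the min_trials requirement")
        kept_pools = {
            c: [np.atleast_2d(np.asarray(pools[c][i], dtype=float).reshape(len(pools[c][i]), -1)) for i in keep]
            for c in classes
        }
        return cls(neuron_ids[keep], classes, kept_pools, min_trials, excluded)

    def draw(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Assemble one resample: X (pseudotrials x neurons x features), y."""
        m = self.n_per_class
        n_feat = next(iter(self.pools.values()))[0].shape[1]
        X = np.empty((len(self.classes) * m, self.n_neurons, n_feat))
        y = np.repeat(self.classes, m)
        for ci, c in enumerate(self.classes):
            for i in range(self.n_neurons):
                pool = self.pools[c][i]
                idx = rng.choice(len(pool), size=m, replace=False)
                X[ci * m : (ci + 1) * m, i, :] = pool[idx]
        return X, y


def assemble_pseudopopulation(
    session,
    *,
    class_column: str = "duration_ms",
    alignment: str = "cue_offset",
    window: tuple[float, float] = (0.0, 1200.0),
    bin_width: float | None = None,
    min_trials: int = 15,
    outcomes: tuple[str, ...] = ("correct",),
    protocol: str | None = None,
    neuron_ids=None,
) -> PseudoPopulation:
    """Build per-class trial pools of window-averaged (or binned) rates.

    Neurons with fewer than ``min_trials`` trials in any class are
    excluded with a recorded reason.  ``protocol`` restricts the pools to
    one cue protocol (used by the generalization analyses).
    """
    trials = session.trials
    if protocol is not None:
        trials = trials[trials["protocol"] == protocol]
    if outcomes is not None:
        trials = trials[trials["outcome"].isin(outcomes)]
    aligned = preprocessing.extract_window_rates(
        session,
        alignment,
        window,
        bin_width,
        outcomes=None,
        trial_ids=trials["trial_id"],
        neuron_ids=neuron_ids,
    )
    tinfo = session.trials.set_index("trial_id").loc[aligned.trial_ids]
    labels = tinfo[class_column].to_numpy()
    classes = np.array(sorted(np.unique(labels)))

    pools_all = {c: [] for c in classes}
    keep, excluded = [], []
    for i, nid in enumerate(aligned.neuron_ids):
        sizes = {c: int((labels == c).sum()) for c in classes}
        bad = [c for c, s in sizes.items() if s < min_trials]
        if bad:
            excluded.append((int(nid), f"min_trials: classes {bad} below {min_trials}"))
            continue
        keep.append(i)
    if not keep:
        raise ValueError("no neuron satisfies the min_trials requirement")
    for c in classes:
        rows = labels == c
        for i in keep:
            pools_all[c].append(aligned.rates[rows, i, :])
    return PseudoPopulation(
        neuron_ids=aligned.neuron_ids[keep],
        classes=classes,
        pools=pools_all,
        n_per_class=min_trials,
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# core SVM machinery


@dataclass
class DecodeResult:
    """Accuracy distribution, pooled confusion matrix, and shuffle null."""

    classes: np.ndarray
    accuracies: np.ndarray  # percent, one per resample
    confusion: np.ndarray  # true x predicted counts, averaged over resamples
    n_folds: int
    n_resamples: int
    null_accuracies: np.ndarray | None = None
    null_p99: float | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def confusion_accuracy(self) -> float:
        """Accuracy recomputed from the confusion matrix (percent)."""
        return float(np.trace(self.confusion) / self.confusion.sum() * 100.0)


def _new_svm(C: float) -> SVC:
    # linear kernel SVC performs one-vs-one multiclass natively
    return SVC(kernel="linear", C=C)


def _cv_run(X, y, classes, n_folds, rng, C):
    """One full stratified CV pass; returns (accuracy %, confusion counts)."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31)))
    conf = np.zeros((len(classes), len(classes)))
    for train_idx, test_idx in skf.split(X, y):
        Xz = preprocessing.zscore_by_train(X, train_idx, axis=0)
        clf = _new_svm(C).fit(Xz[train_idx], y[train_idx])
        pred = clf.predict(Xz[test_idx])
        conf += confusion_matrix(y[test_idx], pred, labels=classes)
    acc = np.trace(conf) / conf.sum() * 100.0
    return acc, conf


def svm_decode(
    features,
    labels=None,
    *,
    n_folds: int = 10,
    n_resamples: int = 100,
    n_shuffles: int = 0,
    shuffle: bool = False,
    seed=None,
    C: float = 1.0,
) -> DecodeResult:
    """Cross-validated linear one-vs-one SVM decoding.

    ``features`` is either a :class:`PseudoPopulation` (a fresh trial
    assembly is drawn per resample) or a (trials x features) array with
    ``labels``.  With ``shuffle=True`` labels are permuted anew each
    resample, so the reported accuracies *are* the chance distribution.
    ``n_shuffles > 0`` additionally runs the identical procedure on
    permuted labels to attach a shuffle null and its 99th percentile.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pop = features if isinstance(features, PseudoPopulation) else None
    if pop is None:
        X_fixed = np.asarray(features, dtype=float)
        y_fixed = np.asarray(labels)
        classes = np.array(sorted(np.unique(y_fixed)))
    else:
        classes = pop.classes

    def one_pass(permute: bool):
        if pop is not None:
            X, y = pop.draw(rng)
            X = X.reshape(X.shape[0], -1)
        else:
            X, y = X_fixed, y_fixed
        if permute:
            y = rng.permutation(y)
        return _cv_run(X, y, classes, n_folds, rng, C)

    accs = np.empty(n_resamples)
    conf_sum = np.zeros((len(classes), len(classes)))
    for r in range(n_resamples):
        accs[r], conf = one_pass(permute=shuffle)
        conf_sum += conf
    null = None
    p99 = None
    if n_shuffles:
        null = np.array([one_pass(permute=True)[0] for _ in range(n_shuffles)])
        p99 = float(np.percentile(null, 99))
    return DecodeResult(
        classes=classes,
        accuracies=accs,
        confusion=conf_sum / n_resamples,
        n_folds=n_folds,
        n_resamples=n_resamples,
        null_accuracies=null,
        null_p99=p99,
    )


# ---------------------------------------------------------------------------
# protocol generalization


def protocol_generalization_decode(
    session,
    *,
    alignment: str = "cue_offset",
    window: tuple[float, float] = (0.0, 1200.0),
    min_trials: int = 15,
    n_folds: int = 5,
    n_resamples: int = 100,
    n_shuffles: int = 100,
    seed=None,
    C: float = 1.0,
    neuron_ids=None,
) -> dict[str, DecodeResult]:
    """Within- and across-protocol duration decoding.

    Within-protocol conditions run stratified CV inside one protocol's
    trials; across-protocol conditions train on all pseudotrials of one
    protocol and test on all pseudotrials of the other (train and test are
    disjoint by construction, so no folding is needed across the
    boundary).  Returns a dict keyed e.g. "color->color", "color->shape".
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    protocols = sorted(session.trials["protocol"].unique())
    pops = {
        p: assemble_pseudopopulation(
            session,
            alignment=alignment,
            window=window,
            min_trials=min_trials,
            protocol=p,
            neuron_ids=neuron_ids,
        )
        for p in protocols
    }
    out: dict[str, DecodeResult] = {}
    for p in protocols:
        out[f"{p}->{p}"] = svm_decode(
            pops[p],
            n_folds=n_folds,
            n_resamples=n_resamples,
            n_shuffles=n_shuffles,
            seed=rng,
            C=C,
        )
    for p_train in protocols:
        for p_test in protocols:
            if p_test == p_train:
                continue
            out[f"{p_train}->{p_test}"] = _across_decode(
                pops[p_train], pops[p_test], n_resamples, n_shuffles, rng, C
            )
    return out


def _across_decode(pop_train, pop_test, n_resamples, n_shuffles, rng, C) -> DecodeResult:
    classes = pop_train.classes

    def one_pass(permute: bool):
        Xtr, ytr = pop_train.draw(rng)
        Xte, yte = pop_test.draw(rng)
        Xtr = Xtr.reshape(Xtr.shape[0], -1)
        Xte = Xte.reshape(Xte.shape[0], -1)
        if permute:
            ytr = rng.permutation(ytr)
        both = np.vstack([Xtr, Xte])
        z = preprocessing.zscore_by_train(both, np.arange(len(Xtr)), axis=0)
        clf = _new_svm(C).fit(z[: len(Xtr)], ytr)
        pred = clf.predict(z[len(Xtr) :])
        conf = confusion_matrix(yte, pred, labels=classes)
        return np.trace(conf) / conf.sum() * 100.0, conf

    accs = np.empty(n_resamples)
    conf_sum = np.zeros((len(classes), len(classes)))
    for r in range(n_resamples):
        accs[r], conf = one_pass(False)
        conf_sum += conf
    null = np.array([one_pass(True)[0] for _ in range(n_shuffles)]) if n_shuffles else None
    return DecodeResult(
        classes=classes,
        accuracies=accs,
        confusion=conf_sum / n_resamples,
        n_folds=1,
        n_resamples=n_resamples,
        null_accuracies=null,
        null_p99=float(np.percentile(null, 99)) if null is not None else None,
    )


# ---------------------------------------------------------------------------
# elapsed-time decoding


@dataclass
class ElapsedTimeResult:
    """Predicted-bin distributions for the elapsed-time decoder.

    ``pred_counts[b, k]`` counts how often true bin b was predicted as bin
    k over all folds and resamples.  Bookkeeping fields expose the
    observation arithmetic: with 20 trials and 20 bins there are 400
    observations per neuron, split 320/80 per 5-fold iteration, and each
    true bin accumulates ``n_resamples * n_folds * (n_trials / n_folds)``
    predictions (20,000 at 1000 resamples).
    """

    duration: float
    n_bins: int
    bin_ms: float
    pred_counts: np.ndarray
    n_observations: int
    n_train: int
    n_test: int
    predictions_per_bin: int
    accuracy: float

    @property
    def medians(self) -> np.ndarray:
        return np.array(
            [_weighted_quantile(np.arange(1, self.n_bins + 1), c, 0.5) for c in self.pred_counts]
        )

    @property
    def iqr(self) -> np.ndarray:
        lo = [_weighted_quantile(np.arange(1, self.n_bins + 1), c, 0.25) for c in self.pred_counts]
        hi = [_weighted_quantile(np.arange(1, self.n_bins + 1), c, 0.75) for c in self.pred_counts]
        return np.array([lo, hi])


def _weighted_quantile(values, counts, q):
    cum = np.cumsum(counts)
    if cum[-1] == 0:
        return np.nan
    return float(values[np.searchsorted(cum, q * cum[-1])])


def elapsed_time_decode(
    session,
    neuron_ids,
    duration: float,
    *,
    n_trials: int = 20,
    n_bins: int = 20,
    n_folds: int = 5,
    n_resamples: int = 1000,
    seed=None,
    C: float = 1.0,
) -> ElapsedTimeResult:
    """Decode elapsed time within the wait period of one target duration.

    The first ``correct_fraction * duration`` of the cue-offset-aligned
    wait (1200/2400/4800 ms for the standard durations) is divided into
    ``n_bins`` equal bins; each (trial, bin) pair is one observation whose
    feature is the per-neuron min-max-normalized mean rate in that bin.  A
    ``n_bins``-class one-vs-one linear SVM is trained with stratified
    ``n_folds``-fold CV (train-only z-scoring) and the distribution of
    predicted bins is accumulated per true bin over folds and resamples.
    Neurons lacking ``n_trials`` correct trials of the duration are
    dropped with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    task = session.task
    frac = task.correct_fraction_threshold if task is not None else 0.8
    span = frac * duration
    bin_ms = span / n_bins
    trials = session.trials
    tids = trials[
        (trials["outcome"] == "correct") & (trials["duration_ms"] == duration)
    ]["trial_id"]
    aligned = preprocessing.extract_window_rates(
        session, "cue_offset", (0.0, span), bin_ms, trial_ids=tids, neuron_ids=neuron_ids
    )
    per_neuron = []
    for i, nid in enumerate(aligned.neuron_ids):
        mat = aligned.rates[:, i, :]
        if mat.shape[0] < n_trials:
            warnings.warn(f"neuron {nid} has < {n_trials} correct trials; dropped", stacklevel=2)
            continue
        per_neuron.append(mat)
    if not per_neuron:
        raise ValueError("no neuron has enough correct trials")

    n_obs = n_trials * n_bins
    y = np.tile(np.arange(n_bins), n_trials)
    conf = np.zeros((n_bins, n_bins))
    for _ in range(n_resamples):
        X = np.empty((n_obs, len(per_neuron)))
        for i, mat in enumerate(per_neuron):
            idx = rng.choice(mat.shape[0], size=n_trials, replace=False)
            sub = preprocessing.minmax_scale(mat[idx], axis=None)
            X[:, i] = sub.reshape(-1)  # rows ordered (trial, bin)
        _, c = _cv_run(X, y, np.arange(n_bins), n_folds, rng, C)
        conf += c

    return ElapsedTimeResult(
        duration=duration,
        n_bins=n_bins,
        bin_ms=bin_ms,
        pred_counts=conf,
        n_observations=n_obs,
        n_train=n_obs - n_obs // n_folds,
        n_test=n_obs // n_folds,
        predictions_per_bin=n_resamples * n_folds * (n_trials // n_folds),
        accuracy=float(np.trace(conf) / conf.sum() * 100.0),
    )


# ---------------------------------------------------------------------------
# correct vs late-error decoding


@dataclass
class ErrorDecodeResult:
    correct: DecodeResult
    late_error: DecodeResult
    null_p99: float | None


def error_trial_decode(
    session,
    neuron_ids=None,
    *,
    classes: tuple[float, float] = (1500.0, 3000.0),
    window: tuple[float, float] = (0.0, 1200.0),
    n_correct_draw: int = 15,
    n_error_draw: int = 8,
    n_folds: int = 10,
    n_resamples: int = 100,
    n_shuffles: int = 100,
    seed=None,
    C: float = 1.0,
) -> ErrorDecodeResult:
    """Train on correct trials, test on held-out correct and late-error trials.

    Two-class (1500 vs 3000 ms) decoding of cue-offset-aligned activity.
    Only neurons with at least one late error for *both* classes qualify;
    late-error trials are resampled (with replacement, to ``n_error_draw``
    per class) each iteration.  Returns accuracies for held-out correct
    trials and for late-error trials, plus the shuffled-label 99th
    percentile.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cls = np.array(classes)

    aligned = preprocessing.extract_window_rates(
        session, "cue_offset", window, outcomes=("correct", "late_error"), neuron_ids=neuron_ids
    )
    tinfo = session.trials.set_index("trial_id").loc[aligned.trial_ids]
    dur = tinfo["duration_ms"].to_numpy(dtype=float)
    out = tinfo["outcome"].to_numpy()

    corr_pools, err_pools, keep = {c: [] for c in cls}, {c: [] for c in cls}, []
    for i, nid in enumerate(aligned.neuron_ids):
        ok = True
        for c in cls:
            if (out[(dur == c)] == "late_error").sum() < 1:
                ok = False
            if ((dur == c) & (out == "correct")).sum() < n_correct_draw:
                ok = False
        if ok:
            keep.append(i)
    if not keep:
        raise ValueError("no neuron has late errors for both classes")
    for c in cls:
        corr_rows = (dur == c) & (out == "correct")
        err_rows = (dur == c) & (out == "late_error")
        for i in keep:
            corr_pools[c].append(aligned.rates[corr_rows, i, 0])
            err_pools[c].append(aligned.rates[err_rows, i, 0])

    n_neu = len(keep)

    def draw(pools, m, replace):
        X = np.empty((len(cls) * m, n_neu))
        y = np.repeat(cls, m)
        for ci, c in enumerate(cls):
            for i in range(n_neu):
                pool = pools[c][i]
                idx = rng.choice(len(pool), size=m, replace=replace)
                X[ci * m : (ci + 1) * m, i] = pool[idx]
        return X, y

    def one_pass(permute: bool):
        Xc, yc = draw(corr_pools, n_correct_draw, False)
        Xe, ye = draw(err_pools, n_error_draw, True)
        skf = StratifiedKFold(n_folds, shuffle=True, random_state=int(rng.integers(2**31)))
        conf_c = np.zeros((2, 2))
        conf_e = np.zeros((2, 2))
        for tr, te in skf.split(Xc, yc):
            ytr = rng.permutation(yc[tr]) if permute else yc[tr]
            stacked = np.vstack([Xc, Xe])
            z = preprocessing.zscore_by_train(stacked, tr, axis=0)
            clf = _new_svm(C).fit(z[tr], ytr)
            conf_c += confusion_matrix(yc[te], clf.predict(z[te]), labels=cls)
            conf_e += confusion_matrix(ye, clf.predict(z[len(Xc) :]), labels=cls)
        return conf_c, conf_e

    acc_c = np.empty(n_resamples)
    acc_e = np.empty(n_resamples)
    sum_c = np.zeros((2, 2))
    sum_e = np.zeros((2, 2))
    for r in range(n_resamples):
        cc, ce = one_pass(False)
        acc_c[r] = np.trace(cc) / cc.sum() * 100.0
        acc_e[r] = np.trace(ce) / ce.sum() * 100.0
        sum_c += cc
        sum_e += ce
    null = None
    p99 = None
    if n_shuffles:
        null = np.empty(n_shuffles)
        for s in range(n_shuffles):
            cc, _ = one_pass(True)
            null[s] = np.trace(cc) / cc.sum() * 100.0
        p99 = float(np.percentile(null, 99))
    res_c = DecodeResult(cls, acc_c, sum_c / n_resamples, n_folds, n_resamples, null, p99)
    res_e = DecodeResult(cls, acc_e, sum_e / n_resamples, n_folds, n_resamples, null, p99)
    return ErrorDecodeResult(res_c, res_e, p99)


# ---------------------------------------------------------------------------
# cross-temporal decoding and cluster permutation test


@dataclass
class CrossTemporalResult:
    """Train-time x test-time generalization matrix (percent accuracy)."""

    times: np.ndarray  # window centers, ms relative to cue offset
    accuracy: np.ndarray  # mean over resamples, train x test
    per_resample: np.ndarray  # (resamples, T, T)
    null: np.ndarray | None  # (shuffles, T, T) or None
    window_ms: float
    step_ms: float


def _sliding_window_rates(session, span, window_ms, step_ms, neuron_ids):
    """Per-trial mean rates in overlapping windows via a rolling sum."""
    aligned = preprocessing.extract_window_rates(
        session, "cue_offset", span, step_ms, neuron_ids=neuron_ids
    )
    k = int(round(window_ms / step_ms))
    csum = np.cumsum(aligned.rates, axis=-1)
    csum = np.concatenate([np.zeros(csum.shape[:-1] + (1,)), csum], axis=-1)
    win = (csum[..., k:] - csum[..., :-k]) / k  # mean rate per window
    starts = span[0] + step_ms * np.arange(win.shape[-1])
    centers = starts + window_ms / 2.0
    return aligned, win, centers


def _generalization_pass(X, y, classes, n_folds, rng, C, permute):
    """Train at every feature-slab w, test at every w'; returns counts."""
    n_w = X.shape[-1]
    correct = np.zeros((n_w, n_w))
    total = np.zeros((n_w, n_w))
    skf = StratifiedKFold(n_folds, shuffle=True, random_state=int(rng.integers(2**31)))
    yy = rng.permutation(y) if permute else y
    for tr, te in skf.split(X[:, :, 0], yy):
        for w in range(n_w):
            z = preprocessing.zscore_by_train(X[:, :, w], tr, axis=0)
            clf = _new_svm(C).fit(z[tr], yy[tr])
            # apply the train window's scaler to every test window
            mu = X[tr, :, w].mean(axis=0)
            sd = X[tr, :, w].std(axis=0)
            sd_safe = np.where(sd > 0, sd, 1.0)
            for w2 in range(n_w):
                zt = (X[te, :, w2] - mu) / sd_safe
                zt[:, sd == 0] = 0.0
                pred = clf.predict(zt)
                correct[w, w2] += np.sum(pred == yy[te])
                total[w, w2] += len(te)
    return correct, total


def cross_temporal_decode(
    session,
    *,
    span: tuple[float, float] = (-900.0, 1800.0),
    window_ms: float = 200.0,
    step_ms: float = 20.0,
    trials_per_class: int = 20,
    n_folds: int = 10,
    n_resamples: int = 20,
    n_shuffles: int = 0,
    neuron_ids=None,
    seed=None,
    C: float = 1.0,
) -> CrossTemporalResult:
    """Sliding-window cross-temporal duration decoding.

    ``span`` is (start, end) in ms relative to cue offset; the default
    covers pre-cue onset (-900) through 1800 ms into the wait.  For every
    train window a classifier is fit (train-only z-scoring) and tested
    against every window of the held-out trials, the train window's scaler
    being applied throughout.  A static code yields a square high-accuracy
    pattern, a dynamic code a diagonal one.  ``n_shuffles`` label-permuted
    matrices per resample feed :func:`cluster_permutation_test`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    aligned, win, centers = _sliding_window_rates(session, span, window_ms, step_ms, neuron_ids)
    tinfo = session.trials.set_index("trial_id").loc[aligned.trial_ids]
    labels = tinfo["duration_ms"].to_numpy(dtype=float)
    classes = np.unique(labels)
    pools = {c: np.where(labels == c)[0] for c in classes}
    if any(len(p) < trials_per_class for p in pools.values()):
        raise ValueError(f"need >= {trials_per_class} correct trials per class")

    m = trials_per_class
    y = np.repeat(classes, m)
    n_w = win.shape[-1]
    per_res = np.empty((n_resamples, n_w, n_w))
    nulls = [] if n_shuffles else None
    for r in range(n_resamples):
        X = np.empty((len(classes) * m, win.shape[1], n_w))
        for ci, c in enumerate(classes):
            for i in range(win.shape[1]):  # independent trial pairing per neuron
                idx = rng.choice(pools[c], size=m, replace=False)
                X[ci * m : (ci + 1) * m, i, :] = win[idx, i, :]
        corr, tot = _generalization_pass(X, y, classes, n_folds, rng, C, permute=False)
        per_res[r] = corr / tot * 100.0
        if n_shuffles:
            for _ in range(n_shuffles):
                corr, tot = _generalization_pass(X, y, classes, n_folds, rng, C, permute=True)
                nulls.append(corr / tot * 100.0)
    return CrossTemporalResult(
        times=centers,
        accuracy=per_res.mean(axis=0),
        per_resample=per_res,
        null=np.array(nulls) if nulls else None,
        window_ms=window_ms,
        step_ms=step_ms,
    )


@dataclass
class ClusterResult:
    """Cluster permutation test outcome on a generalization matrix."""

    mask: np.ndarray  # significant-cluster pixels
    labels: np.ndarray  # connected-component labels of threshold-exceeding pixels
    cluster_sizes: list[int]
    significant_clusters: list[int]  # component ids whose size beats the null
    null_max_sizes: np.ndarray
    pixel_threshold: np.ndarray
    size_threshold: float


_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def cluster_permutation_test(
    true_matrices: np.ndarray,
    null_matrices: np.ndarray,
    alpha_cluster: float = 0.01,
    alpha_rank: float = 0.01,
) -> ClusterResult:
    """Cluster-based permutation significance for accuracy matrices.

    Pixels where the mean true accuracy exceeds the pixelwise
    ``1 - alpha_cluster`` null quantile form candidate clusters under
    4-connectivity; a true cluster is significant iff its size exceeds the
    ``1 - alpha_rank`` quantile of the null maximum-cluster-size
    distribution (each null matrix thresholded against the same pixelwise
    quantiles).
    """
    true_matrices = np.asarray(true_matrices, dtype=float)
    null_matrices = np.asarray(null_matrices, dtype=float)
    mean_true = true_matrices if true_matrices.ndim == 2 else true_matrices.mean(axis=0)
    thresh = np.quantile(null_matrices, 1.0 - alpha_cluster, axis=0)

    sig = mean_true > thresh
    labels, n_clusters = ndimage.label(sig, structure=_FOUR_CONN)
    sizes = [int((labels == k).sum()) for k in range(1, n_clusters + 1)]

    null_max = np.zeros(len(null_matrices))
    for i, m in enumerate(null_matrices):
        lab, n = ndimage.label(m > thresh, structure=_FOUR_CONN)
        if n:
            null_max[i] = np.bincount(lab.ravel())[1:].max()
    size_thr = float(np.quantile(null_max, 1.0 - alpha_rank))

    sig_ids = [k for k, s in zip(range(1, n_clusters + 1), sizes) if s > size_thr]
    mask = np.isin(labels, sig_ids)
    return ClusterResult(mask, labels, sizes, sig_ids, null_max, thresh, size_thr)


# ---------------------------------------------------------------------------
# bin-stability decoding


def bin_stability_decode(
    session,
    neuron_ids=None,
    *,
    n_bins: int = 20,
    trials_per_class: int = 20,
    n_folds: int = 5,
    n_resamples: int = 100,
    n_shuffles: int = 0,
    seed=None,
    C: float = 1.0,
) -> CrossTemporalResult:
    """Stability of duration selectivity across proportional wait bins.

    Each duration's wait (first ``correct_fraction * duration``) is split
    into ``n_bins`` proportional bins (60/120/240 ms for the standard
    durations); a three-class duration decoder trained on bin b is tested
    on every bin b'.  High accuracy across the whole matrix indicates a
    stable duration code.  Returned in the same container as
    :func:`cross_temporal_decode` with ``times`` = bin numbers (1-based).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    task = session.task
    frac = task.correct_fraction_threshold if task is not None else 0.8
    trials = session.trials
    durations = np.array(sorted(trials["duration_ms"].unique()))

    # per class: (trials x neurons x bins) proportional-bin rates
    feats = {}
    for d in durations:
        span = frac * d
        tids = trials[(trials["outcome"] == "correct") & (trials["duration_ms"] == d)]["trial_id"]
        a = preprocessing.extract_window_rates(
            session, "cue_offset", (0.0, span), span / n_bins, trial_ids=tids, neuron_ids=neuron_ids
        )
        if a.rates.shape[0] < trials_per_class:
            raise ValueError(f"need >= {trials_per_class} correct trials for duration {d}")
        feats[d] = a.rates

    n_neu = next(iter(feats.values())).shape[1]
    m = trials_per_class
    y = np.repeat(durations, m)
    per_res = np.empty((n_resamples, n_bins, n_bins))
    nulls = [] if n_shuffles else None
    for r in range(n_resamples):
        X = np.empty((len(durations) * m, n_neu, n_bins))
        for ci, d in enumerate(durations):
            mat = feats[d]
            for i in range(n_neu):
                idx = rng.choice(mat.shape[0], size=m, replace=False)
                X[ci * m : (ci + 1) * m, i, :] = mat[idx, i, :]
        corr, tot = _generalization_pass(X, y, durations, n_folds, rng, C, permute=False)
        per_res[r] = corr / tot * 100.0
        if n_shuffles:
            for _ in range(n_shuffles):
                corr, tot = _generalization_pass(X, y, durations, n_folds, rng, C, permute=True)
                nulls.append(corr / tot * 100.0)
    return CrossTemporalResult(
        times=np.arange(1, n_bins + 1, dtype=float),
        accuracy=per_res.mean(axis=0),
        per_resample=per_res,
        null=np.array(nulls) if nulls else None,
        window_ms=float("nan"),
        step_ms=float("nan"),
    )
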