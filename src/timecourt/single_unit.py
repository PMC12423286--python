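"""Per-neuron statistics: selectivity, tuning, trends, ramping, scaling.

Two-way ANOVA duration selectivity, preferred-duration tuning curves with
weighted-SD widths, the Jonckheere-Terpstra ordered trend test, sequence
surfaces, ramping classification with shuffle-null model fits, and the
temporal-scaling-factor grid search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from scipy.optimize import curve_fit

from . import preprocessing

# ---------------------------------------------------------------------------
# two-way ANOVA


@dataclass
class AnovaResult:
    """Two-way (duration x protocol) ANOVA decomposition for one neuron."""

    ss: dict[str, float]
    df: dict[str, float]
    f: dict[str, float]
    p: dict[str, float]
    ms_error: float
    alpha: float
    classification: str
    condition_means: dict[float, float]

    def significant(self, factor: str) -> bool:
        p = self.p[factor]
        return bool(np.isfinite(p) and p < self.alpha)


def two_way_anova(
    rates,
    durations,
    protocols,
    alpha: float = 0.01,
) -> AnovaResult:
    """Full-factorial two-way ANOVA of per-trial rates.

    Uses Type II sums of squares, which coincide with the classical
    decomposition for balanced designs and remain the appropriate
    main-effect test when the delayed-retry protocol leaves cells
    unbalanced.  Classification: "time" iff only the duration main effect
    is significant at ``alpha``; similarly "protocol"/"interaction" for a
    single other significant term; "mixed" when several are; "none"
    otherwise.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    y = np.asarray(rates, dtype=float)
    dur = np.asarray(durations)
    prot = np.asarray(protocols)
    if not (len(y) == len(dur) == len(prot)):
        raise ValueError("rates, durations and protocols must be the same length")
    df = pd.DataFrame({"y": y, "dur": dur.astype(str), "prot": prot.astype(str)})
    counts = df.groupby(["dur", "prot"]).size()
    for (d, p_), c in counts.items():
        if c < 2:
            raise ValueError(f"cell (duration={d}, protocol={p_}) has {c} trial(s); need >= 2")
    if counts.size != df["dur"].nunique() * df["prot"].nunique():
        missing = {
            (d, p_)
            for d in df["dur"].unique()
            for p_ in df["prot"].unique()
            if (d, p_) not in counts.index
        }
        raise ValueError(f"empty cell(s): {sorted(missing)}")

    model = smf.ols("y ~ C(dur) * C(prot)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    key = {"C(dur)": "duration", "C(prot)": "protocol", "C(dur):C(prot)": "interaction"}
    ss = {key[k]: float(table.loc[k, "sum_sq"]) for k in key}
    dfs = {key[k]: float(table.loc[k, "df"]) for k in key}
    fstat = {key[k]: float(table.loc[k, "F"]) for k in key}
    pval = {key[k]: float(table.loc[k, "PR(>F)"]) for k in key}
    ss["error"] = float(table.loc["Residual", "sum_sq"])
    dfs["error"] = float(table.loc["Residual", "df"])
    ss["total"] = float(np.sum((y - y.mean()) ** 2))
    ms_error = ss["error"] / dfs["error"] if dfs["error"] > 0 else 0.0

    sig = [f for f in ("duration", "protocol", "interaction") if np.isfinite(pval[f]) and pval[f] < alpha]
    if not sig:
        cls = "none"
    elif sig == ["duration"]:
        cls = "time"
    elif sig == ["protocol"]:
        cls = "protocol"
    elif sig == ["interaction"]:
        cls = "interaction"
    else:
        cls = "mixed"

    means = {float(d): float(y[dur == d].mean()) for d in np.unique(dur)}
    return AnovaResult(ss, dfs, fstat, pval, ms_error, alpha, cls, means)


def preferred_duration(condition_means: dict[float, float]) -> tuple[float, bool]:
    """Duration with the highest mean rate; ties go to the shorter duration.

    Returns (preferred, tie_flag).
    """
    ds = sorted(condition_means)
    best = max(condition_means.values())
    winners = [d for d in ds if condition_means[d] == best]
    return winners[0], len(winners) > 1


@dataclass
class TimeNeuronStatus:
    """Duration-selectivity status of one neuron across both alignments."""

    time_cue: bool
    time_resp: bool
    preferred_cue: float
    preferred_resp: float
    tie_cue: bool
    tie_resp: bool
    overlap: bool
    preference_change: bool


def classify_time_neuron(anova_cue: AnovaResult, anova_resp: AnovaResult) -> TimeNeuronStatus:
    """Combine cue-offset- and response-aligned ANOVAs into a status record.

    A neuron counts as a "time" neuron in an alignment when that
    alignment's ANOVA classification is "time" (duration main effect only).
    ``overlap`` marks significance in both alignments;
    ``preference_change`` marks a different preferred duration across them.
    """
    tc = anova_cue.classification == "time"
    tr = anova_resp.classification == "time"
    pc, tie_c = preferred_duration(anova_cue.condition_means)
    pr, tie_r = preferred_duration(anova_resp.condition_means)
    return TimeNeuronStatus(
        time_cue=tc,
        time_resp=tr,
        preferred_cue=pc,
        preferred_resp=pr,
        tie_cue=tie_c,
        tie_resp=tie_r,
        overlap=tc and tr,
        preference_change=(pc != pr),
    )


def scan_time_neurons(
    session,
    alpha: float = 0.01,
    window_ms: float = 1200.0,
) -> pd.DataFrame:
    """Run the two-alignment selectivity ANOVA for every neuron.

    Returns one row per neuron with classification, preference and overlap
    flags; the ``window_ms`` analysis window is aligned after cue offset
    and before response onset respectively (correct trials only).
    """
    cue = preprocessing.extract_window_rates(session, "cue_offset", (0.0, window_ms))
    resp = preprocessing.extract_window_rates(session, "response_onset", (-window_ms, 0.0))
    trials = session.trials.set_index("trial_id")
    rows = []
    for j, nid in enumerate(cue.neuron_ids):
        res = {}
        for aligned, name in ((cue, "cue"), (resp, "resp")):
            t = trials.loc[aligned.trial_ids]
            res[name] = two_way_anova(
                aligned.rates[:, j, 0],
                t["duration_ms"].to_numpy(),
                t["protocol"].to_numpy(),
                alpha=alpha,
            )
        status = classify_time_neuron(res["cue"], res["resp"])
        rows.append(
            {
                "neuron_id": nid,
                "class_cue": res["cue"].classification,
                "class_resp": res["resp"].classification,
                "time_cue": status.time_cue,
                "time_resp": status.time_resp,
                "time_any": status.time_cue or status.time_resp,
                "preferred_cue": status.preferred_cue,
                "preferred_resp": status.preferred_resp,
                "overlap": status.overlap,
                "preference_change": status.preference_change,
                "p_duration_cue": res["cue"].p["duration"],
                "p_duration_resp": res["resp"].p["duration"],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tuning curves


@dataclass
class TuningResult:
    """Normalized 3-point tuning curve and its width."""

    durations: np.ndarray
    curve: np.ndarray  # 0..100 %
    preferred_ms: float
    tie: bool
    weighted_sd_ms: float
    monotonic: bool | None


def tuning_curve(mean_rates: dict[float, float]) -> TuningResult:
    """Min-max normalize mean rates to a 0-100% tuning curve.

    The tuning width is the weighted SD of the duration axis with the
    normalized responses as weights.  The monotonicity flag applies to
    extreme-preferring neurons only (1500-preferring: non-strictly
    decreasing; longest-preferring: non-strictly increasing); it is None
    for a middle-preferring neuron.
    """
    ds = np.array(sorted(mean_rates), dtype=float)
    y = np.array([mean_rates[d] for d in ds], dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("all condition means equal; tuning undefined")
    curve = (y - y.min()) / np.ptp(y) * 100.0
    pref, tie = preferred_duration({float(d): float(v) for d, v in zip(ds, y)})
    w = curve
    xbar = np.sum(w * ds) / np.sum(w)
    wsd = float(np.sqrt(np.sum(w * (ds - xbar) ** 2) / np.sum(w)))
    if pref == ds[0]:
        mono = bool(np.all(np.diff(y) <= 0))
    elif pref == ds[-1]:
        mono = bool(np.all(np.diff(y) >= 0))
    else:
        mono = None
    return TuningResult(ds, curve, pref, tie, wsd, mono)


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra trend test


@dataclass
class JTResult:
    statistic: float
    z: float
    p_value: float
    method: str


def _jt_statistic(groups: list[np.ndarray]) -> float:
    t = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a = groups[i][:, None]
            b = groups[j][None, :]
            t += np.sum(a < b) + 0.5 * np.sum(a == b)
    return float(t)


def jonckheere_terpstra(
    groups,
    alternative: str = "increasing",
    method: str = "auto",
) -> JTResult:
    """Jonckheere-Terpstra test for an ordered trend across groups.

    The statistic is the sum of pairwise Mann-Whitney counts over ordered
    group pairs (ties count 1/2).  ``method="normal"`` uses the
    tie-corrected normal approximation; ``method="exact"`` enumerates every
    distinct arrangement of the pooled sample over the group sizes (the
    default switches to exact for total n <= 12).
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 ordered groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    if alternative not in ("increasing", "decreasing"):
        raise ValueError("alternative must be 'increasing' or 'decreasing'")
    if alternative == "decreasing":
        groups = groups[::-1]

    t_obs = _jt_statistic(groups)
    n_i = np.array([len(g) for g in groups], dtype=float)
    n = n_i.sum()
    pooled = np.concatenate(groups)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tj = tie_counts.astype(float)

    mu = (n**2 - np.sum(n_i**2)) / 4.0
    a = n * (n - 1) * (2 * n + 5) - np.sum(n_i * (n_i - 1) * (2 * n_i + 5)) - np.sum(
        tj * (tj - 1) * (2 * tj + 5)
    )
    b = np.sum(n_i * (n_i - 1) * (n_i - 2)) * np.sum(tj * (tj - 1) * (tj - 2))
    c = np.sum(n_i * (n_i - 1)) * np.sum(tj * (tj - 1))
    var = a / 72.0
    if n > 2:
        var += b / (36.0 * n * (n - 1) * (n - 2))
    var += c / (8.0 * n * (n - 1))
    if var <= 1e-12 or t_obs == mu:
        z = 0.0
        p_norm = 0.5
    else:
        # continuity correction: P(T >= t) includes the atom at t itself
        z = (t_obs - mu - 0.5) / np.sqrt(var)
        p_norm = float(scipy.stats.norm.sf(z))

    use_exact = method == "exact" or (method == "auto" and n <= 12)
    if use_exact:
        p = _jt_exact_p(pooled, [len(g) for g in groups], t_obs)
        return JTResult(t_obs, z, p, "exact")
    return JTResult(t_obs, z, p_norm, "normal")


def _jt_exact_p(pooled: np.ndarray, sizes: list[int], t_obs: float) -> float:
    """One-sided exact p by full enumeration of group assignments.

    Enumerates which positions of the pooled sample land in each group
    (within-group order is irrelevant to the statistic), covering all
    n!/(n_1!...n_k!) distinct label arrangements exactly once.
    """
    from itertools import combinations

    counts = [0, 0]  # total, at_least

    def recurse(remaining: tuple[int, ...], gi: int, chosen: list[np.ndarray]) -> None:
        if gi == len(sizes):
            counts[0] += 1
            if _jt_statistic(chosen) >= t_obs - 1e-12:
                counts[1] += 1
            return
        for combo in combinations(remaining, sizes[gi]):
            rest = tuple(i for i in remaining if i not in combo)
            recurse(rest, gi + 1, chosen + [pooled[list(combo)]])

    recurse(tuple(range(len(pooled))), 0, [])
    return counts[1] / counts[0]


# ---------------------------------------------------------------------------
# sequence surfaces


def sequence_surface(
    rates: np.ndarray,
    dt_ms: float,
    sigma_ms: float = 200.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Peak-sorted normalized activation surface for a set of neurons.

    ``rates`` is (neurons x time) trial-averaged activity.  Each row is
    Gaussian-smoothed, min-max normalized over its own window (constant
    rows become flat zeros), and rows are ordered by peak time.  Returns
    ``(surface, order)`` where ``order`` indexes the input rows.
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    if rates.shape[0] < 1:
        raise ValueError("need at least one neuron")
    sm = preprocessing.gaussian_smooth(rates, sigma_ms, dt_ms, axis=-1)
    norm = preprocessing.minmax_scale(sm, axis=-1)
    peaks = np.argmax(norm, axis=-1)
    # secondary content key keeps the order permutation-invariant under ties
    order = np.array(sorted(range(len(norm)), key=lambda i: (peaks[i], tuple(norm[i]))))
    return norm[order], order


# ---------------------------------------------------------------------------
# ramping analysis


@dataclass
class RampFit:
    """Ramping classification and shuffle-tested model fits for one neuron."""

    increasing: bool
    p_ttest: float
    mean_initial: float
    mean_final: float
    peak_in_final: bool
    params: dict[str, np.ndarray] = field(default_factory=dict)
    r2: dict[str, float] = field(default_factory=dict)
    null_r2: dict[str, np.ndarray] = field(default_factory=dict)
    threshold: dict[str, float] = field(default_factory=dict)
    significant: dict[str, bool] = field(default_factory=dict)


def _model_linear(x, a, b):
    return a * x + b


def _model_exp(x, a, b, c):
    return a * np.exp(b * x) + c


def _model_sigmoid(x, L, k, x0, c):
    return L / (1.0 + np.exp(-k * (x - x0))) + c


_RAMP_MODELS = {
    "linear": (_model_linear, [(-10, 10), (-10, 10)]),
    "exponential": (_model_exp, [(-10, 10), (-20, 20), (-10, 10)]),
    "sigmoidal": (_model_sigmoid, [(-10, 10), (0.1, 100), (-1, 2), (-10, 10)]),
}


def _fit_one(x, y, name, rng, n_starts):
    fn, bounds = _RAMP_MODELS[name]
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if name == "linear":
        coef = np.polyfit(x, y, 1)
        pred = np.polyval(coef, x)
        return coef, _r2(y, pred)
    best = (None, -np.inf)
    for _ in range(n_starts):
        p0 = rng.uniform(lo, hi)
        try:
            popt, _ = curve_fit(fn, x, y, p0=p0, bounds=(lo, hi), maxfev=2000)
        except RuntimeError:
            continue
        r2 = _r2(y, fn(x, *popt))
        if r2 > best[1]:
            best = (popt, r2)
    if best[0] is None:
        return np.full(len(lo), np.nan), 0.0
    return best


def _r2(y, pred):
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot


def ramping_analysis(
    session,
    neuron_id: int,
    duration: float,
    *,
    bin_ms: float = 100.0,
    alpha: float = 0.05,
    n_shuffles: int = 1000,
    n_multistart: int = 5,
    seed=None,
) -> RampFit:
    """Test one neuron's wait activity for a systematic increase.

    "Increasing" requires the peak of the binned wait profile to fall in
    the final 600 ms before the response AND a paired t-test (initial 600
    ms after cue offset vs final 600 ms before response, per trial) to be
    significant with final > initial.  Linear/exponential/sigmoidal models
    are then fit to the 100 ms-binned, min-max normalized profile
    (cue-offset aligned wait of this duration); each model's significance
    is judged against the 95th percentile of its own ``n_shuffles``
    bin-shuffled r2 values.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    task = session.task
    frac = task.correct_fraction_threshold if task is not None else 0.8
    span = frac * duration
    trials = session.trials
    tids = trials[
        (trials["outcome"] == "correct") & (trials["duration_ms"] == duration)
    ]["trial_id"]
    if len(tids) < 2:
        raise ValueError("need at least 2 correct trials")

    init = preprocessing.extract_window_rates(
        session, "cue_offset", (0.0, 600.0), trial_ids=tids, neuron_ids=[neuron_id]
    )
    fin = preprocessing.extract_window_rates(
        session, "response_onset", (-600.0, 0.0), trial_ids=tids, neuron_ids=[neuron_id]
    )
    common = np.intersect1d(init.trial_ids, fin.trial_ids)
    xi = init.rates[np.isin(init.trial_ids, common), 0, 0]
    xf = fin.rates[np.isin(fin.trial_ids, common), 0, 0]
    if len(common) < 2:
        raise ValueError("need at least 2 paired trials")
    tt = scipy.stats.ttest_rel(xf, xi)
    p_t = float(tt.pvalue) if np.isfinite(tt.pvalue) else 1.0

    prof = preprocessing.extract_window_rates(
        session, "cue_offset", (0.0, span), bin_ms, trial_ids=tids, neuron_ids=[neuron_id]
    )
    mean_prof = prof.rates[:, 0, :].mean(axis=0)
    y = preprocessing.minmax_scale(mean_prof)
    centers = prof.bin_centers
    x = (centers - centers[0]) / (centers[-1] - centers[0]) if len(centers) > 1 else centers * 0
    peak_in_final = bool(centers[np.argmax(y)] >= span - 600.0)
    increasing = peak_in_final and p_t < alpha and xf.mean() > xi.mean()

    fit = RampFit(
        increasing=increasing,
        p_ttest=p_t,
        mean_initial=float(xi.mean()),
        mean_final=float(xf.mean()),
        peak_in_final=peak_in_final,
    )
    for name in _RAMP_MODELS:
        params, r2 = _fit_one(x, y, name, rng, n_multistart)
        fit.params[name] = np.asarray(params)
        fit.r2[name] = r2
        null = np.empty(n_shuffles)
        for s in range(n_shuffles):
            ys = rng.permutation(y)
            _, null[s] = _fit_one(x, ys, name, rng, n_multistart)
        fit.null_r2[name] = null
        thr = float(np.percentile(null, 95)) if n_shuffles else np.inf
        fit.threshold[name] = thr
        fit.significant[name] = bool(r2 > thr)
    return fit


# ---------------------------------------------------------------------------
# temporal scaling


@dataclass
class ScalingResult:
    """Grid-search outcome for temporal scaling between two durations."""

    factors: np.ndarray
    mse: np.ndarray
    optimal_factor: float
    optimal_mse: float
    expected_factor: float | None = None
    within_10pct: bool | None = None


DEFAULT_SCALING_GRID = np.round(np.arange(0.05, 3.0000001, 0.05), 10)


def temporal_scaling(
    profile_long: np.ndarray,
    profile_short: np.ndarray,
    factors: np.ndarray | None = None,
    *,
    bin_ms: float = 10.0,
    expected_factor: float | None = None,
) -> ScalingResult:
    """MSE grid search for the factor that compresses a long-duration
    profile onto a short-duration profile.

    Both profiles are samples on a uniform ``bin_ms`` grid anchored at the
    wait onset (t = k * bin_ms).  For each candidate factor f the long
    profile's time axis is compressed by f (a point at time t of the
    compressed profile takes the long profile's value at t/f, linearly
    interpolated) and the MSE against the short profile is computed over
    the overlapping span; factors leaving < 2 overlapping samples are
    skipped.  The optimal factor attains the grid-minimum MSE (ties to the
    smaller factor).  ``within_10pct`` flags |optimal - expected| <= 10% of
    the expected analytic factor (e.g. 0.5 for a 2:1 duration pair).
    """
    long = np.asarray(profile_long, dtype=float)
    short = np.asarray(profile_short, dtype=float)
    if factors is None:
        factors = DEFAULT_SCALING_GRID
    factors = np.asarray(factors, dtype=float)
    t_short = np.arange(len(short)) * bin_ms
    t_long = np.arange(len(long)) * bin_ms
    long_span = t_long[-1]
    mse = np.full(len(factors), np.nan)
    for i, f in enumerate(factors):
        valid = t_short <= long_span * f + 1e-9
        if valid.sum() < 2:
            continue
        vals = np.interp(t_short[valid] / f, t_long, long)
        mse[i] = float(np.mean((vals - short[valid]) ** 2))
    if np.all(np.isnan(mse)):
        raise ValueError("no factor produced >= 2 overlapping bins")
    best = int(np.nanargmin(mse))
    within = None
    if expected_factor is not None:
        within = bool(abs(factors[best] - expected_factor) <= 0.1 * expected_factor)
    return ScalingResult(factors, mse, float(factors[best]), float(mse[best]), expected_factor, within)


def wait_profile(
    session,
    neuron_id: int,
    duration: float,
    bin_ms: float = 10.0,
) -> np.ndarray:
    """Trial-averaged cue-offset-aligned wait profile at ``bin_ms`` bins.

    Spans the first ``correct_fraction * duration`` of the wait (the
    earliest-correct span: 1200/2400/4800 ms for the standard durations),
    correct trials only.
    """
    task = session.task
    frac = task.correct_fraction_threshold if task is not None else 0.8
    span = frac * duration
    trials = session.trials
    tids = trials[
        (trials["outcome"] == "correct") & (trials["duration_ms"] == duration)
    ]["trial_id"]
    prof = preprocessing.extract_window_rates(
        session, "cue_offset", (0.0, span), bin_ms, trial_ids=tids, neuron_ids=[neuron_id]
    )
    return prof.rates[:, 0, :].mean(axis=0)
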