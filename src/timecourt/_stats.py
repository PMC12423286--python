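"""Internal vectorized statistics helpers.

A closed-form balanced two-way ANOVA (cell-means decomposition) used by the
sliding-window omega-squared timecourse and by large recovery simulations,
where fitting one OLS model per neuron per window would dominate runtime.
The general (possibly unbalanced) per-neuron ANOVA in
:mod:`timecourt.single_unit` goes through statsmodels instead; the two
routes are cross-checked against each other in the test suite.
"""

from __future__ import annotations

import numpy as np

FACTORS = ("duration", "protocol", "interaction")


def balanced_anova_ss(y: np.ndarray, ia: np.ndarray, ib: np.ndarray, n_a: int, n_b: int):
    """Balanced two-way fixed-effects ANOVA, vectorized over leading axes.

    Parameters
    ----------
    y
        Responses with trials on the *last* axis; any leading axes (e.g.
        neurons x windows) are carried through.
    ia, ib
        Integer factor levels per trial (0..n_a-1, 0..n_b-1).  Every
        (a, b) cell must contain the same number of trials.

    Returns
    -------
    dict
        ``ss`` (per factor + "error" + "total"), ``df`` (per factor +
        "error"), and ``ms_error``; all arrays share the leading shape of
        ``y``.
    """
    y = np.asarray(y, dtype=float)
    ia = np.asarray(ia)
    ib = np.asarray(ib)
    n = y.shape[-1]
    cell = ia * n_b + ib
    counts = np.bincount(cell, minlength=n_a * n_b)
    if counts.min() < 1 or counts.max() != counts.min():
        raise ValueError("design must be balanced with every cell filled")
    r = int(counts[0])

    grand = y.mean(axis=-1, keepdims=True)
    ss_total = ((y - grand) ** 2).sum(axis=-1)

    # cell sums via matmul against an indicator matrix (vectorized bincount)
    ind = np.zeros((n, n_a * n_b))
    ind[np.arange(n), cell] = 1.0
    cell_means = (y @ ind) / r  # (..., n_a*n_b)
    cm = cell_means.reshape(y.shape[:-1] + (n_a, n_b))
    mean_a = cm.mean(axis=-1)
    mean_b = cm.mean(axis=-2)
    g = grand[..., 0]
    ss_a = r * n_b * ((mean_a - g[..., None]) ** 2).sum(axis=-1)
    ss_b = r * n_a * ((mean_b - g[..., None]) ** 2).sum(axis=-1)
    ss_cells = r * ((cm - g[..., None, None]) ** 2).sum(axis=(-2, -1))
    ss_int = ss_cells - ss_a - ss_b
    ss_err = ss_total - ss_cells

    df = {
        "duration": n_a - 1,
        "protocol": n_b - 1,
        "interaction": (n_a - 1) * (n_b - 1),
        "error": n - n_a * n_b,
    }
    ms_error = ss_err / df["error"] if df["error"] > 0 else np.zeros_like(ss_err)
    ss = {
        "duration": ss_a,
        "protocol": ss_b,
        "interaction": np.clip(ss_int, 0.0, None),
        "error": np.clip(ss_err, 0.0, None),
        "total": ss_total,
    }
    return {"ss": ss, "df": df, "ms_error": ms_error}


def omega_squared(anova: dict) -> dict[str, np.ndarray]:
    """Bias-corrected percent explained variance per factor.

    omega^2 = (SS_term - df_term * MS_error) / (SS_total + MS_error) * 100.
    Not floored at zero: under the null, per-window values dip slightly
    negative, and that is what makes the estimator unbiased.
    """
    ss, df, mse = anova["ss"], anova["df"], anova["ms_error"]
    denom = ss["total"] + mse
    out = {}
    for f in FACTORS:
        num = ss[f] - df[f] * mse
        with np.errstate(invalid="ignore", divide="ignore"):
            val = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0) * 100.0, 0.0)
        out[f] = val
    return out
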