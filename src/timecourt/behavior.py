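"""Behavioral quantification of time estimation.

Response-time histograms, fixed-center Gaussian fits, and the scalar
(Weber-like) property: the SD of the timing distribution growing in
proportion to the timed duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class RtFit:
    """Fixed-center Gaussian fit to a response-time histogram."""

    duration: float
    bin_width: float
    counts: np.ndarray
    bin_centers: np.ndarray
    gauss_mean: float
    gauss_sigma: float
    amplitude: float
    r_squared: float
    excluded_bins: int = 0


def histogram_rts(
    rts,
    bin_width: float = 200.0,
    exclude_leading_bins: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Bin response times into contiguous half-open bins starting at 0.

    Returns ``(counts, bin_centers)`` with the leading
    ``exclude_leading_bins`` bins dropped (used to discard sub-400 ms
    opt-out responses on the longest duration before fitting).
    """
    rts = np.asarray([r for r in np.ravel(rts) if not np.isnan(r)], dtype=float)
    if rts.size == 0:
        raise ValueError("no response times to histogram")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.floor(rts.max() / bin_width)) + 1
    edges = bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(rts, bins=edges)
    centers = edges[:-1] + bin_width / 2.0
    k = int(exclude_leading_bins)
    return counts[k:].astype(float), centers[k:]


def fit_rt_gaussian(
    counts: np.ndarray,
    bin_centers: np.ndarray,
    *,
    duration: float = float("nan"),
    excluded_bins: int = 0,
) -> RtFit:
    """Fit ``A * exp(-(x - c)^2 / (2 sigma^2))`` to histogram counts.

    The center ``c`` is fixed to the center of the modal bin (ties broken
    to the earliest bin, with a warning), which keeps the spread estimate
    robust to early low-frequency responses; amplitude and sigma are then
    fit by least squares on the raw counts.  ``r_squared = 1 -
    SS_res/SS_tot``.
    """
    counts = np.asarray(counts, dtype=float)
    bin_centers = np.asarray(bin_centers, dtype=float)
    if np.count_nonzero(counts) < 3:
        raise ValueError("need at least 3 nonzero bins to fit")
    modal = int(np.argmax(counts))  # argmax returns the earliest maximal bin
    if np.count_nonzero(counts == counts[modal]) > 1:
        warnings.warn("modal-bin tie broken to the earliest bin", stacklevel=2)
    center = float(bin_centers[modal])
    bw = float(np.median(np.diff(bin_centers))) if len(bin_centers) > 1 else 200.0

    def model(x, amp, sigma):
        return amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)

    w = counts / counts.sum()
    sigma0 = float(np.sqrt(np.sum(w * (bin_centers - center) ** 2))) or bw
    try:
        (amp, sigma), _ = curve_fit(
            model,
            bin_centers,
            counts,
            p0=[counts[modal], sigma0],
            bounds=([0.0, 1e-9], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError:  # pragma: no cover - pathological histograms
        amp, sigma = counts[modal], sigma0
    resid = counts - model(bin_centers, amp, sigma)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return RtFit(
        duration=duration,
        bin_width=bw,
        counts=counts,
        bin_centers=bin_centers,
        gauss_mean=center,
        gauss_sigma=float(sigma),
        amplitude=float(amp),
        r_squared=r2,
        excluded_bins=excluded_bins,
    )


def fit_session_rts(
    rts_by_duration: dict[float, np.ndarray],
    bin_width: float = 200.0,
    *,
    exclude_leading_bins_longest: int = 2,
) -> list[RtFit]:
    """Histogram and fit the RTs of each target duration.

    The leading-bin exclusion (2 bins = 400 ms by default) applies only to
    the longest duration, where sub-400 ms responses reflect strategic
    opt-outs rather than genuine time estimates.
    """
    longest = max(rts_by_duration)
    fits = []
    for d in sorted(rts_by_duration):
        k = exclude_leading_bins_longest if d == longest else 0
        counts, centers = histogram_rts(rts_by_duration[d], bin_width, k)
        fits.append(fit_rt_gaussian(counts, centers, duration=d, excluded_bins=k))
    return fits


@dataclass
class ScalarSummary:
    """Center/sigma pairs across durations plus the scalar-property flag."""

    table: pd.DataFrame
    monotonic: bool = field(default=False)


def scalar_summary(fits: list[RtFit]) -> ScalarSummary:
    """Summarize Gaussian fits across durations, sorted by duration.

    ``monotonic`` is True iff sigma strictly increases with the fitted
    center — the scalar-timing signature.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 fits")
    fits = sorted(fits, key=lambda f: f.duration)
    table = pd.DataFrame(
        {
            "duration": [f.duration for f in fits],
            "center": [f.gauss_mean for f in fits],
            "sigma": [f.gauss_sigma for f in fits],
            "r_squared": [f.r_squared for f in fits],
        }
    )
    sig = table["sigma"].to_numpy()
    mono = bool(np.all(np.diff(sig) > 0))
    return ScalarSummary(table=table, monotonic=mono)
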