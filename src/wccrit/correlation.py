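"""Empirical autocorrelation of the firing rate and correlation times.

The normalized autocorrelation

    C_RR(t) = [<R(t'+t) R(t')> - <R>^2] / [<R^2> - <R>^2]

is estimated by fast convolution on the uniform sampling grid, with the
plug-in (biased) variance in the denominator for stability at long lags,
and per-lag standard errors from non-overlapping batch means.  The
maximum correlation time is extracted from a least-squares exponential
fit of the long-time tail, restricted to a window of correlation values
(default [0.01, 0.2] of the zero-lag peak) so that the fit sees the
slowest mode only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .simulate import RateTimeSeries

__all__ = ["CorrelationEstimate", "empirical_autocorrelation", "fit_correlation_time"]


@dataclass
class CorrelationEstimate:
    """Normalized autocorrelation on a lag grid with batch-means errors."""

    lags: np.ndarray  # ms
    values: np.ndarray  # C(0) = 1
    se: np.ndarray  # per-lag standard error
    n_samples: int


def _acf_fft(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Biased autocovariance estimate for lags 0..n_lags-1 via FFT."""
    n = len(x)
    x = x - x.mean()
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(fx * np.conj(fx), nfft)[:n_lags].real / n
    return acov


def empirical_autocorrelation(
    series: RateTimeSeries,
    max_lag: float,
    burn_in: float = 0.0,
    *,
    n_batches: int = 20,
) -> CorrelationEstimate:
    """Estimate C_RR(t) up to ``max_lag`` ms after discarding ``burn_in``.

    Standard errors come from recomputing the normalized autocorrelation
    on ``n_batches`` non-overlapping segments of the record.  Requires a
    record at least 10 lags long after burn-in; a constant series has no
    defined autocorrelation and is rejected.
    """
    work = series.discard(burn_in) if burn_in > 0 else series
    n_lags = int(round(max_lag / work.dt)) + 1
    x = work.rate
    if len(x) < 10 * (n_lags - 1) or len(x) < 2:
        raise ValueError("record too short: need length >= 10 * max_lag after burn-in")
    acov = _acf_fft(x, n_lags)
    if acov[0] <= 0:
        raise ValueError("zero variance: autocorrelation undefined for a constant series")
    values = acov / acov[0]

    batch_len = len(x) // n_batches
    if batch_len <= n_lags:
        n_batches = max(len(x) // (2 * n_lags), 2)
        batch_len = len(x) // n_batches
    rows = []
    for b in range(n_batches):
        seg = x[b * batch_len : (b + 1) * batch_len]
        c = _acf_fft(seg, n_lags)
        if c[0] > 0:
            rows.append(c / c[0])
    rows = np.stack(rows)
    se = rows.std(axis=0, ddof=1) / math.sqrt(len(rows))
    lags = work.dt * np.arange(n_lags)
    return CorrelationEstimate(lags=lags, values=values, se=se, n_samples=len(x))


def fit_correlation_time(
    corr: CorrelationEstimate,
    window: tuple[float, float] = (0.01, 0.2),
) -> float:
    """Maximum correlation time (ms) from the exponential tail.

    Least-squares slope of ln C vs t over the lags where the correlation
    (relative to its zero-lag peak) lies inside ``window``; returns
    -1/slope.  Non-positive correlation values are excluded; at least 5
    usable lags are required.
    """
    lo, hi = window
    if not 0 < lo < hi:
        raise ValueError("window must satisfy 0 < lo < hi")
    peak = corr.values[0]
    c = corr.values / peak
    mask = (c > 0) & (c >= lo) & (c <= hi) & (corr.lags > 0)
    if mask.sum() < 5:
        raise ValueError(
            f"only {int(mask.sum())} usable lags in the window {window}; need >= 5"
        )
    slope, _ = np.polyfit(corr.lags[mask], np.log(c[mask]), 1)
    if slope >= 0:
        raise ValueError("non-decaying tail: cannot extract a correlation time")
    return float(-1.0 / slope)
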