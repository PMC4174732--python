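"""Per-set variability and timing-mode statistics.

Precision of an isochronous performance is summarized by the coefficient of
variation (CV = SD/mean x 100).  The timing mode behind a performance is
read off the lag-one autocorrelation of produced intervals: an internal
timekeeper with motor delays (event-based timing) forces it into [-0.5, 0],
while dynamics-driven (emergent) timing yields values in (0, 0.5).  Because
the mode can drift within a performance, the coefficient is computed in
sliding windows (windowed lag-one autocorrelation, wg1), then summarized by
a Fisher-Z mean and by the percentage of positive/negative window values.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Tuple, Union

import numpy as np

from .errors import InsufficientDataError, ValidationError
from .series import IntervalSeries
from .tempo import round_half_up

logger = logging.getLogger(__name__)

#: Clipping bound applied before the Fisher Z-transform.
_Z_CLIP = 1.0 - 1e-12

ArrayLike = Union[np.ndarray, Sequence[float], IntervalSeries]


def _durations(series: ArrayLike) -> np.ndarray:
    if isinstance(series, IntervalSeries):
        return series.durations_ms
    return np.asarray(series, dtype=float)


def coefficient_of_variation(series: ArrayLike) -> float:
    """Coefficient of variation in percent: sample SD / mean x 100."""
    x = _durations(series)
    if x.size < 2:
        raise InsufficientDataError("CV needs at least 2 intervals")
    mean = float(np.mean(x))
    if mean <= 0:
        raise ValidationError("CV requires a positive mean")
    return float(np.std(x, ddof=1) / mean * 100.0)


def lag_one_autocorr(durations: ArrayLike) -> float:
    """Sample lag-one autocorrelation (mean-centered, lag-0 normalized)."""
    x = _durations(durations)
    if x.size < 3:
        raise InsufficientDataError("lag-one autocorrelation needs at least 3 values")
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        raise InsufficientDataError("lag-one autocorrelation undefined for constant series")
    return float(np.dot(xc[:-1], xc[1:]) / denom)


def lag_autocorr(durations: ArrayLike, lag: int) -> float:
    """Sample autocorrelation at an arbitrary positive lag."""
    x = _durations(durations)
    if lag < 1 or x.size < lag + 2:
        raise InsufficientDataError("series too short for requested lag")
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        raise InsufficientDataError("autocorrelation undefined for constant series")
    return float(np.dot(xc[:-lag], xc[lag:]) / denom)


def windowed_lag_one(
    series: ArrayLike,
    window_length: int = 30,
    step: int = 1,
    nested_mean: bool = False,
) -> np.ndarray:
    """Lag-one autocorrelation in sliding windows along the series.

    Each value is the lag-one autocorrelation of ``window_length``
    consecutive intervals; the window advances by ``step``.  With
    ``nested_mean`` each value is instead the mean of the lag-one
    autocorrelations of all minimal (3-interval) sub-windows inside the
    window — an alternative reading of "mean of a set of autocorrelations"
    kept behind this switch.
    """
    x = _durations(series)
    if window_length < 3:
        raise ValidationError("window_length must be at least 3")
    if step < 1:
        raise ValidationError("step must be at least 1")
    if x.size < window_length + 1:
        raise InsufficientDataError(
            f"series of length {x.size} is too short for window {window_length}"
        )
    starts = range(0, x.size - window_length + 1, step)
    if not nested_mean:
        return np.array([lag_one_autocorr(x[s : s + window_length]) for s in starts])
    out = []
    for s in starts:
        w = x[s : s + window_length]
        subs = [lag_one_autocorr(w[j : j + 3]) for j in range(window_length - 2)]
        out.append(float(np.mean(subs)))
    return np.array(out)


@dataclass
class WGammaSummary:
    """Summary of a windowed lag-one autocorrelation series.

    ``mean_wgamma`` is the inverse Fisher-Z of the mean Z-transformed window
    values (``mean_wgamma_raw`` keeps the plain arithmetic mean for
    descriptive output).  Window values of exactly zero count as
    non-positive, so the positive/negative percentages always sum to 100.
    """

    windowed_values: np.ndarray
    mean_wgamma: float
    mean_wgamma_raw: float
    mean_z: float
    pct_positive: float
    pct_negative: float
    window_length: int
    n_windows: int


def summarize_wgamma(windowed: ArrayLike, window_length: int = 30) -> WGammaSummary:
    """Fisher-Z mean and sign percentages of windowed autocorrelations.

    Coefficients at exactly +/-1 are clipped to +/-(1 - 1e-12) before the
    Z-transform, with a logged warning.
    """
    w = np.asarray(_durations(windowed), dtype=float)
    if w.size < 1:
        raise InsufficientDataError("need at least one windowed value")
    if np.any(np.abs(w) > 1.0):
        raise ValidationError("autocorrelation coefficients must lie in [-1, 1]")
    if np.any(np.abs(w) >= 1.0):
        logger.warning("clipping %d coefficient(s) at +/-1 before Fisher Z", int((np.abs(w) >= 1).sum()))
    z = np.arctanh(np.clip(w, -_Z_CLIP, _Z_CLIP))
    mean_z = float(np.mean(z))
    pct_pos = float(100.0 * np.count_nonzero(w > 0) / w.size)
    return WGammaSummary(
        windowed_values=w,
        mean_wgamma=float(np.tanh(mean_z)),
        mean_wgamma_raw=float(np.mean(w)),
        mean_z=mean_z,
        pct_positive=pct_pos,
        pct_negative=100.0 - pct_pos,
        window_length=window_length,
        n_windows=int(w.size),
    )


def wgamma_of_series(
    series: ArrayLike, window_length: int = 30, step: int = 1, nested_mean: bool = False
) -> WGammaSummary:
    """Convenience: windowed lag-one autocorrelation plus its summary."""
    w = windowed_lag_one(series, window_length=window_length, step=step, nested_mean=nested_mean)
    return summarize_wgamma(w, window_length=window_length)


def differential_percent(pct_ktt: float, pct_nktt: float) -> Tuple[float, float]:
    """Difference of positive-wg1 percentages and its equivalent increase.

    Returns ``(pct_ktt - pct_nktt, 100 * difference / pct_nktt)``, both
    rounded half-up to 2 decimals.
    """
    for p in (pct_ktt, pct_nktt):
        if not 0.0 <= p <= 100.0:
            raise ValidationError("percentages must lie in [0, 100]")
    diff = pct_ktt - pct_nktt
    if pct_nktt == 0.0:
        if diff == 0.0:
            return 0.0, 0.0
        raise ValidationError("equivalent increase undefined for a zero baseline")
    return round_half_up(diff), round_half_up(100.0 * diff / pct_nktt)


def classify_timing_mode(summary: WGammaSummary, threshold_pct: float = 60.0) -> str:
    """Label a performance ``event_based``, ``emergent``, or ``mixed``.

    Event-based requires a negative Fisher-Z mean wg1 with at least
    ``threshold_pct`` of windows negative; emergent is the mirror image;
    anything else (including a zero mean) is mixed.
    """
    if summary.mean_wgamma < 0 and summary.pct_negative >= threshold_pct:
        return "event_based"
    if summary.mean_wgamma > 0 and summary.pct_positive >= threshold_pct:
        return "emergent"
    return "mixed"
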