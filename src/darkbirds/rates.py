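"""Extinction-rate curves from chronologies.

The per-year rate at time t is d(t)/N(t): extinctions binned to year t
over the number of species still extant at the start of year t (the
present-day extant count plus every modelled species not yet extinct).
Rates are smoothed with a centred 100-year rolling mean per draw and
summarized across draws by the per-year median (mean by flag) with an
equal-tailed credible envelope; rates are compared to a background of
2 E/MSY (extinctions per million species-years) after multiplying by
one million.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

DEFAULT_SPAN = (-124049, 2019)
EXTANT_PRESENT = 10865


@dataclass
class RateSeries:
    """Per-year extinction counts, extant pool and rate for one chronology."""

    years: np.ndarray  # integer year axis, inclusive
    d: np.ndarray  # extinctions per year
    N: np.ndarray  # extant at the start of each year
    rate: np.ndarray  # d / N

    @property
    def total_events(self) -> int:
        return int(self.d.sum())


@dataclass
class RateSummary:
    years: np.ndarray
    central: np.ndarray  # per-year median (or mean) of rolling rates
    lo: np.ndarray
    hi: np.ndarray
    peaks: list  # [(year, rate), ...]


def extinction_rate_series(
    event_years, span: tuple[int, int] = DEFAULT_SPAN, extant_present: int = EXTANT_PRESENT
) -> RateSeries:
    """Bin a chronology's extinction years into a per-year rate series.

    Events are floored to integer years. N(t) counts species not yet
    extinct at the start of year t (a species lost in year t is alive at
    its start), so rate(t) <= 1 always and N is non-increasing.
    """
    years_f = np.asarray(getattr(event_years, "years", event_years), dtype=float)
    lo, hi = span
    binned = np.floor(years_f).astype(int)
    if len(binned) and (binned.min() < lo or binned.max() > hi):
        raise ValueError(f"event year outside span [{lo}, {hi}]")
    axis = np.arange(lo, hi + 1)
    d = np.bincount(binned - lo, minlength=len(axis)) if len(binned) else np.zeros(len(axis), dtype=int)
    # species extinct in year >= t are extant at the start of year t
    still_to_die = d[::-1].cumsum()[::-1]
    N = extant_present + still_to_die
    return RateSeries(years=axis, d=d, N=N.astype(float), rate=d / N)


def rolling_mean_rate(series: RateSeries | np.ndarray, window: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Centred rolling mean over complete windows only.

    Returns (years, smoothed); the year axis shrinks by window - 1.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if isinstance(series, RateSeries):
        years, values = series.years, series.rate
    else:
        values = np.asarray(series, dtype=float)
        years = np.arange(len(values))
    if window > len(values):
        raise ValueError("window longer than series")
    # O(n) complete-window mean via cumulative sums
    c = np.concatenate([[0.0], np.cumsum(values, dtype=np.float64)])
    smoothed = (c[window:] - c[:-window]) / window
    start = (window - 1) // 2
    return years[start : start + len(smoothed)], smoothed


def summarize_rate_draws(
    series_list: list[tuple[np.ndarray, np.ndarray]],
    level: float = 0.95,
    central: str = "median",
    peak_prominence: float | None = None,
) -> RateSummary:
    """Cross-draw summary of (already rolled) rate series.

    All series must share one year axis. ``central`` is the per-year
    median by default (the mean by flag); the envelope is the
    equal-tailed interval at ``level``. Peaks are local maxima of the
    central curve above a prominence threshold (default: 10% of the
    central maximum) -- a reporting aid for identifying extinction waves.
    """
    if len(series_list) < 2:
        raise ValueError("need at least 2 draws to summarize")
    years0 = np.asarray(series_list[0][0])
    for yrs, _ in series_list[1:]:
        if len(yrs) != len(years0) or not np.array_equal(np.asarray(yrs), years0):
            raise ValueError("rate series have mismatched year axes")
    stack = np.vstack([np.asarray(v, dtype=np.float32) for _, v in series_list])
    if central == "median":
        mid = np.median(stack, axis=0)
    elif central == "mean":
        mid = stack.mean(axis=0)
    else:
        raise ValueError("central must be 'median' or 'mean'")
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(stack, alpha, axis=0)
    hi = np.quantile(stack, 1.0 - alpha, axis=0)
    prom = peak_prominence if peak_prominence is not None else 0.1 * float(mid.max() or 1.0)
    idx, _ = scipy.signal.find_peaks(mid, prominence=prom)
    peaks = [(int(years0[i]), float(mid[i])) for i in idx]
    return RateSummary(years=years0, central=np.asarray(mid, float), lo=np.asarray(lo, float), hi=np.asarray(hi, float), peaks=peaks)


def rate_to_background_ratio(rate, background_emsy: float = 2.0):
    """Ratio of a per-species-per-year rate to the background E/MSY.

    The rate is converted to E/MSY by multiplying by one million, then
    divided by the background (default 2 E/MSY).
    """
    if background_emsy <= 0:
        raise ValueError("background must be > 0")
    return np.asarray(rate, dtype=float) * 1e6 / background_emsy
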