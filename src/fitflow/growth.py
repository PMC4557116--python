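"""Microcolony growth rates and the slow-growing-fraction statistic.

The growth rate of a microcolony is the maximum slope of ln(area) against
time over any contiguous window of at least three measurements spanning at
least 180 minutes with an OLS R^2 >= 0.95 — the maximum-slope rule makes
the estimate insensitive to lag phases before growth and to crowding after.

The fraction of slow-growing colonies in a population is read off the
empirical CDF of the per-colony rates: a tangent line is fitted at the
point of maximal CDF slope (the density mode).  For a uniform rate
distribution the tangent explains 100% of the data; for a single Gaussian
the small unexplained masses in the lower-left and upper-right corners of
the CDF cancel.  Any *excess* of unexplained slow mass over unexplained
fast mass is therefore attributable to a distinct slow subpopulation:

    fraction_slow = max(0, F(x_lo) - (1 - F(x_hi)))

where x_lo and x_hi are the tangent's intercepts with 0 and 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import ColonyTrack

MIN_POINTS = 3
MIN_SPAN_MINUTES = 180.0
MIN_R2 = 0.95
MIN_RATES = 50  # floor for the slow-fraction statistic


@dataclass
class GrowthRateResult:
    track_id: int
    rate: float  # max slope of ln(area) vs time, per hour
    window: tuple[float, float]  # (start, end) times in minutes
    r_squared: float
    qualified: bool


@dataclass
class SlowFractionResult:
    x0: float  # rate at maximal CDF slope (density mode)
    slope: float  # tangent slope, CDF units per rate unit
    x_lo: float  # tangent = 0 intercept
    x_hi: float  # tangent = 1 intercept
    unexplained_slow: float  # CDF mass strictly below x_lo
    unexplained_fast: float  # mass strictly above x_hi
    fraction_slow: float  # max(0, unexplained_slow - unexplained_fast)
    percent_explained: float  # 100 * (1 - slow - fast)
    n: int


def _window_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope and R^2 of y on t.  Flat y (zero variance) gives R^2 = 1."""
    tm = t.mean()
    ym = y.mean()
    dt = t - tm
    dy = y - ym
    stt = float(dt @ dt)
    sty = float(dt @ dy)
    syy = float(dy @ dy)
    slope = sty / stt
    if syy <= 0:
        return slope, 1.0
    r2 = (sty * sty) / (stt * syy)
    return slope, r2


def colony_growth_rate(
    track: ColonyTrack | tuple[np.ndarray, np.ndarray],
    min_points: int = MIN_POINTS,
    min_span_minutes: float = MIN_SPAN_MINUTES,
    min_r2: float = MIN_R2,
) -> GrowthRateResult:
    """Maximum qualifying-window slope of ln(area) vs time, in 1/h.

    ``track`` is a :class:`~fitflow.imaging.ColonyTrack` or a
    ``(times_minutes, areas)`` pair.  All contiguous windows of at least
    ``min_points`` records spanning at least ``min_span_minutes`` are fitted
    by OLS on the natural-log areas; among windows with R^2 >= ``min_r2``
    the maximum slope wins.  If no window qualifies, ``qualified`` is False
    and the best-R^2 window's slope is reported for diagnostics.
    """
    if isinstance(track, ColonyTrack):
        times = np.asarray(track.times, dtype=float)
        areas = np.asarray(track.areas, dtype=float)
        track_id = track.track_id
    else:
        times, areas = track
        times = np.asarray(times, dtype=float)
        areas = np.asarray(areas, dtype=float)
        track_id = -1
    if len(times) < min_points:
        return GrowthRateResult(track_id, float("nan"), (float("nan"),) * 2, float("nan"), False)
    if np.any(areas <= 0):
        raise ValueError("non-positive area in track (upstream segmentation bug)")
    y = np.log(areas)
    n = len(times)
    best_slope = -np.inf
    best: tuple[float, tuple[float, float], float] | None = None
    fallback: tuple[float, tuple[float, float], float] | None = None
    for i in range(n - min_points + 1):
        for j in range(i + min_points - 1, n):
            if times[j] - times[i] < min_span_minutes:
                continue
            slope, r2 = _window_fit(times[i : j + 1], y[i : j + 1])
            if fallback is None or r2 > fallback[2]:
                fallback = (slope, (times[i], times[j]), r2)
            if r2 >= min_r2 and slope > best_slope:
                best_slope = slope
                best = (slope, (times[i], times[j]), r2)
    if best is not None:
        slope, window, r2 = best
        return GrowthRateResult(track_id, slope * 60.0, window, r2, True)
    if fallback is not None:
        slope, window, r2 = fallback
        return GrowthRateResult(track_id, slope * 60.0, window, r2, False)
    return GrowthRateResult(track_id, float("nan"), (float("nan"),) * 2, float("nan"), False)


def growth_rates(
    tracks: list[ColonyTrack],
    min_points: int = MIN_POINTS,
    min_span_minutes: float = MIN_SPAN_MINUTES,
    min_r2: float = MIN_R2,
    require_doubling: bool = True,
) -> list[GrowthRateResult]:
    """Per-track growth rates, restricted to doubling-passed tracks."""
    out = []
    for tr in tracks:
        if require_doubling and not tr.passed_doubling:
            continue
        if tr.n_records < min_points:
            continue
        out.append(
            colony_growth_rate(
                tr,
                min_points=min_points,
                min_span_minutes=min_span_minutes,
                min_r2=min_r2,
            )
        )
    return out


def slow_fraction(
    rates: np.ndarray,
    window: int | None = None,
    min_rates: int = MIN_RATES,
) -> SlowFractionResult:
    """CDF-tangent estimate of the slow-growing colony fraction.

    The empirical CDF of the sorted rates (F(x_(i)) = i/n) is scanned with
    a sliding window of ``window`` consecutive order statistics (default
    max(11, 5% of n)); the window with the largest OLS slope of F on x
    defines the tangent point x0 (ties broken toward the median rate) and
    the tangent slope.  Mass below the tangent's zero-intercept is
    "unexplained slow", mass above its one-intercept "unexplained fast";
    their difference, clipped at zero, is the slow-growing fraction.
    Invariant under shifting all rates and equivariant under positive
    scaling.
    """
    rates = np.sort(np.asarray(rates, dtype=float))
    n = len(rates)
    if n < min_rates:
        raise ValueError(f"need >= {min_rates} rates, got {n}")
    if window is None:
        window = max(11, int(np.ceil(0.05 * n)))
    window = min(window, n)
    F = np.arange(1, n + 1) / n

    # vectorised sliding-window OLS slope of F on x
    w = window
    x = rates
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cx2 = np.concatenate([[0.0], np.cumsum(x * x)])
    cf = np.concatenate([[0.0], np.cumsum(F)])
    cxf = np.concatenate([[0.0], np.cumsum(x * F)])
    sx = cx[w:] - cx[:-w]
    sx2 = cx2[w:] - cx2[:-w]
    sf = cf[w:] - cf[:-w]
    sxf = cxf[w:] - cxf[:-w]
    stt = sx2 - sx * sx / w
    sty = sxf - sx * sf / w
    # windows of (near-)tied rates have no usable slope; the cutoff is
    # relative so the statistic stays scale-equivariant
    usable = stt > 1e-12 * np.maximum(sx2, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = np.where(usable, sty / np.where(usable, stt, 1.0), -np.inf)
    if not np.any(np.isfinite(slopes) & (slopes > 0)):
        raise ValueError("degenerate rate distribution: no positive CDF slope")
    smax = slopes.max()
    # near-exact ties broken toward the window whose centre is nearest the median
    candidates = np.nonzero(slopes >= smax * (1 - 1e-9))[0]
    centers = candidates + (w - 1) / 2
    pick = candidates[np.argmin(np.abs(centers - (n - 1) / 2))]
    s = float(slopes[pick])
    center_idx = pick + (w - 1) // 2
    x0 = float(rates[center_idx])
    F0 = F[center_idx]
    x_lo = x0 - F0 / s
    x_hi = x0 + (1.0 - F0) / s
    unexplained_slow = float(np.count_nonzero(rates < x_lo)) / n
    unexplained_fast = float(np.count_nonzero(rates > x_hi)) / n
    fraction_slow = max(0.0, unexplained_slow - unexplained_fast)
    return SlowFractionResult(
        x0=x0,
        slope=s,
        x_lo=float(x_lo),
        x_hi=float(x_hi),
        unexplained_slow=unexplained_slow,
        unexplained_fast=unexplained_fast,
        fraction_slow=fraction_slow,
        percent_explained=100.0 * (1.0 - unexplained_slow - unexplained_fast),
        n=n,
    )


@dataclass
class DistributionSummary:
    mode: float  # rate at maximal CDF slope
    width: float  # interquartile range of the rates
    fraction_slow: float
    n: int


def distribution_summary(
    rates: np.ndarray, window: int | None = None, min_rates: int = MIN_RATES
) -> DistributionSummary:
    """Mode, IQR width and slow fraction of a growth-rate sample.

    Conditions can shift the mode (overall slowdown), broaden the
    distribution, or grow a distinct slow tail; reporting all three
    separates those effects.
    """
    res = slow_fraction(rates, window=window, min_rates=min_rates)
    q1, q3 = np.percentile(np.asarray(rates, dtype=float), [25, 75])
    return DistributionSummary(
        mode=res.x0, width=float(q3 - q1), fraction_slow=res.fraction_slow, n=res.n
    )
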