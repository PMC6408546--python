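"""Minimum sampling effort for whole-period stem-flux estimation.

How many discrete (e.g. manual) measurements would have been needed to
characterize the variance of the full automated record? For each sample size
n on a grid, replicates of n values are drawn with replacement from the
pooled stem measurements, the sample variance of each draw is computed, and
the median variance over replicates is tracked against n. The median curve
falls steeply at small n and stabilizes once n "explains" the population
variance; the stabilization point — the breakpoint located by the crossing of
the progressive and retrograde sequential Mann-Kendall statistics of the
curve — is the minimum number of measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class SufficiencyCurve:
    n_grid: np.ndarray
    replicate_variances: np.ndarray  # (len(n_grid), reps)
    median_variance: np.ndarray
    breakpoint_n: Optional[int] = None
    breakpoint_flagged: bool = False
    mk_progressive: np.ndarray = field(default=None)
    mk_retrograde: np.ndarray = field(default=None)
    trend_left: Optional[tuple] = None  # (slope, intercept) of log sigma vs n
    trend_right: Optional[tuple] = None

    @property
    def median_sigma(self) -> np.ndarray:
        return np.sqrt(self.median_variance)


def resample_variances(
    pool: np.ndarray,
    n_grid: np.ndarray | range = range(3, 251),
    reps: int = 40,
    seed: int | np.random.Generator = 0,
) -> SufficiencyCurve:
    """Median-of-replicate-variances curve over a sample-size grid.

    Draws are with replacement from ``pool`` (NaNs dropped); each replicate
    statistic is the (n-1)-denominator sample variance. Identical (pool,
    grid, reps, seed) inputs reproduce the curve exactly.
    """
    pool = np.asarray(pool, dtype=float)
    pool = pool[~np.isnan(pool)]
    if pool.size < 3:
        raise ValueError("measurement pool must contain >= 3 values")
    n_grid = np.asarray(list(n_grid), dtype=int)
    if np.any(np.diff(n_grid) <= 0):
        raise ValueError("n_grid must be strictly increasing")
    rng = np.random.default_rng(seed)
    variances = np.empty((n_grid.size, reps))
    for i, n in enumerate(n_grid):
        draws = rng.choice(pool, size=(reps, int(n)), replace=True)
        variances[i] = draws.var(axis=1, ddof=1)
    return SufficiencyCurve(
        n_grid=n_grid,
        replicate_variances=variances,
        median_variance=np.median(variances, axis=1),
    )


def sequential_mann_kendall(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Progressive u(t) and retrograde u'(t) sequential Mann-Kendall statistics.

    The progressive statistic standardizes the cumulative exceedance count
    t_i = sum_{k<=i} #{j < k : x_k > x_j} by its null mean i(i-1)/4 and
    variance i(i-1)(2i+5)/72. The retrograde series is the same statistic on
    the reversed series, sign-flipped and re-reversed onto the original time
    axis; their crossing locates a change in trend. Ties receive half credit,
    which keeps the statistic centred (an all-tied series gives u identically
    zero) and prevents flat curve segments from masquerading as trends.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("series must have length >= 4")

    def progressive(v: np.ndarray) -> np.ndarray:
        counts = np.empty(n)
        for k in range(n):
            counts[k] = np.sum(v[k] > v[:k]) + 0.5 * np.sum(v[k] == v[:k])
        t = np.cumsum(counts)
        i = np.arange(1, n + 1, dtype=float)
        mean = i * (i - 1) / 4.0
        var = i * (i - 1) * (2.0 * i + 5.0) / 72.0
        with np.errstate(invalid="ignore", divide="ignore"):
            u = (t - mean) / np.sqrt(var)
        u[var == 0] = 0.0
        return u

    u_prog = progressive(x)
    u_retro = -progressive(x[::-1])[::-1]
    return u_prog, u_retro


def detect_breakpoint(curve: SufficiencyCurve, on: str = "variance") -> SufficiencyCurve:
    """Locate the variance-stabilization breakpoint on the median curve.

    The breakpoint separates two trend regimes: it is the grid point whose
    two-segment least-squares fit (straight lines on log sigma vs log n, left
    and right of the split — sampling variance decays as a power of n, so the
    declining limb is linear on that axis) minimizes the total residual sum
    of squares: the "two variance regression trends" summary of the curve. The sequential
    Mann-Kendall statistics of the curve are stored for trend reporting, and
    the detection is flagged as unreliable when the right-hand segment still
    carries a significant Mann-Kendall trend (the variance never stabilized,
    e.g. a strictly monotone curve) or when the curve is constant.
    """
    med = np.asarray(curve.median_variance, dtype=float)
    if on == "sigma":
        values = np.sqrt(med)
    elif on == "log_sigma":
        values = 0.5 * np.log(np.maximum(med, 1e-300))
    else:
        values = med
    if np.all(values == values[0]):
        curve.breakpoint_n = None
        curve.breakpoint_flagged = True
        return curve

    u, u_retro = sequential_mann_kendall(values)
    curve.mk_progressive = u
    curve.mk_retrograde = u_retro

    n_pts = curve.n_grid.size
    log_sigma = 0.5 * np.log(np.maximum(med, 1e-300))
    x = np.log(curve.n_grid.astype(float))

    def seg_rss(xs: np.ndarray, ys: np.ndarray) -> float:
        coef = np.polyfit(xs, ys, 1)
        return float(np.sum((ys - np.polyval(coef, xs)) ** 2))

    best_split, best_cost = None, np.inf
    for split in range(3, n_pts - 3):
        cost = seg_rss(x[:split], log_sigma[:split]) + seg_rss(x[split:], log_sigma[split:])
        if cost < best_cost:
            best_split, best_cost = split, cost

    curve.breakpoint_n = int(curve.n_grid[best_split])
    curve.trend_left = tuple(np.polyfit(x[:best_split], log_sigma[:best_split], 1))
    curve.trend_right = tuple(np.polyfit(x[best_split:], log_sigma[best_split:], 1))

    # stabilization check: the right-hand limb must be trend-free both
    # statistically (sequential MK) and practically (negligible slope
    # relative to the declining limb)
    u_right, _ = sequential_mann_kendall(values[best_split:])
    slope_ratio = (
        abs(curve.trend_right[0]) / abs(curve.trend_left[0])
        if curve.trend_left[0] != 0 else np.inf
    )
    curve.breakpoint_flagged = bool(abs(u_right[-1]) >= 1.96 and slope_ratio > 0.1)
    return curve


def minimum_sampling_effort(
    pool: np.ndarray,
    n_grid: np.ndarray | range = range(3, 251),
    reps: int = 40,
    seed: int | np.random.Generator = 0,
    on: str = "variance",
) -> SufficiencyCurve:
    """Resample, build the median-variance curve, and detect its breakpoint."""
    curve = resample_variances(pool, n_grid=n_grid, reps=reps, seed=seed)
    return detect_breakpoint(curve, on=on)
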