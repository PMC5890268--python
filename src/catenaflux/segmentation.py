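"""Structural-change segmentation of the soil-moisture record.

Partitions a daily moisture series into regimes by globally optimal piecewise
linear regression (each segment gets its own intercept and time trend),
selects the number of breakpoints by BIC, and tests for structural change
with a supF statistic whose null distribution is obtained by parametric
simulation.  The optimal partition for a given number of breaks is found by
dynamic programming over a precomputed triangle of segment RSS values, which
is exactly equivalent to exhaustive enumeration of admissible breakpoint
sets.

Breakpoint convention: a breakpoint is the index (and date) of the *first
observation of the new segment*; segments are half-open index ranges
``[start, end)`` that tile the series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Segment",
    "SegmentationConfig",
    "SegmentationResult",
    "daily_moisture_series",
    "optimal_breakpoints",
    "segment_moisture",
    "select_n_breaks",
    "sup_f_test",
]

_K_REGRESSORS = 2  # intercept + linear time trend per segment


@dataclass(frozen=True)
class SegmentationConfig:
    """Tuning of the segmentation: ``max_breaks`` candidate breakpoint
    counts, minimum segment fraction ``h`` of the series length, and the
    number of null simulations behind the supF p-value."""

    max_breaks: int = 4
    h: float = 0.15
    n_null_sims: int = 999
    max_gap_days: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.h < 0.5):
            raise ValueError("h must be in (0, 0.5)")
        if self.max_breaks < 0:
            raise ValueError("max_breaks must be >= 0")

    def min_segment(self, n: int) -> int:
        return max(int(math.ceil(self.h * n)), _K_REGRESSORS + 1)


@dataclass(frozen=True)
class Segment:
    start: int      # inclusive
    end: int        # exclusive
    intercept: float
    slope: float
    rss: float
    n: int


@dataclass
class SegmentationResult:
    breakpoints: list[int]
    breakpoint_dates: list[pd.Timestamp] | None
    segments: list[Segment]
    bic_table: dict[int, float]
    chosen_n_breaks: int
    supF: float | None = None
    p_value: float | None = None
    n: int = 0
    rss_table: dict[int, float] = field(default_factory=dict)


class _SegmentCost:
    """O(1) per-segment OLS RSS of y ~ 1 + t on [i, j) via prefix sums."""

    def __init__(self, y: np.ndarray):
        y = np.asarray(y, dtype=float)
        n = y.size
        x = np.arange(n, dtype=float)
        z = np.zeros(1)
        self.n = n
        self.cx = np.concatenate([z, np.cumsum(x)])
        self.cxx = np.concatenate([z, np.cumsum(x * x)])
        self.cy = np.concatenate([z, np.cumsum(y)])
        self.cyy = np.concatenate([z, np.cumsum(y * y)])
        self.cxy = np.concatenate([z, np.cumsum(x * y)])

    def rss(self, i, j):
        """RSS of the per-segment OLS fit; i, j broadcastable arrays."""
        i = np.asarray(i)
        j = np.asarray(j)
        m = (j - i).astype(float)
        sx = self.cx[j] - self.cx[i]
        sxx = self.cxx[j] - self.cxx[i]
        sy = self.cy[j] - self.cy[i]
        syy = self.cyy[j] - self.cyy[i]
        sxy = self.cxy[j] - self.cxy[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            sxx_c = sxx - sx * sx / m
            sxy_c = sxy - sx * sy / m
            syy_c = syy - sy * sy / m
            out = syy_c - np.where(sxx_c > 0, sxy_c * sxy_c
                                   / np.where(sxx_c > 0, sxx_c, 1.0), 0.0)
        return np.maximum(out, 0.0)

    def fit(self, i: int, j: int) -> Segment:
        m = j - i
        sx = self.cx[j] - self.cx[i]
        sy = self.cy[j] - self.cy[i]
        sxy = self.cxy[j] - self.cxy[i]
        sxx = self.cxx[j] - self.cxx[i]
        sxx_c = sxx - sx * sx / m
        slope = (sxy - sx * sy / m) / sxx_c if sxx_c > 0 else 0.0
        intercept = sy / m - slope * sx / m
        return Segment(start=i, end=j, intercept=float(intercept),
                       slope=float(slope), rss=float(self.rss(i, j)), n=m)


def _dp_partition(cost: _SegmentCost, n_breaks: int, min_len: int
                  ) -> tuple[list[int], float]:
    """Globally RSS-optimal breakpoints (starts of segments 2..m+1)."""
    n = cost.n
    if n < (n_breaks + 1) * min_len:
        raise ValueError(
            f"series of length {n} cannot hold {n_breaks + 1} segments of "
            f"length >= {min_len}")
    starts = np.arange(n + 1)
    rss_mat = cost.rss(starts[:, None], starts[None, :])
    short = (starts[None, :] - starts[:, None]) < min_len
    rss_mat = np.where(short, np.inf, rss_mat)

    # dp[m][j]: best cost of splitting y[0:j] into m+1 segments
    dp = np.full((n_breaks + 1, n + 1), np.inf)
    arg = np.zeros((n_breaks + 1, n + 1), dtype=int)
    dp[0] = rss_mat[0]
    for m in range(1, n_breaks + 1):
        cand = dp[m - 1][:, None] + rss_mat  # (i, j)
        arg[m] = np.argmin(cand, axis=0)
        dp[m] = cand[arg[m], starts]
    total = float(dp[n_breaks, n])
    bps: list[int] = []
    j = n
    for m in range(n_breaks, 0, -1):
        i = int(arg[m, j])
        bps.append(i)
        j = i
    return sorted(bps), total


def optimal_breakpoints(
    y: Sequence[float], n_breaks: int, config: SegmentationConfig | None = None
) -> tuple[list[int], list[Segment]]:
    """Breakpoint set minimising total RSS of per-segment OLS fits."""
    config = config or SegmentationConfig()
    y = np.asarray(y, dtype=float)
    cost = _SegmentCost(y)
    min_len = config.min_segment(y.size)
    bps, _ = _dp_partition(cost, n_breaks, min_len)
    edges = [0, *bps, y.size]
    segments = [cost.fit(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
    return bps, segments


def select_n_breaks(
    y: Sequence[float],
    config: SegmentationConfig | None = None,
    dates: pd.DatetimeIndex | None = None,
    rng: np.random.Generator | None = None,
) -> SegmentationResult:
    """Choose the breakpoint count by BIC over m = 0..max_breaks.

    The parameter count for m breaks is ``(m+1)*2 + m + 1`` (two regression
    coefficients per segment, the break positions, one error variance).
    When ``rng`` is given the supF structural-change test is run as well.
    """
    config = config or SegmentationConfig()
    y = np.asarray(y, dtype=float)
    n = y.size
    cost = _SegmentCost(y)
    min_len = config.min_segment(n)
    bic_table: dict[int, float] = {}
    rss_table: dict[int, float] = {}
    fits: dict[int, list[int]] = {}
    for m in range(config.max_breaks + 1):
        if n < (m + 1) * min_len:
            break
        bps, total = _dp_partition(cost, m, min_len)
        rss_table[m] = total
        p = (m + 1) * _K_REGRESSORS + m + 1
        bic_table[m] = n * math.log(max(total, 1e-300) / n) + p * math.log(n)
        fits[m] = bps
    if not bic_table:
        raise ValueError("series too short for any admissible segmentation")
    chosen = min(bic_table, key=lambda m: (bic_table[m], m))
    bps = fits[chosen]
    edges = [0, *bps, n]
    segments = [cost.fit(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
    bp_dates = [dates[i] for i in bps] if dates is not None else None
    result = SegmentationResult(
        breakpoints=bps, breakpoint_dates=bp_dates, segments=segments,
        bic_table=bic_table, chosen_n_breaks=chosen, n=n, rss_table=rss_table)
    if rng is not None:
        result.supF, result.p_value = sup_f_test(y, config, rng=rng)
    return result


def _supf_stat(cost: _SegmentCost, min_len: int) -> float:
    """Max single-break F statistic over admissible break positions."""
    n = cost.n
    rss0 = float(cost.rss(0, n))
    splits = np.arange(min_len, n - min_len + 1)
    if splits.size == 0:
        return 0.0
    rss1 = cost.rss(np.zeros_like(splits), splits) + cost.rss(splits, n)
    dof = n - 2 * _K_REGRESSORS
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss0 - rss1) / _K_REGRESSORS) / (rss1 / dof)
    f = np.where(rss1 > 0, f, 0.0)
    return float(np.max(f))


def sup_f_test(
    y: Sequence[float],
    config: SegmentationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """supF structural-change test with a simulated null distribution.

    The F statistic compares the single-regression fit against the best
    one-break fit at each admissible split; the p-value is estimated from
    ``n_null_sims`` series of iid Gaussian noise (the statistic is invariant
    to the null's intercept, trend and error variance).
    """
    config = config or SegmentationConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    y = np.asarray(y, dtype=float)
    n = y.size
    min_len = config.min_segment(n)
    if n < 2 * min_len:
        raise ValueError("series too short for a single admissible break")
    observed = _supf_stat(_SegmentCost(y), min_len)
    exceed = 0
    for _ in range(config.n_null_sims):
        null = _supf_stat(_SegmentCost(rng.standard_normal(n)), min_len)
        if null >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + config.n_null_sims)
    return observed, p


def daily_moisture_series(
    sensors: pd.DataFrame,
    value_col: str = "moisture",
    max_gap_days: int = 3,
) -> pd.Series:
    """Daily catena-mean series: average the variable over all sensors per
    day, fill gaps of up to ``max_gap_days`` days by linear interpolation."""
    df = sensors.copy()
    df["date"] = pd.to_datetime(df["timestamp"]).dt.normalize()
    daily = df.groupby("date")[value_col].mean()
    full = pd.date_range(daily.index.min(), daily.index.max(), freq="D")
    daily = daily.reindex(full)
    # fill interior gaps of <= max_gap_days entirely; leave longer gaps NaN
    filled = daily.interpolate(method="linear", limit_area="inside")
    isna = daily.isna().to_numpy()
    run_start = None
    keep = np.zeros(len(daily), dtype=bool)
    for i, bad in enumerate([*isna, False]):
        if bad and run_start is None:
            run_start = i
        elif not bad and run_start is not None:
            if i - run_start <= max_gap_days:
                keep[run_start:i] = True
            run_start = None
    out = daily.copy()
    out[keep] = filled[keep]
    return out


def segment_moisture(
    sensors: pd.DataFrame,
    config: SegmentationConfig | None = None,
    rng: np.random.Generator | None = None,
    value_col: str = "moisture",
) -> SegmentationResult:
    """Segment the daily catena-mean moisture record.

    Gaps longer than ``max_gap_days`` split the record; the longest
    contiguous chunk is segmented.
    """
    config = config or SegmentationConfig()
    daily = daily_moisture_series(sensors, value_col, config.max_gap_days)
    # longest run without NaN
    isna = daily.isna().to_numpy()
    best, cur_start, best_rng = 0, None, (0, 0)
    for i, bad in enumerate([*isna, True]):
        if not bad and cur_start is None:
            cur_start = i
        elif bad and cur_start is not None:
            if i - cur_start > best:
                best, best_rng = i - cur_start, (cur_start, i)
            cur_start = None
    chunk = daily.iloc[best_rng[0]:best_rng[1]]
    return select_n_breaks(chunk.to_numpy(), config, dates=chunk.index, rng=rng)
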