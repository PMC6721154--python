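"""Duration of increased melatonin secretion.

The statistic: within one group, fraction concentrations over the day are
submitted to a repeated-measures ANOVA (glands x sampling times); the
within-subject error mean square feeds least-significant-difference (LSD)
contrasts of every timepoint against the lowest timepoint of the
preceding and of the following photophase (or subjective day, under
constant conditions).  The elevated window runs from the first timepoint
significantly above the preceding reference minimum to the last timepoint
significantly above the following one; its length in hours is the
duration of increased secretion for that cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .clocktime import wrap24
from .light_schedule import LightSchedule, scotophase_windows
from .simulator import FractionSeries


class MissingWindowError(ValueError):
    """The day lacks a preceding or following photophase in the series."""


@dataclass
class RmAnovaResult:
    ms_error: float
    df_error: int
    time_means: np.ndarray
    n_subjects: int
    ss_time: float
    ss_subject: float
    ss_error: float


@dataclass
class DurationResult:
    day_index: int
    start_time: float | None  # clock, decimal hours
    end_time: float | None
    duration_h: float | None
    ref_min_prev: tuple[float, float]  # (clock time, group mean)
    ref_min_next: tuple[float, float]
    alpha: float
    day1_convention: bool = False  # previous reference taken within day 1

    @property
    def defined(self) -> bool:
        return self.duration_h is not None


def rm_anova(data: np.ndarray) -> RmAnovaResult:
    """One-group repeated-measures decomposition of a subjects x times matrix.

    SS_total = SS_subject + SS_time + SS_error with
    df_error = (n_times - 1)(n_subjects - 1).  Missing cells are not
    imputed and raise.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 3:
        raise ValueError("need a glands x timepoints matrix, >=2 glands, >=3 times")
    if np.any(~np.isfinite(x)):
        raise ValueError("missing cells are not allowed")
    n, t = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    ss_subject = float(t * ((row_means - grand) ** 2).sum())
    ss_time = float(n * ((col_means - grand) ** 2).sum())
    ss_error = max(ss_total - ss_subject - ss_time, 0.0)
    df_error = (t - 1) * (n - 1)
    return RmAnovaResult(ms_error=ss_error / df_error, df_error=df_error,
                         time_means=col_means, n_subjects=n,
                         ss_time=ss_time, ss_subject=ss_subject, ss_error=ss_error)


def lsd_threshold(res: RmAnovaResult, alpha: float = 0.05) -> float:
    """Least significant difference between two timepoint means."""
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, res.df_error)
    return float(tcrit * math.sqrt(2.0 * res.ms_error / res.n_subjects))


def lsd_contrast(res: RmAnovaResult, t1: int, t2: int, alpha: float = 0.05) -> bool:
    """Whether the means at two timepoints differ by more than the LSD.

    At ms_error = 0 (noise-free fixtures) any nonzero difference counts
    as significant (the limit of the test as the error variance vanishes);
    a difference exactly at the boundary is not significant.
    """
    diff = abs(res.time_means[t1] - res.time_means[t2])
    if res.ms_error == 0.0:
        return diff > 0.0
    return diff > lsd_threshold(res, alpha)


def _night_for_day(nights, day_index: int):
    lo, hi = 24.0 * (day_index - 1), 24.0 * day_index
    for k, (s, e) in enumerate(nights):
        if lo - 1e-6 <= s < hi - 1e-6:
            return k, (s, e)
    raise MissingWindowError(f"no scotophase/subjective night starts on day {day_index}")


def _context(series_set, schedule, day_index, reference):
    if len(series_set) < 2:
        raise ValueError("need at least 2 glands")
    grid = series_set[0].t_mid
    for s in series_set[1:]:
        if len(s.t_mid) != len(grid) or not np.allclose(s.t_mid, grid):
            raise ValueError("glands must share the fraction time grid")

    nights = scotophase_windows(schedule, reference)
    k, (n_start, n_end) = _night_for_day(nights, day_index)

    t0 = float(grid[0])
    day1_convention = False
    if k == 0:
        prev_lo, prev_hi = t0, n_start
        day1_convention = True
    else:
        prev_lo, prev_hi = nights[k - 1][1], n_start
    next_lo = n_end
    next_hi = nights[k + 1][0] if k + 1 < len(nights) else min(n_end + 24.0, grid[-1])

    prev_idx = np.nonzero((grid >= prev_lo - 1e-9) & (grid < prev_hi - 1e-9))[0]
    next_idx = np.nonzero((grid >= next_lo - 1e-9) & (grid < next_hi + 1e-9))[0]
    if prev_idx.size == 0:
        raise MissingWindowError(
            f"day {day_index}: no fractions in the preceding photophase/subjective day")
    if next_idx.size == 0:
        raise MissingWindowError(
            f"day {day_index}: no fractions in the following photophase/subjective day")

    lo_i, hi_i = int(prev_idx[0]), int(next_idx[-1])
    sub = slice(lo_i, hi_i + 1)
    x = np.vstack([s.concentration[sub] for s in series_set])
    res = rm_anova(x)
    means = res.time_means
    t_sub = grid[sub]

    ref_prev_loc = int(prev_idx[np.argmin(means[prev_idx[0] - lo_i: prev_idx[-1] - lo_i + 1])]) - lo_i
    ref_next_loc = int(next_idx[np.argmin(means[next_idx[0] - lo_i: next_idx[-1] - lo_i + 1])]) - lo_i
    return res, t_sub, ref_prev_loc, ref_next_loc, day1_convention


def _scan(values, res, t_sub, ref_prev, ref_next, alpha, day_index,
          day1_convention) -> DurationResult:
    """First/last timepoint of ``values`` significantly different from the
    reference minima, using the group error term."""
    thr = lsd_threshold(res, alpha) if res.ms_error > 0 else 0.0

    def sig_prev(i):
        return abs(values[i] - values[ref_prev]) > thr

    def sig_next(i):
        return abs(values[i] - values[ref_next]) > thr

    # a single isolated significant fraction is treated as an assay outlier:
    # the window boundaries require two consecutive significant timepoints
    start_i = None
    for i in range(ref_prev + 1, ref_next - 1):
        if sig_prev(i) and sig_prev(i + 1):
            start_i = i
            break
    end_i = None
    for i in range(ref_next - 1, ref_prev + 1, -1):
        if sig_next(i) and sig_next(i - 1):
            end_i = i
            break
    ref_prev_info = (wrap24(7.0 + t_sub[ref_prev]), float(values[ref_prev]))
    ref_next_info = (wrap24(7.0 + t_sub[ref_next]), float(values[ref_next]))
    if start_i is None or end_i is None or end_i < start_i:
        return DurationResult(day_index, None, None, None, ref_prev_info,
                              ref_next_info, alpha, day1_convention)
    return DurationResult(
        day_index=day_index,
        start_time=wrap24(7.0 + t_sub[start_i]),
        end_time=wrap24(7.0 + t_sub[end_i]),
        duration_h=float(t_sub[end_i] - t_sub[start_i]),
        ref_min_prev=ref_prev_info, ref_min_next=ref_next_info,
        alpha=alpha, day1_convention=day1_convention)


def elevated_duration(series_set: list[FractionSeries], schedule: LightSchedule,
                      day_index: int, alpha: float = 0.05,
                      reference: LightSchedule | None = None) -> DurationResult:
    """Elevated-secretion duration for one cycle of one group.

    ``day_index`` is 1-based; the cycle analysed is the scotophase (or
    projected subjective night) starting on that day.  For day 1, where
    culture provides no preceding photophase, the reference is the lowest
    point of the first photophase itself (flagged in the result).
    """
    res, t_sub, ref_prev, ref_next, day1 = _context(
        series_set, schedule, day_index, reference)
    return _scan(res.time_means, res, t_sub, ref_prev, ref_next, alpha,
                 day_index, day1)


def elevated_duration_per_gland(series_set: list[FractionSeries],
                                schedule: LightSchedule, day_index: int,
                                alpha: float = 0.05,
                                reference: LightSchedule | None = None
                                ) -> list[DurationResult]:
    """Per-gland elevated windows, scanned against the group references
    with the group RM-ANOVA error term (used for the cross-group Duncan
    comparison of durations)."""
    res, t_sub, ref_prev, ref_next, day1 = _context(
        series_set, schedule, day_index, reference)
    grid = series_set[0].t_mid
    lo_i = int(np.nonzero(np.isclose(grid, t_sub[0]))[0][0])
    out = []
    for s in series_set:
        vals = s.concentration[lo_i: lo_i + len(t_sub)]
        out.append(_scan(vals, res, t_sub, ref_prev, ref_next, alpha,
                         day_index, day1))
    return out
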