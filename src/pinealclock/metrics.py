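"""Per-cycle rhythm characterisation of melatonin fraction profiles.

For each culture day (07.00-to-07.00 window) of an individual profile the
following points are determined: the minimum and maximum (value and clock
time), the threshold crossings I50/I75 (times at which secretion first
rises through 50%/75% of the cycle maximum on the ascent) and D50/D75
(the corresponding last descent crossings after the maximum, searched
into the next window when the peak spans the day boundary), the peak
mid-point M (circular midpoint of I75 and D75 on the 24-h clock) and the
fold amplitude max/min.  Under constant conditions the descent often
stays above 50% of the maximum; D50 (and, if needed, D75) are then
undefined, and M is undefined whenever D75 is.

Group summaries average per-gland metrics, using resultant-vector
(circular) means for clock times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .clocktime import circular_mean_hours, circular_sem_minutes, wrap24
from .simulator import FractionSeries

DAY_LEN = 24.0
DESCENT_SEARCH_H = 14.0  # how far past the window a boundary-spanning peak may extend


@dataclass
class RhythmMetrics:
    day_index: int
    min_time: float  # clock, decimal hours
    min_value: float  # ng/min
    max_time: float
    max_value: float
    i50: float | None
    i75: float | None
    d50: float | None
    d75: float | None
    m: float | None
    fold_amplitude: float

    def as_dict(self) -> dict:
        return {
            "day": self.day_index, "min_time": self.min_time,
            "min_value": self.min_value, "max_time": self.max_time,
            "max_value": self.max_value, "i50": self.i50, "i75": self.i75,
            "d50": self.d50, "d75": self.d75, "m": self.m,
            "fold_amplitude": self.fold_amplitude,
        }


def cycle_windows(series: FractionSeries) -> list[tuple[float, float]]:
    """07.00-bounded day windows in culture time.

    Day 1 runs from the first recorded fraction to the first 07.00; the
    last window is truncated at the series end.
    """
    t = series.t_mid
    if t[-1] - t[0] < DAY_LEN - 1e-9:
        raise ValueError("series must span at least 24 h")
    t0, t_end = float(t[0]), float(t[-1])
    first_bound = math.ceil((t0 - 1e-9) / DAY_LEN) * DAY_LEN
    bounds = [t0] if first_bound > t0 else []
    b = first_bound
    while b < t_end:
        bounds.append(b)
        b += DAY_LEN
    bounds.append(t_end + 1e-9)
    return [(a, b) for a, b in zip(bounds, bounds[1:]) if b - a > 1e-6]


def _interp_crossing(t0, v0, t1, v1, thr):
    if v1 == v0:
        return 0.5 * (t0 + t1)
    return t0 + (thr - v0) / (v1 - v0) * (t1 - t0)


def _first_rise(t, v, thr):
    """First upward crossing of thr along (t, v); None if absent."""
    for i in range(1, len(v)):
        if v[i - 1] < thr <= v[i]:
            return _interp_crossing(t[i - 1], v[i - 1], t[i], v[i], thr)
    return None


def _last_fall(t, v, thr):
    """Last downward crossing of thr along (t, v); None if absent."""
    out = None
    for i in range(1, len(v)):
        if v[i - 1] >= thr > v[i]:
            out = _interp_crossing(t[i - 1], v[i - 1], t[i], v[i], thr)
    return out


def extract_metrics(series: FractionSeries, window: tuple[float, float],
                    day_index: int = 0) -> RhythmMetrics:
    """Rhythm points of one profile within one day window."""
    t_all, v_all = series.t_mid, series.secretion
    lo, hi = window
    mask = (t_all >= lo - 1e-9) & (t_all < hi - 1e-9)
    idx = np.nonzero(mask)[0]
    if idx.size < 8:
        raise ValueError(f"fewer than 8 fractions in window {window}")
    t, v = t_all[idx], v_all[idx]

    i_min, i_max = int(np.argmin(v)), int(np.argmax(v))
    min_value, max_value = float(v[i_min]), float(v[i_max])
    min_time, max_time = wrap24(7.0 + t[i_min]), wrap24(7.0 + t[i_max])
    fold = max_value / min_value if min_value > 0 else math.inf

    und = RhythmMetrics(day_index, min_time, min_value, max_time, max_value,
                        None, None, None, None, None, 1.0 if max_value == min_value else fold)
    if max_value == min_value:
        return und

    # ascent: from the lowest point preceding the maximum up to the maximum
    i_pre = int(np.argmin(v[: i_max + 1])) if i_max > 0 else 0
    asc_t, asc_v = t[i_pre : i_max + 1], v[i_pre : i_max + 1]
    i50 = _first_rise(asc_t, asc_v, 0.50 * max_value)
    i75 = _first_rise(asc_t, asc_v, 0.75 * max_value)

    # descent: from the maximum to the following trough, allowed to run
    # into the next window when the peak spans the 07.00 boundary
    g_max = idx[i_max]
    g_end = g_max
    t_limit = t[i_max] + DESCENT_SEARCH_H
    while g_end + 1 < len(t_all) and t_all[g_end + 1] <= t_limit:
        g_end += 1
    seg_t, seg_v = t_all[g_max : g_end + 1], v_all[g_max : g_end + 1]
    if len(seg_v) > 1:
        i_post = int(np.argmin(seg_v))
        seg_t, seg_v = seg_t[: i_post + 1], seg_v[: i_post + 1]
    d50 = _last_fall(seg_t, seg_v, 0.50 * max_value)
    d75 = _last_fall(seg_t, seg_v, 0.75 * max_value)

    m = None
    if i75 is not None and d75 is not None:
        i75_clock, d75_clock = wrap24(7.0 + i75), wrap24(7.0 + d75)
        m = wrap24(i75_clock + wrap24(d75_clock - i75_clock) / 2.0)

    return RhythmMetrics(
        day_index=day_index, min_time=min_time, min_value=min_value,
        max_time=max_time, max_value=max_value,
        i50=None if i50 is None else wrap24(7.0 + i50),
        i75=None if i75 is None else wrap24(7.0 + i75),
        d50=None if d50 is None else wrap24(7.0 + d50),
        d75=None if d75 is None else wrap24(7.0 + d75),
        m=m, fold_amplitude=fold)


_TIME_METRICS = {"min_time", "max_time", "i50", "i75", "d50", "d75", "m"}
_VALUE_METRICS = {"min_value", "max_value", "fold_amplitude"}


def group_metrics(series_set: list[FractionSeries], window: tuple[float, float],
                  day_index: int = 0) -> dict:
    """Mean +/- SEM of each rhythm point over glands.

    Clock times are averaged circularly (resultant vector) and their SEMs
    reported in minutes; secretion values and folds arithmetically.
    Glands with an undefined point are excluded, with the defined count
    reported per metric.
    """
    if len(series_set) < 2:
        raise ValueError("need at least 2 glands")
    per = [extract_metrics(s, window, day_index) for s in series_set]
    out: dict[str, dict] = {}
    for name in sorted(_TIME_METRICS | _VALUE_METRICS):
        vals = [getattr(p, name) for p in per]
        vals = [v for v in vals if v is not None and math.isfinite(v)]
        if not vals:
            out[name] = {"mean": None, "sem": None, "n": 0,
                         "reason": "undefined for all glands"}
            continue
        if name in _TIME_METRICS:
            out[name] = {"mean": circular_mean_hours(vals),
                         "sem_min": circular_sem_minutes(vals), "n": len(vals)}
        else:
            arr = np.asarray(vals, dtype=float)
            sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
            out[name] = {"mean": float(arr.mean()), "sem": sem, "n": int(arr.size)}
    out["per_gland"] = per
    return out
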