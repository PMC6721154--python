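"""Cross-group inference: one-way ANOVA, Duncan's multiple range test with
a compact letter display, and free-running period estimation by peak
mid-point regression.

Duncan's test sorts the group means, compares means p ranks apart against
the critical range R_p = q*(alpha_p, p, df) * sqrt(MS_error / n) with the
protection level alpha_p = 1 - (1 - alpha)**(p - 1) and q* the
studentized-range quantile, stepping down from the widest span with the
usual rule that no subrange of an accepted (homogeneous) range is tested.
Groups sharing a letter in the resulting display do not differ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .clocktime import unwrap_hours


@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    ms_error: float
    group_means: dict


@dataclass
class DuncanResult:
    groups: list  # sorted by ascending mean
    means: dict
    ms_error: float
    df_error: int
    alpha: float
    significant_pairs: set  # frozenset pairs of group labels that differ
    letters: dict  # group -> letter string

    def differ(self, g1, g2) -> bool:
        return frozenset((g1, g2)) in self.significant_pairs


def one_way_anova(samples: dict) -> AnovaResult:
    """Classical one-way decomposition over per-group value lists."""
    groups = list(samples)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = {g: np.asarray(samples[g], dtype=float) for g in groups}
    for g, a in arrs.items():
        if a.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    allv = np.concatenate(list(arrs.values()))
    grand = allv.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs.values())
    df_b = len(groups) - 1
    df_w = allv.size - len(groups)
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    f = ms_b / ms_w if ms_w > 0 else (0.0 if ss_between == 0 else math.inf)
    return AnovaResult(f=float(f), df_between=df_b, df_within=df_w,
                       ms_error=float(ms_w),
                       group_means={g: float(a.mean()) for g, a in arrs.items()})


def studentized_range_quantile(p_alpha: float, k: int, df: float) -> float:
    """Upper quantile q with P(Q_{k,df} <= q) = 1 - p_alpha."""
    if k < 2 or df < 1 or not (0 < p_alpha < 1):
        raise ValueError("need k >= 2, df >= 1, 0 < p_alpha < 1")
    q = stats.studentized_range.ppf(1.0 - p_alpha, k, df)
    if not np.isfinite(q):
        raise RuntimeError(
            f"studentized-range quantile did not converge (alpha={p_alpha}, k={k}, df={df})")
    return float(q)


def duncan_mrt(samples: dict, alpha: float = 0.05) -> DuncanResult:
    """Duncan's multiple range test with compact letter display.

    Unbalanced designs use the harmonic mean of the group sizes in the
    critical range (the groups in the source experiments are all n = 4,
    so this only matters for general use).
    """
    res = one_way_anova(samples)
    if res.df_within < 1:
        raise ValueError("no within-group degrees of freedom")
    sizes = [len(samples[g]) for g in samples]
    n_h = len(sizes) / sum(1.0 / s for s in sizes)
    order = sorted(res.group_means, key=lambda g: (res.group_means[g], str(g)))
    k = len(order)
    se = math.sqrt(res.ms_error / n_h)

    accepted: list[tuple[int, int]] = []  # homogeneous index ranges (inclusive)
    significant: set = set()

    def covered(i, j):
        return any(a <= i and j <= b for a, b in accepted)

    for span in range(k, 1, -1):
        alpha_p = 1.0 - (1.0 - alpha) ** (span - 1)
        if se > 0:
            r_p = studentized_range_quantile(alpha_p, span, res.df_within) * se
        else:
            r_p = 0.0
        for i in range(0, k - span + 1):
            j = i + span - 1
            if covered(i, j):
                continue
            diff = res.group_means[order[j]] - res.group_means[order[i]]
            if (diff <= r_p) if se > 0 else (diff <= 0.0):
                accepted.append((i, j))
            else:
                significant.add(frozenset((order[i], order[j])))

    # pairs not inside any accepted range differ
    for i in range(k):
        for j in range(i + 1, k):
            if not covered(i, j):
                significant.add(frozenset((order[i], order[j])))

    # compact letter display from maximal homogeneous ranges
    ranges = accepted + [(i, i) for i in range(k)]
    maximal = [r for r in ranges
               if not any(r != o and o[0] <= r[0] and r[1] <= o[1] for o in ranges)]
    maximal.sort()
    letters = {g: "" for g in order}
    for idx, (a, b) in enumerate(maximal):
        ch = chr(ord("a") + idx)
        for i in range(a, b + 1):
            letters[order[i]] += ch

    return DuncanResult(groups=order, means=res.group_means,
                        ms_error=res.ms_error, df_error=res.df_within,
                        alpha=alpha, significant_pairs=significant, letters=letters)


def fit_free_running_period(m_points) -> float:
    """Free-running period from daily peak mid-points.

    ``m_points`` are (day, clock time in decimal hours) pairs.  The clock
    times are unwrapped across midnight and regressed on the day number;
    tau = 24 + slope, so a daily phase advance (negative slope) gives a
    period below 24 h.
    """
    pts = sorted(m_points)
    if len(pts) < 3:
        raise ValueError("need at least 3 peak mid-points")
    days = np.array([p[0] for p in pts], dtype=float)
    times = unwrap_hours([p[1] for p in pts])
    slope = np.polyfit(days, times, 1)[0]
    return float(24.0 + slope)
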