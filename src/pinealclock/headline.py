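"""Headline rhythm quantities recomputed from end-to-end simulations.

Each quantity runs the default-parameter simulator (4 glands) under the
relevant lighting protocol for every requested seed, applies the rhythm
extraction or the LSD duration statistic, and averages over seeds --
circularly for clock times, arithmetically for durations and folds.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .clocktime import circular_mean_hours
from .duration import elevated_duration
from .light_schedule import build_experiment_schedule
from .metrics import cycle_windows, extract_metrics
from .simulator import SuperfusionParams, default_params, simulate_culture


def derived_seeds(base_seed: int, n: int = 5) -> list[int]:
    """n reproducible sub-seeds below 2**31 derived from one base seed."""
    return [int(s) for s in
            np.random.SeedSequence(base_seed).generate_state(n) % (2 ** 31)]


def _simulate(experiment, group, seed, params, sp):
    schedule = build_experiment_schedule(experiment, group)
    series = simulate_culture(params, replace(sp, seed=seed), schedule)
    return series, schedule


def _mean_duration(experiment, group, day, seeds, params, sp, reference=None):
    vals = []
    for sd in seeds:
        series, schedule = _simulate(experiment, group, sd, params, sp)
        res = elevated_duration(series, schedule, day, alpha=0.05,
                                reference=reference)
        if res.defined:
            vals.append(res.duration_h)
    return float(np.mean(vals)) if vals else None


def _metrics_by_day(experiment, group, seeds, params, sp):
    """metric -> day -> list of per-gland values pooled over seeds."""
    pooled: dict[int, list] = {}
    for sd in seeds:
        series, _ = _simulate(experiment, group, sd, params, sp)
        windows = cycle_windows(series[0])
        for day, win in enumerate(windows, start=1):
            for s in series:
                pooled.setdefault(day, []).append(extract_metrics(s, win, day))
    return pooled


def headline_quantities(seeds, params=None, sp=None) -> dict[str, float]:
    params = params or default_params()
    sp = sp or SuperfusionParams()
    out: dict[str, float] = {}

    out["duration_12L12D_dd_day5_h"] = _mean_duration("II", "I", 5, seeds, params, sp)
    out["duration_8L16D_day2_h"] = _mean_duration("II", "II", 2, seeds, params, sp)
    out["duration_8L16D_dd_day5_h"] = _mean_duration("II", "II", 5, seeds, params, sp)
    out["duration_16L8D_day1_h"] = _mean_duration("II", "III", 1, seeds, params, sp)

    dd = _metrics_by_day("I", "V", seeds, params, sp)
    for day, key in ((2, "m_DD_day2_clock"), (4, "m_DD_day4_clock")):
        ms = [m.m for m in dd[day] if m.m is not None]
        out[key] = circular_mean_hours(ms) if ms else None
    out["fold_DD_day1"] = float(np.mean([m.fold_amplitude for m in dd[1]]))
    per_day = [float(np.mean([m.fold_amplitude for m in dd[d]])) for d in (2, 3, 4, 5)]
    out["fold_DD_days2to5_max"] = max(per_day)

    ll = _metrics_by_day("I", "VI", seeds, params, sp)
    out["fold_LL_day1"] = float(np.mean([m.fold_amplitude for m in ll[1]]))

    ld = _metrics_by_day("I", "I", seeds, params, sp)
    out["fold_12L12D_day1"] = float(np.mean([m.fold_amplitude for m in ld[1]]))
    out["fold_12L12D_days2to5"] = float(np.mean(
        [np.mean([m.fold_amplitude for m in ld[d]]) for d in (2, 3, 4, 5)]))
    return out
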