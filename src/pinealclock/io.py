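"""CSV formats.

The fraction-series CSV has one row per gland per 30-min fraction:

    gland_id, day, clock_hhmm, t_hours, conc_ng_ml, secretion_ng_min

with ``t_hours`` culture time of the fraction mid-point (decimal hours,
6 significant digits), ``clock_hhmm`` the corresponding clock time as an
"hh.mm" string, ``day`` the 1-based 07.00-bounded culture day.  The same
file is the input format for all analysis functions.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .clocktime import hhmm_to_hours, hours_to_hhmm
from .simulator import FractionSeries

COLUMNS = ["gland_id", "day", "clock_hhmm", "t_hours", "conc_ng_ml", "secretion_ng_min"]


def series_to_frame(series_set: list[FractionSeries]) -> pd.DataFrame:
    rows = []
    for s in series_set:
        for t, c, conc, sec in zip(s.t_mid, s.clock, s.concentration, s.secretion):
            rows.append({
                "gland_id": s.gland_id,
                "day": int(t // 24) + 1,
                "clock_hhmm": hours_to_hhmm(c),
                "t_hours": float(f"{t:.6g}"),
                "conc_ng_ml": float(f"{conc:.6g}"),
                "secretion_ng_min": float(f"{sec:.6g}"),
            })
    return pd.DataFrame(rows, columns=COLUMNS)


def write_series(path, series_set: list[FractionSeries], seed=None) -> None:
    df = series_to_frame(series_set)
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def read_series(path) -> list[FractionSeries]:
    """Read a fraction-series CSV, validating schema and clock strings."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    out = []
    grid_len = None
    for row_no, text in enumerate(df["clock_hhmm"].astype(str), start=2):
        try:
            hhmm_to_hours(text)
        except ValueError as exc:
            raise ValueError(f"column clock_hhmm, row {row_no}: {exc}") from None
    flow = None
    for gid, sub in df.groupby("gland_id", sort=False):
        sub = sub.sort_values("t_hours")
        t = sub["t_hours"].to_numpy(float)
        conc = sub["conc_ng_ml"].to_numpy(float)
        sec = sub["secretion_ng_min"].to_numpy(float)
        if grid_len is None:
            grid_len = len(t)
        elif len(t) != grid_len:
            first_bad = sub.index[0] + 2
            raise ValueError(
                f"gland {gid!r} has {len(t)} fractions, expected {grid_len} "
                f"(near row {first_bad})")
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(conc > 0, sec / conc, np.nan)
        f = float(np.nanmedian(ratios)) if np.any(conc > 0) else 0.1
        flow = f if flow is None else flow
        clock = np.array([hhmm_to_hours(x) for x in sub["clock_hhmm"].astype(str)])
        out.append(FractionSeries(gland_id=str(gid), t_mid=t, clock=clock,
                                  concentration=conc, secretion=sec,
                                  flow=f if math.isfinite(f) else 0.1))
    if not out:
        raise ValueError("no fraction rows found")
    return out
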