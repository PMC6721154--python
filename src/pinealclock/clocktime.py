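"""Clock-time conventions.

All arithmetic uses decimal hours on a 24-h clock; display uses "hh.mm"
strings (e.g. "15.15" means quarter past three, i.e. 15.25 decimal hours).
Times of day are circular quantities, so averaging and differencing go
through resultant-vector / wrapped arithmetic rather than naive means.
"""

from __future__ import annotations

import math
import re

import numpy as np

_HHMM_RE = re.compile(r"^(\d{1,2})\.(\d{2})$")


def hhmm_to_hours(text: str) -> float:
    """Parse an "hh.mm" clock string to decimal hours in [0, 24).

    "15.15" -> 15.25; "01.05" -> 1.0833...
    """
    m = _HHMM_RE.match(text.strip())
    if not m:
        raise ValueError(f"not an hh.mm clock string: {text!r}")
    hh, mm = int(m.group(1)), int(m.group(2))
    if hh > 23 or mm > 59:
        raise ValueError(f"clock time out of range: {text!r}")
    return hh + mm / 60.0


def hours_to_hhmm(hours: float) -> str:
    """Format decimal hours as an "hh.mm" clock string (nearest minute)."""
    h = float(hours) % 24.0
    total_min = int(round(h * 60.0))
    if total_min == 1440:
        total_min = 0
    return f"{total_min // 60:02d}.{total_min % 60:02d}"


def wrap24(hours: float) -> float:
    """Reduce decimal hours to [0, 24)."""
    return float(hours) % 24.0


def wrap_signed(delta: float) -> float:
    """Reduce an hour difference to the signed interval (-12, 12]."""
    d = (float(delta) + 12.0) % 24.0 - 12.0
    return 12.0 if d == -12.0 else d


def circular_mean_hours(times, weights=None) -> float:
    """Resultant-vector mean of clock times (decimal hours) on the 24-h circle.

    {23.5, 0.5} -> 0.0, not 12.0.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("no times to average")
    ang = t * (2.0 * math.pi / 24.0)
    w = np.ones_like(ang) if weights is None else np.asarray(weights, dtype=float)
    x = float(np.sum(w * np.cos(ang)))
    y = float(np.sum(w * np.sin(ang)))
    if math.hypot(x, y) < 1e-12:
        raise ValueError("circular mean undefined (zero resultant)")
    return (math.atan2(y, x) * 24.0 / (2.0 * math.pi)) % 24.0


def circular_sem_minutes(times) -> float:
    """SEM of clock times in minutes, computed on deviations wrapped around
    the circular mean (adequate for the tightly clustered times this
    package produces)."""
    t = np.asarray(times, dtype=float)
    if t.size < 2:
        return 0.0
    mu = circular_mean_hours(t)
    dev = np.array([wrap_signed(x - mu) for x in t])
    return float(np.std(dev, ddof=1) / math.sqrt(t.size) * 60.0)


def unwrap_hours(times) -> np.ndarray:
    """Unwrap a sequence of clock times across midnight.

    Each successive value is shifted by a multiple of 24 h so that it lies
    within +/-12 h of its predecessor, turning e.g. (3.5, 1.1, 22.5, 20.5)
    into (3.5, 1.1, -1.5, -3.5).
    """
    t = np.asarray(times, dtype=float)
    out = t.copy()
    for i in range(1, len(out)):
        out[i] = out[i - 1] + wrap_signed(t[i] - out[i - 1])
    return out


def hhmm_number_to_hours(value: float) -> float:
    """Convert a numeric hh.mm value as printed in the tables (20.30 means
    20:30) to decimal hours (20.5)."""
    hh = int(value)
    mm = round((value - hh) * 100)
    if mm < 0 or mm > 59:
        raise ValueError(f"not an hh.mm number: {value}")
    return hh + mm / 60.0


def hours_to_hhmm_number(hours: float) -> float:
    """Convert decimal hours to the numeric hh.mm convention (20.5 -> 20.30)."""
    h = float(hours) % 24.0
    total_min = int(round(h * 60.0))
    if total_min == 1440:
        total_min = 0
    return total_min // 60 + (total_min % 60) / 100.0
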