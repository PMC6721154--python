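"""Lighting protocols as piecewise-constant illuminance functions.

A :class:`LightSchedule` maps culture time (hours since the start of
culture) to illuminance in lux.  Culture time 0 corresponds to 07.00 on
day 1 (the day-boundary convention of the superfusion protocol: 07.00
starts each culture day), and the photophase illuminance is 100 lx.

Builders are provided for the five explant experiments:

I   five days of 12L:12D with photophase 07-19 (I), 01-13 (II), 13-01
    (III), the reversed cycle 12D:12L (IV), continuous darkness (V) or
    continuous illumination (VI);
II  four days of 12L:12D (I), 8L:16D photophase 09-17 (II), 16L:8D
    photophase 05-21 (III) or 12D:12L (IV), then two days of darkness;
III four days of darkness with a 6-h 100-lx pulse on day 2 at 10-16 (II),
    19-01 (III) or 01-07 (IV); group I unpulsed;
IV  two days of 12L:12D then one day of darkness, with darkness 13-16
    (II) or 13-19 (III) on day 2;
V   two days of 12L:12D then one day of darkness, with light pulses from
    01.00 lasting 45/90/180 min (II/III/IV) on day 2.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import yaml

from .clocktime import wrap24

PHOTO_LUX = 100.0  # fluorescent lamp at the chamber sheets
DAY_START_CLOCK = 7.0  # 07.00 starts each culture day
MIN_NIGHT_H = 7.0  # dark intervals shorter than this are pulses, not nights


@dataclass(frozen=True)
class Interval:
    start: float  # hours since culture start
    end: float
    lux: float

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"interval end {self.end} <= start {self.start}")
        if self.lux < 0:
            raise ValueError("illuminance must be >= 0")


@dataclass(frozen=True)
class LightSchedule:
    """Piecewise-constant illuminance over [0, horizon) culture hours.

    Intervals are contiguous, non-overlapping and half-open: a transition
    instant belongs to the following interval.  ``clock_anchor`` is the
    clock time (decimal hours) at culture time 0.
    """

    intervals: tuple[Interval, ...]
    horizon: float
    clock_anchor: float = DAY_START_CLOCK
    _starts: tuple[float, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        iv = tuple(sorted(self.intervals, key=lambda i: i.start))
        if not iv:
            raise ValueError("schedule needs at least one interval")
        if abs(iv[0].start) > 1e-9:
            raise ValueError("intervals must start at 0")
        for a, b in zip(iv, iv[1:]):
            if abs(a.end - b.start) > 1e-9:
                raise ValueError(f"gap or overlap between {a} and {b}")
        if abs(iv[-1].end - self.horizon) > 1e-9:
            raise ValueError("intervals must cover [0, horizon)")
        object.__setattr__(self, "intervals", iv)
        object.__setattr__(self, "_starts", tuple(i.start for i in iv))

    # -- queries ---------------------------------------------------------

    def illuminance_at(self, t: float) -> float:
        """Illuminance (lx) at culture time t; half-open [start, end)."""
        if t < 0 or t >= self.horizon:
            raise ValueError(f"t={t} outside [0, {self.horizon})")
        idx = bisect_right(self._starts, t) - 1
        return self.intervals[idx].lux

    def clock_at(self, t: float) -> float:
        """Clock time (decimal hours) at culture time t."""
        return wrap24(self.clock_anchor + t)

    def culture_time(self, day: int, clock: float) -> float:
        """Culture time of a clock time on a given culture day (1-based).

        Day d spans culture times [24*(d-1) - anchor + 7 ... ), i.e. day 1
        starts at culture time 0 (= 07.00) under the default anchor.
        """
        t0_day = 24.0 * (day - 1) + (DAY_START_CLOCK - self.clock_anchor)
        return t0_day + wrap24(clock - DAY_START_CLOCK)

    def light_hours(self) -> float:
        """Total hours of light over the horizon."""
        return sum((i.end - i.start) for i in self.intervals if i.lux > 0)

    def transitions(self) -> list[tuple[float, float, float]]:
        """(time, lux_before, lux_after) at each illuminance change."""
        out = []
        for a, b in zip(self.intervals, self.intervals[1:]):
            if a.lux != b.lux:
                out.append((b.start, a.lux, b.lux))
        return out

    def dark_windows(self, min_len: float = 0.0) -> list[tuple[float, float]]:
        """Merged dark (0 lx) windows of at least ``min_len`` hours."""
        out: list[list[float]] = []
        for iv in self.intervals:
            if iv.lux == 0:
                if out and abs(out[-1][1] - iv.start) < 1e-9:
                    out[-1][1] = iv.end
                else:
                    out.append([iv.start, iv.end])
        return [(a, b) for a, b in out if b - a >= min_len - 1e-9]

    def is_constant(self) -> bool:
        return len({iv.lux > 0 for iv in self.intervals}) == 1

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "horizon_h": self.horizon,
            "clock_anchor": self.clock_anchor,
            "intervals": [
                {"start_h": iv.start, "end_h": iv.end, "lux": iv.lux}
                for iv in self.intervals
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LightSchedule":
        return cls(
            intervals=tuple(
                Interval(i["start_h"], i["end_h"], i["lux"]) for i in d["intervals"]
            ),
            horizon=float(d["horizon_h"]),
            clock_anchor=float(d.get("clock_anchor", DAY_START_CLOCK)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "LightSchedule":
        return cls.from_dict(yaml.safe_load(text))


def from_segments(segments, horizon, clock_anchor=DAY_START_CLOCK) -> LightSchedule:
    """Build a schedule from (start, end, lux) triples, merging/clipping to
    [0, horizon) and filling unspecified time with darkness."""
    marks = sorted({0.0, horizon} | {s for s, _, _ in segments} | {e for _, e, _ in segments})
    marks = [m for m in marks if 0.0 <= m <= horizon]
    out = []
    for a, b in zip(marks, marks[1:]):
        lux = 0.0
        for s, e, lx in segments:
            if s <= a and b <= e:
                lux = lx
        if out and out[-1].lux == lux:
            out[-1] = Interval(out[-1].start, b, lux)
        else:
            out.append(Interval(a, b, lux))
    return LightSchedule(tuple(out), horizon, clock_anchor)


def ld_cycle(lights_on: float, lights_off: float, days: int,
             extra_dark_days: int = 0, lux: float = PHOTO_LUX) -> LightSchedule:
    """Daily light from clock ``lights_on`` to ``lights_off`` for ``days``
    days, optionally followed by days of darkness.  Culture time 0 = 07.00."""
    segs = []
    for d in range(days):
        # signed offset: a photophase opening before 07.00 starts that same
        # culture day (clipped at culture start on day 1)
        off = lights_on - DAY_START_CLOCK
        if off > 12.0:
            off -= 24.0
        on = 24.0 * d + off
        dur = wrap24(lights_off - lights_on)
        segs.append((on, on + dur, lux))
    horizon = 24.0 * (days + extra_dark_days)
    segs = [(max(0.0, s), min(horizon, e), lx) for s, e, lx in segs if e > 0 and s < horizon]
    return from_segments(segs, horizon)


_EXPERIMENT_ARMS = {
    "I": ("I", "II", "III", "IV", "V", "VI"),
    "II": ("I", "II", "III", "IV"),
    "III": ("I", "II", "III", "IV"),
    "IV": ("I", "II", "III"),
    "V": ("I", "II", "III", "IV"),
}


def experiment_arms() -> dict[str, tuple[str, ...]]:
    """The 21 defined (experiment, group) arms."""
    return dict(_EXPERIMENT_ARMS)


def build_experiment_schedule(experiment: str, group: str) -> LightSchedule:
    """Exact lighting protocol for one (experiment, group) arm."""
    exp, grp = str(experiment).strip().upper(), str(group).strip().upper()
    if exp not in _EXPERIMENT_ARMS or grp not in _EXPERIMENT_ARMS.get(exp, ()):
        valid = ", ".join(
            f"({e}, {g})" for e, gs in _EXPERIMENT_ARMS.items() for g in gs
        )
        raise ValueError(f"unknown arm ({experiment}, {group}); valid arms: {valid}")

    if exp == "I":
        days = 5
        if grp == "I":
            return ld_cycle(7.0, 19.0, days)
        if grp == "II":
            return ld_cycle(1.0, 13.0, days)
        if grp == "III":
            return ld_cycle(13.0, 1.0, days)
        if grp == "IV":
            return ld_cycle(19.0, 7.0, days)
        if grp == "V":
            return from_segments([], 24.0 * days)
        return from_segments([(0.0, 24.0 * days, PHOTO_LUX)], 24.0 * days)

    if exp == "II":
        if grp == "I":
            return ld_cycle(7.0, 19.0, 4, extra_dark_days=2)
        if grp == "II":
            return ld_cycle(9.0, 17.0, 4, extra_dark_days=2)
        if grp == "III":
            return ld_cycle(5.0, 21.0, 4, extra_dark_days=2)
        return ld_cycle(19.0, 7.0, 4, extra_dark_days=2)

    if exp == "III":
        horizon = 24.0 * 4
        pulses = {"I": [], "II": [(10.0, 16.0)], "III": [(19.0, 1.0)], "IV": [(1.0, 7.0)]}
        segs = []
        for on, off in pulses[grp]:
            # pulse during day 2; 19.00-01.00 and 01.00-07.00 start on day 2
            start = 24.0 + wrap24(on - DAY_START_CLOCK)
            segs.append((start, start + wrap24(off - on), PHOTO_LUX))
        return from_segments(segs, horizon)

    if exp == "IV":
        base = ld_cycle(7.0, 19.0, 2, extra_dark_days=1)
        if grp == "I":
            return base
        dark = {"II": (13.0, 16.0), "III": (13.0, 19.0)}[grp]
        segs = []
        for iv in base.intervals:
            if iv.lux > 0:
                segs.append([iv.start, iv.end, iv.lux])
        d0 = 24.0 + (dark[0] - DAY_START_CLOCK)
        d1 = 24.0 + (dark[1] - DAY_START_CLOCK)
        out = []
        for s, e, lx in segs:
            if e <= d0 or s >= d1:
                out.append((s, e, lx))
            else:
                if s < d0:
                    out.append((s, d0, lx))
                if e > d1:
                    out.append((d1, e, lx))
        return from_segments(out, base.horizon)

    # Experiment V
    base = ld_cycle(7.0, 19.0, 2, extra_dark_days=1)
    if grp == "I":
        return base
    minutes = {"II": 45.0, "III": 90.0, "IV": 180.0}[grp]
    start = 24.0 + wrap24(1.0 - DAY_START_CLOCK)  # 01.00 during night of day 2
    segs = [(iv.start, iv.end, iv.lux) for iv in base.intervals if iv.lux > 0]
    segs.append((start, start + minutes / 60.0, PHOTO_LUX))
    return from_segments(segs, base.horizon)


def scotophase_windows(schedule: LightSchedule,
                       reference: LightSchedule | None = None,
                       min_night: float = MIN_NIGHT_H) -> list[tuple[float, float]]:
    """Scotophase (or subjective-night) windows over the schedule horizon.

    Returns (start, end) culture-time pairs, one per night.  Dark windows
    shorter than ``min_night`` hours (darkness pulses) are not nights.
    Where the schedule is constant -- a DD/LL tail or a fully constant
    protocol -- the last experienced cycle (or the ``reference`` schedule
    for fully constant protocols) is projected forward at a 24-h period,
    giving the subjective nights.
    """
    nights = schedule.dark_windows(min_len=min_night)
    # nights fully inside the alternating part of the schedule
    last_on = max((iv.start for iv in schedule.intervals if iv.lux > 0), default=None)

    if last_on is None:
        # constant darkness throughout: project the reference cycle
        if reference is None or reference.is_constant():
            raise ValueError("constant schedule: a cyclic reference schedule is required")
        ref = scotophase_windows(reference, min_night=min_night)
        s0, e0 = ref[0]
        out = []
        start = s0 - 24.0 * (int(s0 // 24) + 1)
        while start < schedule.horizon:
            if start + (e0 - s0) > 0:
                out.append((max(start, 0.0), min(start + (e0 - s0), schedule.horizon)))
            start += 24.0
        return out

    if schedule.is_constant():
        # constant light throughout
        if reference is None or reference.is_constant():
            raise ValueError("constant schedule: a cyclic reference schedule is required")
        return scotophase_windows(reference, min_night=min_night)

    # An alternating schedule with a constant dark tail (e.g. the DD days
    # of experiment II) merges the tail into one long final dark window;
    # split anything longer than 20 h into successive subjective nights of
    # the last experienced scotophase length, spaced 24 h apart.
    night_len = None
    for s, e in nights:
        if e - s <= 20.0:
            night_len = e - s
    out: list[tuple[float, float]] = []
    for s, e in nights:
        if e - s <= 20.0:
            out.append((s, e))
        else:
            length = night_len if night_len is not None else min(e - s, 24.0 - 1e-9)
            start = s
            while start < e - 1e-9:
                out.append((start, min(start + length, e)))
                start += 24.0
    return out
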