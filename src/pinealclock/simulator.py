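"""Synthetic melatonin secretion from pineal explants in superfusion culture.

The generator couples four processes:

* a circadian **phase oscillator**, tracked as subjective time ``s`` in
  [0, 24) h with ``s = 0`` at subjective night onset.  In darkness the
  phase runs at ``24/tau_dd`` per hour (tau_dd < 24, so free-running
  rhythms in darkness phase-advance day by day); in light at ``24/tau_ll``.
  Light acting inside the subjective night shifts the phase through a
  sinusoidal phase-response curve (delays in the first half of the night,
  advances in the second half, dead zone during subjective day).  The PRC
  amplitude adapts away under sustained illumination, which lets an
  entrained cycle pin night onset at lights-off while a continuously lit
  culture escapes into free run.  Darkness falling late in the subjective
  day pulls the phase forward to night onset (darkness initiates the
  night), which is what re-entrains a reversed cycle within one day; the
  pull is armed only for a limited time after light exposure, so cultures
  held in darkness free-run undisturbed.
* a **photoperiod memory**: the stored scotophase fraction (``duty``) sets
  the width of the nightly secretion plateau.  It is rewritten once per
  completed dark window (7-20 h long), i.e. with a one-day lag, and is
  frozen under constant conditions -- the "calendar".
* an **amplitude/desynchronization state**: a startup amplitude deficit
  that recovers over the first day, and a desynchronization index that
  grows under constant conditions, compressing the rhythm toward a mid
  level (troughs rise, peaks fall) until only a small residual fold
  remains.
* an acute **masking gate**: light suppresses secretion toward a low floor
  with a fast time constant and darkness releases it; under many hours of
  sustained light the floor itself slowly rises (the daytime baseline
  creeps up under continuous illumination).

The instantaneous secretion rate is passed through the first-order mixing
of the superfusion chamber (time constant volume/flow, about 13.5 min),
averaged over 30-min medium fractions, and given multiplicative lognormal
assay noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .light_schedule import LightSchedule

DUTY_MIN = 4.0 / 24.0
DUTY_MAX = 20.0 / 24.0
NIGHT_MIN_H = 7.0
NIGHT_MAX_H = 20.0


@dataclass(frozen=True)
class PinealParams:
    """Oscillator, memory, damping and masking parameters.

    Defaults are calibrated against the printed rhythm parameters of the
    turkey explant experiments (LD fold amplitudes, free-running peak
    mid-point drift, photoperiod-dependent peak durations, pulse
    responses); see docs/methods.md for the calibration surface.
    """

    # free-running periods (h)
    tau_dd: float = 21.64
    tau_ll: float = 22.29
    # light PRC: -gain * sin(2*pi*s/night_len) inside the subjective night,
    # amplitude adapting as exp(-t_light/prc_adapt_tau)
    entrain_gain: float = 2.8
    prc_advance_frac: float = 0.3
    prc_adapt_tau: float = 17.0
    # darkness pull toward night onset, active for s in the late subjective
    # day once darkness falls, armed for dark_pull_memory hours after light
    dark_pull: float = 2.2
    dark_pull_zone: float = 22.5
    dark_pull_memory: float = 16.0
    # secretion bounds (ng/min)
    s_min: float = 0.06
    s_max: float = 2.45
    # circadian waveform (subjective hours): steep rise after night onset,
    # slow fall whose midpoint tracks the stored night length
    rise_mid: float = 1.5
    rise_sigma: float = 0.6
    fall_base: float = 4.68
    fall_per_night_h: float = 0.615
    fall_age_h_per_h: float = 0.014
    fall_sigma: float = 0.68
    # photoperiod memory
    duty_adapt_days: int = 1  # update lag: one completed cycle
    # startup amplitude deficit; recovery proceeds in darkness and is
    # strongly retarded by light
    amp0: float = 0.06
    amp_tau_dark: float = 55.0
    amp_tau_light: float = 80.0
    # desynchronization (peak compression) under constant conditions:
    # switch-like after ~a day of constant darkness, gradual over days in
    # constant light
    desync_max: float = 0.80
    desync_t50_dark: float = 21.5
    desync_t50_dark_min: float = 18.0
    desync_age_rate: float = 0.0
    desync_n_dark: float = 17.0
    desync_t50_light: float = 80.0
    desync_n_light: float = 2.0
    desync_tau_up: float = 1.0
    desync_tau_down: float = 24.0
    # culture-age rise of the clockless secretion baseline carried by the
    # desynchronized fraction (fraction of the dynamic range)
    base_early: float = 0.042
    base_max: float = 0.16
    base_t50: float = 22.0
    base_n: float = 6.0
    base_dark_t50: float = 4.0
    base_dark_n: float = 3.0
    base_dark_decay_tau: float = 0.55
    # acute masking gate
    mask_tau_on: float = 3.5
    mask_tau_off: float = 0.7
    mask_floor: float = 0.035
    # slow rise of the light-adapted gate floor (continuous illumination)
    ll_gate_max: float = 1.0
    ll_t50: float = 16.0
    ll_n: float = 14.0
    ll_decay_tau: float = 3.0
    # per-gland initial phase jitter (h, SD)
    phase_jitter_sd: float = 0.2
    # culture-establishment phase lag on day 1 (h)
    startup_delay: float = 3.73
    gate0: float = 0.35

    def __post_init__(self):
        if self.tau_dd <= 0 or self.tau_ll <= 0:
            raise ValueError("free-running periods must be positive")
        if not (0 < self.s_min < self.s_max):
            raise ValueError("need 0 < s_min < s_max")
        if not (0 <= self.mask_floor < 1):
            raise ValueError("mask_floor must be in [0, 1)")
        if not (0 <= self.desync_max <= 1):
            raise ValueError("desync_max must be in [0, 1]")


@dataclass
class PinealState:
    """Instantaneous oscillator state.

    ``phase`` is circadian phase in [0, 1) with 0 at subjective night
    onset; ``duty`` the stored scotophase fraction; ``amp`` the current
    amplitude multiplier; ``gate`` the masking gate.  The auxiliary timers
    track light exposure (for PRC adaptation and the light-adapted gate
    floor), time since the last light exposure (arming the darkness pull)
    and time since the last illuminance transition (desynchronization).
    """

    phase: float = 0.0
    duty: float = 0.5
    amp: float = 1.0
    gate: float = 1.0
    desync: float = 0.0
    t_light: float = 0.0
    t_since_light: float = math.inf
    t_const: float = 0.0
    pending_dark_onset: float | None = None
    clock_h: float = 0.0  # bookkeeping only

    def __post_init__(self):
        self.phase %= 1.0
        if not (0 < self.duty < 1):
            raise ValueError("duty must be in (0, 1)")
        if not (0 <= self.gate <= 1):
            raise ValueError("gate must be in [0, 1]")


@dataclass(frozen=True)
class SuperfusionParams:
    """Chamber geometry, fraction collection and assay noise."""

    flow: float = 0.1  # ml/min
    dead_volume: float = 1.35  # ml
    fraction_minutes: float = 30.0
    ria_cv: float = 0.08
    n_glands: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.flow <= 0 or self.dead_volume <= 0:
            raise ValueError("flow and dead_volume must be positive")
        if self.ria_cv < 0:
            raise ValueError("ria_cv must be >= 0")

    @property
    def mixing_tau_h(self) -> float:
        """First-order mixing time constant V/F in hours (~0.225 h)."""
        return self.dead_volume / self.flow / 60.0


@dataclass
class SecretionProfile:
    """Dense instantaneous secretion rate (ng/min) on a time grid (h)."""

    times: np.ndarray
    rate: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(self.rate < 0):
            raise ValueError("secretion rate must be non-negative")


@dataclass
class FractionSeries:
    """Per-gland 30-min medium fractions.

    ``t_mid`` are culture times (h) of fraction mid-points, ``clock`` the
    corresponding clock times (decimal hours), ``concentration`` ng/ml and
    ``secretion`` ng/min (= concentration x flow).
    """

    gland_id: str
    t_mid: np.ndarray
    clock: np.ndarray
    concentration: np.ndarray
    secretion: np.ndarray
    flow: float = 0.1
    seed: int | None = None

    def __post_init__(self):
        for name in ("t_mid", "clock", "concentration", "secretion"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))


# ---------------------------------------------------------------------------
# dynamics kernel
# ---------------------------------------------------------------------------

def _sig(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def _hill(t, t50, n):
    t = max(float(t), 1e-9)
    return 1.0 / (1.0 + (t50 / t) ** n)


def circadian_waveform(s, duty: float, p: PinealParams, age_h: float = 0.0):
    """Nightly secretion waveform on subjective time s (h), in [0, 1].

    A steep rise shortly after night onset and a slow fall whose midpoint
    tracks the stored night length (duty x 24 h); the episode broadens
    slightly with time in vitro (the fall midpoint drifts late by
    ``fall_age_h_per_h`` per culture hour).
    """
    s = np.asarray(s, dtype=float) % 24.0
    night_h = duty * 24.0
    fall_mid = (p.fall_base + p.fall_per_night_h * night_h
                + p.fall_age_h_per_h * age_h)
    return _sig((s - p.rise_mid) / p.rise_sigma) * _sig((fall_mid - s) / p.fall_sigma)


def secretion_rate(state: PinealState, params: PinealParams) -> float:
    """Instantaneous secretion (ng/min) for a single state.

    rate = s_min + (s_max - s_min) * C * gate with
    C = (1 - desync) * amp * waveform + baseline(t_culture), clipped to
    [0, 1]; ``clock_h`` serves as culture time for the baseline term.
    """
    p = params
    w = float(circadian_waveform(state.phase * 24.0, state.duty, p, state.clock_h))
    gate_b = max(_hill(state.t_since_light, p.base_dark_t50, p.base_dark_n),
                 state.desync / p.desync_max)
    base = (p.base_early
            + p.base_max * _hill(state.clock_h, p.base_t50, p.base_n)) * gate_b
    c = (1.0 - state.desync) * state.amp * w + base
    c = min(max(c, 0.0), 1.0)
    return p.s_min + (p.s_max - p.s_min) * c * state.gate


def _gate_floor(p: PinealParams, t_light: float) -> float:
    return p.mask_floor + (p.ll_gate_max - p.mask_floor) * _hill(t_light, p.ll_t50, p.ll_n)


def advance_state(state: PinealState, params: PinealParams, light: float,
                  dt: float, *, light_prev: float | None = None) -> PinealState:
    """Advance the oscillator state by dt hours under the given illuminance.

    ``light_prev`` (lux over the preceding step) marks illuminance
    transitions for the photoperiod memory and the desynchronization
    timer; if omitted, no transition is assumed.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > 0.1:
        raise ValueError("dt must be <= 0.1 h for a stable update")
    if light < 0:
        raise ValueError("illuminance must be >= 0")
    p = params
    st = replace_state(state)

    lit = light > 0
    was_lit = lit if light_prev is None else light_prev > 0
    if lit != was_lit:
        st.t_const = 0.0
        if not lit:  # lights off
            st.pending_dark_onset = st.clock_h
        else:  # lights on: a completed dark window updates the duty memory
            if st.pending_dark_onset is not None:
                dark_len = st.clock_h - st.pending_dark_onset
                if NIGHT_MIN_H <= dark_len <= NIGHT_MAX_H:
                    st.duty = min(max(dark_len / 24.0, DUTY_MIN), DUTY_MAX)
            st.pending_dark_onset = None

    s = st.phase * 24.0
    night_h = st.duty * 24.0
    if lit:
        ds = 24.0 / p.tau_ll
        x = s / night_h
        if x < 0.8:
            gain = p.entrain_gain * math.exp(-st.t_light / p.prc_adapt_tau)
            if x < 0.4:  # delay lobe, first part of subjective night
                ds += -gain * math.sin(math.pi * x / 0.4)
            else:  # weaker advance lobe; dead zone from 0.8 onward
                ds += gain * p.prc_advance_frac * math.sin(math.pi * (x - 0.4) / 0.4)
    else:
        ds = 24.0 / p.tau_dd
        if s >= p.dark_pull_zone and st.t_since_light < p.dark_pull_memory:
            strength = p.dark_pull * (1.0 - st.desync) ** 2
            ds += strength * math.sin(
                math.pi * (s - p.dark_pull_zone) / (24.0 - p.dark_pull_zone))
    st.phase = (s + ds * dt) / 24.0 % 1.0

    # masking gate
    if lit:
        target, tau = _gate_floor(p, st.t_light), p.mask_tau_on
    else:
        target, tau = 1.0, p.mask_tau_off
    st.gate += (target - st.gate) * (1.0 - math.exp(-dt / tau))

    # amplitude recovery
    tau_a = p.amp_tau_light if lit else p.amp_tau_dark
    st.amp += (1.0 - st.amp) * (1.0 - math.exp(-dt / tau_a))

    # desynchronization under constant conditions
    st.t_const += dt
    if lit:
        target_d = p.desync_max * _hill(st.t_const, p.desync_t50_light, p.desync_n_light)
    else:
        t50 = max(p.desync_t50_dark - p.desync_age_rate * st.clock_h,
                  p.desync_t50_dark_min)
        target_d = p.desync_max * _hill(st.t_const, t50, p.desync_n_dark)
    tau_d = p.desync_tau_up if target_d > st.desync else p.desync_tau_down
    st.desync += (target_d - st.desync) * (1.0 - math.exp(-dt / tau_d))

    # light-exposure timers
    if lit:
        st.t_light += dt
        if math.isfinite(st.t_since_light):
            st.t_since_light *= math.exp(-dt / p.base_dark_decay_tau)
        else:
            st.t_since_light = 0.0
    else:
        st.t_light *= math.exp(-dt / p.ll_decay_tau)
        st.t_since_light += dt

    st.clock_h += dt
    return st


def replace_state(state: PinealState) -> PinealState:
    out = PinealState.__new__(PinealState)
    out.__dict__.update(state.__dict__)
    return out


# ---------------------------------------------------------------------------
# chamber, fractions, culture
# ---------------------------------------------------------------------------

def chamber_filter(profile: SecretionProfile, sp: SuperfusionParams) -> SecretionProfile:
    """First-order mixing of the superfusion set (time constant V/F).

    Exact exponential update on the (uniform or non-uniform) grid; mass is
    conserved in steady state and a unit step reaches 1 - 1/e of its final
    value one time constant after onset.
    """
    tau = sp.mixing_tau_h
    t, x = profile.times, profile.rate
    y = np.empty_like(x)
    y[0] = x[0]
    a = np.exp(-np.diff(t) / tau)
    for i in range(1, len(x)):
        y[i] = a[i - 1] * y[i - 1] + (1.0 - a[i - 1]) * x[i]
    return SecretionProfile(times=t, rate=y)


def collect_fractions(profile: SecretionProfile, sp: SuperfusionParams,
                      rng: np.random.Generator | None = None,
                      gland_id: str = "gland", t_start: float | None = None,
                      clock_anchor: float = 7.0, seed: int | None = None) -> FractionSeries:
    """Average the secretion profile over 30-min bins and apply assay noise.

    Concentration per fraction is (mean rate over the bin)/flow, multiplied
    by unit-mean lognormal noise of coefficient of variation ``ria_cv``;
    the secretion column is recomputed as concentration x flow.
    """
    dt_frac = sp.fraction_minutes / 60.0
    t0 = profile.times[0] if t_start is None else float(t_start)
    t_end = profile.times[-1]
    n = int(math.floor((t_end - t0) / dt_frac + 1e-9))
    if n < 1:
        raise ValueError("profile shorter than one fraction")
    edges = t0 + dt_frac * np.arange(n + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    idx = np.searchsorted(profile.times, edges)
    csum = np.concatenate([[0.0], np.cumsum(profile.rate)])
    counts = np.diff(idx)
    if np.any(counts == 0):
        raise ValueError("profile grid too coarse for fraction bins")
    means = (csum[idx[1:]] - csum[idx[:-1]]) / counts
    conc = means / sp.flow
    if sp.ria_cv > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + sp.ria_cv ** 2))
        conc = conc * rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=n)
    return FractionSeries(
        gland_id=gland_id,
        t_mid=mids,
        clock=(clock_anchor + mids) % 24.0,
        concentration=conc,
        secretion=conc * sp.flow,
        flow=sp.flow,
        seed=seed,
    )


def default_params() -> PinealParams:
    """The documented default parameter set (see docs/methods.md)."""
    return PinealParams()


def initial_state(params: PinealParams, initial_duty: float = 0.5,
                  initial_phase_clock: float = 19.0,
                  clock_anchor: float = 7.0, phase_jitter: float = 0.0) -> PinealState:
    """Entrained initial state at culture start.

    ``initial_phase_clock`` is the clock time of subjective night onset in
    the rearing cycle (lights-off, 19.00 by default).  The startup delay
    shifts the day-1 phase back, reproducing the late first-day rhythm of
    freshly explanted glands.
    """
    s0 = (clock_anchor - initial_phase_clock) % 24.0 - params.startup_delay + phase_jitter
    return PinealState(
        phase=(s0 / 24.0) % 1.0,
        duty=initial_duty,
        amp=params.amp0,
        gate=params.gate0,
        desync=0.0,
        t_light=0.0,
        t_since_light=0.0,
        t_const=0.0,
        pending_dark_onset=0.0,
        clock_h=0.0,
    )


def simulate_rates(params: PinealParams, schedule: LightSchedule,
                   initial_duty: float = 0.5, initial_phase_clock: float = 19.0,
                   phase_jitters=(0.0,), dt: float = 0.01):
    """Dense secretion-rate profiles for glands differing only in initial
    phase jitter.  Returns (times, rates) with rates of shape
    (n_glands, n_times)."""
    n_steps = int(round(schedule.horizon / dt))
    times = dt * np.arange(n_steps + 1)
    lux = np.array([schedule.illuminance_at(min(t, schedule.horizon - 1e-9))
                    for t in times])
    jit = np.asarray(phase_jitters, dtype=float)
    n_g = len(jit)

    p = params
    s = np.array([(7.0 - initial_phase_clock) % 24.0 - p.startup_delay + j
                  for j in jit]) % 24.0
    duty = float(initial_duty)
    amp = p.amp0
    gate = p.gate0
    desync = 0.0
    t_light = 0.0
    t_since_light = 0.0
    t_const = 0.0
    pending_dark_onset = 0.0 if lux[0] == 0 else None

    rates = np.empty((n_g, n_steps + 1))

    def emit(i):
        w = circadian_waveform(s, duty, p, times[i])
        gate_b = max(_hill(t_since_light, p.base_dark_t50, p.base_dark_n),
                     desync / p.desync_max)
        base = (p.base_early
                + p.base_max * _hill(times[i], p.base_t50, p.base_n)) * gate_b
        c = np.clip((1.0 - desync) * amp * w + base, 0.0, 1.0)
        rates[:, i] = p.s_min + (p.s_max - p.s_min) * c * gate

    emit(0)
    for i in range(1, n_steps + 1):
        light, light_prev = lux[i], lux[i - 1]
        lit, was_lit = light > 0, light_prev > 0
        if lit != was_lit:
            t_const = 0.0
            if not lit:
                pending_dark_onset = times[i]
            else:
                if pending_dark_onset is not None:
                    dark_len = times[i] - pending_dark_onset
                    if NIGHT_MIN_H <= dark_len <= NIGHT_MAX_H:
                        duty = min(max(dark_len / 24.0, DUTY_MIN), DUTY_MAX)
                pending_dark_onset = None

        night_h = duty * 24.0
        if lit:
            ds = np.full(n_g, 24.0 / p.tau_ll)
            gain = p.entrain_gain * math.exp(-t_light / p.prc_adapt_tau)
            x = s / night_h
            delay = np.sin(np.pi * np.clip(x, 0.0, 0.4) / 0.4) * (x < 0.4)
            adv = (np.sin(np.pi * (np.clip(x, 0.4, 0.8) - 0.4) / 0.4)
                   * ((x >= 0.4) & (x < 0.8)))
            ds += gain * (p.prc_advance_frac * adv - delay)
        else:
            ds = np.full(n_g, 24.0 / p.tau_dd)
            if t_since_light < p.dark_pull_memory:
                strength = p.dark_pull * (1.0 - desync) ** 2
                in_zone = s >= p.dark_pull_zone
                ds += strength * np.sin(
                    np.pi * (s - p.dark_pull_zone) / (24.0 - p.dark_pull_zone)
                ) * in_zone
        s = (s + ds * dt) % 24.0

        if lit:
            target, tau = _gate_floor(p, t_light), p.mask_tau_on
        else:
            target, tau = 1.0, p.mask_tau_off
        gate += (target - gate) * (1.0 - math.exp(-dt / tau))

        tau_a = p.amp_tau_light if lit else p.amp_tau_dark
        amp += (1.0 - amp) * (1.0 - math.exp(-dt / tau_a))

        t_const += dt
        if lit:
            target_d = p.desync_max * _hill(t_const, p.desync_t50_light, p.desync_n_light)
        else:
            t50 = max(p.desync_t50_dark - p.desync_age_rate * times[i],
                      p.desync_t50_dark_min)
            target_d = p.desync_max * _hill(t_const, t50, p.desync_n_dark)
        tau_d = p.desync_tau_up if target_d > desync else p.desync_tau_down
        desync += (target_d - desync) * (1.0 - math.exp(-dt / tau_d))

        if lit:
            t_light += dt
            t_since_light *= math.exp(-dt / p.base_dark_decay_tau)
        else:
            t_light *= math.exp(-dt / p.ll_decay_tau)
            t_since_light += dt

        emit(i)

    return times, rates


def simulate_culture(params: PinealParams, sp: SuperfusionParams,
                     schedule: LightSchedule, initial_duty: float = 0.5,
                     initial_phase_clock: float = 19.0,
                     record_start: float = 2.0, dt: float = 0.01) -> list[FractionSeries]:
    """Simulate n_glands independent fraction series under a schedule.

    Glands share parameters and lighting but carry independent initial
    phase jitter and independent assay noise; the run is reproducible
    under a fixed ``sp.seed``.  Recording starts ``record_start`` hours
    into culture (glands are mounted about 09.00).
    """
    if schedule.horizon - record_start < sp.fraction_minutes / 60.0:
        raise ValueError("schedule horizon shorter than one fraction")
    if sp.n_glands < 1:
        raise ValueError("need at least one gland")
    ss = np.random.SeedSequence(sp.seed)
    children = ss.spawn(sp.n_glands + 1)
    jitter_rng = np.random.default_rng(children[0])
    jit = jitter_rng.normal(0.0, params.phase_jitter_sd, size=sp.n_glands)

    times, rates = simulate_rates(
        params, schedule, initial_duty=initial_duty,
        initial_phase_clock=initial_phase_clock, phase_jitters=jit, dt=dt)

    out = []
    tau = sp.mixing_tau_h
    a = math.exp(-dt / tau)
    for g in range(sp.n_glands):
        x = rates[g]
        y = np.empty_like(x)
        y[0] = x[0]
        for i in range(1, len(x)):
            y[i] = a * y[i - 1] + (1.0 - a) * x[i]
        prof = SecretionProfile(times=times, rate=y)
        rng = np.random.default_rng(children[g + 1])
        fs = collect_fractions(prof, sp, rng=rng, gland_id=f"gland{g + 1}",
                               t_start=record_start,
                               clock_anchor=schedule.clock_anchor)
        fs.seed = sp.seed
        out.append(fs)
    return out
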