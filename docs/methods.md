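# Methods

`pinealclock` simulates melatonin (MLT) secretion from turkey pineal
explants kept in superfusion culture under arbitrary lighting protocols,
and implements the rhythm-quantification procedure used for such data:
per-cycle threshold-crossing points, fold amplitudes, and an
elevated-secretion duration defined through repeated-measures ANOVA with
LSD contrasts, compared across groups with Duncan's multiple range test.
This note describes the model, its parameters, the statistics, and what
the synthetic data can and cannot stand in for.

## The measurement chain

A gland in superfusion culture secretes at an instantaneous rate r(t)
(ng/min). The culture chamber and tubing (volume V ~ 1.35 ml, flow
F = 0.1 ml/min) act as a first-order mixing stage with time constant
V/F ~ 13.5 min; the outflow is collected in 30-min fractions, so each
observation is the bin average of the filtered rate divided by the flow
(ng/ml). Radioimmunoassay error is modelled as unit-mean lognormal noise
with a coefficient of variation of 8% (the assay's intra-assay CV was
below 10%). The assay's four-parameter-logistic calibration curve
(`assay` module, A = 1380, B = 0.95, C = 45.7, D = -1.2) is provided with
its exact algebraic inverse for users working from bound counts; it is
off by default because fraction-level CV noise already represents the
measurement error.

Clock convention: culture time 0 is 07.00 on day 1, and 07.00 bounds
each culture day. Recording starts 2 h into culture (glands are mounted
about 09.00); this is configurable, since the original protocol states
only the time of sacrifice.

## The oscillator

The circadian state is a subjective time s in [0, 24) h, with s = 0 at
subjective night onset. Phase velocity is 24/tau_dd per hour in darkness
and 24/tau_ll in light, with

* tau_dd = 21.64 h, the least-squares slope of the printed free-running
  peak mid-points over days 1-4 in darkness (the day-5 jump in that
  series is anomalous and deliberately not modelled), and
* tau_ll = 22.29 h from the continuous-light mid-point drift over days
  1-5.

Both periods are below 24 h (daily phase advances under constant
conditions), with the advance slower in light.

**Light PRC.** Light falling in the subjective night shifts phase through
a two-lobed response: a delay lobe over the first 40% of the night, a
weaker advance lobe (30% of the delay amplitude) over the next 40%, and a
dead zone covering the remainder of the night and the whole subjective
day. The PRC amplitude adapts under sustained light with a 17-h time
constant. Entrainment works by *pinning*: a free-running phase tries to
cross into subjective night while the lights are still on, and the delay
lobe holds it just past night onset until lights-off. Because the
amplitude adapts away, a continuously lit culture escapes the pin after
roughly one day and free-runs - reproducing a circadian rhythm under
constant light whose phase drifts with tau_ll. The advance lobe is kept
weak so that dawn does not expel the phase from the night (the residual
morning secretion after lights-on is a masking phenomenon, below).

**Darkness initiation.** Darkness falling late in the subjective day
(s > 22.5 h) pulls the phase rapidly toward night onset. The pull is
armed only while recent light exposure is remembered (a darkness timer
below ~16 h), so cultures held in darkness free-run undisturbed. This
term is what re-entrains a reversed light-dark cycle within a single
day, and it distinguishes a 6-h darkness pulse in the photophase (which
reaches the pull zone and advances the next peak) from a 3-h pulse
(which barely does). It is implemented as a continuous velocity term
rather than an instantaneous reset at the dark transition: a one-shot
reset cannot make that 3-h/6-h distinction and introduces a
discontinuity in the secretion waveform.

**Photoperiod memory.** The stored scotophase fraction (duty) is
rewritten each time a dark window of 7-20 h completes (at lights-on),
clamped to [4/24, 20/24]; shorter dark windows are pulses and leave the
memory untouched. The update therefore acts with a one-day lag, and
constant conditions freeze it - the "calendar". The duty sets the width
of the secretion plateau below.

## Secretion

The instantaneous rate is

    r = s_min + (s_max - s_min) * C * gate,   C = (1 - d) * a * w(s) + B,

clipped so that C is in [0, 1], with s_min = 0.06 and s_max = 2.45 ng/min
chosen so the entrained rhythm spans roughly 40-fold.

**Waveform** w(s): the product of a steep rise sigmoid shortly after
night onset (midpoint 1.5 subjective h, width 0.6 h) and a slow fall
sigmoid whose midpoint is 4.68 + 0.633 x (night length in h) + 0.014 x
(culture age in h), width 0.68 h. The rapid rise / slow fall matches the
step-wise nocturnal increase and gradual morning decline of the measured
profiles; the night-length term makes the elevated episode track the
memorized scotophase; the small age term (a ~0.34 h/day broadening of
the episode) is needed to reconcile the day-2 free-running peak
mid-point with the 13.5-h elevated window still measured on culture day
5.

**Startup amplitude** a: explanted glands start at a = 0.09 of full
amplitude and recover toward 1 in darkness (tau 55 h), only very slowly
in light (tau 80 h). Together with a phase lag of 3.73 h at culture
start (the oscillator restarts late after explantation) this produces
the documented day-1 transient: a roughly 20-fold, late-peaked first
cycle under the entrained cycle, ~10-fold in darkness, ~13.6-fold under
constant light.

**Desynchronization** d: under constant conditions the explant's cell
population loses coherence. In darkness this is switch-like - d relaxes
to 0.8 once about 21.5 h of constant darkness have elapsed (Hill
exponent 17, relaxation 1 h) - so the first free-running cycle is almost
intact and later cycles are compressed below 2.5-fold. In light the
same process is gradual (half-time 80 h), matching the slow amplitude
decay over five days of continuous illumination. Under an alternating
cycle the frequent transitions keep d near zero (decay tau 24 h).

**Clockless baseline** B: a culture-age-dependent fraction of the
dynamic range (Hill: max 0.16, half-time 22 h, exponent 6, plus a small
early-darkness component of 0.042) expressed when the tissue is in
sustained darkness or desynchronized. It reproduces the progressive
elevation of the free-running minima (0.16, 0.36, ~0.5 ng/min on days
1-3) while leaving the entrained photophase minima at the 0.05-0.06
ng/min floor, because in light the masking gate suppresses it like any
other secretion. Its darkness gate rises over ~4-12 h of darkness and
fades within the first hour of light.

**Masking gate.** Light drives the gate toward a floor of 0.035 with a
3.5-h time constant; darkness releases it with a 0.7-h time constant.
The slow suppression means a 45-180-min light pulse produces a graded,
partial drop in nocturnal secretion (deeper with longer pulses, with
immediate recovery after short pulses), while only a 6-h exposure
reaches the daytime level. Under many hours of continuous light the
gate floor itself rises (Hill in cumulative light exposure, half-time
16 h), producing the creeping daytime baseline seen under constant
illumination; this adaptation resets within a few hours of darkness.

**Gland individuality.** Glands within a group share all parameters and
differ by an initial phase jitter (SD 0.2 h) and independent assay
noise. Inter-gland amplitude variability exists in real data (the
printed secretion SEMs suggest ~10-30%) but is off by default; it can be
emulated through parameter overrides.

Integration is an explicit fixed-step update at dt = 0.01 h; all
dynamics are smooth and slow at that scale, and a fixed step keeps runs
bit-reproducible. One seed expands into per-gland substreams via
`numpy.random.SeedSequence`.

## Rhythm metrics

For each 07.00-bounded day of an individual profile: minimum and maximum
(value and clock time), I50/I75 (first upward crossings of 50%/75% of
the cycle maximum on the ascent, linearly interpolated between fraction
mid-times), D50/D75 (last downward crossings after the maximum,
searched up to 14 h past the maximum so peaks spanning the day boundary
keep their descent), M (circular midpoint of I75 and D75), and the fold
amplitude max/min. Thresholds are absolute fractions of the maximum
(not of the min-max range); with 20-40-fold rhythms the distinction is
negligible, but it is pinned here. When the descent never falls below a
threshold - routine under constant conditions, where compression keeps
the trough above 50% and sometimes 75% of the peak - the corresponding
point, and M if D75 is missing, are reported undefined rather than
guessed. Group summaries average clock times circularly
(resultant-vector mean); naive averaging fails near midnight.

## Elevated-secretion duration

Within one group, the fraction concentrations from the preceding
photophase (or subjective day) through the following one enter a
one-group repeated-measures ANOVA (glands x sampling times; error
df = (T-1)(n-1)). The reference points are the timepoints with the
lowest group mean in the preceding and following photophase windows.
Scanning forward from the first reference, the window starts at the
first timepoint significantly different from it by LSD
(|diff| > t(1-alpha/2, df) x sqrt(2 MS_err / n)); scanning backward from
the second reference, it ends at the last timepoint significantly
different from that one. The duration is the time between the two
fraction mid-points. Conventions:

* subjective nights under constant conditions are the last experienced
  scotophase projected forward at 24 h (`scotophase_windows`); dark
  windows shorter than 7 h are pulses, not nights;
* day 1 has no preceding photophase in culture, so the reference is the
  first photophase's own pre-peak minimum (flagged in the result);
* both boundaries must be supported by two consecutive significant
  fractions; a single isolated significant fraction is treated as an
  assay outlier (without this guard one noisy fraction hours after the
  peak can drag the endpoint late);
* at zero error variance (noise-free fixtures) any nonzero difference
  counts as significant - the limit of the test;
* no multiplicity correction beyond the (unprotected, liberal) LSD, and
  plain RM-ANOVA without sphericity correction, faithful to the original
  procedure.

Durations are compared across groups by one-way ANOVA followed by
Duncan's multiple range test: means are sorted and means p ranks apart
are tested against R_p = q*(alpha_p, p, df) x sqrt(MS_err/n) with
protection alpha_p = 1 - (1-alpha)^(p-1), stepping down with the no-test
rule inside accepted ranges; unbalanced designs use the harmonic mean n
(the source experiments are all n = 4, so this never binds). The
studentized-range quantile comes from scipy's numerical distribution
rather than hard-coded tables, cross-checked in the tests against
published table values and the k = 2 identity q = sqrt(2) t. The compact
letter display assigns one letter per maximal homogeneous range, which
is minimal on a line of sorted means.

## Calibration and what passing tests mean

Default parameters were calibrated by running this full pipeline
(4 glands, 8% CV, 30-min fractions) against the published rhythm
parameters of the five explant experiments - fold amplitudes and their
day-1 transients, the free-running mid-point drift, the
photoperiod-dependent elevated durations (13.5/15.1/10.1/15.3 h), the
pulse responses - and then frozen; `scripts/acceptance.py` and the
acceptance tests re-derive those quantities from scratch at 5 seeds.
The problem sizes (<= 6 days x 48 fractions x 4 glands x 5 seeds per
quantity) keep every check inexpensive.

The generator emulates the *mean structure* and assay noise of
superfusion data. It does not emulate: inter-gland amplitude
heterogeneity (off by default), serial correlation of assay error,
drifts in flow or chamber volume, tissue deterioration beyond the
smooth baseline/desynchronization trends (in particular the abrupt
day-5 jump of the printed free-running mid-point series is left
unexplained, as in the source), or any intensity dependence of light
(a single 100-lx photophase level is assumed; darkness includes the
<10-lx red rearing light). Conclusions from passing tests therefore
concern the internal consistency of the model plus statistics pipeline
with the published summary numbers, not a validated fit to raw data,
which were never deposited.

## Numerical conventions

Half-open lighting intervals (a transition instant belongs to the
following interval); clock strings "hh.mm" with decimal hours
internally; crossing times by linear interpolation between fraction
mid-times; circular means by resultant vector; ties in Duncan's sorting
broken by group label (affects letter names only). Degenerate inputs -
constant series, all-undefined metrics, missing adjacent windows - are
reported as undefined/n.d. with the reason, never imputed.
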