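# Methods

## Model and assumptions

The respiratory system is modeled by the one-compartment force balance
F = K·V + K′·(dV/dt) + K″·(dV/dt)², where V is the inspired volume above
FRC and dV/dt the airflow at the mouth. The model omits inertance and
assumes linear compliance and constant resistance coefficients; the
defaults K = 8.52 cmH₂O/L, K′ = 3.5 cmH₂O/(L/s), K″ = 1.5 cmH₂O/(L/s)² are
the classical mean resting-adult coefficients. Work is computed for
inspiration only: expiration is treated as passive (elastic recoil) and
contributes zero work. No pleural-pressure ("added work", ∫P dV from
esophageal balloon data) pathway is modeled.

Inspiratory flow is a half-sine impulse a·sin(2πft) truncated at its first
zero crossing t = 1/(2f). A composite inspiration is a sum of such impulses
with a common onset and zero relative phase — the modeling assumption that
the contributing muscle groups contract in unison. Under that assumption
the lowest-frequency impulse has the longest half-period, every faster
impulse is embedded inside it, and the composite inspiratory time is
T_I = 1/(2·min fᵢ). Consequently 1/(2·T_I) recovers only the *lowest*
instantaneous frequency in a breath; faster components are invisible to
T_I-based characterization even though they raise the viscous (∝f) and
turbulent (∝f²) work. Whether partially overlapping (staggered-onset)
impulses occur in real breaths is an open modeling question; the common
onset reading is implemented and nonzero phases are rejected explicitly.

## Work calculators

Per-breath closed form (half-sine lobe of tidal volume V_T at frequency f):
elastic ½KV_T², viscous ¼K′π²fV_T², turbulent ⅔K″π²f²V_T³. The
`WorkBreakdown` container stores the three components; `total` is their
exact sum by construction.

`work_numeric` integrates the same quantities from sampled flow by the
trapezoidal rule (elastic ∫K·V dV, viscous ∫K′(dV/dt)²dt, turbulent
∫K″(dV/dt)³dt over the first positive lobe, running volume by cumulative
trapezoid). It accepts arbitrary lobe shapes and doubles as the independent
check of every closed form: on a clean half-sine at dt = 10⁻⁴ s it agrees
with the closed form to better than one part in 10⁴ per component, with
observed convergence order ≥ 1 as dt shrinks.

Mean work per unit time multiplies the per-breath work by the breathing
rate in Hz (B/60), with V_T = V_A/B + V_D taken from the ventilatory
demand. Internally all frequencies and rates are Hz, volumes L, flows L/s,
so mean work carries cmH₂O·L/s. The absolute time base (per second vs per
minute) is a convention; the percent change between the two models is
invariant to it, which is why the comparison tables are insensitive to this
choice. The sinusoidal model is implemented as the f = B_hz special case of
the non-sinusoidal one, so the diagonal reduction holds to machine
precision rather than to a tolerance.

## Duty cycle, feasibility, Limit

An inspiration at frequency f occupies T_I = 1/(2f) of the period
T_Tot = 60/B: duty = 100·T_I/T_Tot. When duty exceeds `max_duty` the
pairing is infeasible and every downstream quantity carries a typed `Limit`
sentinel (a singleton value, never an exception), so tables print `Limit`
cells rather than failing. `max_duty` defaults to 100%; setting 90%
reproduces the flow-limit variant that reserves a minimum expiratory time
of 10% of T_Tot. A 10⁻¹² relative guard keeps exact-boundary cells
(duty = 100.0) feasible against floating-point roundoff.

The published duty-cycle table contains six cells inconsistent with its own
defining construction (at 0.75 Hz for 7.5/15/30/60 BPM and in the 45 BPM
column at 0.50/1.00 Hz); `compare.PRINTED_DUTY_DISCREPANCIES` records them
and they are flagged rather than matched. The percent-change table has no
such inconsistencies: all 20 numeric cells and all 5 Limit cells regenerate
exactly at one-decimal rounding.

## Segmentation

Breaths are segmented from sampled flow by sign: T_I is the contiguous
positive lobe (zero crossing to zero crossing, boundaries linearly
interpolated between samples), T_E the following non-positive phase
including zero-flow pauses, extending to the next onset or the end of the
signal. An all-positive or all-zero signal contains no complete breath and
is rejected. Default sampling is dt = 1 ms; synthesis and segmentation
round-trip T_I and T_E to within one sample interval.

## Table display conventions

Percent-change cells are rounded to one decimal, ties away from zero;
duty-cycle cells to two decimals trimmed to at least one. CSV output uses a
first column `inst_freq_hz`, columns named by BPM, and the literal `Limit`
for infeasible cells. Minus signs are plain hyphen-minus.

## Synthetic breath trains

`generate_breath_train` emulates quiet adult breathing as a non-stationary
train: per-breath fundamental frequency lognormal (median 0.25 Hz, log-sd
0.2), period normal (mean 4 s, sd 0.4 s, i.e. around 15 BPM), reference
tidal volume 0.5 L, optional faster components as (frequency multiple,
amplitude fraction) pairs, optional additive Gaussian sample noise applied
last. Draws violating T_I < 0.9·T_Tot are rejected and redrawn (error after
100 rejections). Expiration is a passive decaying exponential
(τ = 0.2·T_E) scaled so each breath's net volume returns to baseline. All
randomness flows through one `numpy` generator seeded from the spec, so
equal specs give byte-identical output.

What the generator does *not* emulate: cardiogenic oscillations, drift and
baseline wander of real pneumotachograph signals, active expiration,
inter-breath correlation (draws are i.i.d.), and staggered component
onsets. Passing round-trip tests on these fixtures therefore demonstrates
the internal consistency of synthesis, segmentation and integration — not
robustness to real-signal artifacts, which would need additional
preprocessing.

## Problem sizes and numerical choices

Reference oracle comparisons use dt = 10⁻⁴ s on single breaths; round-trip
checks use 100-breath trains at dt = 1 ms (~4×10⁵ samples, well under a
minute to generate and analyze). Comparison grids are 5×5 and effectively
instant. Zero-crossing interpolation is linear; an exactly-zero sample is
taken as the crossing itself. Composite sampling requires dt to divide the
dominant half-period to within one sample; undersampling a requested
sinusoid beyond the Nyquist interval 1/(2f) is rejected with a message
naming the bound.

## Known limitations

- Single-compartment, frequency-independent coefficients; no inertance,
  no nonlinear compliance, no airway pressure waveform.
- The closed forms assume the half-sine lobe shape; arbitrary lobes are
  handled only by the numeric integrator.
- The comparison tables validate ratios between the two models; absolute
  mean-work ordinates depend on the per-second time-base convention.
- Segmentation is sign-based and assumes a calibrated, zero-centered flow
  signal; noisy signals near zero flow will fragment breaths unless
  smoothed upstream.
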