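"""Synthesis and segmentation of inspiratory flow waveforms.

Inspiratory flow is modeled as one or more half-sine impulses
a * sin(2*pi*f*t) truncated at the first zero crossing t = 1/(2f).  Each
impulse stands for the airflow contribution of one set of respiratory
muscles contracting in unison (common onset, zero phase); their pointwise
sum is the composite inspiration.  Because the lowest-frequency impulse has
the longest half-period, every other impulse is embedded inside it and the
composite inspiratory time is T_I = 1/(2*min f_i) — so T_I alone only ever
reveals the *lowest* instantaneous frequency in the breath.

Sign convention: inspiration is positive flow, expiration non-positive
(including zero-flow pauses).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .timing import BreathTiming


@dataclass(frozen=True)
class FlowComponent:
    """One half-sine impulse of inspiratory flow.

    Parameters
    ----------
    amplitude : float
        Peak flow a, L/s.  Positive.
    frequency : float
        Instantaneous frequency f, Hz.  Positive.
    phase : float
        Fixed at zero: components share a common onset (muscles contracting
        in unison).  A nonzero value is rejected; the field exists as an
        extension point for staggered-onset models.
    """

    amplitude: float
    frequency: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if not (self.amplitude > 0 and math.isfinite(self.amplitude)):
            raise ValueError(f"amplitude must be positive, got {self.amplitude}")
        if not (self.frequency > 0 and math.isfinite(self.frequency)):
            raise ValueError(f"frequency must be positive, got {self.frequency}")
        if self.phase != 0.0:
            raise ValueError(
                "nonzero phase is not supported: impulses share a common onset"
            )

    @property
    def half_period(self) -> float:
        """Support of the impulse, T_I_i = 1/(2f), s."""
        return 1.0 / (2.0 * self.frequency)

    @property
    def tidal_volume(self) -> float:
        """Volume delivered by the impulse, a/(pi*f), L."""
        return self.amplitude / (math.pi * self.frequency)


@dataclass(frozen=True)
class FlowSignal:
    """Uniformly sampled airflow trace.

    dt is the sample interval in seconds; samples are flow in L/s with
    inspiration positive.
    """

    dt: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if not (self.dt > 0 and math.isfinite(self.dt)):
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("signal needs at least 2 samples in a 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite samples")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        """Sample times t = 0, dt, 2dt, ..., s."""
        return np.arange(self.samples.size) * self.dt

    @property
    def duration(self) -> float:
        """Time spanned by the samples, (n-1)*dt, s."""
        return (self.samples.size - 1) * self.dt

    def to_frame(self) -> pd.DataFrame:
        """Two-column frame ``time_s, flow_lps``."""
        return pd.DataFrame({"time_s": self.times, "flow_lps": self.samples})


@dataclass(frozen=True)
class CompositeInspiration:
    """An inspiration built from one or more common-onset impulses."""

    components: tuple

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        if len(comps) < 1:
            raise ValueError("a composite inspiration needs at least one component")
        for c in comps:
            if not isinstance(c, FlowComponent):
                raise TypeError(f"expected FlowComponent, got {type(c).__name__}")
        object.__setattr__(self, "components", comps)

    @property
    def T_I(self) -> float:
        """Composite inspiratory time: the longest half-period, 1/(2*min f_i)."""
        return max(c.half_period for c in self.components)

    @property
    def f_fundamental(self) -> float:
        """Lowest component frequency — the only one T_I can reveal."""
        return min(c.frequency for c in self.components)

    @property
    def tidal_volume(self) -> float:
        """Total inspired volume, sum of a_i/(pi*f_i), L."""
        return sum(c.tidal_volume for c in self.components)


def sinusoidal_flow(a: float, f: float, duration: float, dt: float) -> FlowSignal:
    """Continuous sinusoidal flow a*sin(2*pi*f*t) sampled at t = 0, dt, ...

    The endpoint at *duration* is included.  dt must resolve the oscillation:
    sampling at or below the Nyquist interval 1/(2f) is rejected.
    """
    for name, val in (("a", a), ("f", f), ("duration", duration), ("dt", dt)):
        if not (val > 0 and math.isfinite(val)):
            raise ValueError(f"{name} must be positive, got {val}")
    nyquist_dt = 1.0 / (2.0 * f)
    if dt > nyquist_dt:
        raise ValueError(
            f"dt={dt} s undersamples a {f} Hz wave: the Nyquist bound "
            f"requires dt <= 1/(2f) = {nyquist_dt} s"
        )
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    return FlowSignal(dt=dt, samples=a * np.sin(2.0 * math.pi * f * t))


def halfsine_impulse(component: FlowComponent, dt: float) -> FlowSignal:
    """Single non-negative half-sine lobe truncated at its zero crossing.

    Samples cover [0, 1/(2f)] inclusive; the endpoints are (numerically)
    zero and every sample is >= 0.  dt must divide the half-period to within
    one sample.
    """
    if not (dt > 0 and math.isfinite(dt)):
        raise ValueError(f"dt must be positive, got {dt}")
    t_half = component.half_period
    n_steps = int(round(t_half / dt))
    if n_steps < 1:
        raise ValueError(
            f"dt={dt} s cannot resolve a half-period of {t_half} s"
        )
    if abs(n_steps * dt - t_half) > dt:
        raise ValueError(
            f"dt={dt} s does not divide the half-period {t_half} s "
            "to within one sample"
        )
    t = np.arange(n_steps + 1) * dt
    samples = component.amplitude * np.sin(2.0 * math.pi * component.frequency * t)
    # the analytic lobe is non-negative on [0, 1/(2f)]; clip roundoff at the end
    np.clip(samples, 0.0, None, out=samples)
    return FlowSignal(dt=dt, samples=samples)


def compose_inspiration(
    components: Sequence[FlowComponent], dt: float
) -> FlowSignal:
    """Pointwise sum of zero-padded half-sine impulses with a common onset.

    The composite lasts 1/(2*min f_i): the lowest-frequency impulse sets the
    inspiratory time and the faster impulses are embedded inside it.
    """
    composite = CompositeInspiration(tuple(components))
    impulses = [halfsine_impulse(c, dt) for c in composite.components]
    n = max(len(s) for s in impulses)
    total = np.zeros(n)
    for s in impulses:
        total[: len(s)] += s.samples
    return FlowSignal(dt=dt, samples=total)


def tidal_volume_halfsine(a: float, f: float) -> float:
    """Tidal volume of one half-sine lobe: integral of a*sin(2*pi*f*t) over
    [0, 1/(2f)], which is a/(pi*f) L."""
    if not (a > 0 and math.isfinite(a)):
        raise ValueError(f"amplitude must be positive, got {a}")
    if not (f > 0 and math.isfinite(f)):
        raise ValueError(f"frequency must be positive, got {f}")
    return a / (math.pi * f)


def amplitude_for_tidal(v_t: float, f: float) -> float:
    """Peak flow that delivers tidal volume *v_t* at frequency *f*: pi*f*V_T."""
    if not (v_t > 0 and math.isfinite(v_t)):
        raise ValueError(f"tidal volume must be positive, got {v_t}")
    if not (f > 0 and math.isfinite(f)):
        raise ValueError(f"frequency must be positive, got {f}")
    return math.pi * f * v_t


@dataclass(frozen=True)
class BreathSegment:
    """One complete breath located inside a flow signal.

    Boundary times are linearly interpolated between samples at sign
    changes, so they need not fall on the sample grid.
    """

    onset_s: float        # start of the inspiratory lobe
    crossover_s: float    # inspiration -> expiration zero crossing
    end_s: float          # end of the non-positive phase (next onset or signal end)
    i_onset: int          # first sample index with positive flow
    i_crossover: int      # first non-positive sample index after the lobe
    i_end: int            # sample index bounding the expiratory phase

    @property
    def timing(self) -> BreathTiming:
        return BreathTiming(
            T_I=self.crossover_s - self.onset_s, T_E=self.end_s - self.crossover_s
        )


def _interp_crossing(t0: float, t1: float, s0: float, s1: float) -> float:
    """Time where the line through (t0,s0),(t1,s1) crosses zero."""
    if s0 == 0.0:
        return t0
    if s1 == s0:
        return t1
    return t0 + (t1 - t0) * (-s0) / (s1 - s0)


def iter_breaths(signal: FlowSignal) -> Iterator[BreathSegment]:
    """Yield complete breaths: a positive lobe followed by a non-positive phase.

    The expiratory phase of each breath extends to the onset of the next
    positive lobe, or to the end of the signal; zero-flow pauses count as
    expiration.  A trailing positive lobe with no expiratory phase after it
    is not a complete breath and is not yielded.
    """
    s = signal.samples
    t = signal.times
    n = s.size
    i = 0
    while True:
        pos = np.flatnonzero(s[i:] > 0)
        if pos.size == 0:
            return
        i_on = i + int(pos[0])
        onset = t[i_on] if i_on == 0 else _interp_crossing(
            t[i_on - 1], t[i_on], s[i_on - 1], s[i_on]
        )
        nonpos = np.flatnonzero(s[i_on:] <= 0)
        if nonpos.size == 0:
            return  # inspiration never ends: incomplete breath
        i_x = i_on + int(nonpos[0])
        crossover = _interp_crossing(t[i_x - 1], t[i_x], s[i_x - 1], s[i_x]) \
            if s[i_x] < 0 else t[i_x]
        nxt = np.flatnonzero(s[i_x:] > 0)
        if nxt.size == 0:
            i_end = n - 1
            end = t[i_end]
        else:
            i_end = i_x + int(nxt[0])
            end = _interp_crossing(t[i_end - 1], t[i_end], s[i_end - 1], s[i_end])
        if end <= crossover:
            return  # no expiratory time at all
        yield BreathSegment(
            onset_s=onset, crossover_s=crossover, end_s=end,
            i_onset=i_on, i_crossover=i_x, i_end=i_end,
        )
        if nxt.size == 0:
            return
        i = i_end


def segment_breaths(signal: FlowSignal) -> list:
    """All complete breaths in the signal (see :func:`iter_breaths`)."""
    return list(iter_breaths(signal))


def segment_breath(signal: FlowSignal) -> BreathTiming:
    """Timing of the first complete breath in the signal.

    T_I is the contiguous positive-flow lobe (zero crossing to zero
    crossing); T_E is the following non-positive phase including zero-flow
    pauses.  Raises when the signal holds no complete breath.
    """
    for seg in iter_breaths(signal):
        return seg.timing
    raise ValueError("no complete breath: need a positive lobe followed by "
                     "a non-positive phase")
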