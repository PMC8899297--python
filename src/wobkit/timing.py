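"""Breath timing: rate, period, instantaneous frequency, duty cycle, compensation.

Breathing *rate* (breaths per minute, 60/T_Tot) and the *instantaneous
inspiratory frequency* (the frequency of the half-sine lobe describing
inspiratory flow, f_I = 1/(2*T_I)) coincide only for a true sinusoid, where
T_I = T_E.  Everything in this module keeps the two quantities distinct and
expresses their competition for the breath period as a duty cycle,
100 * T_I / T_Tot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Union


class Limit:
    """Sentinel for an infeasible frequency/rate pairing.

    A pairing is infeasible when the inspiratory time 1/(2f) demanded by the
    instantaneous frequency exceeds the allowed fraction of the breath period
    60/B.  ``Limit`` propagates through tables and comparisons as a value,
    never as an exception.
    """

    _singleton = None

    def __new__(cls) -> "Limit":
        if cls._singleton is None:
            cls._singleton = super().__new__(cls)
        return cls._singleton

    def __repr__(self) -> str:
        return "Limit"


LIMIT = Limit()


def is_limit(value: object) -> bool:
    """True if *value* is the infeasibility sentinel."""
    return isinstance(value, Limit)


@dataclass(frozen=True)
class BreathTiming:
    """Inspiratory time, expiratory time and derived per-breath quantities.

    Parameters
    ----------
    T_I : float
        Inspiratory time, s.  Must be positive.
    T_E : float
        Expiratory time, s (any pause at the end of expiration is included).
        Must be positive.
    """

    T_I: float
    T_E: float

    def __post_init__(self) -> None:
        if not (self.T_I > 0 and math.isfinite(self.T_I)):
            raise ValueError(f"T_I must be positive and finite, got {self.T_I}")
        if not (self.T_E > 0 and math.isfinite(self.T_E)):
            raise ValueError(f"T_E must be positive and finite, got {self.T_E}")

    @property
    def T_Tot(self) -> float:
        """Total breath period T_I + T_E, s."""
        return self.T_I + self.T_E

    @property
    def rate_bpm(self) -> float:
        """Breathing rate 60/T_Tot, breaths per minute."""
        return 60.0 / self.T_Tot

    @property
    def f_I(self) -> float:
        """Instantaneous inspiratory frequency 1/(2*T_I), Hz."""
        return 1.0 / (2.0 * self.T_I)

    @property
    def f_E(self) -> float:
        """Instantaneous expiratory frequency 1/(2*T_E), Hz."""
        return 1.0 / (2.0 * self.T_E)

    @property
    def duty_pct(self) -> float:
        """Inspiratory duty cycle 100*T_I/T_Tot, %."""
        return 100.0 * self.T_I / self.T_Tot


@dataclass(frozen=True)
class DutyCycleResult:
    """Duty cycle of a (frequency, rate) pairing, or the Limit condition."""

    percent: Union[float, Limit]
    T_I: float
    T_Tot: float

    @property
    def is_limit(self) -> bool:
        return is_limit(self.percent)


def rate_from_period(t_tot: float) -> float:
    """Breathing rate in BPM from the breath period in seconds (60/T_Tot)."""
    if not (t_tot > 0 and math.isfinite(t_tot)):
        raise ValueError(f"breath period must be positive, got {t_tot}")
    return 60.0 / t_tot


def period_from_rate(b_rate_bpm: float) -> float:
    """Breath period in seconds from the rate in BPM (60/B)."""
    if not (b_rate_bpm > 0 and math.isfinite(b_rate_bpm)):
        raise ValueError(f"breathing rate must be positive, got {b_rate_bpm}")
    return 60.0 / b_rate_bpm


def inspired_frequency(t_i: float) -> float:
    """Instantaneous frequency of an inspired half-sine lobe, 1/(2*T_I) Hz."""
    if not (t_i > 0 and math.isfinite(t_i)):
        raise ValueError(f"inspiratory time must be positive, got {t_i}")
    return 1.0 / (2.0 * t_i)


def inspiratory_time(f_i: float) -> float:
    """Inverse of :func:`inspired_frequency`: T_I = 1/(2*f_I) seconds."""
    if not (f_i > 0 and math.isfinite(f_i)):
        raise ValueError(f"inspiratory frequency must be positive, got {f_i}")
    return 1.0 / (2.0 * f_i)


def is_sinusoidal(timing: BreathTiming, tol: float = 1e-9) -> bool:
    """True when T_I and T_E agree to within *tol* seconds.

    This is the only case where "frequency" and "rate" describe the same
    thing: f = 1/T_Tot = 1/(2 T_I) = 1/(2 T_E).
    """
    return abs(timing.T_I - timing.T_E) <= tol


def duty_cycle(f: float, b_rate_bpm: float, max_duty: float = 100.0) -> DutyCycleResult:
    """Inspiratory duty cycle of instantaneous frequency *f* at rate *b_rate_bpm*.

    The inspiration at frequency f occupies T_I = 1/(2f) of the period
    T_Tot = 60/B, so the duty cycle is 100*T_I/T_Tot.  When that exceeds
    *max_duty* percent the pairing is infeasible and the result carries the
    :data:`LIMIT` sentinel instead of a number.
    """
    if not (f > 0 and math.isfinite(f)):
        raise ValueError(f"instantaneous frequency must be positive, got {f}")
    if not (b_rate_bpm > 0 and math.isfinite(b_rate_bpm)):
        raise ValueError(f"breathing rate must be positive, got {b_rate_bpm}")
    if not (0 < max_duty <= 100):
        raise ValueError(f"max_duty must lie in (0, 100], got {max_duty}")
    t_i = inspiratory_time(f)
    t_tot = period_from_rate(b_rate_bpm)
    pct = 100.0 * t_i / t_tot
    if pct > max_duty * (1 + 1e-12):  # guard exact-boundary cells against roundoff
        return DutyCycleResult(LIMIT, t_i, t_tot)
    return DutyCycleResult(min(pct, max_duty), t_i, t_tot)


def alveolar_ventilation(v_t: float, v_d: float, b_rate_bpm: float) -> float:
    """Alveolar ventilation (V_T - V_D) * B_rate, L/min.

    Raises when V_T <= V_D: no gas reaches the alveoli once the whole tidal
    volume sits in dead space.
    """
    if v_d < 0:
        raise ValueError(f"dead space must be non-negative, got {v_d}")
    if not (b_rate_bpm > 0):
        raise ValueError(f"breathing rate must be positive, got {b_rate_bpm}")
    if not (v_t > v_d):
        raise ValueError(
            f"tidal volume ({v_t} L) must exceed dead space ({v_d} L) "
            "for alveolar delivery"
        )
    return (v_t - v_d) * b_rate_bpm


def apply_load_compensation(
    baseline: BreathTiming, d_ti_pct: float, d_te_pct: float
) -> BreathTiming:
    """Retimed breath after a resistive-load response.

    Loads lengthen inspiration and (typically) expiration by the given
    percentages; the new period, rate, instantaneous frequency and duty
    cycle are all available on the returned :class:`BreathTiming`.
    """
    t_i = baseline.T_I * (1.0 + d_ti_pct / 100.0)
    t_e = baseline.T_E * (1.0 + d_te_pct / 100.0)
    if t_i <= 0 or t_e <= 0:
        raise ValueError(
            "compensation shrinks a phase below zero "
            f"(dTI={d_ti_pct}%, dTE={d_te_pct}%)"
        )
    return BreathTiming(T_I=t_i, T_E=t_e)


@dataclass(frozen=True)
class CompensationResult:
    """Retimed breath at constant period, with the implied mean-work change."""

    timing: BreathTiming
    duty: DutyCycleResult
    mean_work: object = None  # WorkBreakdown when ventilation/mechanics given


def compensate_preserving_ventilation(
    baseline: BreathTiming,
    new_f_i: float,
    ventilation=None,
    mechanics=None,
    max_duty: float = 100.0,
) -> Union[CompensationResult, Limit]:
    """Retime a breath to a new inspiratory frequency at constant T_Tot.

    Holding T_Tot fixed holds the breathing rate fixed, and hence (at fixed
    tidal volume) alveolar ventilation.  Expiration absorbs the slack:
    T_E = T_Tot - 1/(2 f_I).  If ``ventilation`` (a VentilationSpec) and
    optionally ``mechanics`` are given, the non-sinusoidal mean work at the
    new frequency is attached.  Returns :data:`LIMIT` when the requested
    frequency cannot fit in the period.
    """
    t_tot = baseline.T_Tot
    t_i = inspiratory_time(new_f_i)
    if t_i > t_tot * max_duty / 100.0 or t_i >= t_tot:
        return LIMIT
    timing = BreathTiming(T_I=t_i, T_E=t_tot - t_i)
    duty = duty_cycle(new_f_i, rate_from_period(t_tot), max_duty)
    work = None
    if ventilation is not None:
        from .work import RespiratoryMechanics, mean_work_nonsinusoidal

        mech = mechanics if mechanics is not None else RespiratoryMechanics()
        spec = replace(ventilation, B_rate=rate_from_period(t_tot))
        work = mean_work_nonsinusoidal(new_f_i, spec, mech, max_duty=max_duty)
    return CompensationResult(timing=timing, duty=duty, mean_work=work)
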