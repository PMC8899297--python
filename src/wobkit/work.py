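"""Work of breathing: per-breath closed forms, numeric integration, mean rates.

The total force driving airflow is F = K*V + K'*(dV/dt) + K''*(dV/dt)^2,
with an elastic coefficient K (cmH2O/L), a viscous (flow-resistive)
coefficient K' (cmH2O/(L/s)) and a turbulent coefficient K''
(cmH2O/(L/s)^2).  For a half-sine inspiration of tidal volume V_T at
instantaneous frequency f, integrating F dV over the breath gives the
per-breath work

    W = 1/2 K V_T^2  +  1/4 K' pi^2 f V_T^2  +  2/3 K'' pi^2 f^2 V_T^3.

Only the viscous and turbulent terms feel the instantaneous frequency;
elastic work depends on the volume displaced alone.  Multiplying by the
breathing rate (in Hz) gives mean work per unit time; the classical
sinusoidal model is the special case f = B, while the non-sinusoidal model
lets the inspiratory frequency float above (or below) the rate, subject to
the duty-cycle feasibility 1/(2f) <= 60/B.  Expiration is passive and
contributes no work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .timing import LIMIT, Limit, duty_cycle
from .waveforms import FlowSignal, iter_breaths

_PI2 = math.pi * math.pi

#: Mean coefficients of resistance for a resting adult, used throughout the
#: classical work-of-breathing literature.
DEFAULT_K = 8.52          # cmH2O/L
DEFAULT_K_PRIME = 3.5     # cmH2O/(L/s)
DEFAULT_K_DOUBLEPRIME = 1.5  # cmH2O/(L/s)^2


@dataclass(frozen=True)
class RespiratoryMechanics:
    """Elastic, viscous and turbulent coefficients of the respiratory system."""

    K: float = DEFAULT_K
    K_prime: float = DEFAULT_K_PRIME
    K_doubleprime: float = DEFAULT_K_DOUBLEPRIME

    def __post_init__(self) -> None:
        for name in ("K", "K_prime", "K_doubleprime"):
            val = getattr(self, name)
            if not (val >= 0 and math.isfinite(val)):
                raise ValueError(f"{name} must be non-negative, got {val}")


@dataclass(frozen=True)
class VentilationSpec:
    """Ventilatory demand: alveolar ventilation, dead space, breathing rate.

    V_A is in L/min, V_D in L, B_rate in breaths/min.  The tidal volume each
    breath must deliver is V_T = V_A/B_rate + V_D: the alveolar share plus
    the dead-space volume re-ventilated every breath.
    """

    V_A: float = 6.0
    V_D: float = 0.2
    B_rate: float = 15.0

    def __post_init__(self) -> None:
        if not (self.V_A > 0 and math.isfinite(self.V_A)):
            raise ValueError(f"V_A must be positive, got {self.V_A}")
        if not (self.V_D >= 0 and math.isfinite(self.V_D)):
            raise ValueError(f"V_D must be non-negative, got {self.V_D}")
        if not (self.B_rate > 0 and math.isfinite(self.B_rate)):
            raise ValueError(f"B_rate must be positive, got {self.B_rate}")

    @property
    def V_T(self) -> float:
        """Tidal volume V_A/B_rate + V_D, L per breath."""
        return self.V_A / self.B_rate + self.V_D

    @property
    def B_hz(self) -> float:
        """Breathing rate expressed in Hz (breaths per second)."""
        return self.B_rate / 60.0


@dataclass(frozen=True)
class WorkBreakdown:
    """Elastic/viscous/turbulent work, per breath or per unit time.

    basis "per_breath" carries cmH2O*L; basis "mean_rate" carries cmH2O*L/s.
    ``total`` is the exact sum of the three components.
    """

    elastic: float
    viscous: float
    turbulent: float
    basis: str

    def __post_init__(self) -> None:
        if self.basis not in ("per_breath", "mean_rate"):
            raise ValueError(f"basis must be per_breath or mean_rate, got {self.basis!r}")
        for name in ("elastic", "viscous", "turbulent"):
            val = getattr(self, name)
            if not (val >= 0 and math.isfinite(val)):
                raise ValueError(f"{name} work must be non-negative, got {val}")

    @property
    def total(self) -> float:
        return self.elastic + self.viscous + self.turbulent

    def scaled(self, factor: float, basis: str) -> "WorkBreakdown":
        return WorkBreakdown(
            elastic=self.elastic * factor,
            viscous=self.viscous * factor,
            turbulent=self.turbulent * factor,
            basis=basis,
        )

    def as_dict(self) -> dict:
        return {
            "elastic": self.elastic,
            "viscous": self.viscous,
            "turbulent": self.turbulent,
            "total": self.total,
            "basis": self.basis,
        }


def total_force(v: float, dvdt: float, mech: RespiratoryMechanics) -> float:
    """Total force K*V + K'*(dV/dt) + K''*(dV/dt)^2, cmH2O."""
    if not (math.isfinite(v) and math.isfinite(dvdt)):
        raise ValueError("volume and flow must be finite")
    return mech.K * v + mech.K_prime * dvdt + mech.K_doubleprime * dvdt * dvdt


def work_single_breath(
    v_t: float, f: float, mech: RespiratoryMechanics = RespiratoryMechanics()
) -> WorkBreakdown:
    """Per-breath work of a half-sine inspiration (closed form).

    elastic = 1/2 K V_T^2; viscous = 1/4 K' pi^2 f V_T^2;
    turbulent = 2/3 K'' pi^2 f^2 V_T^3.
    """
    if not (v_t > 0 and math.isfinite(v_t)):
        raise ValueError(f"tidal volume must be positive, got {v_t}")
    if not (f > 0 and math.isfinite(f)):
        raise ValueError(f"frequency must be positive, got {f}")
    return WorkBreakdown(
        elastic=0.5 * mech.K * v_t * v_t,
        viscous=0.25 * mech.K_prime * _PI2 * f * v_t * v_t,
        turbulent=(2.0 / 3.0) * mech.K_doubleprime * _PI2 * f * f * v_t ** 3,
        basis="per_breath",
    )


def work_numeric(
    signal: FlowSignal, mech: RespiratoryMechanics = RespiratoryMechanics()
) -> WorkBreakdown:
    """Per-breath work by trapezoidal integration over the inspiratory lobe.

    With V(t) the running inspired volume and v = dV/dt the sampled flow:
    elastic = K * int V v dt, viscous = K' * int v^2 dt,
    turbulent = K'' * int v^3 dt, taken over the first positive lobe.
    Accepts arbitrary lobe shapes; on a clean half-sine it converges to
    :func:`work_single_breath` as dt -> 0 and serves as its independent
    check.  An identically zero signal does no work; a signal with no
    inspiratory lobe otherwise is an error.
    """
    s = signal.samples
    if not np.any(s > 0):
        if np.all(s == 0):
            return WorkBreakdown(0.0, 0.0, 0.0, basis="per_breath")
        raise ValueError("signal has no inspiratory (positive-flow) lobe")
    i_on = int(np.argmax(s > 0))
    after = np.flatnonzero(s[i_on:] <= 0)
    i_x = i_on + int(after[0]) if after.size else s.size - 1
    lo = max(i_on - 1, 0)
    flow = np.clip(s[lo : i_x + 1], 0.0, None)  # bounding samples sit at/below zero
    dt = signal.dt
    vol = cumulative_trapezoid(flow, dx=dt, initial=0.0)
    return WorkBreakdown(
        elastic=mech.K * float(np.trapezoid(vol * flow, dx=dt)),
        viscous=mech.K_prime * float(np.trapezoid(flow ** 2, dx=dt)),
        turbulent=mech.K_doubleprime * float(np.trapezoid(flow ** 3, dx=dt)),
        basis="per_breath",
    )


def tidal_from_ventilation(spec: VentilationSpec) -> float:
    """Tidal volume implied by a ventilation spec: V_A/B_rate + V_D, L."""
    return spec.V_T


def mean_work_sinusoidal(
    spec: VentilationSpec, mech: RespiratoryMechanics = RespiratoryMechanics()
) -> WorkBreakdown:
    """Classical mean work rate for continuous sinusoidal breathing.

    The waveform frequency equals the breathing rate (f = B), so the mean
    rate is B_hz times the per-breath work at frequency B_hz, in cmH2O*L/s.
    """
    per_breath = work_single_breath(spec.V_T, spec.B_hz, mech)
    return per_breath.scaled(spec.B_hz, basis="mean_rate")


def mean_work_nonsinusoidal(
    f: float,
    spec: VentilationSpec,
    mech: RespiratoryMechanics = RespiratoryMechanics(),
    max_duty: float = 100.0,
) -> Union[WorkBreakdown, Limit]:
    """Mean work rate when the inspiratory frequency floats free of the rate.

    Each of the B breaths per unit time is a half-sine at instantaneous
    frequency *f* delivering V_T = V_A/B + V_D, so the mean rate is
    B_hz * W(V_T, f).  Elastic mean work is independent of f; viscous scales
    with f and turbulent with f^2.  Returns :data:`LIMIT` when 1/(2f)
    exceeds the allowed fraction of the breath period (infeasible pairing).
    Reduces exactly to :func:`mean_work_sinusoidal` at f = B_hz.
    """
    if duty_cycle(f, spec.B_rate, max_duty).is_limit:
        return LIMIT
    per_breath = work_single_breath(spec.V_T, f, mech)
    return per_breath.scaled(spec.B_hz, basis="mean_rate")


def analyze_breaths(
    signal: FlowSignal, mech: RespiratoryMechanics = RespiratoryMechanics()
):
    """Per-breath timing, frequency, duty cycle, volume and numeric work.

    Segments the signal into complete breaths and returns a DataFrame with
    one row per breath: T_I_s, T_E_s, T_Tot_s, f_I_hz, duty_pct, V_T_l and
    the elastic/viscous/turbulent/total work of the inspiratory lobe
    (cmH2O*L per breath).
    """
    import pandas as pd

    rows = []
    s = signal.samples
    dt = signal.dt
    for k, seg in enumerate(iter_breaths(signal)):
        timing = seg.timing
        lo = max(seg.i_onset - 1, 0)
        lobe = np.clip(s[lo : seg.i_crossover + 1], 0.0, None)
        wb = work_numeric(FlowSignal(dt=dt, samples=lobe), mech)
        v_t = float(np.trapezoid(lobe, dx=dt))
        rows.append(
            {
                "breath_idx": k,
                "T_I_s": timing.T_I,
                "T_E_s": timing.T_E,
                "T_Tot_s": timing.T_Tot,
                "f_I_hz": timing.f_I,
                "rate_bpm": timing.rate_bpm,
                "duty_pct": timing.duty_pct,
                "V_T_l": v_t,
                "W_elastic": wb.elastic,
                "W_viscous": wb.viscous,
                "W_turbulent": wb.turbulent,
                "W_total": wb.total,
            }
        )
    return pd.DataFrame(rows)
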