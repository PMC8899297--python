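"""Synthetic non-stationary breath trains for testing and demonstration.

Real breathing is time-variant: inspiratory frequency, period and depth
drift from breath to breath, inspiration and expiration are unequal, and a
breath's inspiratory lobe may carry more than one frequency component.
The generator emulates this by drawing per-breath parameters from seeded
distributions, synthesizing each inspiration as a sum of common-onset
half-sine impulses, and filling the rest of the period with a passive
exponential expiration that returns the lung volume to baseline.  A truth
table records the exact per-breath parameters so analyses can be checked
against them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

from .waveforms import FlowComponent, FlowSignal, compose_inspiration

#: Expiratory decay: time constant as a fraction of T_E.  Five time
#: constants fit inside the expiratory window, so the lobe is essentially
#: complete before the next breath.
_EXP_TAU_FRAC = 0.2


@dataclass(frozen=True)
class BreathTrainSpec:
    """Distributional recipe for a seeded train of breaths.

    Defaults emulate quiet adult breathing around 15 BPM: fundamental
    inspiratory frequency lognormal with median 0.25 Hz and log-sd 0.2,
    breath period normal with mean 4 s and sd 0.4 s, and a reference tidal
    volume of 0.5 L.  ``extra_components`` adds faster impulses to every
    inspiration as (frequency multiple > 1, amplitude fraction) pairs.
    """

    n_breaths: int = 10
    f_median_hz: float = 0.25
    f_sigma_log: float = 0.2
    t_tot_mean_s: float = 4.0
    t_tot_sd_s: float = 0.4
    v_t_ref_l: float = 0.5
    amp_sigma_log: float = 0.0
    extra_components: Tuple[Tuple[float, float], ...] = ()
    noise_sd: float = 0.0
    seed: int = 0
    min_exp_frac: float = 0.1  # expiration keeps at least this fraction of T_Tot

    def __post_init__(self) -> None:
        if self.n_breaths < 1:
            raise ValueError("n_breaths must be >= 1")
        for name in ("f_median_hz", "t_tot_mean_s", "v_t_ref_l"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        for name in ("f_sigma_log", "t_tot_sd_s", "amp_sigma_log", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 <= self.min_exp_frac < 1):
            raise ValueError("min_exp_frac must lie in [0, 1)")
        for ratio, rel in self.extra_components:
            if ratio <= 1:
                raise ValueError(
                    "extra component frequency multiples must exceed 1 "
                    "(the fundamental sets T_I)"
                )
            if rel <= 0:
                raise ValueError("extra component amplitudes must be positive")


def _draw_breath(spec: BreathTrainSpec, rng: np.random.Generator):
    """One feasible (components, T_Tot) draw; rejects T_I >= allowed window."""
    for _ in range(100):
        f1 = float(rng.lognormal(math.log(spec.f_median_hz), spec.f_sigma_log)) \
            if spec.f_sigma_log > 0 else spec.f_median_hz
        t_tot = float(rng.normal(spec.t_tot_mean_s, spec.t_tot_sd_s)) \
            if spec.t_tot_sd_s > 0 else spec.t_tot_mean_s
        amp_scale = float(rng.lognormal(0.0, spec.amp_sigma_log)) \
            if spec.amp_sigma_log > 0 else 1.0
        if t_tot <= 0:
            continue
        t_i = 1.0 / (2.0 * f1)
        if t_i >= t_tot * (1.0 - spec.min_exp_frac):
            continue
        a1 = amp_scale * math.pi * f1 * spec.v_t_ref_l
        comps = [FlowComponent(amplitude=a1, frequency=f1)]
        for ratio, rel in spec.extra_components:
            comps.append(FlowComponent(amplitude=a1 * rel, frequency=f1 * ratio))
        return comps, t_tot
    raise RuntimeError(
        "could not draw a feasible breath (T_I < T_Tot) in 100 attempts; "
        "check f_median_hz against t_tot_mean_s"
    )


def generate_breath_train(
    spec: BreathTrainSpec, dt: float = 0.001
) -> Tuple[FlowSignal, pd.DataFrame]:
    """Seeded train of breaths plus its per-breath truth table.

    Each breath is a composite inspiration (sum of half-sine impulses, all
    starting at the breath onset) followed by a passive expiration: a
    negative exponential lobe scaled so the breath's net volume is zero.
    Gaussian sample noise, if any, is added last.  The truth table columns
    are ``breath_idx, T_I_s, T_E_s, T_Tot_s, f1_hz, a1_lps, ..., V_T_l``
    with one fN/aN pair per component.  Identical specs (same seed) yield
    identical output.
    """
    if not (dt > 0 and math.isfinite(dt)):
        raise ValueError(f"dt must be positive, got {dt}")
    rng = np.random.default_rng(spec.seed)
    n_comp = 1 + len(spec.extra_components)
    chunks = []
    rows = []
    for k in range(spec.n_breaths):
        comps, t_tot = _draw_breath(spec, rng)
        insp = compose_inspiration(comps, dt)
        n_i = len(insp) - 1          # inspiration spans samples 0..n_i
        t_i = n_i * dt               # grid-aligned inspiratory time
        n_tot = int(round(t_tot / dt))
        n_e = n_tot - n_i
        if n_e < 1:
            raise RuntimeError("breath period leaves no room for expiration")
        v_t = sum(c.tidal_volume for c in comps)
        t_e = n_e * dt
        tau = _EXP_TAU_FRAC * t_e
        te_times = (np.arange(1, n_e) * dt)  # strictly inside the expiration
        shape = np.exp(-te_times / tau)
        # scale so the trapezoidal integral of the breath is (numerically) zero
        area = float(np.trapezoid(np.concatenate(([0.0], shape)), dx=dt))
        exp_flow = -shape * (v_t / area) if area > 0 else np.zeros(n_e - 1)
        # samples 0..n_i-1: inspiration (sample n_i is the shared zero crossing,
        # carried by the first expiratory slot to keep breaths abutting cleanly)
        breath = np.concatenate((insp.samples[:n_i], [0.0], exp_flow))
        chunks.append(breath)
        row = {
            "breath_idx": k,
            "T_I_s": comps[0].half_period,
            "T_E_s": n_tot * dt - comps[0].half_period,
            "T_Tot_s": n_tot * dt,
            "V_T_l": v_t,
        }
        for i, c in enumerate(comps, start=1):
            row[f"f{i}_hz"] = c.frequency
            row[f"a{i}_lps"] = c.amplitude
        rows.append(row)
    chunks.append(np.zeros(1))  # close the final expiration on the grid
    samples = np.concatenate(chunks)
    if spec.noise_sd > 0:
        samples = samples + rng.normal(0.0, spec.noise_sd, samples.size)
    truth = pd.DataFrame(rows)
    ordered = ["breath_idx", "T_I_s", "T_E_s", "T_Tot_s"]
    for i in range(1, n_comp + 1):
        ordered += [f"f{i}_hz", f"a{i}_lps"]
    ordered.append("V_T_l")
    return FlowSignal(dt=dt, samples=samples), truth[ordered]
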