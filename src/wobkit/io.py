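"""Flow-signal CSV and JSON configuration handling.

Flow traces travel as two-column CSV with header ``time_s,flow_lps``, a
monotone time column and uniform spacing (validated to 1 part in 1e4).
Configuration is JSON with ``mechanics``, ``ventilation`` and
``max_duty_pct`` sections; missing sections fall back to the resting-adult
defaults.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple, Union

import numpy as np
import pandas as pd

from .waveforms import FlowSignal
from .work import RespiratoryMechanics, VentilationSpec

FLOW_COLUMNS = ("time_s", "flow_lps")


def read_flow_csv(path: Union[str, Path]) -> FlowSignal:
    """Read a uniformly sampled flow trace from ``time_s,flow_lps`` CSV."""
    df = pd.read_csv(path)
    for col in FLOW_COLUMNS:
        if col not in df.columns:
            raise ValueError(
                f"{path}: missing required column {col!r} "
                f"(found {list(df.columns)})"
            )
    t = df["time_s"].to_numpy(dtype=float)
    flow = df["flow_lps"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples, got {t.size}")
    steps = np.diff(t)
    if np.any(steps <= 0):
        bad = int(np.argmax(steps <= 0)) + 1
        raise ValueError(f"{path}: column time_s not strictly increasing at row {bad}")
    dt = float(np.mean(steps))
    if np.max(np.abs(steps - dt)) > 1e-4 * dt:
        bad = int(np.argmax(np.abs(steps - dt))) + 1
        raise ValueError(
            f"{path}: column time_s not uniformly spaced (row {bad}; "
            "spacing must be uniform to 1 part in 1e4)"
        )
    return FlowSignal(dt=dt, samples=flow)


def write_flow_csv(signal: FlowSignal, path: Union[str, Path]) -> None:
    """Write a flow trace as ``time_s,flow_lps`` CSV."""
    signal.to_frame().to_csv(path, index=False)


DEFAULT_CONFIG = {
    "mechanics": {"K": 8.52, "K_prime": 3.5, "K_doubleprime": 1.5},
    "ventilation": {"V_A_lpm": 6.0, "V_D_l": 0.2, "B_rate_bpm": 15.0},
    "max_duty_pct": 100.0,
}


def load_config(
    path: Union[str, Path, None] = None,
) -> Tuple[RespiratoryMechanics, VentilationSpec, float]:
    """Load (mechanics, ventilation, max_duty_pct) from a JSON config file.

    Absent file or absent keys mean defaults.  Unknown keys are rejected
    with a diagnostic naming the offending field.
    """
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            try:
                user = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: not valid JSON ({exc})") from exc
        for section, value in user.items():
            if section not in cfg:
                raise ValueError(
                    f"{path}: unknown config key {section!r} "
                    f"(expected one of {sorted(cfg)})"
                )
            if isinstance(cfg[section], dict):
                for key, v in value.items():
                    if key not in cfg[section]:
                        raise ValueError(
                            f"{path}: unknown key {key!r} in section {section!r} "
                            f"(expected one of {sorted(cfg[section])})"
                        )
                    cfg[section][key] = v
            else:
                cfg[section] = value
    mech = RespiratoryMechanics(
        K=cfg["mechanics"]["K"],
        K_prime=cfg["mechanics"]["K_prime"],
        K_doubleprime=cfg["mechanics"]["K_doubleprime"],
    )
    vent = VentilationSpec(
        V_A=cfg["ventilation"]["V_A_lpm"],
        V_D=cfg["ventilation"]["V_D_l"],
        B_rate=cfg["ventilation"]["B_rate_bpm"],
    )
    return mech, vent, float(cfg["max_duty_pct"])
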