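"""Sinusoidal vs non-sinusoidal model comparison: percent change, tables, curves.

The classical sinusoidal mean-work model ties the waveform frequency to the
breathing rate; the non-sinusoidal model lets the instantaneous inspiratory
frequency f float independently of the rate B.  The disagreement between
them at a (f, B) pairing is the percent change

    P_C = 100 * (W_NS - W_S) / |W_S|,

positive when f > B/60 (the sinusoidal model underestimates the work) and
negative when f < B/60.  Pairings whose inspiratory time 1/(2f) cannot fit
in the breath period are reported as the Limit condition.
"""

from __future__ import annotations

import decimal
import io
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .timing import LIMIT, Limit, duty_cycle, is_limit
from .work import (
    RespiratoryMechanics,
    VentilationSpec,
    mean_work_nonsinusoidal,
    mean_work_sinusoidal,
)

#: Default grids spanning the quiet-to-tachypneic range of adult breathing.
DEFAULT_FREQS_HZ = (0.125, 0.25, 0.50, 0.75, 1.00)
DEFAULT_RATES_BPM = (7.5, 15.0, 30.0, 45.0, 60.0)


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (display convention for tables)."""
    q = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def percent_change(
    f: float,
    b_rate_bpm: float,
    spec: Optional[VentilationSpec] = None,
    mech: RespiratoryMechanics = RespiratoryMechanics(),
    max_duty: float = 100.0,
) -> Union[float, Limit]:
    """Percent change of total mean work, non-sinusoidal vs sinusoidal model.

    *spec* supplies V_A and V_D; its breathing rate is overridden by
    *b_rate_bpm*.  Exactly zero when f equals the rate in Hz; Limit when the
    pairing is infeasible.
    """
    base = spec if spec is not None else VentilationSpec()
    at_rate = VentilationSpec(V_A=base.V_A, V_D=base.V_D, B_rate=b_rate_bpm)
    w_ns = mean_work_nonsinusoidal(f, at_rate, mech, max_duty=max_duty)
    if is_limit(w_ns):
        return LIMIT
    w_s = mean_work_sinusoidal(at_rate, mech)
    if f == at_rate.B_hz:
        return 0.0  # algebraic reduction; avoid 1-ulp residue on the diagonal
    return 100.0 * (w_ns.total - w_s.total) / abs(w_s.total)


@dataclass(frozen=True)
class ComparisonGrid:
    """Frequency-by-rate grid of percentages with Limit sentinels.

    Rows are instantaneous frequencies (Hz), columns breathing rates (BPM);
    cells hold unrounded floats or :data:`LIMIT`.
    """

    freqs_hz: tuple
    rates_bpm: tuple
    cells: tuple  # tuple of row-tuples
    quantity: str  # "duty_pct" or "percent_change"

    def cell(self, f: float, b: float) -> Union[float, Limit]:
        i = self.freqs_hz.index(f)
        j = self.rates_bpm.index(b)
        return self.cells[i][j]

    def rounded(self, ndigits: int = 1) -> "ComparisonGrid":
        rows = tuple(
            tuple(c if is_limit(c) else round_half_away(c, ndigits) for c in row)
            for row in self.cells
        )
        return ComparisonGrid(self.freqs_hz, self.rates_bpm, rows, self.quantity)

    def feasible_values(self) -> list:
        return [c for row in self.cells for c in row if not is_limit(c)]

    def _format_cell(self, c: Union[float, Limit]) -> str:
        if is_limit(c):
            return "Limit"
        if self.quantity == "duty_pct":
            # two decimals, trimmed to at least one (6.25 but 50.0)
            txt = f"{round_half_away(c, 2):.2f}"
            if txt.endswith("0"):
                txt = txt[:-1]
            return txt
        return f"{round_half_away(c, 1):.1f}"

    def to_dataframe(self, formatted: bool = False) -> pd.DataFrame:
        cols = [str(b) for b in self.rates_bpm]
        if formatted:
            data = [[self._format_cell(c) for c in row] for row in self.cells]
        else:
            data = [[math.nan if is_limit(c) else c for c in row] for row in self.cells]
        df = pd.DataFrame(data, columns=cols)
        df.insert(0, "inst_freq_hz", list(self.freqs_hz))
        return df

    def to_csv(self) -> str:
        """CSV with first column ``inst_freq_hz``, columns named by BPM,
        cells numeric or the literal ``Limit``."""
        df = self.to_dataframe(formatted=True)
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        return buf.getvalue()

    def to_markdown(self) -> str:
        df = self.to_dataframe(formatted=True)
        header = "| " + " | ".join(df.columns) + " |"
        rule = "|" + "|".join(["---"] * len(df.columns)) + "|"
        lines = [header, rule]
        for _, row in df.iterrows():
            lines.append("| " + " | ".join(str(v) for v in row) + " |")
        return "\n".join(lines)

    def to_text(self) -> str:
        df = self.to_dataframe(formatted=True)
        return df.to_string(index=False)


def build_duty_table(
    freqs_hz: Sequence[float] = DEFAULT_FREQS_HZ,
    rates_bpm: Sequence[float] = DEFAULT_RATES_BPM,
    max_duty: float = 100.0,
) -> ComparisonGrid:
    """Duty-cycle grid 100*(1/(2f))/(60/B) with Limit beyond *max_duty*."""
    rows = []
    for f in freqs_hz:
        row = []
        for b in rates_bpm:
            res = duty_cycle(f, b, max_duty)
            row.append(res.percent)
        rows.append(tuple(row))
    return ComparisonGrid(tuple(freqs_hz), tuple(rates_bpm), tuple(rows), "duty_pct")


def build_pc_table(
    freqs_hz: Sequence[float] = DEFAULT_FREQS_HZ,
    rates_bpm: Sequence[float] = DEFAULT_RATES_BPM,
    spec: Optional[VentilationSpec] = None,
    mech: RespiratoryMechanics = RespiratoryMechanics(),
    max_duty: float = 100.0,
) -> ComparisonGrid:
    """Percent-change grid between the two mean-work models (unrounded)."""
    rows = []
    for f in freqs_hz:
        row = [percent_change(f, b, spec, mech, max_duty) for b in rates_bpm]
        rows.append(tuple(row))
    return ComparisonGrid(
        tuple(freqs_hz), tuple(rates_bpm), tuple(rows), "percent_change"
    )


#: Published duty-cycle table cells that disagree with the construction
#: duty = 100*(1/(2f))/(60/B) they are defined by.  Keyed by (f_hz, B_bpm),
#: value is the percentage as printed.  These cells are flagged, not matched.
PRINTED_DUTY_DISCREPANCIES = {
    (0.50, 45.0): 66.6,   # construction gives 75.0
    (0.75, 7.5): 9.38,    # construction gives 8.33
    (0.75, 15.0): 18.75,  # construction gives 16.67
    (0.75, 30.0): 37.5,   # construction gives 33.33
    (0.75, 60.0): 75.0,   # construction gives 66.67
    (1.00, 45.0): 33.3,   # construction gives 37.5
}


@dataclass(frozen=True)
class CurveFamily:
    """Mean-work components across breathing rates, one curve per frequency.

    ``elastic`` is shared by every curve (it has no frequency dependence);
    ``viscous``, ``turbulent`` and ``total`` are (n_freqs, n_rates) arrays
    masked (NaN, with ``feasible`` False) where the duty limit is exceeded.
    The classical sinusoidal model is included as the f = B/60 locus; each
    frequency curve crosses it exactly at B = 60*f.
    """

    freqs_hz: tuple
    rates_bpm: np.ndarray
    elastic: np.ndarray      # (n_rates,)
    viscous: np.ndarray      # (n_freqs, n_rates)
    turbulent: np.ndarray    # (n_freqs, n_rates)
    total: np.ndarray        # (n_freqs, n_rates)
    feasible: np.ndarray     # (n_freqs, n_rates) bool
    classical: dict          # component name -> (n_rates,) array

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: one row per (curve, rate) point."""
        rows = []
        for i, f in enumerate(self.freqs_hz):
            for j, b in enumerate(self.rates_bpm):
                rows.append(
                    {
                        "inst_freq_hz": f,
                        "rate_bpm": b,
                        "feasible": bool(self.feasible[i, j]),
                        "W_elastic": self.elastic[j],
                        "W_viscous": self.viscous[i, j],
                        "W_turbulent": self.turbulent[i, j],
                        "W_total": self.total[i, j],
                    }
                )
        for j, b in enumerate(self.rates_bpm):
            rows.append(
                {
                    "inst_freq_hz": b / 60.0,
                    "rate_bpm": b,
                    "feasible": True,
                    "W_elastic": self.classical["elastic"][j],
                    "W_viscous": self.classical["viscous"][j],
                    "W_turbulent": self.classical["turbulent"][j],
                    "W_total": self.classical["total"][j],
                }
            )
        df = pd.DataFrame(rows)
        df["curve"] = np.where(
            df.index < len(self.freqs_hz) * len(self.rates_bpm),
            df["inst_freq_hz"].map(lambda f: f"f={f:g}Hz"),
            "classical",
        )
        return df


def build_curves(
    freqs_hz: Sequence[float],
    rates_bpm: Sequence[float],
    spec: Optional[VentilationSpec] = None,
    mech: RespiratoryMechanics = RespiratoryMechanics(),
    max_duty: float = 100.0,
) -> CurveFamily:
    """Mean-work curve family over a rate grid, one curve per frequency.

    Curves truncate (NaN) where the inspiratory time would exceed the duty
    limit; the elastic ordinate is identical across frequencies at equal
    rate, and the classical curve is evaluated at f = B/60 everywhere.
    """
    base = spec if spec is not None else VentilationSpec()
    rates = np.asarray(list(rates_bpm), dtype=float)
    if rates.size == 0 or np.any(rates <= 0):
        raise ValueError("rate grid must be non-empty and positive")
    if np.any(np.diff(rates) <= 0):
        raise ValueError("rate grid must be strictly ascending")
    freqs = tuple(freqs_hz)
    n_f, n_b = len(freqs), rates.size

    elastic = np.empty(n_b)
    classical = {k: np.empty(n_b) for k in ("elastic", "viscous", "turbulent", "total")}
    viscous = np.full((n_f, n_b), np.nan)
    turbulent = np.full((n_f, n_b), np.nan)
    total = np.full((n_f, n_b), np.nan)
    feasible = np.zeros((n_f, n_b), dtype=bool)

    for j, b in enumerate(rates):
        at_rate = VentilationSpec(V_A=base.V_A, V_D=base.V_D, B_rate=float(b))
        w_s = mean_work_sinusoidal(at_rate, mech)
        elastic[j] = w_s.elastic  # elastic term is frequency-free
        for key in classical:
            classical[key][j] = getattr(w_s, key) if key != "total" else w_s.total
        for i, f in enumerate(freqs):
            w_ns = mean_work_nonsinusoidal(f, at_rate, mech, max_duty=max_duty)
            if is_limit(w_ns):
                continue
            feasible[i, j] = True
            viscous[i, j] = w_ns.viscous
            turbulent[i, j] = w_ns.turbulent
            total[i, j] = w_ns.total

    return CurveFamily(
        freqs_hz=freqs,
        rates_bpm=rates,
        elastic=elastic,
        viscous=viscous,
        turbulent=turbulent,
        total=total,
        feasible=feasible,
        classical=classical,
    )
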