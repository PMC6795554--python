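"""Oocyte analyses: on-gating charge integration and Q-V curves, Q_max,
linear-leak isolation of the gating pore current, Q_max normalization, and
the through-origin correlation of gating pore amplitude against Q_max.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .clamp import TraceSet
from .features import IVCurve

__all__ = [
    "GatingPoreReport",
    "integrate_gating_charge",
    "qv_curve",
    "normalize_qv",
    "steady_state_iv",
    "isolate_gating_pore",
    "correlate_gp_qmax",
    "CorrelationResult",
]

LEAK_FIT_WINDOW = (-20.0, 10.0)
STEADY_FRACTION = 0.25
QMAX_VOLTAGE = 40.0


def integrate_gating_charge(traces: TraceSet, sweep: int, window=None) -> float:
    """Trapezoidal integral of the current over the depolarization window.

    Current in nA over time in ms gives pC; returned in nC.
    """
    window = traces.sweep_window if window is None else window
    t0, t1 = window
    if t0 < traces.time[0] - 1e-9 or t1 > traces.time[-1] + 1e-9:
        raise ValueError("integration window outside the sweep")
    sl = traces.window_slice(window)
    t = traces.time[sl]
    i = traces.current[sweep, sl]
    return float(np.trapezoid(i, t)) / 1000.0


def qv_curve(traces: TraceSet) -> tuple[IVCurve, float]:
    """Q(V) from gating-current sweeps, and Qmax = Q(+40 mV).

    Each sweep's steady level (mean of the last 25% of the step, i.e. after
    the charge-displacement transient has settled) is subtracted before
    integrating, so that steady gating-pore or residual leak offsets do not
    contribute to Q_on.
    """
    t0, t1 = traces.sweep_window
    tail = (t1 - STEADY_FRACTION * (t1 - t0), t1)
    sl_tail = traces.window_slice(tail)
    sl_all = traces.window_slice((t0, t1))
    order = np.argsort(traces.levels)
    qs = []
    for j in order:
        i = traces.current[int(j)]
        baseline = float(np.mean(i[sl_tail]))
        t = traces.time[sl_all]
        qs.append(float(np.trapezoid(i[sl_all] - baseline, t)) / 1000.0)
    v = traces.levels[order]
    curve = IVCurve(v, np.array(qs), kind="charge_nC")
    if not np.any(np.abs(v - QMAX_VOLTAGE) < 1e-6):
        raise ValueError("gating-charge protocol lacks the +40 mV sweep")
    return curve, curve.at(QMAX_VOLTAGE)


def normalize_qv(curve: IVCurve, qmax: float) -> IVCurve:
    """Q(V)/Qmax; requires Qmax > 0."""
    if qmax <= 0:
        raise ValueError("Qmax must be > 0 to normalize")
    return IVCurve(curve.voltage, curve.value / qmax, kind="normalized_Q")


def steady_state_iv(traces: TraceSet) -> IVCurve:
    """Total steady-state IV: mean of the final 25% of each 200-ms step."""
    t0, t1 = traces.sweep_window
    sl = traces.window_slice((t1 - STEADY_FRACTION * (t1 - t0), t1))
    order = np.argsort(traces.levels)
    vals = [float(np.mean(traces.current[int(j), sl])) for j in order]
    return IVCurve(traces.levels[order], np.array(vals), kind="steady_nA")


def isolate_gating_pore(steady_iv: IVCurve, fit_window=LEAK_FIT_WINDOW) -> tuple[IVCurve, tuple[float, float]]:
    """Subtract the nonspecific linear leak, estimated by a least-squares
    line over ``fit_window`` (default -20..+10 mV), from the steady-state IV.

    Returns the residual (gating pore) IV and the fitted (slope uS,
    intercept nA at 0 mV) leak line.
    """
    v, i = steady_iv.voltage, steady_iv.value
    mask = (v >= fit_window[0] - 1e-9) & (v <= fit_window[1] + 1e-9)
    if np.count_nonzero(mask) < 3:
        raise ValueError("need >= 3 points inside the leak fit window")
    slope, intercept = np.polyfit(v[mask], i[mask], 1)
    residual = i - (slope * v + intercept)
    return IVCurve(v, residual, kind="gating_pore_nA"), (float(slope), float(intercept))


@dataclass
class CorrelationResult:
    slope: float        # nA per nC, through-origin
    pearson_r: float    # plain correlation of (Qmax, I_gp)
    r2_adj: float       # adjusted R^2 of the constrained fit (uncentered)
    n: int


def correlate_gp_qmax(qmax: np.ndarray, i_gp: np.ndarray) -> CorrelationResult:
    """Through-origin regression of gating pore current at -120 mV on Qmax.

    slope = sum(Q*I)/sum(Q^2); Pearson's R is the ordinary correlation of
    the two series; the adjusted R^2 comes from the one-parameter
    through-origin model with uncentered total sum of squares.
    """
    qmax = np.asarray(qmax, dtype=float)
    i_gp = np.asarray(i_gp, dtype=float)
    if qmax.size != i_gp.size or qmax.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.all(qmax == 0):
        raise ValueError("all Qmax values are zero")
    fit = sm.OLS(i_gp, qmax).fit()
    r = float(np.corrcoef(qmax, i_gp)[0, 1])
    return CorrelationResult(slope=float(fit.params[0]), pearson_r=r,
                             r2_adj=float(fit.rsquared_adj), n=int(qmax.size))


@dataclass
class GatingPoreReport:
    """Per-oocyte derived quantities from the two oocyte protocols."""

    oocyte_id: str
    genotype: str
    qv: IVCurve
    qmax_nC: float
    qv_normalized: IVCurve
    steady_iv: IVCurve
    leak_line: tuple[float, float]
    gp_iv: IVCurve
    i_gp_m120_nA: float
    i_gp_per_qmax: float
    extras: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "oocyte_id": self.oocyte_id, "genotype": self.genotype,
            "qmax_nC": self.qmax_nC, "i_gp_m120_nA": self.i_gp_m120_nA,
            "i_gp_per_qmax_nA_nC": self.i_gp_per_qmax,
            "leak_slope_uS": self.leak_line[0], "leak_intercept_nA": self.leak_line[1],
        }


def extract_oocyte(charge_traces: TraceSet, leak_traces: TraceSet,
                   oocyte_id: str = "oo0") -> GatingPoreReport:
    """Full oocyte pipeline: Q-V and Qmax from the gating-charge protocol,
    gating pore IV by leak-line isolation from the 200-ms leak protocol."""
    qv, qmax = qv_curve(charge_traces)
    qv_norm = normalize_qv(qv, qmax) if qmax > 0 else IVCurve(qv.voltage, qv.value * 0.0, "normalized_Q")
    ss = steady_state_iv(leak_traces)
    gp, line = isolate_gating_pore(ss)
    i120 = gp.at(-120.0)
    return GatingPoreReport(
        oocyte_id=oocyte_id, genotype=str(charge_traces.meta.get("genotype", "?")),
        qv=qv, qmax_nC=qmax, qv_normalized=qv_norm, steady_iv=ss,
        leak_line=line, gp_iv=gp, i_gp_m120_nA=i120,
        i_gp_per_qmax=i120 / qmax if qmax > 0 else np.nan,
    )
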