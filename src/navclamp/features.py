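"""HEK-cell measurements: peak/persistent/resurgent currents, current
density, reversal-potential extrapolation, conductance and availability
curves, Boltzmann and single-exponential fits.

Every operation mirrors the measurement definitions used on the recordings:
peaks are the minimum (most inward) value over the relevant pulse window,
persistent current is the mean over the last 10% of the 50-ms step, the
resurgent peak is the minimum during the repolarization step (with a short
guard after the edge to exclude the instantaneous tail), and midpoints come
from Boltzmann fits of the normalized conductance / availability curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .clamp import TraceSet

__all__ = [
    "IVCurve",
    "BoltzmannFit",
    "ExtractionReport",
    "measure_peak_transient",
    "current_density",
    "peak_iv",
    "estimate_reversal",
    "conductance_curve",
    "fit_boltzmann",
    "availability_curve",
    "fit_decay_tau",
    "measure_persistent",
    "measure_resurgent",
    "normalize_to_max_transient",
    "extract_cell",
]

RESURGENT_GUARD_MS = 0.5
PERSISTENT_FRACTION = 0.10


@dataclass
class IVCurve:
    """Ordered (voltage, value) pairs with a semantics tag."""

    voltage: np.ndarray
    value: np.ndarray
    kind: str = "peak_pA"

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.voltage.size != self.value.size:
            raise ValueError("voltage and value must have equal length")
        if self.voltage.size and np.any(np.diff(self.voltage) <= 0):
            raise ValueError("voltages must be strictly increasing")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("IV values must be finite")

    def at(self, V: float) -> float:
        i = int(np.argmin(np.abs(self.voltage - V)))
        if abs(self.voltage[i] - V) > 1e-6:
            raise ValueError(f"no point at {V} mV")
        return float(self.value[i])


@dataclass
class BoltzmannFit:
    V_half: float
    k: float
    scale: float
    rss: float


def measure_peak_transient(traces: TraceSet, sweep: int, window=None) -> float:
    """Peak (most inward) current over the test-pulse window, pA."""
    window = traces.sweep_window if window is None else window
    sl = traces.window_slice(window)
    if sl.start >= sl.stop:
        raise ValueError("empty measurement window")
    return float(np.min(traces.current[sweep, sl]))


def current_density(peak: float, Cm: float) -> float:
    """Current density pA/pF."""
    if Cm <= 0:
        raise ValueError("Cm must be > 0")
    return peak / Cm


def peak_iv(traces: TraceSet) -> IVCurve:
    """Per-sweep peak transient current over the sweep segment."""
    order = np.argsort(traces.levels)
    peaks = [measure_peak_transient(traces, int(j)) for j in order]
    return IVCurve(traces.levels[order], np.array(peaks), kind="peak_pA")


def estimate_reversal(iv: IVCurve, limb_offset: float = 10.0) -> float:
    """Reversal potential by linear extrapolation of the ascending IV limb.

    The limb is the contiguous run of points from (voltage of the IV minimum
    + limb_offset) up to the last voltage before the interpolated zero
    crossing; a least-squares line through it is extrapolated to zero
    current.
    """
    v, i = iv.voltage, iv.value
    i_min = int(np.argmin(i))
    v_start = v[i_min] + limb_offset
    mask = (v >= v_start - 1e-9) & (i < 0)
    # contiguity: stop at the first non-negative current past the start
    idx = np.flatnonzero(mask)
    if idx.size:
        first = idx[0]
        stop = next((j for j in range(first, v.size) if i[j] >= 0), v.size)
        idx = np.arange(first, stop)
    if idx.size < 3:
        raise ValueError("ascending limb not identifiable (need >= 3 points)")
    a, b = np.polyfit(v[idx], i[idx], 1)
    if a <= 0:
        raise ValueError("ascending limb has non-positive slope")
    return float(-b / a)


def conductance_curve(iv: IVCurve, V_rev: float, exclude_mV: float = 2.5) -> IVCurve:
    """Normalized conductance G/G_max with G = I/(V - V_rev).

    Voltages within ``exclude_mV`` of the reversal potential are dropped
    (vanishing driving force).
    """
    mask = np.abs(iv.voltage - V_rev) > exclude_mV
    v = iv.voltage[mask]
    g = iv.value[mask] / (v - V_rev)
    g_max = np.max(g)
    if g_max <= 0:
        raise ValueError("no positive conductance found")
    return IVCurve(v, g / g_max, kind="normalized_G")


def _boltzmann(V, scale, V_half, k, sign):
    return scale / (1.0 + np.exp(sign * (V - V_half) / k))


def fit_boltzmann(curve: IVCurve, increasing: bool = True) -> BoltzmannFit:
    """Nonlinear least-squares Boltzmann fit with three deterministic
    initializations (midpoint estimate and +/-10 mV); lowest residual sum of
    squares wins, ties broken by the smaller |k|."""
    v, y = curve.voltage, curve.value
    if v.size < 5:
        raise ValueError("need >= 5 points spanning the transition")
    sign = -1.0 if increasing else 1.0
    ymax = float(np.max(y))
    half = 0.5 * ymax
    crossings = np.flatnonzero(np.diff(np.sign(y - half)))
    v_mid = float(v[crossings[0]]) if crossings.size else float(np.median(v))
    best, tried = None, []
    for v0 in (v_mid, v_mid - 10.0, v_mid + 10.0):
        try:
            popt, _ = curve_fit(
                lambda V, s, vh, k: _boltzmann(V, s, vh, k, sign),
                v, y, p0=(max(ymax, 0.1), v0, 6.0),
                bounds=([1e-3, -150.0, 0.5], [5.0, 80.0, 40.0]),
                maxfev=20000,
            )
        except RuntimeError:
            tried.append(v0)
            continue
        rss = float(np.sum((y - _boltzmann(v, *popt, sign)) ** 2))
        cand = BoltzmannFit(V_half=float(popt[1]), k=float(popt[2]),
                            scale=float(popt[0]), rss=rss)
        if best is None or (cand.rss, abs(cand.k)) < (best.rss, abs(best.k)):
            best = cand
    if best is None:
        raise RuntimeError(f"Boltzmann fit failed from initializations {tried}")
    return best


def availability_curve(traces: TraceSet) -> IVCurve:
    """Fraction available (I/I_max) vs prepulse voltage from the
    inactivation protocol: peak at the fixed test pulse, normalized to the
    cell's maximum."""
    test_window = traces.windows[traces.protocol.sweep_seg + 2]
    order = np.argsort(traces.levels)
    peaks = np.array([measure_peak_transient(traces, int(j), window=test_window)
                      for j in order])
    i_max = np.min(peaks)  # most inward
    if i_max >= 0:
        raise ValueError("no inward test-pulse current; cannot normalize")
    return IVCurve(traces.levels[order], peaks / i_max, kind="fraction_available")


def fit_decay_tau(traces: TraceSet, sweep: int, window=None) -> float:
    """Fast-inactivation time constant (ms): single-exponential least-squares
    fit I(t) = A exp(-t/tau) + C from the sweep's peak to the end of the
    pulse."""
    window = traces.sweep_window if window is None else window
    sl = traces.window_slice(window)
    t = traces.time[sl]
    i = traces.current[sweep, sl]
    k0 = int(np.argmin(i))
    t_fit = t[k0:] - t[k0]
    i_fit = i[k0:]
    if t_fit.size < 5 or i_fit[0] >= i_fit[-1] - 1e-12:
        raise ValueError("trace does not decay after its peak")
    amp0 = i_fit[0] - i_fit[-1]
    tau0 = max(0.2, float(t_fit[-1]) / 10.0)
    popt, _ = curve_fit(
        lambda tt, A, tau, C: A * np.exp(-tt / tau) + C,
        t_fit, i_fit, p0=(amp0, tau0, i_fit[-1]),
        bounds=([-np.inf, 1e-3, -np.inf], [np.inf, 1e3, np.inf]), maxfev=20000,
    )
    return float(popt[1])


def measure_persistent(traces: TraceSet, sweep: int,
                       fraction: float = PERSISTENT_FRACTION) -> float:
    """Mean current over the final ``fraction`` of the test pulse, pA."""
    t0, t1 = traces.sweep_window
    window = (t1 - fraction * (t1 - t0), t1)
    sl = traces.window_slice(window)
    if sl.start >= sl.stop:
        raise ValueError("empty persistent window")
    return float(np.mean(traces.current[sweep, sl]))


def measure_resurgent(traces: TraceSet, sweep: int,
                      guard_ms: float = RESURGENT_GUARD_MS) -> float:
    """Peak (most inward) current during the repolarization step, excluding
    the first ``guard_ms`` after the edge, pA."""
    t0, t1 = traces.sweep_window
    sl = traces.window_slice((t0 + guard_ms, t1))
    if sl.start >= sl.stop:
        raise ValueError("empty resurgent window")
    return float(np.min(traces.current[sweep, sl]))


def normalize_to_max_transient(value: float, max_peak: float) -> float:
    """Express an (inward, negative) amplitude as a positive percentage of
    the cell's maximum peak transient amplitude."""
    if max_peak == 0:
        raise ValueError("maximum peak transient is zero")
    return 100.0 * value / max_peak


@dataclass
class ExtractionReport:
    """Per-cell derived features from the three HEK protocols."""

    genotype: str
    cell_id: str
    Cm: float
    peak_iv: IVCurve
    max_peak_pA: float
    max_peak_density: float
    v_rev: float
    gv_curve: IVCurve
    act_fit: BoltzmannFit
    availability: IVCurve
    inact_fit: BoltzmannFit
    taus: IVCurve
    persistent_iv: IVCurve
    persistent_pA: float
    persistent_density: float
    persistent_pct: float
    resurgent_iv: IVCurve | None = None
    resurgent_pA: float = np.nan
    resurgent_density: float = np.nan
    resurgent_pct: float = np.nan
    extras: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "genotype": self.genotype, "cell_id": self.cell_id, "Cm_pF": self.Cm,
            "max_peak_pA": self.max_peak_pA, "max_peak_density_pA_pF": self.max_peak_density,
            "v_rev_mV": self.v_rev,
            "act_v_half_mV": self.act_fit.V_half, "act_k_mV": self.act_fit.k,
            "inact_v_half_mV": self.inact_fit.V_half, "inact_k_mV": self.inact_fit.k,
            "persistent_pA": self.persistent_pA,
            "persistent_density_pA_pF": self.persistent_density,
            "persistent_pct": self.persistent_pct,
            "resurgent_pA": self.resurgent_pA,
            "resurgent_density_pA_pF": self.resurgent_density,
            "resurgent_pct": self.resurgent_pct,
        }


def extract_cell(act: TraceSet, inact: TraceSet | None = None,
                 res: TraceSet | None = None, Cm: float | None = None,
                 cell_id: str = "cell0", tau_range=(-30.0, 20.0),
                 at_mV: float = -30.0) -> ExtractionReport:
    """Run the full measurement pipeline for one cell.

    ``act`` is required (peak IV, reversal, conductance fit, persistent
    currents); ``inact`` adds the availability curve and its fit; ``res``
    adds resurgent measures.  ``at_mV`` is the voltage at which the single
    persistent / resurgent summary values are taken (-30 mV in the study).
    """
    Cm = float(act.meta.get("Cm_pF", 1.0)) if Cm is None else Cm
    iv = peak_iv(act)
    max_peak = float(np.min(iv.value))
    v_rev = estimate_reversal(iv)
    gv = conductance_curve(iv, v_rev)
    act_fit = fit_boltzmann(gv, increasing=True)

    order = np.argsort(act.levels)
    pers = np.array([measure_persistent(act, int(j)) for j in order])
    persistent_iv = IVCurve(act.levels[order], pers, kind="persistent_pA")
    p30 = persistent_iv.at(at_mV)

    taus_v, taus = [], []
    for j in order:
        V = act.levels[j]
        if tau_range[0] - 1e-9 <= V <= tau_range[1] + 1e-9:
            try:
                taus.append(fit_decay_tau(act, int(j)))
                taus_v.append(V)
            except (ValueError, RuntimeError):
                continue
    tau_curve = IVCurve(np.array(taus_v), np.array(taus), kind="tau_ms")

    if inact is not None:
        avail = availability_curve(inact)
        inact_fit = fit_boltzmann(avail, increasing=False)
    else:
        avail = IVCurve(np.array([]), np.array([]), kind="fraction_available")
        inact_fit = BoltzmannFit(np.nan, np.nan, np.nan, np.nan)

    report = ExtractionReport(
        genotype=str(act.meta.get("genotype", "?")), cell_id=cell_id, Cm=Cm,
        peak_iv=iv, max_peak_pA=max_peak,
        max_peak_density=current_density(max_peak, Cm), v_rev=v_rev,
        gv_curve=gv, act_fit=act_fit, availability=avail, inact_fit=inact_fit,
        taus=tau_curve, persistent_iv=persistent_iv, persistent_pA=p30,
        persistent_density=current_density(p30, Cm),
        persistent_pct=normalize_to_max_transient(p30, max_peak),
    )
    if res is not None:
        order_r = np.argsort(res.levels)
        surge = np.array([measure_resurgent(res, int(j)) for j in order_r])
        report.resurgent_iv = IVCurve(res.levels[order_r], surge, kind="resurgent_pA")
        r30 = report.resurgent_iv.at(at_mV)
        report.resurgent_pA = r30
        report.resurgent_density = current_density(r30, Cm)
        report.resurgent_pct = normalize_to_max_transient(r30, max_peak)
    return report
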