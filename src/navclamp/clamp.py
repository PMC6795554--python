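"""Voltage-clamp protocol emulation.

Declarative step/sweep protocols are run against a HEK cell model (whole-cell
patch) or an oocyte model (cut-open clamp), producing sweep trace sets with
linear leak, capacitive transients, recording noise and the study's
leak-subtraction modes (P/-5 for HEK, P/N for oocyte gating currents).

The clamp is idealized: the command potential is reached instantly and held
exactly (series resistance enters only through the residual capacitive
transient time constant).  Within each constant-voltage segment the gating
state is integrated with an adaptive stiff-capable solver (LSODA) and sampled
onto the protocol's regular time base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.integrate import solve_ivp
from scipy.signal import butter, lfilter

from .channel import (
    ChannelParams,
    gating_pore_current,
    holding_state,
    open_fraction,
)

__all__ = [
    "CellModel",
    "OocyteModel",
    "Segment",
    "VoltageProtocol",
    "TraceSet",
    "build_protocol",
    "run_protocol",
    "run_oocyte_protocol",
    "PROTOCOL_NAMES",
]


class CellModel(BaseModel):
    """HEK-cell recording context (whole-cell patch clamp).

    Cm pF; Rs MOhm; comp_frac series-resistance compensation in [0,1];
    g_leak nS; E_leak mV; expr dimensionless expression scale; noise_sd pA;
    endogenous_peak pA (small native voltage-gated current of untransfected
    HEK cells, inward negative).
    """

    model_config = ConfigDict(frozen=True)

    Cm: float = 16.0
    Rs: float = 1.5
    comp_frac: float = 0.9
    g_leak: float = 1.0
    E_leak: float = 0.0
    expr: float = 1.0
    noise_sd: float = 0.0
    noise_cutoff_kHz: float = 2.9
    endogenous_peak: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "CellModel":
        if self.Cm <= 0:
            raise ValueError("Cm must be > 0")
        if self.g_leak < 0 or self.noise_sd < 0:
            raise ValueError("g_leak and noise_sd must be >= 0")
        if not (0.0 <= self.comp_frac <= 1.0):
            raise ValueError("comp_frac must lie in [0, 1]")
        if self.expr < 0:
            raise ValueError("expr must be >= 0")
        return self


class OocyteModel(BaseModel):
    """Cut-open oocyte recording context.

    Qmax_cell nC of mobile gating charge (proportional to surface channel
    count); linear leak g_leak_lin in uS with reversal E_leak mV; noise_sd in
    nA; ttx True blocks the central pore (the standard recording condition).
    """

    model_config = ConfigDict(frozen=True)

    Qmax_cell: float = 0.85
    g_leak_lin: float = 0.5
    E_leak: float = -20.0
    noise_sd: float = 0.0
    noise_cutoff_kHz: float = 2.0
    ttx: bool = True
    guanidinium: bool = False

    @model_validator(mode="after")
    def _check(self) -> "OocyteModel":
        if self.Qmax_cell < 0:
            raise ValueError("Qmax_cell must be >= 0")
        if self.g_leak_lin < 0 or self.noise_sd < 0:
            raise ValueError("g_leak_lin and noise_sd must be >= 0")
        return self


class Segment(BaseModel):
    model_config = ConfigDict(frozen=True)

    kind: Literal["fixed", "sweep"]
    duration: float
    level: Optional[float] = None
    start: Optional[float] = None
    stop: Optional[float] = None
    step: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "Segment":
        if self.duration <= 0:
            raise ValueError("segment duration must be > 0")
        if self.kind == "fixed" and self.level is None:
            raise ValueError("fixed segment requires a level")
        if self.kind == "sweep":
            if None in (self.start, self.stop, self.step):
                raise ValueError("sweep segment requires start/stop/step")
            if self.step == 0:
                raise ValueError("sweep step must be nonzero")
        return self

    def levels(self) -> np.ndarray:
        if self.kind == "fixed":
            return np.array([self.level], dtype=float)
        n = int(round((self.stop - self.start) / self.step)) + 1
        if n < 1:
            raise ValueError("sweep start/stop/step define no sweeps")
        return self.start + self.step * np.arange(n)


class SubtractionMode(str, Enum):
    NONE = "none"
    P_MINUS_5 = "p_minus_5"
    P_OVER_N = "p_over_n"


class VoltageProtocol(BaseModel):
    """Declarative voltage program: a recorded pre-step holding segment
    (baseline) followed by the programmed segments; exactly one segment may be
    the sweep segment whose level varies across sweeps."""

    model_config = ConfigDict(frozen=True)

    name: str
    holding: float
    segments: tuple[Segment, ...]
    sample_interval: float
    subtraction: SubtractionMode = SubtractionMode.NONE
    baseline: float = 2.0
    pn_from: float = -120.0
    pn_to: float = -100.0

    @model_validator(mode="after")
    def _check(self) -> "VoltageProtocol":
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")
        n_sweep = sum(1 for s in self.segments if s.kind == "sweep")
        if n_sweep != 1:
            raise ValueError("protocol must contain exactly one sweep segment")
        return self

    @property
    def sweep_seg(self) -> int:
        """Index (within segments) of the sweep-varying segment."""
        return next(i for i, s in enumerate(self.segments) if s.kind == "sweep")

    def sweep_levels(self) -> np.ndarray:
        return self.segments[self.sweep_seg].levels()

    def n_sweeps(self) -> int:
        return len(self.sweep_levels())

    def total_duration(self) -> float:
        return self.baseline + sum(s.duration for s in self.segments)

    def time_base(self) -> np.ndarray:
        n = int(round(self.total_duration() / self.sample_interval)) + 1
        return np.arange(n) * self.sample_interval

    def segment_windows(self) -> list[tuple[float, float]]:
        """(t0, t1) per recorded segment, baseline first."""
        out = [(0.0, self.baseline)]
        t = self.baseline
        for s in self.segments:
            out.append((t, t + s.duration))
            t += s.duration
        return out

    def sweep_waveform(self, sweep_level: float) -> list[tuple[float, float, float]]:
        """(V, t0, t1) per segment for one sweep, including the baseline."""
        out = [(self.holding, 0.0, self.baseline)]
        t = self.baseline
        for s in self.segments:
            V = sweep_level if s.kind == "sweep" else s.level
            out.append((float(V), t, t + s.duration))
            t += s.duration
        return out


PROTOCOL_NAMES = ("activation_iv", "inactivation", "resurgent", "gp_leak", "gating_charge")


def build_protocol(name: str) -> VoltageProtocol:
    """Construct one of the study's five named protocols.

    activation_iv: hold -100 mV, 50-ms steps -80..+60 mV in 5-mV increments
    (29 sweeps), P/-5 subtraction.
    inactivation: 500-ms prepulses -130..+10 mV in 10-mV increments followed
    by a 20-ms test pulse to +10 mV, P/-5.
    resurgent: 20 ms at +30 mV, then 50-ms repolarizations +10..-65 mV in
    5-mV increments (16 sweeps), P/-5.
    gp_leak: oocyte, 200-ms steps -140..+40 mV in 10-mV increments, no
    on-line subtraction.
    gating_charge: oocyte, 20-ms steps -140..+40 mV in 10-mV increments,
    P/N subtraction from a -120 to -100 mV subpulse.
    """
    if name == "activation_iv":
        return VoltageProtocol(
            name=name, holding=-100.0, sample_interval=0.02,
            subtraction=SubtractionMode.P_MINUS_5,
            segments=(Segment(kind="sweep", start=-80.0, stop=60.0, step=5.0, duration=50.0),),
        )
    if name == "inactivation":
        return VoltageProtocol(
            name=name, holding=-100.0, sample_interval=0.02,
            subtraction=SubtractionMode.P_MINUS_5,
            segments=(
                Segment(kind="sweep", start=-130.0, stop=10.0, step=10.0, duration=500.0),
                Segment(kind="fixed", level=10.0, duration=20.0),
            ),
        )
    if name == "resurgent":
        return VoltageProtocol(
            name=name, holding=-100.0, sample_interval=0.02,
            subtraction=SubtractionMode.P_MINUS_5,
            segments=(
                Segment(kind="fixed", level=30.0, duration=20.0),
                Segment(kind="sweep", start=10.0, stop=-65.0, step=-5.0, duration=50.0),
            ),
        )
    if name == "gp_leak":
        return VoltageProtocol(
            name=name, holding=-100.0, sample_interval=0.1,
            subtraction=SubtractionMode.NONE, baseline=5.0,
            segments=(Segment(kind="sweep", start=-140.0, stop=40.0, step=10.0, duration=200.0),),
        )
    if name == "gating_charge":
        return VoltageProtocol(
            name=name, holding=-100.0, sample_interval=0.1,
            subtraction=SubtractionMode.P_OVER_N, baseline=5.0,
            segments=(Segment(kind="sweep", start=-140.0, stop=40.0, step=10.0, duration=20.0),),
        )
    raise ValueError(f"unknown protocol {name!r}; expected one of {PROTOCOL_NAMES}")


@dataclass
class TraceSet:
    """Sweep traces sharing one time base.

    current is (n_sweeps, T) in pA (HEK context) or nA (oocyte context);
    voltage is the command waveform; levels holds the per-sweep value of the
    sweep-varying segment; windows are the recorded (t0, t1) per segment with
    the baseline at index 0, so protocol segment i occupies windows[i+1].
    """

    protocol: VoltageProtocol
    time: np.ndarray
    voltage: np.ndarray
    current: np.ndarray
    levels: np.ndarray
    windows: list[tuple[float, float]]
    meta: dict = field(default_factory=dict)

    @property
    def sweep_window(self) -> tuple[float, float]:
        return self.windows[self.protocol.sweep_seg + 1]

    def window_slice(self, window: tuple[float, float]) -> slice:
        t0, t1 = window
        i0 = int(np.searchsorted(self.time, t0 - 1e-9))
        i1 = int(np.searchsorted(self.time, t1 - 1e-9))
        return slice(i0, i1)

    def sweep_index(self, level: float) -> int:
        i = int(np.argmin(np.abs(self.levels - level)))
        if abs(self.levels[i] - level) > 1e-6:
            raise ValueError(f"no sweep at level {level} mV")
        return i


# --------------------------------------------------------------------------
# state integration


_RTOL = 1e-8
_ATOL = 1e-10


def _make_rhs(p: ChannelParams, V: float):
    """Fast closure over the constant-segment kinetics in the internal
    (m, A, b, q) variables with A = h (1-b), the total available unblocked
    fraction; agrees with :func:`navclamp.channel.derivatives` after the
    change of variables (checked by the test suite)."""
    minf, taum = p.m_inf(V), p.tau_m(V)
    hinf, tauh = p.h_inf(V), p.tau_h(V)
    qinf, tauq = p.q_inf(V), p.tau_q
    koff, kon, fp = p.kb_off(V), p.kb_on, p.f_p

    def rhs(_t, y):
        m, A, b, q = y
        m3 = m * m * m
        dm = (minf - m) / taum
        dA = ((1.0 - b) * hinf - A) / tauh - kon * m3 * (1.0 - fp) * A + koff * b
        db = kon * m3 * ((1.0 - fp) * A + fp * (1.0 - b)) - koff * b
        dq = (qinf - q) / tauq
        return (dm, dA, db, dq)

    return rhs


def _integrate_states(p: ChannelParams, waveform, t: np.ndarray, y0: np.ndarray) -> np.ndarray:
    """Integrate (m, h, b, q) along a piecewise-constant waveform.

    ``y0`` and the returned samples are in the public (m, h, b, q) variables;
    integration runs in (m, A, b, q) with A = h (1-b) for regularity.
    Sample points falling exactly on a segment boundary belong to the *new*
    segment (voltage has already stepped).
    """
    out = np.empty((4, t.size))
    y = np.asarray(y0, dtype=float).copy()
    y[1] = y[1] * (1.0 - y[2])  # h -> A
    for V, t0, t1 in waveform:
        idx0 = int(np.searchsorted(t, t0 - 1e-9))
        is_last = t1 >= t[-1] - 1e-9
        idx1 = t.size if is_last else int(np.searchsorted(t, t1 - 1e-9))
        t_eval = t[idx0:idx1]
        need_end = t_eval.size == 0 or t_eval[-1] < t1 - 1e-12
        t_solve = np.append(t_eval, t1) if need_end else t_eval
        sol = solve_ivp(
            _make_rhs(p, V), (t0, t1), y,
            method="LSODA", t_eval=t_solve, rtol=_RTOL, atol=_ATOL,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed in segment at {V} mV: {sol.message}")
        ys = sol.y
        y = ys[:, -1].copy()
        if need_end:
            ys = ys[:, :-1]
        out[:, idx0:idx1] = ys
    out[1] = out[1] / np.maximum(1.0 - out[2], 1e-12)  # A -> h
    return np.clip(out, 0.0, 1.0)


def _recording_noise(rng: np.random.Generator, sd: float, n: int,
                     dt_ms: float, cutoff_kHz: float) -> np.ndarray:
    """Band-limited Gaussian recording noise with the given RMS.

    White noise is passed through a 2nd-order Butterworth low-pass at the
    acquisition-filter cutoff and rescaled to RMS ``sd``, emulating the
    amplifier filter chain; ``sd`` therefore characterizes the noise visible
    in the recorded trace.  Falls back to white noise when the cutoff is at
    or above the Nyquist frequency.
    """
    white = rng.standard_normal(n)
    wn = 2.0 * dt_ms * cutoff_kHz  # cutoff / Nyquist
    if wn >= 1.0:
        return sd * white
    b, a = butter(2, wn)
    x = lfilter(b, a, white)
    h = lfilter(b, a, np.concatenate([[1.0], np.zeros(4095)]))
    gain = float(np.sqrt(np.sum(h * h)))
    return sd * x / gain


def _command_voltage(waveform, t: np.ndarray) -> np.ndarray:
    v = np.empty_like(t)
    for V, t0, t1 in waveform:
        idx0 = int(np.searchsorted(t, t0 - 1e-9))
        idx1 = t.size if t1 >= t[-1] - 1e-9 else int(np.searchsorted(t, t1 - 1e-9))
        v[idx0:idx1] = V
    return v


def _ionic_trace(p: ChannelParams, states: np.ndarray, v: np.ndarray, g_scale: float) -> np.ndarray:
    """Central-pore current (pA) along a trajectory, conductance g_scale nS."""
    m, h, b, _ = states
    return g_scale * open_fraction(m, h, b, p) * (v - p.E_rev)


def _capacitive_trace(cell: CellModel, waveform, t: np.ndarray) -> np.ndarray:
    """Residual capacitive transients (pA) after Rs compensation.

    Each step edge injects (dV/Rs_u) * exp(-(t-t_edge)/tau_c) with
    Rs_u = Rs (1 - comp_frac) and tau_c = Rs_u * Cm; fully compensated or
    zero-Rs cells have no transient.
    """
    rs_u = cell.Rs * (1.0 - cell.comp_frac)
    if rs_u <= 0:
        return np.zeros_like(t)
    tau_c = rs_u * cell.Cm * 1e-3  # MOhm * pF = us -> ms
    out = np.zeros_like(t)
    for (Va, _, t_edge), (Vb, _, _) in zip(waveform[:-1], waveform[1:]):
        dV = Vb - Va
        if dV == 0.0:
            continue
        mask = t >= t_edge - 1e-9
        out[mask] += 1000.0 * (dV / rs_u) * np.exp(-(t[mask] - t_edge) / tau_c)
    return out


def _endogenous_gain(cell: CellModel) -> float:
    # Extra conductance gated like the transfected channel, scaled so its
    # peak transient is approximately the configured endogenous amplitude.
    return abs(cell.endogenous_peak) / 35.0


def _hek_sweep_deterministic(cell: CellModel, p: ChannelParams, waveform, t: np.ndarray,
                             y0: np.ndarray) -> np.ndarray:
    states = _integrate_states(p, waveform, t, y0)
    v = _command_voltage(waveform, t)
    g_total = cell.expr * p.g_max + _endogenous_gain(cell)
    i = _ionic_trace(p, states, v, g_total)
    i += cell.g_leak * (v - cell.E_leak)
    i += _capacitive_trace(cell, waveform, t)
    return i


def _scaled_waveform(waveform, holding: float, factor: float):
    return [(holding + (V - holding) * factor, t0, t1) for V, t0, t1 in waveform]


def run_protocol(cell: CellModel, p: ChannelParams, prot: VoltageProtocol,
                 seed: int | None = 0) -> TraceSet:
    """Run a HEK protocol: ionic + leak + capacitive + Gaussian noise, with
    the requested subtraction applied.  Deterministic given the seed.

    P/-5 subtraction is emulated on the deterministic response: the linear
    response to five sub-sweeps of amplitude -dV/5 from holding (computed
    once -- they share one command waveform) is added to the test response
    and the six-fold holding baseline removed.  Band-limited recording noise
    at the configured RMS is then added to the assembled sweep, so
    ``noise_sd`` describes the trace as recorded.
    """
    rng = np.random.default_rng(seed)
    t = prot.time_base()
    levels = prot.sweep_levels()
    y0 = holding_state(p, prot.holding).as_array()
    i_hold = float(
        _ionic_trace(p, y0[:, None], np.array([prot.holding]),
                     cell.expr * p.g_max + _endogenous_gain(cell))[0]
        + cell.g_leak * (prot.holding - cell.E_leak)
    )
    cur = np.empty((levels.size, t.size))
    vcmd = np.empty_like(cur)
    for j, lev in enumerate(levels):
        wf = prot.sweep_waveform(lev)
        vcmd[j] = _command_voltage(wf, t)
        i_main = _hek_sweep_deterministic(cell, p, wf, t, y0)
        if prot.subtraction is SubtractionMode.P_MINUS_5:
            wf_sub = _scaled_waveform(wf, prot.holding, -0.2)
            i_sub = _hek_sweep_deterministic(cell, p, wf_sub, t, y0)
            i = i_main + 5.0 * i_sub - 6.0 * i_hold
        else:
            i = i_main
        if cell.noise_sd > 0:
            i = i + _recording_noise(rng, cell.noise_sd, t.size,
                                     prot.sample_interval, cell.noise_cutoff_kHz)
        cur[j] = i
    return TraceSet(
        protocol=prot, time=t, voltage=vcmd, current=cur, levels=levels,
        windows=prot.segment_windows(),
        meta={"context": "hek", "genotype": p.genotype.value, "seed": seed,
              "subtraction": prot.subtraction.value, "units_i": "pA",
              "Cm_pF": cell.Cm, "expr": cell.expr},
    )


# --------------------------------------------------------------------------
# oocyte context


def _oocyte_sweep_deterministic(oo: OocyteModel, p: ChannelParams, waveform,
                                t: np.ndarray, y0: np.ndarray) -> np.ndarray:
    states = _integrate_states(p, waveform, t, y0)
    v = _command_voltage(waveform, t)
    q = states[3]
    i = np.zeros_like(t)
    # on-gating current: Qmax * dq/dt; nC/ms = uA -> x1000 nA
    qinf = p.q_inf(v)
    i += 1000.0 * oo.Qmax_cell * (qinf - q) / p.tau_q
    i += gating_pore_current(v, p, oo.Qmax_cell, guanidinium=oo.guanidinium)
    if not oo.ttx:
        # central-pore conductance proportional to expressed charge (uS per nC)
        g_na = 12.0 * oo.Qmax_cell
        i += _ionic_trace(p, states, v, g_na)
    i += oo.g_leak_lin * (v - oo.E_leak)
    return i


def run_oocyte_protocol(oo: OocyteModel, p: ChannelParams, prot: VoltageProtocol,
                        seed: int | None = 0) -> TraceSet:
    """Run an oocyte protocol (currents in nA).

    The membrane capacitance is treated as analog-compensated (no capacitive
    term).  With subtraction P/N the linear background is estimated from a
    simulated subpulse (pn_from -> pn_to) exactly as an on-line P/N routine
    would, and the fitted line in V is removed from every sweep.
    """
    rng = np.random.default_rng(seed)
    t = prot.time_base()
    levels = prot.sweep_levels()
    y0 = holding_state(p, prot.holding).as_array()
    meta = {"context": "oocyte", "genotype": p.genotype.value, "seed": seed,
            "subtraction": prot.subtraction.value, "units_i": "nA",
            "Qmax_cell_nC": oo.Qmax_cell}

    pn_line = None
    if prot.subtraction is SubtractionMode.P_OVER_N:
        settle, hold_dur = 10.0, 10.0
        wf_sub = [(prot.pn_from, 0.0, settle), (prot.pn_to, settle, settle + hold_dur)]
        t_sub = np.arange(int(round((settle + hold_dur) / prot.sample_interval)) + 1) * prot.sample_interval
        y0_sub = holding_state(p, prot.pn_from).as_array()
        i_sub = _oocyte_sweep_deterministic(oo, p, wf_sub, t_sub, y0_sub)
        if oo.noise_sd > 0:
            i_sub = i_sub + _recording_noise(rng, oo.noise_sd, t_sub.size,
                                             prot.sample_interval,
                                             oo.noise_cutoff_kHz)
        # steady means of the second half of each phase
        ph1 = (t_sub >= settle * 0.5) & (t_sub < settle)
        ph2 = t_sub >= settle + hold_dur * 0.5
        i_lo, i_hi = float(np.mean(i_sub[ph1])), float(np.mean(i_sub[ph2]))
        g_hat = (i_hi - i_lo) / (prot.pn_to - prot.pn_from)
        pn_line = (g_hat, i_hi)  # I_lin(V) ~= i_hi + g_hat (V - pn_to)
        meta["pn_g_hat_uS"] = g_hat

    cur = np.empty((levels.size, t.size))
    vcmd = np.empty_like(cur)
    for j, lev in enumerate(levels):
        wf = prot.sweep_waveform(lev)
        v = _command_voltage(wf, t)
        vcmd[j] = v
        i = _oocyte_sweep_deterministic(oo, p, wf, t, y0)
        if oo.noise_sd > 0:
            i = i + _recording_noise(rng, oo.noise_sd, t.size,
                                     prot.sample_interval, oo.noise_cutoff_kHz)
        if pn_line is not None:
            g_hat, i_ref = pn_line
            i = i - (i_ref + g_hat * (v - prot.pn_to))
        cur[j] = i
    return TraceSet(protocol=prot, time=t, voltage=vcmd, current=cur,
                    levels=levels, windows=prot.segment_windows(), meta=meta)
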