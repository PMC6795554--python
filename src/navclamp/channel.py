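"""Mechanistic hNav1.2 channel model for the WT channel and the epilepsy
variants R1882Q and R853Q.

The central pore is described by a Hodgkin-Huxley m^3 h scheme with two
additions that realize the phenomenology measured in whole-cell recordings:

* a non-inactivating fraction ``f_p`` of the conductance, which produces the
  small persistent current that remains late in a depolarizing step, and
* an open-channel block variable ``b`` representing the Navbeta4 C-terminal
  peptide.  The peptide binds open channels (on-rate proportional to open
  probability) and, while bound, holds the inactivation gate out of the pore
  (foot-in-the-door).  On repolarization the blocker unbinds faster than the
  inactivation gate rebinds, which yields the characteristic resurgent hump.

Two further components live on the voltage-sensor side: the gating-charge
movement ``q`` (a first-order relaxation towards a Boltzmann Q-V, used to
emulate on-gating currents in oocytes) and, for the R853Q voltage-sensor
mutation only, a gating-pore (omega) conductance that is open in the resting
("down") conformation of the DII voltage sensor and therefore passes inward
current at hyperpolarized potentials.

Units: mV, ms; central-pore currents in pA (conductance nS); oocyte-context
gating and gating-pore currents in nA with charge in nC.  Inward current is
negative throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from importlib import resources

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.special import expit

__all__ = [
    "Genotype",
    "ChannelParams",
    "GatingState",
    "steady_state",
    "bell_tau",
    "ionic_current",
    "gating_pore_current",
    "gating_charge_QV",
    "derivatives",
    "holding_state",
    "load_genotype",
    "calibrate_gating_pore",
]


class Genotype(str, Enum):
    WT = "WT"
    R1882Q = "R1882Q"
    R853Q = "R853Q"


def steady_state(V, V_half: float, k: float, increasing: bool = True):
    """Boltzmann steady-state curve 1/(1+exp(-/+ (V - V_half)/k)).

    ``increasing=True`` gives a curve rising with voltage (activation,
    gating charge); ``False`` gives a falling curve (availability, the
    resting-state occupancy of a voltage sensor).  Always 0.5 at ``V_half``.
    """
    if k <= 0:
        raise ValueError(f"slope factor k must be > 0, got {k}")
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("voltage must be finite")
    x = (V - V_half) / k
    out = expit(x) if increasing else expit(-x)
    return float(out) if out.ndim == 0 else out


def bell_tau(V, tau0: float, amp: float, Vpeak: float, sigma: float):
    """Constant-plus-Gaussian bell time constant in voltage (ms)."""
    V = np.asarray(V, dtype=float)
    out = tau0 + amp * np.exp(-(((V - Vpeak) / sigma) ** 2))
    return float(out) if out.ndim == 0 else out


class ChannelParams(BaseModel):
    """Full biophysical description of one genotype.

    Central pore: g_max (nS), E_rev (mV), activation (V_half_m/k_m, bell tau_m),
    fast inactivation (V_half_h/k_h, bell tau_h), persistent fraction f_p.
    Peptide block: kb_on (1/ms, at unit open probability), kb_off0 (1/ms at
    0 mV), delta_b (mV; unblock accelerates with hyperpolarization).
    Gating charge: V_half_q/k_q (mV), tau_q (ms).
    Gating pore: s_gp (nA per nC per mV), V_half_gp/k_gp of the conducting
    "down" state, E_gp (mV), perm_guanidinium (factor >= 1 applied only when
    the bath contains guanidinium).
    """

    model_config = ConfigDict(frozen=True)

    genotype: Genotype
    g_max: float
    E_rev: float
    V_half_m: float
    k_m: float
    tau_m0: float
    tau_m_amp: float
    tau_m_Vpeak: float
    tau_m_sigma: float
    V_half_h: float
    k_h: float
    tau_h0: float
    tau_h_amp: float
    tau_h_Vpeak: float
    tau_h_sigma: float
    f_p: float
    kb_on: float
    kb_off0: float
    delta_b: float
    V_half_q: float
    k_q: float
    tau_q: float
    s_gp: float
    V_half_gp: float
    k_gp: float
    E_gp: float
    perm_guanidinium: float = 1.0
    schema_version: int = 1

    @model_validator(mode="after")
    def _invariants(self) -> "ChannelParams":
        for name in ("k_m", "k_h", "k_q", "k_gp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("tau_m0", "tau_h0", "tau_q"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("tau_m_amp", "tau_h_amp", "tau_m_sigma", "tau_h_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.f_p <= 1.0):
            raise ValueError("f_p must lie in [0, 1]")
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")
        if self.kb_on < 0 or self.kb_off0 < 0:
            raise ValueError("block rates must be >= 0")
        if self.s_gp < 0:
            raise ValueError("s_gp must be >= 0")
        if self.perm_guanidinium < 1.0:
            raise ValueError("perm_guanidinium must be >= 1")
        if self.genotype is Genotype.WT and self.s_gp != 0.0:
            raise ValueError("WT carries no gating pore current (s_gp must be 0)")
        return self

    # -- steady states and time constants ------------------------------------
    def m_inf(self, V):
        return steady_state(V, self.V_half_m, self.k_m, increasing=True)

    def h_inf(self, V):
        return steady_state(V, self.V_half_h, self.k_h, increasing=False)

    def q_inf(self, V):
        return steady_state(V, self.V_half_q, self.k_q, increasing=True)

    def p_down(self, V):
        """Resting-state occupancy of the DII voltage sensor (gating pore open)."""
        return steady_state(V, self.V_half_gp, self.k_gp, increasing=False)

    def tau_m(self, V):
        return bell_tau(V, self.tau_m0, self.tau_m_amp, self.tau_m_Vpeak, self.tau_m_sigma)

    def tau_h(self, V):
        return bell_tau(V, self.tau_h0, self.tau_h_amp, self.tau_h_Vpeak, self.tau_h_sigma)

    def kb_off(self, V):
        """Voltage-dependent unblock rate (1/ms); faster when hyperpolarized."""
        V = np.asarray(V, dtype=float)
        out = self.kb_off0 * np.exp(-V / self.delta_b)
        return float(out) if out.ndim == 0 else out


@dataclass
class GatingState:
    """Aggregate gating variables, each confined to [0, 1].

    m: activation; h: availability of the fast-inactivating fraction;
    b: peptide-blocked fraction; q: normalized gating charge moved.
    """

    m: float
    h: float
    b: float
    q: float

    def __post_init__(self) -> None:
        for name in ("m", "h", "b", "q"):
            v = getattr(self, name)
            if not (-1e-9 <= v <= 1.0 + 1e-9):
                raise ValueError(f"state variable {name}={v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.m, self.h, self.b, self.q], dtype=float)


def open_fraction(m, h, b, p: ChannelParams):
    """Conducting fraction of the central pore: m^3 [h (1-f_p) + f_p] (1-b)."""
    return m ** 3 * (h * (1.0 - p.f_p) + p.f_p) * (1.0 - b)


def ionic_current(state: GatingState, V, p: ChannelParams, expr: float = 1.0):
    """Central-pore sodium current in pA (inward negative).

    ``expr`` is the dimensionless per-cell expression scale multiplying the
    reference maximal conductance.
    """
    if expr < 0:
        raise ValueError("expression scale must be >= 0")
    V = np.asarray(V, dtype=float)
    out = expr * p.g_max * open_fraction(state.m, state.h, state.b, p) * (V - p.E_rev)
    return float(out) if out.ndim == 0 else out


def gating_pore_current(V, p: ChannelParams, Qmax_cell: float, guanidinium: bool = False):
    """Gating-pore (omega) current in nA for a cell expressing Qmax_cell nC.

    Conducts in the resting ("down") conformation of the mutated voltage
    sensor, hence at hyperpolarized potentials; identically zero when
    ``s_gp == 0`` (the WT channel).  The guanidinium flag applies the
    permeability factor for a guanidinium-containing bath.
    """
    if Qmax_cell < 0:
        raise ValueError("Qmax_cell must be >= 0")
    V = np.asarray(V, dtype=float)
    if p.s_gp == 0.0:
        out = np.zeros_like(V)
        return float(out) if out.ndim == 0 else out
    perm = p.perm_guanidinium if guanidinium else 1.0
    out = perm * p.s_gp * Qmax_cell * p.p_down(V) * (V - p.E_gp)
    return float(out) if out.ndim == 0 else out


def gating_charge_QV(V, p: ChannelParams, Qmax_cell: float):
    """Equilibrium gating charge moved at V, in nC; monotone non-decreasing."""
    if Qmax_cell < 0:
        raise ValueError("Qmax_cell must be >= 0")
    return Qmax_cell * steady_state(V, p.V_half_q, p.k_q, increasing=True)


def derivatives(state: GatingState, V: float, p: ChannelParams) -> np.ndarray:
    """Time derivatives (1/ms) of (m, h, b, q) at constant voltage V.

    ``h`` is the availability of the *unblocked* pool.  The peptide blocks
    open channels (on-rate weighted by open probability) and, while bound,
    holds the inactivation gate out of its receptor, so blocked channels
    neither inactivate nor recover; on unblock they rejoin the unblocked
    pool fully available.  This is what lets the current rebound during
    repolarization (resurgent current): unblock outpaces inactivation.

    In terms of the total available unblocked fraction A = h (1-b):

        dA/dt = ((1-b) h_inf - A)/tau_h - kb_on m^3 (1-f_p) A + kb_off(V) b
        db/dt = kb_on m^3 [h (1-f_p) + f_p] (1-b) - kb_off(V) b

    and dh/dt follows by the chain rule.  The persistent-mode fraction f_p
    participates in block but not in inactivation bookkeeping (an O(f_p)
    approximation, f_p < 2% here).
    """
    m, h, b, q = state.m, state.h, state.b, state.q
    dm = (p.m_inf(V) - m) / p.tau_m(V)
    dq = (p.q_inf(V) - q) / p.tau_q
    w_open = m ** 3 * (h * (1.0 - p.f_p) + p.f_p)
    beta = p.kb_off(V)
    db = p.kb_on * w_open * (1.0 - b) - beta * b
    if b >= 1.0 - 1e-12:
        dh = 0.0
    else:
        dh = ((p.h_inf(V) - h) / p.tau_h(V)
              + beta * (b / (1.0 - b)) * (1.0 - h)
              - p.kb_on * m ** 3 * (1.0 - p.f_p) * h * (1.0 - h)
              + p.kb_on * m ** 3 * p.f_p * h)
    return np.array([dm, dh, db, dq], dtype=float)


def holding_state(p: ChannelParams, V: float) -> GatingState:
    """Steady gating state at a holding potential (b at its fixed point)."""
    m = p.m_inf(V)
    h = p.h_inf(V)
    q = p.q_inf(V)
    alpha = p.kb_on * m ** 3 * (h * (1.0 - p.f_p) + p.f_p)
    beta = p.kb_off(V)
    b = alpha / (alpha + beta) if (alpha + beta) > 0 else 0.0
    return GatingState(m=m, h=h, b=b, q=q)


def calibrate_gating_pore(p: ChannelParams, target_slope: float) -> ChannelParams:
    """Set s_gp so that the gating pore passes exactly ``target_slope`` nA per
    nC of expressed gating charge at -120 mV (closed-form solve).

    ``target_slope`` must be <= 0: the gating pore current at -120 mV is
    inward.  A target of 0 removes the gating pore.
    """
    if p.genotype is not Genotype.R853Q:
        raise ValueError("gating pore calibration applies to R853Q only")
    if target_slope > 0:
        raise ValueError("gating pore current at -120 mV is inward; target must be <= 0")
    if target_slope == 0.0:
        return p.model_copy(update={"s_gp": 0.0})
    drive = p.p_down(-120.0) * (-120.0 - p.E_gp)
    s_gp = target_slope / drive
    return p.model_copy(update={"s_gp": float(s_gp)})


def _params_text(genotype: Genotype) -> str:
    fname = f"{genotype.value.lower()}.json"
    return resources.files("navclamp.params").joinpath(fname).read_text()


def load_genotype(genotype: Genotype | str) -> ChannelParams:
    """Load the shipped calibrated parameter set for a genotype."""
    genotype = Genotype(genotype)
    return ChannelParams.model_validate(json.loads(_params_text(genotype)))
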