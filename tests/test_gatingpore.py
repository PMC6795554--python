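"""Oocyte-analysis tests: charge integration against closed forms, Q-V and
its normalization, leak-line isolation with an injection oracle, and the
through-origin correlation."""

import numpy as np
import pytest

from navclamp.channel import gating_pore_current, load_genotype
from navclamp.clamp import (OocyteModel, Segment, SubtractionMode, TraceSet,
                            VoltageProtocol, build_protocol,
                            run_oocyte_protocol)
from navclamp.features import IVCurve
from navclamp.gatingpore import (correlate_gp_qmax, extract_oocyte,
                                 integrate_gating_charge, isolate_gating_pore,
                                 normalize_qv, qv_curve, steady_state_iv)


def _charge_toy(currents, dt=0.1, duration=20.0, level=40.0):
    n, T = currents.shape
    prot = VoltageProtocol(
        name="toy_q", holding=-100.0, sample_interval=dt, baseline=2.0,
        segments=(Segment(kind="sweep", start=level, stop=level, step=10.0,
                          duration=duration),))
    t = np.arange(T) * dt
    return TraceSet(protocol=prot, time=t, voltage=np.full((n, T), level),
                    current=currents, levels=np.array([level]),
                    windows=[(0.0, 2.0), (2.0, 2.0 + duration)], meta={})


def test_integrate_rectangle():
    # 0.5 uA (= 500 nA) flowing for 2 ms carries 1.0 nC
    dt = 0.01
    T = int(round(22.0 / dt)) + 1
    t = np.arange(T) * dt
    i = np.where((t >= 2.0) & (t < 4.0), 500.0, 0.0)[None, :]
    tr = _charge_toy(i, dt=dt)
    assert integrate_gating_charge(tr, 0) == pytest.approx(1.0, rel=5e-3)


def test_integrate_exponential_closed_form():
    dt = 0.05
    T = int(round(22.0 / dt)) + 1
    t = np.arange(T) * dt
    tau, i0, T_pulse = 2.0, 300.0, 20.0
    i = np.where(t >= 2.0, i0 * np.exp(-(t - 2.0) / tau), 0.0)[None, :]
    tr = _charge_toy(i, dt=dt)
    expected = i0 * tau * (1.0 - np.exp(-T_pulse / tau)) / 1000.0
    assert integrate_gating_charge(tr, 0) == pytest.approx(expected, rel=1e-3)


def test_integrate_window_outside_sweep():
    tr = _charge_toy(np.zeros((1, 221)))
    with pytest.raises(ValueError):
        integrate_gating_charge(tr, 0, window=(10.0, 100.0))


def test_qv_curve_zero_charge_oocyte():
    p = load_genotype("WT")
    oo = OocyteModel(Qmax_cell=0.0, g_leak_lin=0.5, noise_sd=0.0)
    tr = run_oocyte_protocol(oo, p, build_protocol("gating_charge"), seed=None)
    curve, qmax = qv_curve(tr)
    assert np.max(np.abs(curve.value)) < 1e-6
    assert qmax == pytest.approx(0.0, abs=1e-6)


def test_qv_monotone_and_qmax(oocyte_cohorts):
    p = load_genotype("WT")
    oo = OocyteModel(Qmax_cell=0.85, g_leak_lin=0.5, noise_sd=0.0)
    tr = run_oocyte_protocol(oo, p, build_protocol("gating_charge"), seed=None)
    curve, qmax = qv_curve(tr)
    assert np.all(np.diff(curve.value) >= -1e-4)
    assert qmax == pytest.approx(0.85, rel=0.01)


def test_qv_requires_plus40_sweep():
    tr = _charge_toy(np.zeros((1, 221)), level=30.0)
    with pytest.raises(ValueError):
        qv_curve(tr)


def test_normalize_qv():
    p = load_genotype("WT")
    v = np.arange(-140.0, 50.0, 10.0)
    q = 0.85 / (1.0 + np.exp(-(v - p.V_half_q) / p.k_q))
    curve = IVCurve(v, q, kind="charge_nC")
    norm = normalize_qv(curve, 0.85)
    assert norm.at(p.V_half_q) == pytest.approx(0.5)
    assert norm.at(40.0) == pytest.approx(1.0, abs=0.01)
    with pytest.raises(ValueError):
        normalize_qv(curve, 0.0)


def test_qv_midpoint_shared_across_genotypes():
    """Normalized Q-V curves of WT and R853Q coincide: the mutation scales
    Qmax (surface expression) without shifting the charge-voltage
    relationship."""
    wt, rq = load_genotype("WT"), load_genotype("R853Q")
    assert wt.V_half_q == rq.V_half_q and wt.k_q == rq.k_q


def test_isolate_pure_linear_leak():
    v = np.arange(-140.0, 50.0, 10.0)
    iv = IVCurve(v, 0.8 * (v + 20.0), kind="steady_nA")
    residual, (slope, intercept) = isolate_gating_pore(iv)
    assert slope == pytest.approx(0.8)
    assert np.max(np.abs(residual.value)) < 1e-9


def test_isolate_recovers_injected_rectifier():
    """Injection oracle: simulate an R853Q oocyte (leak + known gating pore),
    isolate the nonlinear component, and compare with the injected gating
    pore current at every voltage; errors stay well under 2x the trace
    noise SD."""
    p = load_genotype("R853Q")
    noise_sd = 10.0
    oo = OocyteModel(Qmax_cell=0.44, g_leak_lin=0.8, E_leak=-20.0,
                     noise_sd=noise_sd)
    tr = run_oocyte_protocol(oo, p, build_protocol("gp_leak"), seed=77)
    ss = steady_state_iv(tr)
    residual, _ = isolate_gating_pore(ss)
    injected = gating_pore_current(residual.voltage, p, oo.Qmax_cell)
    assert np.max(np.abs(residual.value - injected)) < 2.0 * noise_sd


def test_isolation_invariant_to_leak_conductance():
    """The isolated gating pore current does not depend on the oocyte's
    linear leak (noiseless limit)."""
    p = load_genotype("R853Q")
    prot = build_protocol("gp_leak")
    out = []
    for g in (0.2, 2.0):
        oo = OocyteModel(Qmax_cell=0.44, g_leak_lin=g, noise_sd=0.0)
        residual, _ = isolate_gating_pore(
            steady_state_iv(run_oocyte_protocol(oo, p, prot, seed=None)))
        out.append(residual.at(-120.0))
    assert out[0] == pytest.approx(out[1], abs=1e-6)


def test_leak_line_idempotent():
    p = load_genotype("R853Q")
    oo = OocyteModel(Qmax_cell=0.44, g_leak_lin=0.8, noise_sd=0.0)
    tr = run_oocyte_protocol(oo, p, build_protocol("gp_leak"), seed=None)
    residual, _ = isolate_gating_pore(steady_state_iv(tr))
    twice, _ = isolate_gating_pore(residual)
    # refit on the already-subtracted curve changes next to nothing
    assert np.max(np.abs(twice.value - residual.value)) < 0.5


def test_wt_residual_is_noise_level(oocyte_cohorts):
    """The WT channel has no gating pore: the isolated current at -120 mV is
    leak-line extrapolation noise (a few nA, set by the slope uncertainty of
    the 4-point fit window), an order of magnitude below the R853Q signal,
    and the cohort slope against Qmax is indistinguishable from zero."""
    wt = oocyte_cohorts["WT"]
    r853q = oocyte_cohorts["R853Q"]
    assert np.max(np.abs(wt["i_gp_m120_nA"])) < 15.0
    assert np.max(np.abs(wt["i_gp_m120_nA"])) < 0.3 * np.min(np.abs(r853q["i_gp_m120_nA"]))
    res = correlate_gp_qmax(wt["qmax_nC"].to_numpy(),
                            wt["i_gp_m120_nA"].to_numpy())
    assert abs(res.slope) < 0.1 * 118.0


def test_correlate_exact_proportionality():
    q = np.array([0.2, 0.4, 0.6, 0.9])
    res = correlate_gp_qmax(q, -118.0 * q)
    assert res.slope == pytest.approx(-118.0)
    assert res.pearson_r == pytest.approx(-1.0)
    assert res.r2_adj == pytest.approx(1.0)


def test_correlate_matches_formula_oracle():
    rng = np.random.default_rng(5)
    q = rng.uniform(0.1, 1.0, 9)
    i = -100.0 * q + rng.normal(0, 5.0, 9)
    res = correlate_gp_qmax(q, i)
    assert res.slope == pytest.approx(np.sum(q * i) / np.sum(q * q), rel=1e-10)
    r_manual = (np.mean(q * i) - q.mean() * i.mean()) / (q.std() * i.std())
    assert res.pearson_r == pytest.approx(r_manual, rel=1e-10)


def test_correlate_validation():
    with pytest.raises(ValueError):
        correlate_gp_qmax(np.array([1.0, 2.0]), np.array([-1.0, -2.0]))
    with pytest.raises(ValueError):
        correlate_gp_qmax(np.zeros(5), np.zeros(5))


def test_extract_oocyte_report(oocyte_cohorts):
    df = oocyte_cohorts["R853Q"]
    assert (df["qmax_nC"] > 0).all()
    assert (df["i_gp_m120_nA"] < 0).all()
    assert np.isfinite(df["i_gp_per_qmax_nA_nC"]).all()
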