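"""Measurement-operation tests against constructed fixtures and closed-form
oracles: peaks, densities, reversal extrapolation, conductance, Boltzmann
and exponential fits, persistent and resurgent windows."""

import numpy as np
import pytest

from navclamp.channel import load_genotype
from navclamp.clamp import Segment, SubtractionMode, TraceSet, VoltageProtocol
from navclamp.features import (IVCurve, availability_curve, conductance_curve,
                               current_density, estimate_reversal,
                               fit_boltzmann, fit_decay_tau,
                               measure_peak_transient, measure_persistent,
                               measure_resurgent, normalize_to_max_transient,
                               peak_iv)
from navclamp.calibrate import _single_sweep, reference_cell
from navclamp.clamp import build_protocol, run_protocol


def _toy_traceset(currents: np.ndarray, levels, duration=50.0, dt=0.1):
    """TraceSet with a single sweep segment and a 2-ms baseline."""
    n_sweeps, T = currents.shape
    prot = VoltageProtocol(
        name="toy", holding=-100.0, sample_interval=dt,
        subtraction=SubtractionMode.NONE,
        segments=(Segment(kind="sweep", start=float(levels[0]),
                          stop=float(levels[-1]),
                          step=float(levels[1] - levels[0]) if n_sweeps > 1 else 5.0,
                          duration=duration),))
    t = np.arange(T) * dt
    v = np.tile(np.where(t < 2.0, -100.0, levels[0]), (n_sweeps, 1))
    return TraceSet(protocol=prot, time=t, voltage=v, current=currents,
                    levels=np.asarray(levels, dtype=float),
                    windows=[(0.0, 2.0), (2.0, 2.0 + duration)], meta={})


def test_peak_transient_constant_and_dip():
    t_len = 521
    flat = np.full((1, t_len), -10.0)
    tr = _toy_traceset(flat, [-20.0])
    assert measure_peak_transient(tr, 0) == -10.0
    dip = flat.copy()
    dip[0, 300] = -500.0
    tr2 = _toy_traceset(dip, [-20.0])
    assert measure_peak_transient(tr2, 0) == -500.0
    with pytest.raises(ValueError):
        measure_peak_transient(tr, 0, window=(30.0, 30.0))


def test_current_density():
    assert current_density(-550.0, 10.0) == -55.0
    assert current_density(0.0, 12.0) == 0.0
    with pytest.raises(ValueError):
        current_density(-550.0, 0.0)


def test_estimate_reversal_exact_line():
    v = np.arange(-30.0, 60.0, 5.0)
    iv = IVCurve(v, np.where(v < -20, -100.0, 2.0 * (v - 65.0)))
    assert estimate_reversal(iv) == pytest.approx(65.0)


def test_estimate_reversal_offset_shift():
    """Adding a constant offset c to the limb shifts the zero crossing by
    -c/slope (linearity of the least-squares line)."""
    v = np.arange(-30.0, 60.0, 5.0)
    base = np.where(v < -20, -100.0, 2.0 * (v - 65.0))
    iv = IVCurve(v, base)
    shifted = IVCurve(v, np.where(v < -20, -100.0, 2.0 * (v - 65.0) - 10.0))
    assert estimate_reversal(shifted) == pytest.approx(
        estimate_reversal(iv) + 5.0)


def test_estimate_reversal_requires_limb():
    iv = IVCurve(np.arange(-30.0, 10.0, 5.0), np.full(8, -100.0))
    with pytest.raises(ValueError):
        estimate_reversal(iv)


def test_reversal_round_trip_on_simulated_iv(ref_runs):
    """On the noiseless simulated WT IV the extrapolated reversal potential
    is close to the generating model's sodium reversal."""
    iv = peak_iv(ref_runs["WT"]["activation_iv"])
    e_rev = load_genotype("WT").E_rev
    assert estimate_reversal(iv) == pytest.approx(e_rev, abs=2.5)


def test_conductance_hand_value_and_normalization():
    v = np.array([-40.0, -30.0, -20.0, -10.0, 0.0])
    i = np.array([0.0, -50.0, -100.0, -80.0, -60.0])
    curve = conductance_curve(IVCurve(v, i), V_rev=60.0)
    # G(-20) = -100/(-20-60) = 1.25 nS is the maximum -> normalizes to 1
    assert curve.at(-20.0) == pytest.approx(1.0)
    assert curve.at(-40.0) == 0.0
    # G(-30) = 50/90 nS relative to 1.25 nS
    assert curve.at(-30.0) == pytest.approx((50.0 / 90.0) / 1.25)
    assert np.max(curve.value) == pytest.approx(1.0)


def test_boltzmann_self_fit_exact():
    v = np.arange(-80.0, 20.0, 5.0)
    y = 1.0 / (1.0 + np.exp(-(v + 26.5) / 6.0))
    fit = fit_boltzmann(IVCurve(v, y), increasing=True)
    assert fit.V_half == pytest.approx(-26.5, abs=1e-6)
    assert fit.k == pytest.approx(6.0, abs=1e-6)
    assert fit.scale == pytest.approx(1.0, abs=1e-6)


def test_boltzmann_fit_matches_grid_search():
    """On a frozen noisy availability fixture the nonlinear fit is at least
    as good as (and consistent with) a dense grid search over (V_half, k)."""
    rng = np.random.default_rng(12)
    v = np.arange(-130.0, 0.0, 10.0)
    y = 1.0 / (1.0 + np.exp((v + 65.0) / 6.0)) + rng.normal(0, 0.02, v.size)
    curve = IVCurve(v, y)
    fit = fit_boltzmann(curve, increasing=False)
    grid_v = np.arange(-75.0, -55.0, 0.25)
    grid_k = np.arange(3.0, 10.0, 0.25)
    best = (np.inf, None, None)
    for vh in grid_v:
        for k in grid_k:
            pred = 1.0 / (1.0 + np.exp((v - vh) / k))
            rss = float(np.sum((y - pred) ** 2))
            if rss < best[0]:
                best = (rss, vh, k)
    assert fit.rss <= best[0] + 1e-9
    assert fit.V_half == pytest.approx(best[1], abs=0.5)
    assert fit.k == pytest.approx(best[2], abs=0.5)


def test_boltzmann_fit_needs_points():
    with pytest.raises(ValueError):
        fit_boltzmann(IVCurve(np.array([0.0, 1.0, 2.0]),
                              np.array([0.1, 0.5, 0.9])))


def test_availability_curve_shape(ref_runs):
    curve = availability_curve(ref_runs["WT"]["inactivation"])
    assert curve.at(-130.0) == pytest.approx(1.0)
    fit = fit_boltzmann(curve, increasing=False)
    mid = np.interp(fit.V_half, curve.voltage, curve.value)
    assert mid == pytest.approx(0.5, abs=0.02)
    assert np.all(curve.value <= 1.05) and np.all(curve.value >= -0.01)


def test_decay_tau_pure_exponential():
    t_len = 521
    dt = 0.1
    t = np.arange(t_len) * dt
    i = np.where(t < 2.0, 0.0, -100.0 * np.exp(-(t - 2.0) / 0.5))
    tr = _toy_traceset(i[None, :], [-15.0], duration=50.0, dt=dt)
    assert fit_decay_tau(tr, 0) == pytest.approx(0.5, abs=1e-6)


def test_decay_tau_matches_loglinear_oracle():
    """With no offset, the nonlinear fit agrees with log-linear regression."""
    dt = 0.05
    t = np.arange(0.0, 22.0, dt)
    tau_true = 1.7
    i = np.where(t < 2.0, 0.0, -80.0 * np.exp(-(t - 2.0) / tau_true))
    tr = _toy_traceset(i[None, :], [-15.0], duration=20.0, dt=dt)
    tau_fit = fit_decay_tau(tr, 0)
    mask = (t >= 2.0) & (i < -1e-6)
    slope = np.polyfit(t[mask], np.log(-i[mask]), 1)[0]
    assert tau_fit == pytest.approx(-1.0 / slope, rel=1e-3)
    assert tau_fit == pytest.approx(tau_true, rel=1e-3)


def test_inactivation_slowed_in_r1882q(ref_runs, ref_reports):
    """R1882Q slows fast inactivation: fitted decay tau at -15 mV larger
    than WT."""
    assert ref_reports["R1882Q"].taus.at(-15.0) > ref_reports["WT"].taus.at(-15.0)


def test_persistent_constant_trace():
    tr = _toy_traceset(np.full((1, 521), -12.0), [-30.0])
    assert measure_persistent(tr, 0) == pytest.approx(-12.0)


def test_persistent_matches_hh_closed_form():
    """With block off, the persistent current after full relaxation equals
    expr * g_max * m_inf^3 * [h_inf (1-f_p) + f_p] * (V - E_rev)."""
    from navclamp.clamp import CellModel
    p = load_genotype("WT").model_copy(update={"kb_on": 0.0})
    # leak-free cell: the single-sweep helper runs without P/-5 subtraction
    cell = CellModel(g_leak=0.0, endogenous_peak=-207.1, noise_sd=0.0)
    prot = _single_sweep(build_protocol("activation_iv"), -30.0)
    tr = run_protocol(cell, p, prot, seed=None)
    measured = measure_persistent(tr, 0)
    g_total = cell.expr * p.g_max + abs(cell.endogenous_peak) / 35.0
    expected = (g_total * p.m_inf(-30.0) ** 3
                * (p.h_inf(-30.0) * (1 - p.f_p) + p.f_p) * (-30.0 - p.E_rev))
    assert measured == pytest.approx(expected, rel=0.01)


def test_resurgent_trivial_dip():
    prot = VoltageProtocol(
        name="res_toy", holding=-100.0, sample_interval=0.1,
        segments=(Segment(kind="fixed", level=30.0, duration=20.0),
                  Segment(kind="sweep", start=-30.0, stop=-30.0, step=5.0,
                          duration=50.0)))
    T = 721
    t = np.arange(T) * 0.1
    i = np.zeros((1, T))
    i[0, np.searchsorted(t, 25.0)] = -50.0
    tr = TraceSet(protocol=prot, time=t, voltage=np.full((1, T), -30.0),
                  current=i, levels=np.array([-30.0]),
                  windows=[(0.0, 2.0), (2.0, 22.0), (22.0, 72.0)], meta={})
    assert measure_resurgent(tr, 0) == -50.0


def test_resurgent_without_block_equals_persistent(ref_runs):
    """With the peptide absent there is no hump: the repolarization minimum
    sits at the (early) decaying tail and the late current equals the
    persistent level."""
    p = load_genotype("WT").model_copy(update={"kb_on": 0.0})
    cell = reference_cell()
    res = run_protocol(cell, p, _single_sweep(build_protocol("resurgent"), -30.0),
                       seed=None)
    act = run_protocol(cell, p, _single_sweep(build_protocol("activation_iv"), -30.0),
                       seed=None)
    persistent = measure_persistent(act, 0)
    t0, t1 = res.sweep_window
    late = np.mean(res.current[0, res.window_slice((t1 - 5.0, t1))])
    assert late == pytest.approx(persistent, rel=0.05)


def test_normalize_to_max_transient():
    assert normalize_to_max_transient(-100.0, -10000.0) == pytest.approx(1.0)
    assert normalize_to_max_transient(0.0, -10000.0) == 0.0
    with pytest.raises(ValueError):
        normalize_to_max_transient(-100.0, 0.0)


def test_extraction_deterministic(ref_runs, ref_reports):
    """Identical traces give identical reports."""
    from navclamp.features import extract_cell
    again = extract_cell(ref_runs["WT"]["activation_iv"],
                         inact=ref_runs["WT"]["inactivation"],
                         res=ref_runs["WT"]["resurgent"],
                         Cm=16.0, cell_id="WT")
    assert again.act_fit.V_half == ref_reports["WT"].act_fit.V_half
    assert again.resurgent_pct == ref_reports["WT"].resurgent_pct
    assert again.max_peak_pA == ref_reports["WT"].max_peak_pA
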