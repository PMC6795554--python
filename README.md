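# navclamp

Voltage-clamp simulation and analysis pipeline for human Nav1.2 sodium
channels: wild type and the two epilepsy variants **R1882Q** (C-terminal,
gain-of-function) and **R853Q** (DII voltage-sensor, mostly
loss-of-function plus an anomalous gating-pore current).

Whole-cell studies of these variants report their biophysics as a small set
of derived numbers — Boltzmann midpoints of activation and availability,
persistent and resurgent current as a percentage of the peak transient,
integrated on-gating charge Q_max, and the slope of gating-pore current
against Q_max.  Each of those numbers is the output of a very specific
measurement procedure (protocol timing, measurement windows, leak
subtraction, curve fits).  This package implements both sides: a mechanistic
channel/recording simulator that stands in for the HEK-cell and *Xenopus*
oocyte recordings, and the exact measurement procedures, verified by
round-trip parameter recovery — calibrated simulated recordings must return
the published values through the same analysis chain.  It is intended for
electrophysiologists and modellers who want a tested, reproducible
implementation of these measurement conventions (or a harness to validate
their own analysis code against known ground truth).

## Model

Central-pore current (pA, inward negative), Hodgkin–Huxley `m³h` with a
persistent fraction and Navβ4-peptide open-channel block:

    I_Na = expr · g_max · m³ · [h(1−f_p) + f_p] · (1−b) · (V − E_rev)

    dm/dt = (m∞(V) − m)/τ_m(V)            m∞ = 1/(1+exp(−(V−V½ₘ)/kₘ))
    db/dt = k_on·m³[h(1−f_p)+f_p](1−b) − k_off(V)·b,   k_off = k₀·e^(−V/δ)

Blocked channels are protected from inactivation (the peptide occupies the
inactivation receptor) and unblock *available*, which produces the resurgent
hump on repolarization.  Gating charge follows a first-order relaxation to a
Boltzmann Q–V (on-gating current `I_g = Q_max·dq/dt`), and the R853Q
voltage sensor additionally conducts a gating-pore current in its resting
conformation:

    I_gp = s_gp · Q_max · P_down(V) · (V − E_gp),   P_down = 1/(1+e^((V−V½)/k))

Measurements implemented: peak transient and current density, reversal by
ascending-limb extrapolation, normalized conductance G = I/(V−V_rev) and
availability curves with Boltzmann fits, single-exponential inactivation
τ, persistent current (mean of the last 10 % of the 50-ms step), resurgent
peak (minimum during repolarization), Q_on by digital integration with P/N
subtraction, gating-pore isolation by linear-leak subtraction over
−20..+10 mV, and the through-origin regression of I_gp(−120 mV) on Q_max.
See `docs/methods.md` for the full account.

## Worked example

Simulate the calibrated WT reference cell through the activation,
inactivation and resurgent protocols and extract its whole-cell features:

```python
from navclamp import build_protocol, extract_cell, load_genotype, run_protocol
from navclamp.calibrate import reference_cell

cell, params = reference_cell(), load_genotype("WT")
runs = {name: run_protocol(cell, params, build_protocol(name), seed=None)
        for name in ("activation_iv", "inactivation", "resurgent")}
rep = extract_cell(runs["activation_iv"], inact=runs["inactivation"],
                   res=runs["resurgent"], Cm=cell.Cm)
print(f"activation V1/2  {rep.act_fit.V_half:8.2f} mV")
print(f"inactivation V1/2 {rep.inact_fit.V_half:7.2f} mV")
print(f"max transient    {rep.max_peak_pA:8.0f} pA")
print(f"persistent at -30 mV {rep.persistent_pct:6.2f} % of max transient")
print(f"resurgent  at -30 mV {rep.resurgent_pct:6.2f} % of max transient")
```

prints

```
activation V1/2    -26.52 mV
inactivation V1/2  -65.06 mV
max transient       -8750 pA
persistent at -30 mV   0.56 % of max transient
resurgent  at -30 mV   2.38 % of max transient
```

i.e. the simulated recording, pushed through the same Boltzmann fits and
measurement windows used on real cells, returns the published WT values
(midpoints −26.50 / −65.01 mV, persistent 0.57 %, resurgent 2.39 %, peak
−8.75 nA).  The same round trip for R1882Q shows the gain-of-function
signature (depolarized availability, larger persistent/resurgent currents)
and for R853Q the loss-of-function one, plus — in the oocyte pipeline — a
gating-pore current whose amplitude at −120 mV scales with Q_max at about
−118 nA/nC.

## Analysis scripts

The study is organized as numbered drivers over the library (all accept
`--seed`; outputs under `results/`):

| script | what it does |
|---|---|
| `analysis/01_calibrate_channels.py` | round-trip calibration of the three genotype parameter sets (writes the JSONs shipped in `src/navclamp/params/`) |
| `analysis/02_hek_biophysics.py` | HEK cohorts (n = 40/25/16): per-cell features and group summary vs published means |
| `analysis/03_oocyte_gating_charge.py` | oocyte cohorts: Q-V integration and Q_max recovery |
| `analysis/04_gating_pore_correlation.py` | gating-pore isolation and the I_gp(−120) vs Q_max through-origin correlation |
| `analysis/05_full_study.py` | everything in one deterministic run with provenance (config hash + seeds) |

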