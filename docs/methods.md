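# Methods

`navclamp` re-creates, as a tested simulation-plus-analysis pipeline, the
voltage-clamp characterization of human Nav1.2 (WT) and the two epilepsy
variants R1882Q and R853Q: transient and persistent sodium currents,
Navβ4-peptide-induced resurgent currents, on-gating charge, and the R853Q
gating-pore (omega) current.  The published numbers are measurements on real
cells; here they serve as **calibration round-trip targets**: the channel
model is configured so that running the *same protocols, windows,
subtractions and fits* on simulated recordings returns the printed values.
Passing therefore validates the measurement pipeline (protocol timing,
windowing, leak handling, fitting), not the biology.

## Channel model

The central pore is Hodgkin–Huxley `m³h` with two extensions:

* **Persistent fraction** `f_p`: a fraction of the conductance that never
  inactivates, so the open fraction is
  `m³ · [h·(1−f_p) + f_p] · (1−b)` and the ionic current is
  `I = expr · g_max · m³ [h(1−f_p)+f_p] (1−b) (V − E_rev)` (pA; inward
  negative).  This mode-switch approximation realizes the window/persistent
  phenomenology without single-channel data.
* **Open-channel block** `b`: the Navβ4 C-terminal peptide blocks open
  channels with on-rate `kb_on · (open probability)` and unbinds at
  `kb_off(V) = kb_off0 · exp(−V/δ_b)` — unblock accelerates with
  hyperpolarization.  While bound, the peptide occupies the receptor of the
  inactivation particle, so blocked channels neither inactivate nor
  recover, and on unblock they rejoin the unblocked pool *available*.  `h`
  is the availability of the unblocked pool; the integrator works in the
  regular variables `(m, A, b, q)` with `A = h(1−b)`:

      dA/dt = ((1−b)·h∞(V) − A)/τ_h(V) − kb_on·m³·(1−f_p)·A + kb_off(V)·b
      db/dt = kb_on·m³·[h(1−f_p)+f_p]·(1−b) − kb_off(V)·b

  This "foot-in-the-door" protection is what produces the resurgent hump on
  repolarization: unblock (fast at −30 mV) transiently outpaces
  inactivation (τ_h ≈ 2–4 ms there).  Without it a mean-field scheme cannot
  make the resurgent peak exceed the persistent floor.  Persistent-mode
  channels participate in block but not in the availability bookkeeping, an
  O(f_p) approximation (f_p < 2 % everywhere here); its visible consequence
  is a small steady block-recycling component in the persistent current,
  which the `f_p` calibration absorbs (the real recordings also contained
  the peptide throughout).

* **Gating charge** `q` relaxes first-order (τ_q = 0.5 ms) toward a
  Boltzmann Q–V (`V½ = −30 mV`, `k = 10 mV`; the source figures are not
  numerically printed, so these are conventional placeholders and no test
  depends on their exact values).  The on-gating current is
  `I_g = Q_max · dq/dt`.
* **Gating pore** (R853Q only): the neutralized S4 arginine opens an
  aqueous conduction pathway when the DII voltage sensor is in its resting
  ("down") conformation, so
  `I_gp = perm · s_gp · Q_max · P_down(V) · (V − E_gp)` with
  `P_down(V) = 1/(1+exp((V−V½_gp)/k_gp))`, `V½_gp = −70 mV` (conducting at
  typical resting potentials), `k_gp = 10 mV`, `E_gp = +90 mV`
  (non-selective cation influx, inwardly rectifying at negative V).
  `s_gp` is set in closed form so that 1 nC of gating charge passes
  −118 nA at −120 mV.  WT has `s_gp = 0` (validated at the type level).
  `perm` is a guanidinium-bath multiplier (≥ 1; applied only when the bath
  flag is set) that reproduces the qualitative amplitude increase with
  guanidinium.

Time constants for m and h are constant-plus-Gaussian bells in voltage.
The τ defaults encode the qualitative orderings only (τ_h at −15 mV
≈ 1.0 ms for WT, ≈ 1.5 ms for R1882Q — the variant slows fast
inactivation; R853Q slightly faster than WT), since the source reports no
numeric time constants.

Units are fixed package-wide: mV, ms; pA and nS in the HEK context; nA, µS
and nC in the oocyte context; inward current negative.

## Clamp emulation

Protocols are declarative (holding, ordered fixed/sweep segments, sample
interval, subtraction mode) and match the study: activation 50-ms steps
−80..+60 mV in 5-mV increments from −100 mV; inactivation 500-ms prepulses
−130..+10 mV in 10-mV steps plus a 20-ms test at +10 mV; resurgent 20 ms at
+30 mV then 50-ms repolarizations +10..−65 mV; oocyte leak 200-ms steps
−140..+40 mV; gating charge 20-ms steps −140..+40 mV.  Unprinted sweep
increments (resurgent 5 mV, oocyte 10 mV) follow the figures' axis
conventions; sampling is 0.02 ms (HEK) and 0.1 ms (oocyte), a convention
the source does not state.

The clamp is idealized (command reached instantly; the study compensated
series resistance up to 90 %).  Within each constant-voltage segment the
state is integrated with LSODA (rtol 1e−8) and sampled onto the regular
time base.  Each sweep carries a 2-ms recorded holding baseline.

The recorded HEK current is ionic + linear leak `g_leak (V−E_leak)` +
residual capacitive transients (`(ΔV/Rs_u)·exp(−t/Rs_u·Cm)` at each edge,
`Rs_u = Rs(1−comp)`) + an endogenous component (−207.1 pA reference
amplitude, modelled as a small extra conductance gated like the transfected
channel) + recording noise.  **P/−5 subtraction** is emulated as five
sub-sweeps of amplitude −ΔV/5 from holding whose responses are added to the
test sweep (minus the six-fold holding baseline); for a purely linear cell
this cancels exactly, which is a test.  The five sub-sweeps share one
command waveform, so their deterministic response is computed once.

**Recording noise** is band-limited: white Gaussian passed through a
2nd-order low-pass at the acquisition cutoff (default 2.9 kHz, the
conventional whole-cell filter setting) and scaled so that `noise_sd` is
the RMS of the *recorded* trace (default 2.5 pA for HEK cohorts, 10 nA for
oocytes).  This matters because two measurements are window extrema
(transient and resurgent peaks): broadband per-sample noise would add an
extreme-value bias of ~3σ to every minimum, which for the small R853Q
resurgent current (≈ −60 pA) would exceed the tolerance the printed values
themselves satisfy.  With the band-limited model the residual bias is
+2–4 % (WT/R1882Q) and ≈ +10 % (R853Q) of the resurgent percentage — the
one measurement where it remains visible — and ≲1 % elsewhere.

Oocyte recordings omit the capacitive term (analog-compensated on the real
rig).  TTX (the standard condition) zeroes the central pore.  **P/N
subtraction** for gating currents estimates the linear background from a
simulated −120→−100 mV subpulse, as the on-line routine does, and removes
the fitted line from every sweep.

## Measurements

All measurement definitions follow the study: peak transient = minimum over
the test pulse; density = peak/Cm; reversal potential by least-squares
extrapolation of the ascending IV limb (points from the IV-minimum voltage
+10 mV up to the interpolated zero crossing — the window itself is not
specified in the source, so this contiguous-run rule is a design choice);
conductance `G = I/(V−V_rev)` normalized to its maximum; availability
`I/I_max` per prepulse; Boltzmann fits `scale/(1+exp(∓(V−V½)/k))` by
nonlinear least squares with three deterministic initializations (midpoint
estimate and ±10 mV; best RSS wins, ties to smaller |k|);
single-exponential decay fits from the sweep peak to the pulse end;
persistent current = mean over the final 10 % of the 50-ms step (45–50 ms —
the study's own text is internally inconsistent here, and the 5-ms legend
reading is used; the window fraction is configurable); resurgent peak =
minimum during the repolarization with a 0.5-ms edge guard (unstated in the
source; needed to exclude the instantaneous tail).

Oocyte side: Q_on by trapezoidal integration of the charge-displacement
current (nA·ms → pC); in the pipeline each sweep's steady tail (mean of the
last 25 % of the step) is subtracted first so that steady gating-pore/leak
residuals do not pollute the integral.  Q_max = Q(+40 mV).  The gating-pore
current is isolated by fitting a line to the total steady-state IV (mean of
the last 25 % of each 200-ms step) over −20..+10 mV and subtracting it at
every voltage.  The cohort analysis regresses I_gp(−120 mV) on Q_max
through the origin (`slope = ΣQI/ΣQ²`, via statsmodels OLS without
intercept); the reported Pearson R is the ordinary correlation of the two
series, and the adjusted R² is the constrained model's, with uncentered
total sum of squares (whether the published R refers to the constrained or
unconstrained fit is not stated, so both are reported).

## Calibration

Because extracted features are nonlinear functionals of the parameters (the
m³ gate alone shifts the fitted G–V midpoint ≈ +1.35·k_m from `V_half_m`),
each genotype is calibrated by nested one-dimensional root searches over
the *full* simulate→extract round trip: `V_half_m` ← activation midpoint,
`V_half_h` ← availability midpoint, `f_p` ← persistent % at −30 mV,
`kb_on` ← resurgent % at −30 mV (Brent's method; persistent/resurgent
single-sweep evaluations for speed), iterated to joint convergence, then
`g_max` ← maximum peak transient amplitude by an exact linear solve.
Searches run on an ideal noiseless cell (no leak, full compensation, no
endogenous current, subtraction off), which measures identically to the
reference cell with P/−5; a final verification pass runs the true
reference-cell pipeline and enforces midpoints ±2 mV, percentages ±15 %
relative, peak ±10 %.  The shipped parameter files
(`src/navclamp/params/*.json`) are the output of
`analysis/01_calibrate_channels.py`.

## Synthetic cohorts

Cohorts are pure functions of (spec, seed).  HEK cells: expression scale
lognormal with median 1 (σ = 0.5), Cm ~ N(16, 2²) pF truncated > 5 pF,
shared leak (1 nS), endogenous amplitude −207.1 pA, recorded noise 2.5 pA
RMS; group sizes 40/25/16 (WT/R1882Q/R853Q).  Oocytes: Q_max truncated
normal.  Two oocyte configurations are deliberate: the Q_max-recovery
cohorts (WT n=5 mean 0.85 nC, R853Q n=6 mean 0.44 nC) use a tight 4 % CV —
a homogeneous injection batch — so that the small-n cohort mean tests the
*integration pipeline* rather than sampling luck; the n=11 correlation
cohort uses a wide spread (sd 0.2 nC, the across-oocyte range that makes
the through-origin regression informative) with recording noise tuned to
3 nA so the correlation reflects the expression spread rather than the
leak-line extrapolation error (the dominant nuisance: extrapolating a
4-point fit to −120 mV amplifies point noise ≈ 5-fold).

What the generator does **not** emulate: electrode drift, seal instability,
liquid-junction potentials, temperature, voltage-clamp error from
uncompensated Rs (an optional mode exists but is off by default), run-down,
and cell-exclusion decisions.  Passing round trips therefore show that the
analysis chain is self-consistent under the modelled variability, not that
it is robust to every artifact of real recordings.

## Numerical choices and degenerate inputs

LSODA with rtol 1e−8/atol 1e−10; state clipped to [0,1] at output (the
internal (m, A, b, q) variables keep the system regular as b→1).  Boltzmann
fits bound k ∈ [0.5, 40] mV.  Conductance points within 2.5 mV of the
estimated reversal are excluded (vanishing driving force).  Zero-charge
oocytes, zero-expression cells and block-free channels are all valid inputs
and covered by tests; `Q_max = 0` makes normalized Q–V undefined and
raises.  Trapezoidal integration at 0.1 ms sampling biases Q_on by ≈ 0.3 %
(τ_q = 0.5 ms), well inside the 5 % recovery tolerance.

## Problem sizes

Default analysis runs use the study's group sizes (HEK 40/25/16, oocytes
5/6/11).  The test suite exercises the same pipelines at reduced cohort
sizes (n = 8 HEK cells per genotype) with fixed seeds, which keeps the
cohort means within the stated tolerances while the full-size runs remain
available through the analysis scripts.

## Known limitations

* Aggregate (mean-field) gating: no stochastic single-channel behavior, no
  full Markov scheme; the block bookkeeping is exact only to O(f_p).
* Resurgent kinetics are calibrated to the −30 mV summary values, not to
  the full resurgent IV shape; the R853Q hump is small and rides the
  repolarization tail, peaking earlier than the WT/R1882Q humps.
* The Q–V midpoint/slope and all τ values are conventions constrained only
  by orderings, since the source prints none of them numerically.
* The endogenous-current emulation shares the transfected channel's gating,
  which is a simplification (its amplitude, not its kinetics, is the point).
* Between-cell variability covers expression, capacitance and noise but not
  gating: all cells of a genotype share one parameter set, so simulated
  cohort SEMs are realistic for amplitudes and densities (set by the
  expression spread) but far smaller than the published SEMs for midpoints
  and normalized percentages.
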