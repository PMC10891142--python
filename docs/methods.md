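# Methods

## The system

Two identical human ventricular myocytes are never coupled to each other;
all interaction flows through one or two fibroblast units.  This isolates
the cellular building block of fibroblast-mediated conduction across
non-conducting barriers (scars, ablation lines) from tissue-level
electrotonic effects, which are deliberately out of scope.

**Myocyte.** Ten Tusscher–Panfilov 2006 epicardial cell: membrane potential,
12 Hodgkin–Huxley gates (m, h, j, x_r1, x_r2, x_s, r, s, d, f, f2, f_CaSS),
the ryanodine-receptor adaptation variable, and intracellular Na⁺, K⁺ and
Ca²⁺ (cytosolic, subspace, SR) — 19 variables.  The 12 currents are I_Na,
I_to, I_K1, I_Kr, I_Ks, I_CaL, I_NaCa, I_NaK, I_pCa, I_pK, I_bCa, I_bNa.
Two variants set the restitution character by scaling the plateau currents:

| variant | G_pCa (nS/pF) | G_pK (nS/pF) |
|---------|--------------:|-------------:|
| Shallow | 0.0619        | 0.0730       |
| Steep   | 0.8666        | 0.00073      |

All other parameters are the source model's epicardial defaults.  An
additional `tau_f_scale` knob (×τ_f for V > 0) exists but is 1 in both
variants; scaling it steepens restitution dramatically and is not part of
the study conditions.  The Steep cell develops APD alternans below a basic
cycle length of ≈290 ms, as its label predicts.

**Fibroblast.** MacCannell "active" fibroblast with fixed intracellular
ion contents: I_fKv = g_Kv·r·s·(V_f − E_K) with g_Kv = 0.25 nS/pF,
activation r (τ ≈ 20–160 ms) and slow inactivation s (τ ≈ 1.6–6.8 s);
inward-rectifier I_fK1 (g_K1 = 0.4822 nS/pF, rectification factor of the
ventricular α/β form); Na/K pump (2.002 pA/pF maximum, K_mK = 1 mM,
K_mNa = 11 mM, reversal shape (V_f + 150)/(V_f + 200)); background
I_bNa (0.0095 nS/pF).  The unmodified cell rests at −48.9 mV here
(published value ≈ −49.6 mV; the small difference traces to evaluating the
Nernst factors at 310 K).

**Resting-potential calibration.** V_FR is tuned by rigidly shifting *both*
the steady-state curves and the time constants of the I_fKv gates along V
(`kv_shift`).  The steady V_f(shift) map is strictly monotone over shifts
in [−20, +100] mV (verified by brute-force scan); `calibrate_kv_shift`
Brent-solves it against a 60-s unstimulated settle (the slow s gate needs
tens of seconds).  Calibrated shifts: +34.70 mV for V_FR = −24.5 mV,
−0.13 mV for −49.0 mV.  Shifting only the steady-state curves (not the
time constants) changes neither the calibration nor, measurably, the
coupled dynamics; the joint shift is the package convention.

**Coupling.**  With i ≠ j,

    C_m dV_i/dt  = −I_ion,i + N_f [G_Loc,i (V_f,i − V_i) + G_Long,i (V_f,j − V_i)] + I_stim,i
    C_f dV_f,i/dt = −I_fib,i +     G_Loc,i (V_i − V_f,i) + G_Long,j (V_j − V_f,i)

C_m = 150 pF, C_f = 50 pF (myofibroblast), N_f = 4 parallel fibroblasts per
unit sharing one state vector; N_f multiplies the myocyte side only, so the
whole-cell charge entering a myocyte through a link equals N_f times the
charge leaving each fibroblast (asserted term-by-term in the tests).  The
motifs zero links: Motif-1 G_Loc1 = G_Long2 = 0, Motif-2 G_Long2 = 0,
Motif-3 none.  Motif-1 and Motif-2 trajectories are bit-identical to the
generic system with those links zeroed.

## Units and stimulus

Voltages mV, time ms.  Both models' ionic currents are densities (pA/pF),
so dV/dt = −I_ion + I_ext is directly mV/ms; gap-junctional currents are
formed from whole-cell conductances (nS) divided by the whole-cell
capacitances above (nS·mV/pF = mV/ms).  The stimulus is +52 pA/pF
(depolarizing) for 1 ms — the ventricular model's own stimulus amplitude,
about twice diastolic threshold; it also enters the K⁺ mass balance, as in
the source model.  Only capture reliability and APD are downstream
observables of the stimulus convention.

## Numerics

Fixed-step operator splitting: gates advance by the Rush–Larsen exponential
update, voltage and concentrations by forward Euler; dt = 0.01 ms (half the
step the ventricular model was published with).  At this step APD90 is
converged to ≈0.3 ms: reducing dt tenfold moves it by < 0.5 ms, the
package's accuracy contract.  Integration is exactly deterministic —
repeated runs are bit-identical, Motif-3 with identical cells and
simultaneous stimuli gives V1(t) ≡ V2(t) exactly, and a zero-conductance
motif bit-matches isolated single-cell runs.  An independent route —
scipy's LSODA over the same right-hand side at rtol 1e-8 — reproduces the
stepper's APD90 to ≈0.15 ms (tested).  Stimulus onsets are snapped to the
step grid; output is sampled every 0.1 ms and AP feature times are linearly
interpolated between samples (APD90 resolution ≈ 0.1 ms).

Quiescent "resting" initial conditions use a 10-s unstimulated settle
(V ≈ −86 mV).  The quiescent ventricular cell has no nearby true fixed
point at physiological Na⁺: the voltage is stationary (|dV/dt| < 1e-3
mV/ms) but pump fluxes drain Na_i on a minutes timescale, so the
steady-state diagnostic uses a 1e-4 relative-residual contract for the
myocyte; the fibroblast reaches a genuine fixed point (residual < 1e-6).
Because pacing starts from rest, APD accommodates by a few ms across beats
11–20; means over the last 10 beats follow the study protocol.

## Measurement conventions

**AP detection.** An AP is a contiguous excursion above −20 mV (≥ 50 ms
separation); fibroblast-driven subthreshold bumps never count.  APD90 runs
from the interpolated upstroke crossing to 90 % repolarization, with the
amplitude referenced to the event's own preceding diastolic minimum (robust
when coupling lifts diastolic V).

**Regimes.** In the infinite-delay protocol the response fraction is the
share of the last 10 pacing stimuli answered by a response-cell AP within
one pacing period (attribution to the most recent stimulus; latencies are
≪ T).  NR ⇔ 0, 1:1 ⇔ 1, IR otherwise — exact, so the three labels
partition all outcomes.  The pacing cell is scored identically: at
T = 300 ms it can itself drop to 2:1 (IR) while loaded by the fibroblasts.

**S1S2 restitution.** Ten S1 beats at 600 ms, then one S2 per requested
diastolic interval, delivered at the 90 %-repolarization time of the last
S1 beat plus the DI (DI-controlled S2); the reported DI is re-measured from
the trace.  An S2 beat counts as captured when its amplitude reaches 70 %
of the steady S1 amplitude; graded near-refractory responses are recorded
but excluded.  The maximal slope is the largest centered finite difference
over the captured curve after an isotonic filter that drops points falling
below the curve's running maximum — restitution is non-decreasing over the
physiological range, and isolated all-or-none dips near capture boundaries
(loss of the dome) would otherwise inject spurious rebound slopes.  The
short-DI limb is sampled at 2.5 ms; in this regime the slope estimate is
refinement-stable (halving the spacing moves it < 5 %).  Measured maxima:
Steep 1.83, Shallow 1.52.  The Shallow parameter set's nominal slope label
(0.7) reflects the dynamic (steady-pacing) restitution protocol and is not
reproduced by any uniform S1S2 convention at 600 ms; the Steep label (1.8)
is.  The full-recovery APD at DI ≥ 1 s plateaus ~14 ms above the
accommodated steady-pacing APD, standard restitution behavior.

## Surrogate cells

For structural testing, a closed-form excitable surrogate replaces the
biophysical myocyte: subthreshold RC relaxation plus a square AP whose
duration follows the prescribed law APD(DI) = APD_max − a·exp(−DI/τ_rest)
(defaults 300 − 150·exp(−DI/100) ms), with a passive RC node standing in
for the fibroblast.  It plugs into the identical motif/protocol/metric/sweep
machinery, runs an 81-point sweep in seconds, and — because its ground truth
is analytic — doubles as the oracle for every metric.  It emulates
excitability, restitution and refractoriness but none of the ionic
mechanisms (no alternans, no calcium dynamics, no rate-dependent AP-shape
change), so surrogate-based tests validate bookkeeping and invariants, not
biophysics; it is never used for quantitative study results.

## Design choices where the design was open

* S2 timing is DI-controlled (from rep-90 of the last S1) rather than
  coupling-interval-controlled; the recorded DI is trace-measured either way.
* Both V_FR targets go through the same explicit calibration; −49.0 mV
  lands at a near-zero shift.
* The response-capture criterion is a full AP (−20 mV crossing), not a
  subthreshold depolarization; the threshold is configurable.
* Sweep results are cached per grid point keyed by a configuration hash;
  re-running a sweep reproduces byte-identical CSV output.
* The CLI accepts `--seed` and records it in the manifest, but every
  simulation in the study is deterministic.

## Problem sizes

Default study conditions throughout: 20 beats per simulation (first 10
discarded), 9×9 conductance grids at 0.5 nS, dt = 0.01 ms.  The test suite
exercises full-resolution single maps and pools reduced grids (1 nS step,
two motifs, two pacing periods) where the published study pools all motifs
and four periods at full resolution; the pooled comparisons are orderings,
not figure reproductions.

## Known limitations

* No tissue: electrotonic diffusion, conduction velocity and wavefront
  curvature are absent by design; τ_D is only a proxy for conduction time.
* No fibroblast–fibroblast coupling; at most 2 myocytes and 2 fibroblast
  units; homogeneous myocytes.
* The intermittent-conduction (IR) band at slow pacing (T = 600 ms) is
  nearly absent in this realization: the Shallow NR→1:1 boundary is sharp
  down to 0.1 nS resolution, while IR bands do appear at T = 400 ms and are
  widespread (in both cells) at T = 300 ms.  Slow-pacing intermittency
  evidently depends on fine details of the fibroblast kinetics; treat
  regime *boundaries* (not the taxonomy) as model-detail-sensitive.
* At T = 300 ms the Shallow variant — whose flat restitution keeps its APD
  near 280 ms regardless of recovery time — loses 1:1 pacing capture when
  fibroblast-loaded and locks into 2:1 from resting initial conditions,
  while the Steep variant shortens its APD and keeps pacing 1:1.  Pooled
  regime-occurrence comparisons between the variants therefore depend
  strongly on which pacing periods enter the pool.
* Fixed-step explicit integration requires dt ≤ ~0.02 ms for stability;
  the solver never adapts, trading speed safety-margins for exact
  reproducibility.
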