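"""Low-level numba kernels for the biophysical cell models and fixed-step drivers.

Everything in this module operates on bare float64 arrays so that the hot
loops compile to machine code.  The public, documented surface lives in
:mod:`fibromotif.cell_models`, :mod:`fibromotif.motif` and
:mod:`fibromotif.protocols`; nothing here should be called directly by users.

Units convention (fixed across the package):

* voltages in mV, time in ms;
* ionic currents of both cell models are densities in pA/pF, so that
  dV/dt = -I_ion + I_ext is directly in mV/ms;
* external/coupling currents ``I_ext`` are positive-depolarizing, already
  divided by the whole-cell capacitance (pA/pF);
* gap-junction conductances are whole-cell nS, divided by C_m = 150 pF or
  C_f = 50 pF where the coupling current is formed (nS * mV / pF = mV/ms).

Integration is operator-split: Hodgkin-Huxley gates advance with the
exponential (Rush-Larsen) update, voltage and concentrations with forward
Euler.  The ventricular model was published with this scheme at a 0.02 ms
step; the package default of 0.01 ms halves that so APD90 is converged to
well under the 0.5 ms contract enforced in the tests.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# State layout (versioned: checkpoints depend on this ordering)
# ---------------------------------------------------------------------------

STATE_LAYOUT_VERSION = 1

#: ten Tusscher-Panfilov 2006 epicardial state, 19 variables.
MYO_STATE_NAMES = (
    "V", "m", "h", "j", "xr1", "xr2", "xs", "r", "s", "d", "f", "f2",
    "fcass", "rbar", "cai", "cass", "casr", "nai", "ki",
)
N_MYO = 19
MYO_GATE_SLICE = slice(1, 13)  # 12 Rush-Larsen gates: m..fcass
N_MYO_GATES = 12

#: MacCannell active-fibroblast state, 3 variables.
FIB_STATE_NAMES = ("vf", "rkv", "skv")
N_FIB = 3
N_FIB_GATES = 2

#: Combined motif state: [M1, M2, F1, F2].
N_MOTIF = 2 * N_MYO + 2 * N_FIB
MOTIF_OFFSETS = (0, N_MYO, 2 * N_MYO, 2 * N_MYO + N_FIB)

# Myocyte parameter-vector layout (see cell_models.MyocyteParams)
# 0 g_na  1 g_k1  2 g_to  3 g_kr  4 g_ks  5 g_cal  6 k_naca  7 p_nak
# 8 g_pca 9 g_pk  10 g_bna 11 g_bca 12 tau_f_mult
N_MYO_PARAMS = 13

# Fibroblast parameter-vector layout (see cell_models.FibroblastParams)
# 0 g_k1  1 g_kv  2 g_bna  3 i_nak_max  4 kv_shift
N_FIB_PARAMS = 5

# Physical constants shared by both models
_RTONF = 8314.472 * 310.0 / 96485.3415  # mV

# Fixed extracellular / fibroblast-intracellular milieu
_KO = 5.4      # mM
_NAO = 140.0   # mM (myocyte bath)
_CAO = 2.0     # mM
_FIB_NAO = 130.011   # mM
_FIB_NAI = 8.5547    # mM
_FIB_KI = 129.4349   # mM

# TP06 cell geometry / capacitance scaling (native units of the model)
_CAP = 0.185
_VC = 0.016404
_VSR = 0.001094
_VSS = 0.00005468
_INV_VCF = 1.0 / (_VC * 96485.3415)
_INV_VCF2 = 1.0 / (2.0 * _VC * 96485.3415)
_INV_VSSF2 = 1.0 / (2.0 * _VSS * 96485.3415)


@njit(cache=True)
def myo_eval(y, p, i_ext, i_stim, d, ginf, gtau):
    """Fill ``d`` with dy/dt and ``ginf``/``gtau`` with gate targets.

    ``i_ext`` is the total positive-depolarizing external current density
    (stimulus + coupling, pA/pF); ``i_stim`` is the stimulus part alone,
    which additionally enters the K+ mass balance as in the source model.
    """
    v = y[0]
    m = y[1]
    h = y[2]
    j = y[3]
    xr1 = y[4]
    xr2 = y[5]
    xs = y[6]
    r = y[7]
    s = y[8]
    dd = y[9]
    f = y[10]
    f2 = y[11]
    fcass = y[12]
    rbar = y[13]
    cai = y[14]
    cass = y[15]
    casr = y[16]
    nai = y[17]
    ki = y[18]

    ek = _RTONF * math.log(_KO / ki)
    ena = _RTONF * math.log(_NAO / nai)
    eks = _RTONF * math.log((_KO + 0.03 * _NAO) / (ki + 0.03 * nai))
    eca = 0.5 * _RTONF * math.log(_CAO / cai)
    vfort = v / _RTONF

    # --- currents -----------------------------------------------------
    i_na = p[0] * m * m * m * h * j * (v - ena)

    ak1 = 0.1 / (1.0 + math.exp(0.06 * (v - ek - 200.0)))
    bk1 = (3.0 * math.exp(0.0002 * (v - ek + 100.0))
           + math.exp(0.1 * (v - ek - 10.0))) / (1.0 + math.exp(-0.5 * (v - ek)))
    i_k1 = p[1] * ak1 / (ak1 + bk1) * (v - ek)

    i_to = p[2] * r * s * (v - ek)
    i_kr = p[3] * math.sqrt(_KO / 5.4) * xr1 * xr2 * (v - ek)
    i_ks = p[4] * xs * xs * (v - eks)

    x = 2.0 * (v - 15.0) / _RTONF
    if abs(x) < 1e-7:
        # removable singularity of the GHK-type driving term
        i_cal = p[5] * dd * f * f2 * fcass * 2.0 * 96485.3415 * (0.25 * cass - _CAO)
    else:
        ex = math.exp(x)
        i_cal = (p[5] * dd * f * f2 * fcass * 4.0 * (v - 15.0)
                 * (96485.3415 / _RTONF) * (0.25 * cass * ex - _CAO) / (ex - 1.0))

    en = math.exp(0.35 * vfort)
    en1 = math.exp(-0.65 * vfort)
    i_naca = (p[6] * (en * nai * nai * nai * _CAO
                      - en1 * _NAO * _NAO * _NAO * cai * 2.5)
              / ((87.5 ** 3 + _NAO ** 3) * (1.38 + _CAO) * (1.0 + 0.1 * en1)))

    i_nak = (p[7] * _KO * nai / ((_KO + 1.0) * (nai + 40.0))
             / (1.0 + 0.1245 * math.exp(-0.1 * vfort) + 0.0353 * math.exp(-vfort)))

    i_pca = p[8] * cai / (cai + 0.0005)
    i_pk = p[9] * (v - ek) / (1.0 + math.exp((25.0 - v) / 5.98))
    i_bna = p[10] * (v - ena)
    i_bca = p[11] * (v - eca)

    i_ion = (i_na + i_to + i_k1 + i_kr + i_ks + i_cal + i_naca + i_nak
             + i_pca + i_pk + i_bca + i_bna)

    # --- gate kinetics ------------------------------------------------
    minf = 1.0 / (1.0 + math.exp((-56.86 - v) / 9.03))
    ginf[0] = minf * minf
    am = 1.0 / (1.0 + math.exp((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + math.exp((v + 35.0) / 5.0)) + 0.1 / (1.0 + math.exp((v - 50.0) / 200.0))
    gtau[0] = am * bm

    hinf = 1.0 / (1.0 + math.exp((v + 71.55) / 7.43))
    ginf[1] = hinf * hinf
    if v >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
    else:
        ah = 0.057 * math.exp(-(v + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.3485 * v)
    gtau[1] = 1.0 / (ah + bh)

    ginf[2] = ginf[1]
    if v >= -40.0:
        aj = 0.0
        bj = 0.6 * math.exp(0.057 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    else:
        aj = ((-2.5428e4 * math.exp(0.2444 * v) - 6.948e-6 * math.exp(-0.04391 * v))
              * (v + 37.78) / (1.0 + math.exp(0.311 * (v + 79.23))))
        bj = 0.02424 * math.exp(-0.01052 * v) / (1.0 + math.exp(-0.1378 * (v + 40.14)))
    gtau[2] = 1.0 / (aj + bj)

    ginf[3] = 1.0 / (1.0 + math.exp((-26.0 - v) / 7.0))
    axr1 = 450.0 / (1.0 + math.exp((-45.0 - v) / 10.0))
    bxr1 = 6.0 / (1.0 + math.exp((v + 30.0) / 11.5))
    gtau[3] = axr1 * bxr1

    ginf[4] = 1.0 / (1.0 + math.exp((v + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + math.exp((-60.0 - v) / 20.0))
    bxr2 = 1.12 / (1.0 + math.exp((v - 60.0) / 20.0))
    gtau[4] = axr2 * bxr2

    ginf[5] = 1.0 / (1.0 + math.exp((-5.0 - v) / 14.0))
    axs = 1400.0 / math.sqrt(1.0 + math.exp((5.0 - v) / 6.0))
    bxs = 1.0 / (1.0 + math.exp((v - 35.0) / 15.0))
    gtau[5] = axs * bxs + 80.0

    ginf[6] = 1.0 / (1.0 + math.exp((20.0 - v) / 6.0))
    gtau[6] = 9.5 * math.exp(-(v + 40.0) * (v + 40.0) / 1800.0) + 0.8

    # epicardial s gate
    ginf[7] = 1.0 / (1.0 + math.exp((v + 20.0) / 5.0))
    gtau[7] = (85.0 * math.exp(-(v + 45.0) * (v + 45.0) / 320.0)
               + 5.0 / (1.0 + math.exp((v - 20.0) / 5.0)) + 3.0)

    ginf[8] = 1.0 / (1.0 + math.exp((-8.0 - v) / 7.5))
    ad = 1.4 / (1.0 + math.exp((-35.0 - v) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + math.exp((v + 5.0) / 5.0))
    gd = 1.0 / (1.0 + math.exp((50.0 - v) / 20.0))
    gtau[8] = ad * bd + gd

    ginf[9] = 1.0 / (1.0 + math.exp((v + 20.0) / 7.0))
    tf = (1102.5 * math.exp(-(v + 27.0) * (v + 27.0) / 225.0)
          + 200.0 / (1.0 + math.exp((13.0 - v) / 10.0))
          + 180.0 / (1.0 + math.exp((v + 30.0) / 10.0)) + 20.0)
    if v > 0.0:
        tf = tf * p[12]  # restitution-slope variant: scaled ICaL inactivation
    gtau[9] = tf

    ginf[10] = 0.67 / (1.0 + math.exp((v + 35.0) / 7.0)) + 0.33
    gtau[10] = (562.0 * math.exp(-(v + 27.0) * (v + 27.0) / 240.0)
                + 31.0 / (1.0 + math.exp((25.0 - v) / 10.0))
                + 80.0 / (1.0 + math.exp((v + 30.0) / 10.0)))

    css = cass / 0.05
    ginf[11] = 0.6 / (1.0 + css * css) + 0.4
    gtau[11] = 80.0 / (1.0 + css * css) + 2.0

    # --- calcium handling ---------------------------------------------
    kcasr = 2.5 - 1.5 / (1.0 + (1.5 / casr) * (1.5 / casr))
    k1 = 0.15 / kcasr
    k2 = 0.045 * kcasr
    drbar = -k2 * cass * rbar + 0.005 * (1.0 - rbar)
    o = k1 * cass * cass * rbar / (0.06 + k1 * cass * cass)
    i_rel = 0.102 * o * (casr - cass)
    i_leak = 0.00036 * (casr - cai)
    i_up = 0.006375 / (1.0 + 0.00025 * 0.00025 / (cai * cai))
    i_xfer = 0.0038 * (cass - cai)

    bufc = 1.0 / (1.0 + 0.2 * 0.001 / ((cai + 0.001) * (cai + 0.001)))
    bufsr = 1.0 / (1.0 + 10.0 * 0.3 / ((casr + 0.3) * (casr + 0.3)))
    bufss = 1.0 / (1.0 + 0.4 * 0.00025 / ((cass + 0.00025) * (cass + 0.00025)))

    d[0] = -i_ion + i_ext
    for g in range(N_MYO_GATES):
        d[1 + g] = (ginf[g] - y[1 + g]) / gtau[g]
    d[13] = drbar
    d[14] = bufc * ((i_leak - i_up) * _VSR / _VC + i_xfer
                    - (i_bca + i_pca - 2.0 * i_naca) * _INV_VCF2 * _CAP)
    d[15] = bufss * (-i_cal * _INV_VSSF2 * _CAP + i_rel * _VSR / _VSS
                     - i_xfer * _VC / _VSS)
    d[16] = bufsr * (i_up - i_rel - i_leak)
    d[17] = -(i_na + i_bna + 3.0 * i_nak + 3.0 * i_naca) * _INV_VCF * _CAP
    # stimulus enters the K+ balance with the source model's (inward-negative)
    # sign convention: i_stim here is positive-depolarizing
    d[18] = -(i_k1 + i_to + i_kr + i_ks - 2.0 * i_nak + i_pk - i_stim) * _INV_VCF * _CAP


@njit(cache=True)
def fib_eval(y, p, i_ext, d, ginf, gtau):
    """MacCannell active-fibroblast derivative and Kv gate targets."""
    vf = y[0]
    r = y[1]
    s = y[2]

    ek = _RTONF * math.log(_KO / _FIB_KI)
    ena = _RTONF * math.log(_FIB_NAO / _FIB_NAI)

    vs = vf - p[4]  # kv_shift moves the IfKv gating curves along V
    ginf[0] = 1.0 / (1.0 + math.exp(-(vs + 20.0) / 11.0))
    gtau[0] = 20.3 + 138.0 * math.exp(-((vs + 20.0) / 25.9) ** 2)
    ginf[1] = 1.0 / (1.0 + math.exp((vs + 23.0) / 7.0))
    gtau[1] = 1574.0 + 5268.0 * math.exp(-((vs + 23.0) / 22.7) ** 2)

    i_kv = p[1] * r * s * (vf - ek)

    ak1 = 0.1 / (1.0 + math.exp(0.06 * (vf - ek - 200.0)))
    bk1 = (3.0 * math.exp(0.0002 * (vf - ek + 100.0))
           + math.exp(0.1 * (vf - ek - 10.0))) / (1.0 + math.exp(-0.5 * (vf - ek)))
    i_k1 = p[0] * ak1 / (ak1 + bk1) * (vf - ek)

    nai15 = _FIB_NAI ** 1.5
    i_nak = (p[3] * (_KO / (_KO + 1.0)) * (nai15 / (nai15 + 11.0 ** 1.5))
             * (vf + 150.0) / (vf + 200.0))

    i_bna = p[2] * (vf - ena)

    d[0] = -(i_kv + i_k1 + i_nak + i_bna) + i_ext
    d[1] = (ginf[0] - r) / gtau[0]
    d[2] = (ginf[1] - s) / gtau[1]


@njit(cache=True)
def _myo_step(y, p, i_ext, i_stim, dt, d, ginf, gtau):
    myo_eval(y, p, i_ext, i_stim, d, ginf, gtau)
    y[0] += dt * d[0]
    for g in range(N_MYO_GATES):
        i = 1 + g
        y[i] = ginf[g] + (y[i] - ginf[g]) * math.exp(-dt / gtau[g])
    for i in range(13, N_MYO):
        y[i] += dt * d[i]


@njit(cache=True)
def _fib_step(y, p, i_ext, dt, d, ginf, gtau):
    fib_eval(y, p, i_ext, d, ginf, gtau)
    y[0] += dt * d[0]
    for g in range(N_FIB_GATES):
        i = 1 + g
        y[i] = ginf[g] + (y[i] - ginf[g]) * math.exp(-dt / gtau[g])


@njit(cache=True)
def run_myocyte(y, p, stim_starts, dur_steps, amp, n_steps, dt, sample_every):
    """Fixed-step integration of one myocyte; mutates ``y`` to the final state.

    ``stim_starts`` are step indices (ascending); the stimulus is active for
    ``dur_steps`` steps from each.  Returns V sampled every ``sample_every``
    steps (the t=0 sample included).
    """
    n_out = n_steps // sample_every + 1
    vout = np.empty(n_out)
    d = np.empty(N_MYO)
    ginf = np.empty(N_MYO_GATES)
    gtau = np.empty(N_MYO_GATES)
    vout[0] = y[0]
    k = 0
    ns = stim_starts.shape[0]
    for step in range(n_steps):
        while k < ns and step >= stim_starts[k] + dur_steps:
            k += 1
        stim = amp if (k < ns and step >= stim_starts[k]) else 0.0
        _myo_step(y, p, stim, stim, dt, d, ginf, gtau)
        if not math.isfinite(y[0]):
            raise ValueError("non-finite membrane potential in myocyte integration")
        if (step + 1) % sample_every == 0:
            vout[(step + 1) // sample_every] = y[0]
    return vout


@njit(cache=True)
def run_fibroblast(y, p, i_ext, n_steps, dt, sample_every):
    """Fixed-step integration of one fibroblast under constant I_ext."""
    n_out = n_steps // sample_every + 1
    vout = np.empty(n_out)
    d = np.empty(N_FIB)
    ginf = np.empty(N_FIB_GATES)
    gtau = np.empty(N_FIB_GATES)
    vout[0] = y[0]
    for step in range(n_steps):
        _fib_step(y, p, i_ext, dt, d, ginf, gtau)
        if not math.isfinite(y[0]):
            raise ValueError("non-finite membrane potential in fibroblast integration")
        if (step + 1) % sample_every == 0:
            vout[(step + 1) // sample_every] = y[0]
    return vout


@njit(cache=True)
def run_motif(y, pm, pf, g_loc1, g_loc2, g_long1, g_long2, n_f, c_m, c_f,
              stim1_starts, stim2_starts, dur_steps, amp, n_steps, dt,
              sample_every):
    """Fixed-step integration of the 4-cell motif; mutates ``y`` in place.

    Coupling topology (i != j):
      myocyte i   <- N_f * [G_Loc_i (Vf_i - V_i) + G_Long_i (Vf_j - V_i)] / C_m
      fibroblast i <-       [G_Loc_i (V_i - Vf_i) + G_Long_j (V_j - Vf_i)] / C_f
    so the M1-F2 link carries G_Long1 and the M2-F1 link carries G_Long2.
    Returns (4, n_out) voltages for (M1, M2, F1, F2).
    """
    n_out = n_steps // sample_every + 1
    vout = np.empty((4, n_out))
    dm = np.empty(N_MYO)
    gim = np.empty(N_MYO_GATES)
    gtm = np.empty(N_MYO_GATES)
    df = np.empty(N_FIB)
    gif = np.empty(N_FIB_GATES)
    gtf = np.empty(N_FIB_GATES)

    m1 = y[0:N_MYO]
    m2 = y[N_MYO:2 * N_MYO]
    f1 = y[2 * N_MYO:2 * N_MYO + N_FIB]
    f2 = y[2 * N_MYO + N_FIB:]

    vout[0, 0] = m1[0]
    vout[1, 0] = m2[0]
    vout[2, 0] = f1[0]
    vout[3, 0] = f2[0]

    k1 = 0
    k2 = 0
    ns1 = stim1_starts.shape[0]
    ns2 = stim2_starts.shape[0]
    for step in range(n_steps):
        while k1 < ns1 and step >= stim1_starts[k1] + dur_steps:
            k1 += 1
        while k2 < ns2 and step >= stim2_starts[k2] + dur_steps:
            k2 += 1
        stim1 = amp if (k1 < ns1 and step >= stim1_starts[k1]) else 0.0
        stim2 = amp if (k2 < ns2 and step >= stim2_starts[k2]) else 0.0

        v1 = m1[0]
        v2 = m2[0]
        vf1 = f1[0]
        vf2 = f2[0]
        im1 = stim1 + n_f * (g_loc1 * (vf1 - v1) + g_long1 * (vf2 - v1)) / c_m
        im2 = stim2 + n_f * (g_loc2 * (vf2 - v2) + g_long2 * (vf1 - v2)) / c_m
        if1 = (g_loc1 * (v1 - vf1) + g_long2 * (v2 - vf1)) / c_f
        if2 = (g_loc2 * (v2 - vf2) + g_long1 * (v1 - vf2)) / c_f

        _myo_step(m1, pm, im1, stim1, dt, dm, gim, gtm)
        _myo_step(m2, pm, im2, stim2, dt, dm, gim, gtm)
        _fib_step(f1, pf, if1, dt, df, gif, gtf)
        _fib_step(f2, pf, if2, dt, df, gif, gtf)

        if not (math.isfinite(m1[0]) and math.isfinite(m2[0])
                and math.isfinite(f1[0]) and math.isfinite(f2[0])):
            raise ValueError("non-finite membrane potential in motif integration")

        if (step + 1) % sample_every == 0:
            i = (step + 1) // sample_every
            vout[0, i] = m1[0]
            vout[1, i] = m2[0]
            vout[2, i] = f1[0]
            vout[3, i] = f2[0]
    return vout


# Default initial state of the ventricular model (resting values the model
# was published with; the package re-equilibrates from here when asked).
MYO_INIT = np.array([
    -85.23,      # V
    0.00172,     # m
    0.7444,      # h
    0.7045,      # j
    0.00621,     # xr1
    0.4712,      # xr2
    0.0095,      # xs
    2.42e-8,     # r
    0.999998,    # s
    3.373e-5,    # d
    0.7888,      # f
    0.9755,      # f2
    0.9953,      # fcass
    0.9073,      # rbar
    0.000126,    # Cai (mM)
    0.00036,     # CaSS (mM)
    3.64,        # CaSR (mM)
    8.604,       # Nai (mM)
    136.89,      # Ki (mM)
])

FIB_INIT = np.array([
    -49.6,       # Vf
    0.06,        # r (Kv activation)
    0.98,        # s (Kv inactivation)
])
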