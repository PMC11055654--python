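"""Numba integration kernels for the single-compartment conductance model.

Units: mV, ms, nS, pF, pA (nS·mV = pA, pF·mV/ms = pA).

Integration scheme: Strang splitting — Rush–Larsen half-steps for the
gating variables around an exponential-Euler membrane update whose
conductances are evaluated at a midpoint voltage. The scheme is stable
through the stiff spike upstroke and second-order accurate, which keeps
spike counts invariant under time-step halving at the default step.

State variables: V (mV), h (Na fast inactivation), n (K activation),
s (Na slow inactivation), w (low-threshold K activation), r (HCN
activation).
"""

import numpy as np
from numba import njit

# parameter-vector layout (see ArchetypeParams.to_array)
P_CM = 0; P_GL = 1; P_EL = 2
P_GNA = 3; P_ENA = 4; P_GK = 5; P_EK = 6; P_SHNA = 7; P_SHK = 8
P_GKLT = 9; P_VW = 10; P_KW = 11; P_TAUW = 12
P_GH = 13; P_EH = 14; P_VR = 15; P_KR = 16
P_TR0 = 17; P_TRAMP = 18; P_TRVH = 19; P_TRK = 20
P_DEPTH = 21; P_VS = 22; P_KS = 23; P_TAUS = 24
P_SIGI = 25; P_TAUC = 26; P_TAUN_SCALE = 27
NPARAMS = 28

_MAX_SPIKES = 8192
_SPIKE_CROSS_MV = 0.0  # ground-truth spike criterion: upward 0 mV crossing


@njit(cache=False)
def _vtrap(x, y):
    """x / (1 - exp(-x/y)), continuous through x = 0."""
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / y / 2.0)
    return x / (1.0 - np.exp(-x / y))


@njit(cache=False)
def _m_inf(v, sh):
    vv = v - sh
    am = 0.1 * _vtrap(vv + 35.0, 10.0)
    bm = 4.0 * np.exp(-(vv + 60.0) / 18.0)
    return am / (am + bm)


@njit(cache=False)
def _h_gate(v, sh):
    vv = v - sh
    ah = 0.35 * np.exp(-(vv + 58.0) / 20.0)
    bh = 5.0 / (1.0 + np.exp(-(vv + 28.0) / 10.0))
    s = ah + bh
    return ah / s, 1.0 / s


@njit(cache=False)
def _n_gate(v, sh):
    vv = v - sh
    an = 0.05 * _vtrap(vv + 34.0, 10.0)
    bn = 0.625 * np.exp(-(vv + 44.0) / 80.0)
    s = an + bn
    return an / s, 1.0 / s


@njit(cache=False)
def _w_inf(v, vw, kw):
    return 1.0 / (1.0 + np.exp(-(v - vw) / kw))


@njit(cache=False)
def _r_gate(v, p):
    rinf = 1.0 / (1.0 + np.exp((v - p[P_VR]) / p[P_KR]))
    tau = p[P_TR0] + p[P_TRAMP] / (1.0 + np.exp(-(v - p[P_TRVH]) / p[P_TRK]))
    return rinf, tau


@njit(cache=False)
def _s_inf(v, depth, vs, ks):
    return 1.0 - depth / (1.0 + np.exp(-(v - vs) / ks))


@njit(cache=False)
def steady_gates(v, p):
    """Gating steady states at a fixed voltage."""
    hinf, _ = _h_gate(v, p[P_SHNA])
    ninf, _ = _n_gate(v, p[P_SHK])
    winf = _w_inf(v, p[P_VW], p[P_KW])
    rinf, _ = _r_gate(v, p)
    sinf = _s_inf(v, p[P_DEPTH], p[P_VS], p[P_KS])
    return hinf, ninf, sinf, winf, rinf


@njit(cache=False)
def ionic_current(v, h, n, s, w, r, p):
    """Total ionic current (pA, outward positive) at a given state."""
    m = _m_inf(v, p[P_SHNA])
    i_na = p[P_GNA] * m * m * m * h * s * (v - p[P_ENA])
    i_k = p[P_GK] * n ** 4 * (v - p[P_EK])
    i_klt = p[P_GKLT] * w * (v - p[P_EK])
    i_h = p[P_GH] * r * (v - p[P_EH])
    i_l = p[P_GL] * (v - p[P_EL])
    return i_na + i_k + i_klt + i_h + i_l


@njit(cache=False, inline="always")
def _gates_half(v, h, n_, s, w, r, p, hdt):
    """Rush–Larsen half-step for all gating variables at voltage v."""
    hinf, tauh = _h_gate(v, p[P_SHNA])
    ninf, taun = _n_gate(v, p[P_SHK])
    taun *= p[P_TAUN_SCALE]
    winf = _w_inf(v, p[P_VW], p[P_KW])
    rinf, taur = _r_gate(v, p)
    sinf = _s_inf(v, p[P_DEPTH], p[P_VS], p[P_KS])
    h += (hinf - h) * (1.0 - np.exp(-hdt / tauh))
    n_ += (ninf - n_) * (1.0 - np.exp(-hdt / taun))
    w += (winf - w) * (1.0 - np.exp(-hdt / p[P_TAUW]))
    r += (rinf - r) * (1.0 - np.exp(-hdt / taur))
    s += (sinf - s) * (1.0 - np.exp(-hdt / p[P_TAUS]))
    return h, n_, s, w, r


@njit(cache=False)
def cc_kernel(p, dt, decim, cmd, noise, v0, h0, n0, s0, w0, r0,
              v_out, spike_times):
    """Current-clamp integration.

    cmd: injected current (pA) per output sample, held constant over the
    decim substeps that follow that sample. noise: standard-normal array
    of length len(cmd)*decim (ignored when sigI == 0). v_out is filled
    with the membrane potential at output resolution; spike_times
    receives ground-truth upward 0 mV crossing times (ms).

    Returns (n_spikes, err_step): err_step >= 0 flags the first substep
    at which the state became non-finite (-1 when integration is clean).
    """
    n_out = cmd.shape[0]
    v = v0; h = h0; n_ = n0; s = s0; w = w0; r = r0
    cm = p[P_CM]
    sig = p[P_SIGI]
    sqdt = np.sqrt(dt)
    hdt = dt / 2.0
    nspk = 0
    gstep = 0
    for j in range(n_out):
        v_out[j] = v
        i_inj = cmd[j]
        for k in range(decim):
            h, n_, s, w, r = _gates_half(v, h, n_, s, w, r, p, hdt)
            i_noise = 0.0
            if sig > 0.0:
                i_noise = sig * noise[gstep] / sqdt

            m = _m_inf(v, p[P_SHNA])
            gna = p[P_GNA] * m * m * m * h * s
            gk = p[P_GK] * n_ ** 4
            gklt = p[P_GKLT] * w
            gh = p[P_GH] * r
            gtot = p[P_GL] + gna + gk + gklt + gh
            e_eff = (p[P_GL] * p[P_EL] + gna * p[P_ENA]
                     + (gk + gklt) * p[P_EK] + gh * p[P_EH]
                     + i_inj + i_noise) / gtot
            v_mid = e_eff + (v - e_eff) * np.exp(-hdt * gtot / cm)

            m = _m_inf(v_mid, p[P_SHNA])
            gna = p[P_GNA] * m * m * m * h * s
            gtot = p[P_GL] + gna + gk + gklt + gh
            e_eff = (p[P_GL] * p[P_EL] + gna * p[P_ENA]
                     + (gk + gklt) * p[P_EK] + gh * p[P_EH]
                     + i_inj + i_noise) / gtot
            v_new = e_eff + (v - e_eff) * np.exp(-dt * gtot / cm)

            h, n_, s, w, r = _gates_half(v_new, h, n_, s, w, r, p, hdt)

            if v < _SPIKE_CROSS_MV and v_new >= _SPIKE_CROSS_MV:
                if nspk < _MAX_SPIKES:
                    spike_times[nspk] = (gstep + 1) * dt
                nspk += 1
            v = v_new
            gstep += 1
        if not np.isfinite(v):
            return nspk, gstep
    return nspk, -1


@njit(cache=False)
def vc_kernel(p, dt, decim, vcmd, v0, h0, n0, s0, w0, r0, i_out):
    """Voltage-clamp integration.

    The clamp drives V toward the command with first-order settling
    (tau = p[P_TAUC], ms); the recorded current is the total membrane
    current: ionic plus capacitive. Returns err_step as in cc_kernel.
    """
    n_out = vcmd.shape[0]
    v = v0; h = h0; n_ = n0; s = s0; w = w0; r = r0
    cm = p[P_CM]
    tauc = p[P_TAUC]
    a_clamp = 1.0 - np.exp(-dt / tauc)
    hdt = dt / 2.0
    gstep = 0
    for j in range(n_out):
        vc = vcmd[j]
        # recorded current at the output sample: ionic + capacitive
        i_out[j] = ionic_current(v, h, n_, s, w, r, p) + cm * (vc - v) * a_clamp / dt
        if not np.isfinite(i_out[j]):
            return gstep
        for k in range(decim):
            h, n_, s, w, r = _gates_half(v, h, n_, s, w, r, p, hdt)
            v += (vc - v) * a_clamp
            h, n_, s, w, r = _gates_half(v, h, n_, s, w, r, p, hdt)
            gstep += 1
    return -1
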