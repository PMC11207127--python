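"""Vectorized numba kernel for the network integrator.

Implementation detail of :mod:`tcsleep.engine`.  Voltage-dependent gating
is advanced with exact exponential (Rush-Larsen) updates whose steady
states and per-step decay factors exp(-dt/tau) are linearly interpolated
from dense lookup tables (0.05 mV grid) built from
:func:`tcsleep.channels.eval_kinetics`, so the kernel shares one set of
rate functions with the reference single-cell models.

Synaptic state is tracked per *presynaptic* cell (all connections from one
source share identical kinetics and pulse clocks), and per-target inputs
are windowed sums over contiguous source ranges computed with prefix sums.
Short-term depression D is updated per presynaptic spike and multiplies
the source's open fraction in the sum.

Layout (column indices):

ctx_state: 0 VD, 1 VS, 2 mNaD, 3 hNaD, 4 mKm, 5 mKCa, 6 mHVA, 7 hHVA,
           8 Ca, 9 mNaS, 10 hNaS, 11 nK
ctx_param: 0 g_nap_d, 1 g_km, 2 g_sd, 3 syn_fac, 4 ca_influx, 5 g_nap_s,
           6 is_py, 7 g_mini
ctx_syn:   0 O_tr, 1 O_nmda, 2 D, 3 pulse_end, 4 last_spike_t,
           5 O_mini, 6 mini_pulse_end
ctx_kin:   0 a_off, 1 a_on, 2 O_inf, 3 U, 4 alphaA, 5 beta
th_state:  0 V, 1 mNa, 2 hNa, 3 nK, 4 mT, 5 hT, 6 O_h, 7 P1, 8 OL, 9 Ca
th_syn:    0 O_tr, 1 R, 2 G, 3 pulse_end
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# gate table rows
G_PYNA_M, G_PYNA_H, G_PYK_N, G_PYKM_M, G_HVA_M, G_HVA_H, G_NAP_M = range(7)
G_TCNA_M, G_TCNA_H, G_TCK_N, G_TCT_M, G_TCT_H, G_RET_M, G_RET_H = range(7, 14)
N_GATES = 14

# scalar parameter indices (sc array)
(S_DT, S_ENA, S_EK, S_EH, S_ECA,
 S_GL_CTX, S_EL_CTX, S_GKL_CTX, S_GNA_D, S_GHVA, S_GKCA,
 S_GNA_S, S_GK_S, S_GDS, S_CM_CTX, S_CA_REST, S_CA_TAU_CTX, S_QT,
 S_GNA_TC, S_GK_TC, S_GT_TC, S_GH_TC, S_GKL_TC, S_GL_TC, S_EL_TC,
 S_GNA_RE, S_GK_RE, S_GT_RE, S_GKL_RE, S_GL_RE, S_EL_RE,
 S_CM_TH, S_CA_TAU_TH, S_CA_INFLUX_TH,
 S_IH_K1, S_IH_K2, S_IH_K3, S_IH_K4, S_IH_GINC,
 S_SYNFAC_TH, S_TMAX,
 S_AMPA_AOFF, S_AMPA_AON, S_AMPA_OINF, S_AMPA_ALPHA_A, S_AMPA_BETA,
 S_NMDA_AOFF, S_NMDA_AON, S_NMDA_OINF, S_NMDA_ALPHA_A, S_NMDA_BETA,
 S_GABA_AOFF, S_GABA_AON, S_GABA_OINF, S_GABA_ALPHA_A, S_GABA_BETA,
 S_GB_AOFF, S_GB_AON, S_GB_RINF, S_GB_K1A, S_GB_K2,
 S_GB_EK4, S_GB_CK3, S_GB_KD,
 S_NMDA_SIG, S_NMDA_VTH, S_GSN, S_DEP_TAU, S_EGABAA, S_EGABAA_TH,
 ) = range(70)
N_SCALARS = 70


@njit(cache=True, inline="always")
def _gpos(V, v0, inv_dv, nv):
    u = (V - v0) * inv_dv
    if u < 0.0:
        u = 0.0
    elif u > nv - 1.001:
        u = nv - 1.001
    pos = int(u)
    return pos, u - pos


@njit(cache=True, inline="always")
def _tab(tab, row, pos, frac):
    return tab[row, pos] * (1.0 - frac) + tab[row, pos + 1] * frac


@njit(cache=True, inline="always")
def _o_step(O, pulse_end, t, dt, a_off, a_on, O_inf, alphaA, beta):
    te = t + dt
    if pulse_end <= t:
        return O * a_off
    if pulse_end >= te:
        return O_inf + (O - O_inf) * a_on
    d1 = pulse_end - t
    O1 = O_inf + (O - O_inf) * math.exp(-(alphaA + beta) * d1)
    return O1 * math.exp(-beta * (dt - d1))


@njit(cache=True)
def run_chunk(
    nsteps, t0, step0,
    npy, nin, ntc, nre,
    sc,
    ctx_state, ctx_param, ctx_syn, ctx_kin,
    th_state, th_syn,
    minf_tab, aexp_tab, tch_inf, tch_tau, v0, inv_dv,
    # projection windows (lo/hi inclusive, per-target conductance uS)
    pypy_lo, pypy_hi, gw_pypy_a, gw_pypy_n,
    inpy_lo, inpy_hi, gw_inpy,
    tcpy_lo, tcpy_hi, gw_tcpy,
    pyin_lo, pyin_hi, gw_pyin_a, gw_pyin_n,
    tcin_lo, tcin_hi, gw_tcin,
    pytc_lo, pytc_hi, gw_pytc,
    retc_lo, retc_hi, gw_retc_a, gw_retc_b,
    tcre_lo, tcre_hi, gw_tcre,
    pyre_lo, pyre_hi, gw_pyre,
    rere_lo, rere_hi, gw_rere,
    # scratch prefix arrays
    pf_py_ad, pf_py_a, pf_py_n, pf_in, pf_tc, pf_re, pf_regb,
    # event inputs
    mini_cells, mini_steps, sn_steps, sn_state,
    # outputs
    spike_t, spike_layer, spike_idx,
    rec_every, lfp_out, rec0,
    vrec_ctx_idx, vrec_th_idx, vrec_out,
):
    dt = sc[S_DT]
    nv = minf_tab.shape[1]
    n_ctx = npy + nin
    n_th = ntc + nre
    n_spk = 0
    mini_ptr = 0
    sn_ptr = 0
    tmax = sc[S_TMAX]
    ena = sc[S_ENA]
    ek = sc[S_EK]
    egabaa = sc[S_EGABAA]

    for k in range(nsteps):
        t = t0 + k * dt

        # -- scheduled transmitter events -------------------------------
        while mini_ptr < mini_steps.shape[0] and mini_steps[mini_ptr] <= k:
            ctx_syn[mini_cells[mini_ptr], 6] = t + tmax
            mini_ptr += 1
        while sn_ptr < sn_steps.shape[0] and sn_steps[sn_ptr] <= k:
            sn_state[1] = t + tmax
            sn_ptr += 1
        sn_state[0] = _o_step(
            sn_state[0], sn_state[1], t, dt,
            sc[S_AMPA_AOFF], sc[S_AMPA_AON], sc[S_AMPA_OINF],
            sc[S_AMPA_ALPHA_A], sc[S_AMPA_BETA],
        )

        # -- prefix sums over presynaptic open fractions -----------------
        acc = 0.0
        for i in range(npy):
            pf_py_ad[i] = acc
            acc += ctx_syn[i, 0] * ctx_syn[i, 2]     # depressed AMPA
        pf_py_ad[npy] = acc
        acc = 0.0
        for i in range(npy):
            pf_py_a[i] = acc
            acc += ctx_syn[i, 0]                     # undepressed AMPA
        pf_py_a[npy] = acc
        acc = 0.0
        for i in range(npy):
            pf_py_n[i] = acc
            acc += ctx_syn[i, 1]                     # NMDA
        pf_py_n[npy] = acc
        acc = 0.0
        for i in range(nin):
            pf_in[i] = acc
            acc += ctx_syn[npy + i, 0] * ctx_syn[npy + i, 2]
        pf_in[nin] = acc
        acc = 0.0
        for i in range(ntc):
            pf_tc[i] = acc
            acc += th_syn[i, 0]
        pf_tc[ntc] = acc
        acc = 0.0
        for i in range(nre):
            pf_re[i] = acc
            acc += th_syn[ntc + i, 0]
        pf_re[nre] = acc
        acc = 0.0
        kd = sc[S_GB_KD]
        for i in range(nre):
            pf_regb[i] = acc
            g4 = th_syn[ntc + i, 2] ** 4
            acc += g4 / (g4 + kd)
        pf_regb[nre] = acc

        lfp = 0.0

        # -- cortical cells ----------------------------------------------
        for c in range(n_ctx):
            VD = ctx_state[c, 0]
            VS = ctx_state[c, 1]
            is_py = ctx_param[c, 6] > 0.5

            # synaptic conductances (uS)
            if is_py:
                j = c
                sA = pf_py_ad[pypy_hi[j] + 1] - pf_py_ad[pypy_lo[j]]
                sN = pf_py_n[pypy_hi[j] + 1] - pf_py_n[pypy_lo[j]]
                if pypy_lo[j] <= j <= pypy_hi[j]:
                    sA -= ctx_syn[j, 0] * ctx_syn[j, 2]
                    sN -= ctx_syn[j, 1]
                gA = gw_pypy_a[j] * sA + gw_tcpy[j] * (
                    pf_tc[tcpy_hi[j] + 1] - pf_tc[tcpy_lo[j]]
                )
                gN = gw_pypy_n[j] * sN
                gG = gw_inpy[j] * (pf_in[inpy_hi[j] + 1] - pf_in[inpy_lo[j]])
            else:
                j = c - npy
                sA = pf_py_ad[pyin_hi[j] + 1] - pf_py_ad[pyin_lo[j]]
                sN = pf_py_n[pyin_hi[j] + 1] - pf_py_n[pyin_lo[j]]
                gA = gw_pyin_a[j] * sA + gw_tcin[j] * (
                    pf_tc[tcin_hi[j] + 1] - pf_tc[tcin_lo[j]]
                )
                gN = gw_pyin_n[j] * sN
                gG = 0.0
            gA += ctx_param[c, 7] * ctx_syn[c, 5]    # mini drive

            fN = 1.0 / (1.0 + math.exp(-(VD - sc[S_NMDA_VTH]) / sc[S_NMDA_SIG]))
            iA = gA * VD                              # E_AMPA = 0
            iN = gN * fN * VD
            iG = gG * (VD - egabaa)
            i_syn_nA = iA + iN + iG
            if is_py:
                lfp -= i_syn_nA

            # gate table position for the dendrite
            pos, frac = _gpos(VD, v0, inv_dv, nv)
            Ca = ctx_state[c, 8]

            mNaD = ctx_state[c, 2]
            hNaD = ctx_state[c, 3]
            mKm = ctx_state[c, 4]
            mKCa = ctx_state[c, 5]
            mHVA = ctx_state[c, 6]
            hHVA = ctx_state[c, 7]
            nap_m = _tab(minf_tab, G_NAP_M, pos, frac)

            I_na = sc[S_GNA_D] * mNaD ** 3 * hNaD * (VD - ena)
            I_nap = ctx_param[c, 0] * nap_m * (VD - ena)
            I_kl = sc[S_GKL_CTX] * (VD - ek)
            I_hva = sc[S_GHVA] * mHVA * mHVA * hHVA * (VD - sc[S_ECA])
            I_kca = sc[S_GKCA] * mKCa * (VD - ek)
            I_km = ctx_param[c, 1] * mKm * (VD - ek)
            I_int = I_na + I_nap + I_kl + I_hva + I_kca + I_km

            dVD = (
                -sc[S_GL_CTX] * (VD - sc[S_EL_CTX])
                - ctx_param[c, 2] * (VD - VS)
                - I_int
                - i_syn_nA * ctx_param[c, 3]
            ) / sc[S_CM_CTX]
            VD_new = VD + dt * dVD

            # calcium pool (fed by I_HVA) and Ca-dependent K gate (Euler)
            Ca_new = Ca + dt * (
                -ctx_param[c, 4] * I_hva - (Ca - sc[S_CA_REST]) / sc[S_CA_TAU_CTX]
            )
            if Ca_new < 0.0:
                Ca_new = 0.0
            a_kca = 0.01 * Ca
            ctx_state[c, 5] = mKCa + dt * sc[S_QT] * (
                a_kca * (1.0 - mKCa) - 0.02 * mKCa
            )
            ctx_state[c, 8] = Ca_new

            # dendritic gating (tables at pre-step VD)
            ctx_state[c, 2] = _tab(minf_tab, G_PYNA_M, pos, frac) + (
                mNaD - _tab(minf_tab, G_PYNA_M, pos, frac)
            ) * _tab(aexp_tab, G_PYNA_M, pos, frac)
            ctx_state[c, 3] = _tab(minf_tab, G_PYNA_H, pos, frac) + (
                hNaD - _tab(minf_tab, G_PYNA_H, pos, frac)
            ) * _tab(aexp_tab, G_PYNA_H, pos, frac)
            ctx_state[c, 4] = _tab(minf_tab, G_PYKM_M, pos, frac) + (
                mKm - _tab(minf_tab, G_PYKM_M, pos, frac)
            ) * _tab(aexp_tab, G_PYKM_M, pos, frac)
            ctx_state[c, 6] = _tab(minf_tab, G_HVA_M, pos, frac) + (
                mHVA - _tab(minf_tab, G_HVA_M, pos, frac)
            ) * _tab(aexp_tab, G_HVA_M, pos, frac)
            ctx_state[c, 7] = _tab(minf_tab, G_HVA_H, pos, frac) + (
                hHVA - _tab(minf_tab, G_HVA_H, pos, frac)
            ) * _tab(aexp_tab, G_HVA_H, pos, frac)

            # quasi-stationary soma: damped fixed point (linear in VS for
            # frozen gating; only the instantaneous Nap term varies)
            mNaS = ctx_state[c, 9]
            hNaS = ctx_state[c, 10]
            nK = ctx_state[c, 11]
            g_na = sc[S_GNA_S] * mNaS ** 3 * hNaS
            g_k = sc[S_GK_S] * nK
            gds = sc[S_GDS]
            Vs = VS
            for _ in range(3):
                posS, fracS = _gpos(Vs, v0, inv_dv, nv)
                g_nap = ctx_param[c, 5] * _tab(minf_tab, G_NAP_M, posS, fracS)
                Vs_new = (gds * VD_new + (g_na + g_nap) * ena + g_k * ek) / (
                    gds + g_na + g_nap + g_k
                )
                Vs = Vs + 0.7 * (Vs_new - Vs)
            VS_new = Vs

            posS, fracS = _gpos(VS_new, v0, inv_dv, nv)
            ctx_state[c, 9] = _tab(minf_tab, G_PYNA_M, posS, fracS) + (
                mNaS - _tab(minf_tab, G_PYNA_M, posS, fracS)
            ) * _tab(aexp_tab, G_PYNA_M, posS, fracS)
            ctx_state[c, 10] = _tab(minf_tab, G_PYNA_H, posS, fracS) + (
                hNaS - _tab(minf_tab, G_PYNA_H, posS, fracS)
            ) * _tab(aexp_tab, G_PYNA_H, posS, fracS)
            ctx_state[c, 11] = _tab(minf_tab, G_PYK_N, posS, fracS) + (
                nK - _tab(minf_tab, G_PYK_N, posS, fracS)
            ) * _tab(aexp_tab, G_PYK_N, posS, fracS)

            ctx_state[c, 0] = VD_new
            ctx_state[c, 1] = VS_new

            # presynaptic spike -> transmitter pulse + depression update
            if VS < 0.0 and VS_new >= 0.0:
                ts = t + dt
                spike_t[n_spk] = ts
                spike_layer[n_spk] = 0 if is_py else 1
                spike_idx[n_spk] = c if is_py else c - npy
                n_spk += 1
                dt_sp = ts - ctx_syn[c, 4]
                U = ctx_kin[c, 3]
                D = ctx_syn[c, 2]
                ctx_syn[c, 2] = 1.0 - (1.0 - D * (1.0 - U)) * math.exp(
                    -dt_sp / sc[S_DEP_TAU]
                )
                ctx_syn[c, 4] = ts
                ctx_syn[c, 3] = ts + tmax

            # transmitter open fractions (per presynaptic cell)
            pe = ctx_syn[c, 3]
            ctx_syn[c, 0] = _o_step(
                ctx_syn[c, 0], pe, t, dt,
                ctx_kin[c, 0], ctx_kin[c, 1], ctx_kin[c, 2],
                ctx_kin[c, 4], ctx_kin[c, 5],
            )
            if is_py:
                ctx_syn[c, 1] = _o_step(
                    ctx_syn[c, 1], pe, t, dt,
                    sc[S_NMDA_AOFF], sc[S_NMDA_AON], sc[S_NMDA_OINF],
                    sc[S_NMDA_ALPHA_A], sc[S_NMDA_BETA],
                )
            ctx_syn[c, 5] = _o_step(
                ctx_syn[c, 5], ctx_syn[c, 6], t, dt,
                sc[S_AMPA_AOFF], sc[S_AMPA_AON], sc[S_AMPA_OINF],
                sc[S_AMPA_ALPHA_A], sc[S_AMPA_BETA],
            )

        # -- thalamic cells ----------------------------------------------
        for c in range(n_th):
            V = th_state[c, 0]
            is_tc = c < ntc

            if is_tc:
                j = c
                gA = gw_pytc[j] * (pf_py_a[pytc_hi[j] + 1] - pf_py_a[pytc_lo[j]])
                gA += sc[S_GSN] * sn_state[0]
                gGA = gw_retc_a[j] * (pf_re[retc_hi[j] + 1] - pf_re[retc_lo[j]])
                gGB = gw_retc_b[j] * (pf_regb[retc_hi[j] + 1] - pf_regb[retc_lo[j]])
            else:
                j = c - ntc
                gA = gw_tcre[j] * (pf_tc[tcre_hi[j] + 1] - pf_tc[tcre_lo[j]])
                gA += gw_pyre[j] * (pf_py_a[pyre_hi[j] + 1] - pf_py_a[pyre_lo[j]])
                sG = pf_re[rere_hi[j] + 1] - pf_re[rere_lo[j]]
                if rere_lo[j] <= j <= rere_hi[j]:
                    sG -= th_syn[ntc + j, 0]
                gGA = gw_rere[j] * sG
                gGB = 0.0

            ega = sc[S_EGABAA_TH] if is_tc else sc[S_EGABAA]
            i_syn_nA = gA * V + gGA * (V - ega) + gGB * (V - ek)

            pos, frac = _gpos(V, v0, inv_dv, nv)
            mNa = th_state[c, 1]
            hNa = th_state[c, 2]
            nK = th_state[c, 3]
            mT = th_state[c, 4]
            hT = th_state[c, 5]
            Ca = th_state[c, 9]

            if is_tc:
                g_na, g_k, g_t = sc[S_GNA_TC], sc[S_GK_TC], sc[S_GT_TC]
                g_kl, g_l, e_l = sc[S_GKL_TC], sc[S_GL_TC], sc[S_EL_TC]
                rm, rh = G_TCT_M, G_TCT_H
            else:
                g_na, g_k, g_t = sc[S_GNA_RE], sc[S_GK_RE], sc[S_GT_RE]
                g_kl, g_l, e_l = sc[S_GKL_RE], sc[S_GL_RE], sc[S_EL_RE]
                rm, rh = G_RET_M, G_RET_H

            I_na = g_na * mNa ** 3 * hNa * (V - ena)
            I_k = g_k * nK ** 4 * (V - ek)
            I_t = g_t * mT * mT * hT * (V - sc[S_ECA])
            I_kl = g_kl * (V - ek)
            I_int = I_na + I_k + I_t + I_kl

            O_h = th_state[c, 6]
            P1 = th_state[c, 7]
            OL = th_state[c, 8]
            if is_tc and sc[S_GH_TC] > 0.0:
                I_int += sc[S_GH_TC] * (O_h + sc[S_IH_GINC] * OL) * (V - sc[S_EH])

            dV = (
                -g_l * (V - e_l) - I_int - i_syn_nA * sc[S_SYNFAC_TH]
            ) / sc[S_CM_TH]
            V_new = V + dt * dV

            # gating
            th_state[c, 1] = _tab(minf_tab, G_TCNA_M, pos, frac) + (
                mNa - _tab(minf_tab, G_TCNA_M, pos, frac)
            ) * _tab(aexp_tab, G_TCNA_M, pos, frac)
            th_state[c, 2] = _tab(minf_tab, G_TCNA_H, pos, frac) + (
                hNa - _tab(minf_tab, G_TCNA_H, pos, frac)
            ) * _tab(aexp_tab, G_TCNA_H, pos, frac)
            th_state[c, 3] = _tab(minf_tab, G_TCK_N, pos, frac) + (
                nK - _tab(minf_tab, G_TCK_N, pos, frac)
            ) * _tab(aexp_tab, G_TCK_N, pos, frac)
            th_state[c, 4] = _tab(minf_tab, rm, pos, frac) + (
                mT - _tab(minf_tab, rm, pos, frac)
            ) * _tab(aexp_tab, rm, pos, frac)
            th_state[c, 5] = _tab(minf_tab, rh, pos, frac) + (
                hT - _tab(minf_tab, rh, pos, frac)
            ) * _tab(aexp_tab, rh, pos, frac)

            # calcium pool fed by I_T
            Ca_new = Ca + dt * (
                -sc[S_CA_INFLUX_TH] * I_t - (Ca - sc[S_CA_REST]) / sc[S_CA_TAU_TH]
            )
            if Ca_new < 0.0:
                Ca_new = 0.0
            th_state[c, 9] = Ca_new

            # I_h open / locked fractions
            if is_tc and sc[S_GH_TC] > 0.0:
                hinf = tch_inf[pos] * (1.0 - frac) + tch_inf[pos + 1] * frac
                taus = tch_tau[pos] * (1.0 - frac) + tch_tau[pos + 1] * frac
                alpha = hinf / taus
                beta = (1.0 - hinf) / taus
                k3, k4 = sc[S_IH_K3], sc[S_IH_K4]
                A = alpha * (1.0 - OL) + k4 * OL
                B = alpha + beta + k3 * P1
                O_new = A / B + (O_h - A / B) * math.exp(-B * dt)
                r = sc[S_IH_K1] * Ca * Ca * Ca * Ca
                lam = r + sc[S_IH_K2]
                P1_new = r / lam + (P1 - r / lam) * math.exp(-lam * dt)
                drive = k3 * P1 * O_h
                OL_new = drive / k4 + (OL - drive / k4) * math.exp(-k4 * dt)
                if O_new < 0.0:
                    O_new = 0.0
                elif O_new > 1.0:
                    O_new = 1.0
                if OL_new < 0.0:
                    OL_new = 0.0
                elif OL_new > 1.0 - O_new:
                    OL_new = 1.0 - O_new
                if P1_new < 0.0:
                    P1_new = 0.0
                elif P1_new > 1.0:
                    P1_new = 1.0
                th_state[c, 6] = O_new
                th_state[c, 7] = P1_new
                th_state[c, 8] = OL_new

            th_state[c, 0] = V_new

            # spike -> transmitter pulse (TC: AMPA; RE: GABA_A + GABA_B)
            if V < 0.0 and V_new >= 0.0:
                ts = t + dt
                spike_t[n_spk] = ts
                spike_layer[n_spk] = 2 if is_tc else 3
                spike_idx[n_spk] = c if is_tc else c - ntc
                n_spk += 1
                th_syn[c, 3] = ts + tmax

            pe = th_syn[c, 3]
            if is_tc:
                th_syn[c, 0] = _o_step(
                    th_syn[c, 0], pe, t, dt,
                    sc[S_AMPA_AOFF], sc[S_AMPA_AON], sc[S_AMPA_OINF],
                    sc[S_AMPA_ALPHA_A], sc[S_AMPA_BETA],
                )
            else:
                th_syn[c, 0] = _o_step(
                    th_syn[c, 0], pe, t, dt,
                    sc[S_GABA_AOFF], sc[S_GABA_AON], sc[S_GABA_OINF],
                    sc[S_GABA_ALPHA_A], sc[S_GABA_BETA],
                )
                R = _o_step(
                    th_syn[c, 1], pe, t, dt,
                    sc[S_GB_AOFF], sc[S_GB_AON], sc[S_GB_RINF],
                    sc[S_GB_K1A], sc[S_GB_K2],
                )
                th_syn[c, 2] = th_syn[c, 2] * sc[S_GB_EK4] + sc[S_GB_CK3] * th_syn[c, 1]
                th_syn[c, 1] = R

        # -- recording (chunks are aligned to rec_every) ------------------
        if (k + 1) % rec_every == 0:
            ri = rec0 + (k + 1) // rec_every - 1
            if 0 <= ri < lfp_out.shape[0]:
                lfp_out[ri] = lfp
                for q in range(vrec_ctx_idx.shape[0]):
                    vrec_out[q, ri] = ctx_state[vrec_ctx_idx[q], 0]
                nq = vrec_ctx_idx.shape[0]
                for q in range(vrec_th_idx.shape[0]):
                    vrec_out[nq + q, ri] = th_state[vrec_th_idx[q], 0]

    return n_spk
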