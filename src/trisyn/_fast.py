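"""Numba-compiled right-hand side.

A flat-parameter mirror of :func:`trisyn.simulate.full_rhs`, used by the
integrator for speed (the action-potential phases need ~1e6 solver steps).
The readable object-based implementation in :mod:`trisyn.simulate` remains
the reference; a test asserts bitwise-level agreement between the two on
random states.  Protocol discontinuities (stimulus and blockade windows) are
handled by the integrator's segmentation, so within one solver call the
stimulus amplitude and blockade factors are constants; only the smooth
energy-deprivation waveform is evaluated here.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard speed dependency
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


# -- parameter-vector layout -------------------------------------------------
# physical constants / geometry / totals
(J_F, J_RTF, J_RT, J_C_N, J_C_A, J_W_PS, J_W_C, J_W_PAP,
 J_C_NA, J_C_K, J_C_CL, J_C_CA, J_C_GLU, J_C_W,
 J_NA_N_IMP, J_NA_A_IMP, J_NA_E_IMP, J_NB_A_IMP, J_NB_E_IMP,
 # transport
 J_PG_NA, J_PG_K, J_PG_CL, J_PG_CA, J_CA_VH, J_CA_SL, J_CA_PW,
 J_PNKA_N, J_PNKA_A, J_ANKA_NA, J_ANKA_K, J_PSCALE,
 J_PKCL, J_PKIR, J_PNKCC1,
 J_PNCX_N, J_PNCX_A, J_ANCX_NA, J_ANCX_CA, J_ETA, J_KNCX,
 J_PEAAT_N, J_PEAAT_A, J_AH_N, J_AH_A, J_LN, J_LA,
 J_PL_NA_N, J_PL_K_N, J_PL_CL_N, J_PL_CA_N, J_PL_GLU_N,
 J_PL_NA_A, J_PL_K_A, J_PL_CL_A, J_PL_CA_A, J_PL_GLU_A,
 # vesicle cycle
 J_K1MAX, J_KM, J_KDV, J_K20, J_K2CAT, J_KM20, J_KM2CAT, J_KM1,
 J_K3, J_KM3, J_K4, J_TAU,
 # protocol: energy mode (0 const / 1 ED waveform), value/P_min, t1, t2, beta
 J_EMODE, J_EVAL, J_ET1, J_ET2, J_EBETA,
 # stimulus (pA) and clamp flag
 J_ISTIM, J_CLAMP,
 # blockade factors
 J_B_GNA, J_B_GK, J_B_GCL, J_B_GCA, J_B_NKA_N, J_B_KCC, J_B_NCX_N,
 J_B_EAAT_N, J_B_LEAK_N, J_B_NKA_A, J_B_KIR, J_B_NKCC1, J_B_NCX_A,
 J_B_EAAT_A, J_B_LEAK_A,
 # NKA voltage-factor form: 0 = saturating (reciprocal), 1 = driven
 J_NKA_FORM) = range(91)

NPAR = 91


@njit(cache=True, fastmath=False)
def _exp(x):
    if x > 500.0:
        x = 500.0
    elif x < -500.0:
        x = -500.0
    return np.exp(x)


@njit(cache=True, fastmath=False)
def _ghk(v, c_in, c_out, z, F, rtf):
    x = v * z / rtf
    if abs(x) < 1e-7:
        return F * z * ((c_in - c_out) + 0.5 * x * (c_in + c_out))
    e = _exp(-x)
    return F * z * x * (c_in - c_out * e) / (1.0 - e)


@njit(cache=True, fastmath=False)
def _vtrap(x, s):
    if abs(x) < 1e-7:
        return s + 0.5 * x
    return x / (1.0 - _exp(-x / s))


@njit(cache=True, fastmath=False)
def _vtrap2(x, s):
    if abs(x) < 1e-7:
        return s - 0.5 * x
    return x / (_exp(x / s) - 1.0)


@njit(cache=True, fastmath=False)
def rhs_fast(t_ms, y, P):
    F = P[J_F]
    rtf = P[J_RTF]
    dy = np.zeros(21)

    w_n = y[19]
    w_a = y[20]
    w_e = P[J_C_W] - w_n - w_a
    if w_n <= 0.0 or w_a <= 0.0 or w_e <= 0.0:
        return dy * np.nan

    na_n = y[0] / w_n
    k_n = y[1] / w_n
    cl_n = y[2] / w_n
    ca_n = y[3] / P[J_W_PS]
    glu_n = y[4] / P[J_W_PS]
    na_a = y[5] / w_a
    k_a = y[6] / w_a
    cl_a = y[7] / w_a
    ca_a = y[8] / P[J_W_PAP]
    glu_a = y[9] / P[J_W_PAP]
    na_e = (P[J_C_NA] - y[0] - y[5]) / w_e
    k_e = (P[J_C_K] - y[1] - y[6]) / w_e
    cl_e = (P[J_C_CL] - y[2] - y[7]) / w_e
    ca_c = (P[J_C_CA] - y[3] - y[8]) / P[J_W_C]
    if ca_c < 0.0:
        ca_c = 0.0
    pool_sum = y[4] + y[13] + y[14] + y[15] + y[16] + y[17] + y[18] + y[9]
    n_f = P[J_C_GLU] - pool_sum
    if n_f < 0.0:
        n_f = 0.0
    glu_c = n_f / P[J_W_C]

    v_n = F / P[J_C_N] * (y[0] + y[1] - y[2] + 2.0 * y[3] - y[4] - P[J_NA_N_IMP])
    v_a = F / P[J_C_A] * (y[5] + y[6] - y[7] + 2.0 * y[8] - y[9]
                          - P[J_NA_A_IMP] + P[J_NB_A_IMP])

    # energy waveform
    if P[J_EMODE] == 0.0:
        energy = P[J_EVAL]
    else:
        t_min = t_ms / 60000.0
        b = P[J_EBETA]
        p_min = P[J_EVAL]
        s1 = b * (t_min - P[J_ET1])
        s2 = -b * (t_min - P[J_ET2])
        ib = 1.0 / (1.0 + _exp(s1)) + 1.0 / (1.0 + _exp(s2))
        energy = p_min + (1.0 - p_min) * ib
        if energy > 1.0:
            energy = 1.0

    m = y[10]
    h = y[11]
    ng = y[12]

    # --- neuron currents
    ig_na = P[J_B_GNA] * P[J_PG_NA] * m * m * m * h * _ghk(v_n, na_n, na_e, 1.0, F, rtf)
    ig_k = P[J_B_GK] * P[J_PG_K] * ng * ng * _ghk(v_n, k_n, k_e, 1.0, F, rtf)
    ig_cl = (P[J_B_GCL] * P[J_PG_CL] / (1.0 + _exp(-(v_n + 10.0) / 10.0))
             * _ghk(v_n, cl_n, cl_e, -1.0, F, rtf))
    s = 1.0 / (1.0 + _exp(-(v_n - P[J_CA_VH]) / P[J_CA_SL]))
    a_ca = s ** P[J_CA_PW]
    ig_ca = P[J_B_GCA] * P[J_PG_CA] * a_ca * _ghk(v_n, ca_n, ca_c, 2.0, F, rtf)

    sigma = (_exp(na_e / 67.3) - 1.0) / 7.0
    x_n = v_n / rtf
    g_n = 1.0 + 0.1245 * _exp(-0.1 * x_n) + 0.0365 * sigma * _exp(-x_n)
    if P[J_NKA_FORM] == 0.0:
        g_n = 1.0 / g_n
    na15 = na_n ** 1.5 if na_n > 0.0 else 0.0
    hill_na = na15 / (na15 + P[J_ANKA_NA] ** 1.5)
    hill_k = k_e / (k_e + P[J_ANKA_K]) if k_e > 0.0 else 0.0
    i_nka_n = (P[J_B_NKA_N] * energy * P[J_PSCALE] * P[J_PNKA_N]
               * g_n * hill_na * hill_k)

    j_kcc = P[J_B_KCC] * P[J_PKCL] * rtf * np.log(k_e * cl_e / (k_n * cl_n))

    il_na_n = P[J_B_LEAK_N] * P[J_PL_NA_N] * _ghk(v_n, na_n, na_e, 1.0, F, rtf)
    il_k_n = P[J_B_LEAK_N] * P[J_PL_K_N] * _ghk(v_n, k_n, k_e, 1.0, F, rtf)
    il_cl_n = P[J_B_LEAK_N] * P[J_PL_CL_N] * _ghk(v_n, cl_n, cl_e, -1.0, F, rtf)

    # --- astrocyte currents
    x_a = v_a / rtf
    g_a = 1.0 + 0.1245 * _exp(-0.1 * x_a) + 0.0365 * sigma * _exp(-x_a)
    if P[J_NKA_FORM] == 0.0:
        g_a = 1.0 / g_a
    na15a = na_a ** 1.5 if na_a > 0.0 else 0.0
    hill_na_a = na15a / (na15a + P[J_ANKA_NA] ** 1.5)
    i_nka_a = (P[J_B_NKA_A] * energy * P[J_PSCALE] * P[J_PNKA_A]
               * g_a * hill_na_a * hill_k)

    e_k_a = rtf * np.log(k_e / k_a)
    dv_kir = v_a - e_k_a
    m_inf = 1.0 / (2.0 + _exp(1.62 * dv_kir / rtf))
    i_kir = P[J_B_KIR] * P[J_PKIR] * m_inf * (k_e / (k_e + 13.0)) * dv_kir

    j_nkcc1 = (P[J_B_NKCC1] * P[J_PNKCC1] * rtf
               * np.log((na_e / na_a) * (k_e / k_a) * (cl_e / cl_a) ** 2))

    il_na_a = P[J_B_LEAK_A] * P[J_PL_NA_A] * _ghk(v_a, na_a, na_e, 1.0, F, rtf)
    il_k_a = P[J_B_LEAK_A] * P[J_PL_K_A] * _ghk(v_a, k_a, k_e, 1.0, F, rtf)
    il_cl_a = P[J_B_LEAK_A] * P[J_PL_CL_A] * _ghk(v_a, cl_a, cl_e, -1.0, F, rtf)

    clamp = P[J_CLAMP] != 0.0
    if clamp:
        i_ncx_n = 0.0
        i_ncx_a = 0.0
        j_eaat_n = 0.0
        j_eaat_a = 0.0
        ig_ca = 0.0
        il_ca_n = 0.0
        il_ca_a = 0.0
        il_glu_n = 0.0
        il_glu_a = 0.0
    else:
        hill_nae = na_e ** 3 / (P[J_ANCX_NA] ** 3 + na_e ** 3)
        hill_cac = ca_c / (P[J_ANCX_CA] + ca_c)
        eta = P[J_ETA]
        den_n = 1.0 + P[J_KNCX] * _exp((eta - 1.0) * x_n)
        num_n = ((na_n / na_e) ** 3 * _exp(eta * x_n)
                 - (ca_n / ca_c) * _exp((eta - 1.0) * x_n))
        i_ncx_n = P[J_B_NCX_N] * P[J_PNCX_N] * hill_nae * hill_cac * num_n / den_n
        den_a = 1.0 + P[J_KNCX] * _exp((eta - 1.0) * x_a)
        num_a = ((na_a / na_e) ** 3 * _exp(eta * x_a)
                 - (ca_a / ca_c) * _exp((eta - 1.0) * x_a))
        i_ncx_a = P[J_B_NCX_A] * P[J_PNCX_A] * hill_nae * hill_cac * num_a / den_a

        glu_c_f = glu_c if glu_c > 1e-12 else 1e-12
        j_eaat_n = (P[J_B_EAAT_N] * P[J_PEAAT_N] * rtf
                    * np.log((na_e / na_n) ** 3 * (k_n / k_e) * P[J_AH_N]
                             * glu_c_f / glu_n))
        j_eaat_a = (P[J_B_EAAT_A] * P[J_PEAAT_A] * rtf
                    * np.log((na_e / na_a) ** 3 * (k_a / k_e) * P[J_AH_A]
                             * glu_c_f / glu_a))
        il_ca_n = P[J_B_LEAK_N] * P[J_PL_CA_N] * _ghk(v_n, ca_n, ca_c, 2.0, F, rtf)
        il_ca_a = P[J_B_LEAK_A] * P[J_PL_CA_A] * _ghk(v_a, ca_a, ca_c, 2.0, F, rtf)
        il_glu_n = P[J_B_LEAK_N] * P[J_PL_GLU_N] * _ghk(v_n, glu_n, glu_c, -1.0, F, rtf)
        il_glu_a = P[J_B_LEAK_A] * P[J_PL_GLU_A] * _ghk(v_a, glu_a, glu_c, -1.0, F, rtf)

    i_stim = P[J_ISTIM]

    dy[0] = (-(ig_na + 3.0 * i_nka_n + 3.0 * i_ncx_n + il_na_n) / F
             + 3.0 * j_eaat_n + i_stim / F)
    dy[1] = -(ig_k - 2.0 * i_nka_n + il_k_n) / F - j_eaat_n + j_kcc
    dy[2] = (ig_cl + il_cl_n) / F + j_kcc
    dy[3] = -(ig_ca - i_ncx_n + il_ca_n) / (2.0 * F)

    dy[5] = (-(3.0 * i_nka_a + 3.0 * i_ncx_a + il_na_a) / F
             + 3.0 * j_eaat_a + j_nkcc1)
    dy[6] = -(-2.0 * i_nka_a + i_kir + il_k_a) / F - j_eaat_a + j_nkcc1
    dy[7] = il_cl_a / F + 2.0 * j_nkcc1
    dy[8] = -(-i_ncx_a + il_ca_a) / (2.0 * F)
    dy[9] = j_eaat_a + il_glu_a / F

    # gates
    a_m = 0.32 * _vtrap(v_n + 52.0, 4.0)
    b_m = 0.28 * _vtrap2(v_n + 25.0, 5.0)
    a_h = 0.128 * _exp(-(v_n + 53.0) / 18.0)
    b_h = 4.0 / (1.0 + _exp(-(v_n + 30.0) / 5.0))
    a_n = 0.016 * _vtrap(v_n + 35.0, 5.0)
    b_n = 0.25 * _exp(-(v_n + 50.0) / 40.0)
    dy[10] = a_m * (1.0 - m) - b_m * m
    dy[11] = a_h * (1.0 - h) - b_h * h
    dy[12] = a_n * (1.0 - ng) - b_n * ng

    # vesicle cycle
    glu_uptake = j_eaat_n + il_glu_n / F
    k1 = P[J_K1MAX] * ca_n / (ca_n + P[J_KM]) if ca_n > 0.0 else 0.0
    g_cat = ca_n / (ca_n + P[J_KDV]) if ca_n > 0.0 else 0.0
    k2 = P[J_K20] + g_cat * P[J_K2CAT]
    k_m2 = P[J_KM20] + g_cat * P[J_KM2CAT]
    k3ca = P[J_K3] * ca_n
    k_m1 = P[J_KM1]
    k_m3 = P[J_KM3]
    recruit = y[4] * y[13] / P[J_TAU]
    dy[4] = -recruit + glu_uptake
    dy[13] = recruit - k1 * y[13] + k_m1 * y[14]
    dy[14] = k1 * y[13] - (k_m1 + k2) * y[14] + k_m2 * y[15]
    dy[15] = k2 * y[14] - (k_m2 + 3.0 * k3ca) * y[15] + k_m3 * y[16]
    dy[16] = 3.0 * k3ca * y[15] - (k_m3 + 2.0 * k3ca) * y[16] + 2.0 * k_m3 * y[17]
    dy[17] = 2.0 * k3ca * y[16] - (2.0 * k_m3 + k3ca) * y[17] + 3.0 * k_m3 * y[18]
    dy[18] = k3ca * y[17] - (3.0 * k_m3 + P[J_K4]) * y[18]

    # volumes
    rt = P[J_RT]
    imp_e = (P[J_NA_E_IMP] + P[J_NB_E_IMP]) / w_e
    osm_e = na_e + k_e + cl_e + imp_e
    dy[19] = P[J_LN] * rt * (na_n + k_n + cl_n + P[J_NA_N_IMP] / w_n - osm_e)
    dy[20] = P[J_LA] * rt * (na_a + k_a + cl_a
                             + (P[J_NA_A_IMP] + P[J_NB_A_IMP]) / w_a - osm_e)

    if clamp:
        dy[3] = 0.0
        dy[4] = 0.0
        dy[8] = 0.0
        dy[9] = 0.0
        for i in range(13, 19):
            dy[i] = 0.0
    return dy
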