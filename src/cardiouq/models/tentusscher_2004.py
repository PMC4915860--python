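"""ten Tusscher, Noble, Noble & Panfilov (2004) human ventricular model,
epicardial variant.

Seventeen states, twelve maximal conductance/density parameters (the inputs
used for conductance inference): G_Na, G_K1, G_to, G_Kr, G_Ks, G_CaL, G_bNa,
G_bCa, G_pCa, G_pK, P_NaK and k_NaCa. Dynamic intracellular Na+, K+ and Ca2+
(with a single SR compartment and switched fCa/g calcium gates).

Currents are in pA/pF; Cm = 0.185 uF; Nao 140, Cao 2, Ko 5.4 mM by default.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .base import CellModel, ParameterVector

R, T, F = 8314.472, 310.0, 96485.3415
RTF = R * T / F
CM = 0.185
V_C, V_SR = 0.016404, 0.001094
NAO, CAO = 140.0, 2.0
P_KNA = 0.03
K_MK, K_MNA = 1.0, 40.0
KM_NAI, KM_CA, K_SAT, ALPHA_NACA, GAMMA = 87.5, 1.38, 0.1, 2.5, 0.35
K_PCA = 0.0005
BUF_C, K_BUF_C = 0.15, 0.001
BUF_SR, K_BUF_SR = 10.0, 0.3
VMAX_UP, K_UP = 0.000425, 0.00025
A_REL, B_REL, C_REL = 0.016464, 0.25, 0.008232
V_LEAK = 8.0e-5


@njit(cache=True)
def rhs(y, t, theta, ko, stim):
    v = y[0]
    ki, nai, cai, casr = y[1], y[2], y[3], y[4]
    m, h, j = y[5], y[6], y[7]
    d, f, fca = y[8], y[9], y[10]
    r_g, s_g = y[11], y[12]
    xr1, xr2, xs = y[13], y[14], y[15]
    g = y[16]

    g_na, g_k1, g_to, g_kr, g_ks, g_cal = theta[0], theta[1], theta[2], theta[3], theta[4], theta[5]
    g_bna, g_bca, g_pca, g_pk, p_nak, k_naca = (
        theta[6],
        theta[7],
        theta[8],
        theta[9],
        theta[10],
        theta[11],
    )

    e_na = RTF * math.log(NAO / nai)
    e_k = RTF * math.log(ko / ki)
    e_ks = RTF * math.log((ko + P_KNA * NAO) / (ki + P_KNA * nai))
    e_ca = 0.5 * RTF * math.log(CAO / cai)

    i_na = g_na * m ** 3 * h * j * (v - e_na)

    vfrt2 = 2.0 * v * F / (R * T)
    if abs(v) > 1e-6:
        i_cal = (
            g_cal
            * d
            * f
            * fca
            * 4.0
            * v
            * F ** 2
            / (R * T)
            * (cai * math.exp(vfrt2) - 0.341 * CAO)
            / (math.exp(vfrt2) - 1.0)
        )
    else:
        i_cal = g_cal * d * f * fca * 2.0 * F * (cai - 0.341 * CAO)

    i_to = g_to * r_g * s_g * (v - e_k)
    i_kr = g_kr * math.sqrt(ko / 5.4) * xr1 * xr2 * (v - e_k)
    i_ks = g_ks * xs ** 2 * (v - e_ks)

    a_k1 = 0.1 / (1.0 + math.exp(0.06 * (v - e_k - 200.0)))
    b_k1 = (
        3.0 * math.exp(0.0002 * (v - e_k + 100.0)) + math.exp(0.1 * (v - e_k - 10.0))
    ) / (1.0 + math.exp(-0.5 * (v - e_k)))
    i_k1 = g_k1 * math.sqrt(ko / 5.4) * (a_k1 / (a_k1 + b_k1)) * (v - e_k)

    vfrt = v * F / (R * T)
    i_naca = (
        k_naca
        * (
            math.exp(GAMMA * vfrt) * nai ** 3 * CAO
            - math.exp((GAMMA - 1.0) * vfrt) * NAO ** 3 * cai * ALPHA_NACA
        )
        / (
            (KM_NAI ** 3 + NAO ** 3)
            * (KM_CA + CAO)
            * (1.0 + K_SAT * math.exp((GAMMA - 1.0) * vfrt))
        )
    )
    i_nak = (
        p_nak
        * ko
        * nai
        / (
            (ko + K_MK)
            * (nai + K_MNA)
            * (1.0 + 0.1245 * math.exp(-0.1 * vfrt) + 0.0353 * math.exp(-vfrt))
        )
    )
    i_pca = g_pca * cai / (cai + K_PCA)
    i_pk = g_pk * (v - e_k) / (1.0 + math.exp((25.0 - v) / 5.98))
    i_bna = g_bna * (v - e_na)
    i_bca = g_bca * (v - e_ca)

    # gating rates
    m_inf = 1.0 / (1.0 + math.exp((-56.86 - v) / 9.03)) ** 2
    a_m = 1.0 / (1.0 + math.exp((-60.0 - v) / 5.0))
    b_m = 0.1 / (1.0 + math.exp((v + 35.0) / 5.0)) + 0.1 / (1.0 + math.exp((v - 50.0) / 200.0))
    tau_m = a_m * b_m
    h_inf = 1.0 / (1.0 + math.exp((v + 71.55) / 7.43)) ** 2
    if v < -40.0:
        a_h = 0.057 * math.exp(-(v + 80.0) / 6.8)
        b_h = 2.7 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.3485 * v)
        a_j = (
            (-2.5428e4 * math.exp(0.2444 * v) - 6.948e-6 * math.exp(-0.04391 * v))
            * (v + 37.78)
            / (1.0 + math.exp(0.311 * (v + 79.23)))
        )
        b_j = 0.02424 * math.exp(-0.01052 * v) / (1.0 + math.exp(-0.1378 * (v + 40.14)))
    else:
        a_h = 0.0
        b_h = 0.77 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
        a_j = 0.0
        b_j = 0.6 * math.exp(0.057 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    tau_h = 1.0 / (a_h + b_h)
    tau_j = 1.0 / (a_j + b_j)
    j_inf = h_inf

    d_inf = 1.0 / (1.0 + math.exp((-5.0 - v) / 7.5))
    a_d = 1.4 / (1.0 + math.exp((-35.0 - v) / 13.0)) + 0.25
    b_d = 1.4 / (1.0 + math.exp((v + 5.0) / 5.0))
    g_d = 1.0 / (1.0 + math.exp((50.0 - v) / 20.0))
    tau_d = a_d * b_d + g_d
    f_inf = 1.0 / (1.0 + math.exp((v + 20.0) / 7.0))
    tau_f = 1125.0 * math.exp(-((v + 27.0) ** 2) / 240.0) + 80.0 + 165.0 / (
        1.0 + math.exp((25.0 - v) / 10.0)
    )

    a_fca = 1.0 / (1.0 + (cai / 0.000325) ** 8)
    b_fca = 0.1 / (1.0 + math.exp((cai - 0.0005) / 0.0001))
    g_fca = 0.2 / (1.0 + math.exp((cai - 0.00075) / 0.0008))
    fca_inf = (a_fca + b_fca + g_fca + 0.23) / 1.46
    d_fca = (fca_inf - fca) / 2.0
    if fca_inf > fca and v > -60.0:
        d_fca = 0.0

    r_inf = 1.0 / (1.0 + math.exp((20.0 - v) / 6.0))
    tau_r = 9.5 * math.exp(-((v + 40.0) ** 2) / 1800.0) + 0.8
    s_inf = 1.0 / (1.0 + math.exp((v + 20.0) / 5.0))
    tau_s = 85.0 * math.exp(-((v + 45.0) ** 2) / 320.0) + 5.0 / (
        1.0 + math.exp((v - 20.0) / 5.0)
    ) + 3.0

    xr1_inf = 1.0 / (1.0 + math.exp((-26.0 - v) / 7.0))
    a_xr1 = 450.0 / (1.0 + math.exp((-45.0 - v) / 10.0))
    b_xr1 = 6.0 / (1.0 + math.exp((v + 30.0) / 11.5))
    tau_xr1 = a_xr1 * b_xr1
    xr2_inf = 1.0 / (1.0 + math.exp((v + 88.0) / 24.0))
    a_xr2 = 3.0 / (1.0 + math.exp((-60.0 - v) / 20.0))
    b_xr2 = 1.12 / (1.0 + math.exp((v - 60.0) / 20.0))
    tau_xr2 = a_xr2 * b_xr2
    xs_inf = 1.0 / (1.0 + math.exp((-5.0 - v) / 14.0))
    a_xs = 1100.0 / math.sqrt(1.0 + math.exp((-10.0 - v) / 6.0))
    b_xs = 1.0 / (1.0 + math.exp((v - 60.0) / 20.0))
    tau_xs = a_xs * b_xs

    # calcium dynamics
    i_leak = V_LEAK * (casr - cai)
    i_up = VMAX_UP / (1.0 + (K_UP / cai) ** 2)
    i_rel = (A_REL * casr ** 2 / (B_REL ** 2 + casr ** 2) + C_REL) * d * g

    g_inf = 1.0 / (1.0 + (cai / 0.00035) ** 6) if cai < 0.00035 else 1.0 / (
        1.0 + (cai / 0.00035) ** 16
    )
    d_g = (g_inf - g) / 2.0
    if g_inf > g and v > -60.0:
        d_g = 0.0

    cai_bufc = 1.0 / (1.0 + BUF_C * K_BUF_C / (cai + K_BUF_C) ** 2)
    casr_bufsr = 1.0 / (1.0 + BUF_SR * K_BUF_SR / (casr + K_BUF_SR) ** 2)

    dy = np.empty(17)
    dy[0] = -(
        i_na + i_cal + i_to + i_kr + i_ks + i_k1 + i_naca + i_nak + i_pca + i_pk + i_bna + i_bca + stim
    )
    dy[1] = -(i_k1 + i_to + i_kr + i_ks + i_pk + stim - 2.0 * i_nak) * CM / (V_C * F)
    dy[2] = -(i_na + i_bna + 3.0 * i_nak + 3.0 * i_naca) * CM / (V_C * F)
    dy[3] = cai_bufc * (
        i_leak - i_up + i_rel - (i_cal + i_bca + i_pca - 2.0 * i_naca) * CM / (2.0 * V_C * F)
    )
    dy[4] = casr_bufsr * V_C / V_SR * (i_up - i_rel - i_leak)
    dy[5] = (m_inf - m) / tau_m
    dy[6] = (h_inf - h) / tau_h
    dy[7] = (j_inf - j) / tau_j
    dy[8] = (d_inf - d) / tau_d
    dy[9] = (f_inf - f) / tau_f
    dy[10] = d_fca
    dy[11] = (r_inf - r_g) / tau_r
    dy[12] = (s_inf - s_g) / tau_s
    dy[13] = (xr1_inf - xr1) / tau_xr1
    dy[14] = (xr2_inf - xr2) / tau_xr2
    dy[15] = (xs_inf - xs) / tau_xs
    dy[16] = d_g
    return dy


def ionic_currents(y, theta, ko=5.4):
    v = y[0]
    ki, nai, cai = y[1], y[2], y[3]
    m, h, j = y[5], y[6], y[7]
    d, f, fca = y[8], y[9], y[10]
    r_g, s_g = y[11], y[12]
    xr1, xr2, xs = y[13], y[14], y[15]
    g_na, g_k1, g_to, g_kr, g_ks, g_cal, g_bna, g_bca, g_pca, g_pk, p_nak, k_naca = theta

    e_na = RTF * math.log(NAO / nai)
    e_k = RTF * math.log(ko / ki)
    e_ks = RTF * math.log((ko + P_KNA * NAO) / (ki + P_KNA * nai))
    e_ca = 0.5 * RTF * math.log(CAO / cai)
    vfrt = v * F / (R * T)
    vfrt2 = 2.0 * vfrt
    a_k1 = 0.1 / (1.0 + math.exp(0.06 * (v - e_k - 200.0)))
    b_k1 = (
        3.0 * math.exp(0.0002 * (v - e_k + 100.0)) + math.exp(0.1 * (v - e_k - 10.0))
    ) / (1.0 + math.exp(-0.5 * (v - e_k)))
    return {
        "I_Na": g_na * m ** 3 * h * j * (v - e_na),
        "I_CaL": g_cal
        * d
        * f
        * fca
        * 4.0
        * v
        * F ** 2
        / (R * T)
        * (cai * math.exp(vfrt2) - 0.341 * CAO)
        / (math.exp(vfrt2) - 1.0),
        "I_to": g_to * r_g * s_g * (v - e_k),
        "I_Kr": g_kr * math.sqrt(ko / 5.4) * xr1 * xr2 * (v - e_k),
        "I_Ks": g_ks * xs ** 2 * (v - e_ks),
        "I_K1": g_k1 * math.sqrt(ko / 5.4) * (a_k1 / (a_k1 + b_k1)) * (v - e_k),
        "I_NaCa": k_naca
        * (
            math.exp(GAMMA * vfrt) * nai ** 3 * CAO
            - math.exp((GAMMA - 1.0) * vfrt) * NAO ** 3 * cai * ALPHA_NACA
        )
        / (
            (KM_NAI ** 3 + NAO ** 3)
            * (KM_CA + CAO)
            * (1.0 + K_SAT * math.exp((GAMMA - 1.0) * vfrt))
        ),
        "I_NaK": p_nak
        * ko
        * nai
        / (
            (ko + K_MK)
            * (nai + K_MNA)
            * (1.0 + 0.1245 * math.exp(-0.1 * vfrt) + 0.0353 * math.exp(-vfrt))
        ),
        "I_pCa": g_pca * cai / (cai + K_PCA),
        "I_pK": g_pk * (v - e_k) / (1.0 + math.exp((25.0 - v) / 5.98)),
        "I_bNa": g_bna * (v - e_na),
        "I_bCa": g_bca * (v - e_ca),
    }


PARAMETER_NAMES = (
    "G_Na",
    "G_K1",
    "G_to",
    "G_Kr",
    "G_Ks",
    "G_CaL",
    "G_bNa",
    "G_bCa",
    "G_pCa",
    "G_pK",
    "P_NaK",
    "k_NaCa",
)
DEFAULTS = (
    14.838,
    5.405,
    0.294,
    0.096,
    0.245,
    0.000175,
    0.00029,
    0.000592,
    0.825,
    0.0146,
    1.362,
    1000.0,
)
STATE_NAMES = (
    "V",
    "K_i",
    "Na_i",
    "Ca_i",
    "Ca_SR",
    "m",
    "h",
    "j",
    "d",
    "f",
    "fCa",
    "r",
    "s",
    "Xr1",
    "Xr2",
    "Xs",
    "g",
)

# Published initial conditions (epicardial variant).
INITIAL_STATE = np.array(
    [
        -86.2,  # V
        138.3,  # K_i
        11.6,  # Na_i
        0.0002,  # Ca_i
        0.2,  # Ca_SR
        0.0,  # m
        0.75,  # h
        0.75,  # j
        0.0,  # d
        1.0,  # f
        1.0,  # fCa
        0.0,  # r
        1.0,  # s
        0.0,  # Xr1
        1.0,  # Xr2
        0.0,  # Xs
        1.0,  # g
    ]
)


def build() -> CellModel:
    units = {n: "nS/pF" for n in PARAMETER_NAMES}
    units["G_CaL"] = "cm^3 uF^-1 s^-1"
    units["P_NaK"] = "pA/pF"
    units["k_NaCa"] = "pA/pF"
    return CellModel(
        name="tentusscher_2004",
        n_state=17,
        state_names=STATE_NAMES,
        parameter_names=PARAMETER_NAMES,
        parameter_units=units,
        defaults=ParameterVector(PARAMETER_NAMES, DEFAULTS),
        initial_state=INITIAL_STATE.copy(),
        rhs=rhs,
        ionic_currents=ionic_currents,
        default_Ko=5.4,
        supports_extracellular_potassium=True,
        reference="ten Tusscher et al., Am J Physiol Heart Circ Physiol 286:H1573-H1589 (2004)",
    )
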