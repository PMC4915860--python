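"""ten Tusscher & Panfilov (2006) human ventricular model (TP06), epicardial
variant.

Nineteen states with dyadic-subspace calcium and a four-state-style SR release
switch. The thirteen emulator/inference inputs are the twelve maximal
conductances/densities plus a dimensionless multiplier on the L-type calcium
slow-inactivation time constant tau_f:

G_Na 14.838, G_K1 5.405, G_to 0.294 (epi), G_Kr 0.153, G_Ks 0.392 (epi),
G_CaL 3.98e-5, tau_f_multiplier 1.0, G_bNa 0.00029, G_bCa 0.000592,
G_pCa 0.1238, G_pK 0.0146, P_NaK 2.724, k_NaCa 1000.

Currents in pA/pF, Cm = 0.185 uF; Nao 140, Cao 2, Ko 5.4 mM by default.
Initial conditions are the published CellML values for the epicardial cell.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .base import CellModel, ParameterVector

R, T, F = 8314.472, 310.0, 96485.3415
RTF = R * T / F
CM = 0.185
V_C, V_SR, V_SS = 0.016404, 0.001094, 0.00005468
NAO, CAO = 140.0, 2.0
P_KNA = 0.03
K_MK, K_MNA = 1.0, 40.0
KM_NAI, KM_CA, K_SAT, ALPHA_NACA, GAMMA = 87.5, 1.38, 0.1, 2.5, 0.35
K_PCA = 0.0005
BUF_C, K_BUF_C = 0.2, 0.001
BUF_SR, K_BUF_SR = 10.0, 0.3
BUF_SS, K_BUF_SS = 0.4, 0.00025
VMAX_UP, K_UP = 0.006375, 0.00025
V_REL, V_XFER, V_LEAK = 0.102, 0.0038, 0.00036
K1P, K2P, K3, K4 = 0.15, 0.045, 0.06, 0.005
EC, MAX_SR, MIN_SR = 1.5, 2.5, 1.0


@njit(cache=True)
def rhs(y, t, theta, ko, stim):
    v = y[0]
    ki, nai, cai, cass, casr = y[1], y[2], y[3], y[4], y[5]
    rprime = y[6]
    m, h, j = y[7], y[8], y[9]
    d, f, f2, fcass = y[10], y[11], y[12], y[13]
    r_g, s_g = y[14], y[15]
    xr1, xr2, xs = y[16], y[17], y[18]

    g_na, g_k1, g_to, g_kr, g_ks, g_cal, tau_f_mult = (
        theta[0],
        theta[1],
        theta[2],
        theta[3],
        theta[4],
        theta[5],
        theta[6],
    )
    g_bna, g_bca, g_pca, g_pk, p_nak, k_naca = (
        theta[7],
        theta[8],
        theta[9],
        theta[10],
        theta[11],
        theta[12],
    )

    e_na = RTF * math.log(NAO / nai)
    e_k = RTF * math.log(ko / ki)
    e_ks = RTF * math.log((ko + P_KNA * NAO) / (ki + P_KNA * nai))
    e_ca = 0.5 * RTF * math.log(CAO / cai)

    i_na = g_na * m ** 3 * h * j * (v - e_na)

    vm15 = v - 15.0
    ex = 2.0 * vm15 * F / (R * T)
    if abs(vm15) > 1e-6:
        i_cal = (
            g_cal
            * d
            * f
            * f2
            * fcass
            * 4.0
            * vm15
            * F ** 2
            / (R * T)
            * (0.25 * cass * math.exp(ex) - CAO)
            / (math.exp(ex) - 1.0)
        )
    else:
        i_cal = g_cal * d * f * f2 * fcass * 2.0 * F * (0.25 * cass - CAO)

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

    d_inf = 1.0 / (1.0 + math.exp((-8.0 - v) / 7.5))
    a_d = 1.4 / (1.0 + math.exp((-35.0 - v) / 13.0)) + 0.25
    b_d = 1.4 / (1.0 + math.exp((v + 5.0) / 5.0))
    g_d = 1.0 / (1.0 + math.exp((50.0 - v) / 20.0))
    tau_d = a_d * b_d + g_d
    f_inf = 1.0 / (1.0 + math.exp((v + 20.0) / 7.0))
    tau_f = tau_f_mult * (
        1102.5 * math.exp(-((v + 27.0) ** 2) / 225.0)
        + 200.0 / (1.0 + math.exp((13.0 - v) / 10.0))
        + 180.0 / (1.0 + math.exp((v + 30.0) / 10.0))
        + 20.0
    )
    f2_inf = 0.67 / (1.0 + math.exp((v + 35.0) / 7.0)) + 0.33
    tau_f2 = (
        562.0 * math.exp(-((v + 27.0) ** 2) / 240.0)
        + 31.0 / (1.0 + math.exp((25.0 - v) / 10.0))
        + 80.0 / (1.0 + math.exp((v + 30.0) / 10.0))
    )
    fcass_inf = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
    tau_fcass = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0

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
    a_xs = 1400.0 / math.sqrt(1.0 + math.exp((5.0 - v) / 6.0))
    b_xs = 1.0 / (1.0 + math.exp((v - 35.0) / 15.0))
    tau_xs = a_xs * b_xs + 80.0

    # calcium dynamics
    kcasr = MAX_SR - (MAX_SR - MIN_SR) / (1.0 + (EC / casr) ** 2)
    k1 = K1P / kcasr
    k2 = K2P * kcasr
    o_gate = k1 * cass ** 2 * rprime / (K3 + k1 * cass ** 2)
    i_rel = V_REL * o_gate * (casr - cass)
    i_leak = V_LEAK * (casr - cai)
    i_up = VMAX_UP / (1.0 + (K_UP / cai) ** 2)
    i_xfer = V_XFER * (cass - cai)

    cai_bufc = 1.0 / (1.0 + BUF_C * K_BUF_C / (cai + K_BUF_C) ** 2)
    casr_bufsr = 1.0 / (1.0 + BUF_SR * K_BUF_SR / (casr + K_BUF_SR) ** 2)
    cass_bufss = 1.0 / (1.0 + BUF_SS * K_BUF_SS / (cass + K_BUF_SS) ** 2)

    dy = np.empty(19)
    dy[0] = -(
        i_na + i_cal + i_to + i_kr + i_ks + i_k1 + i_naca + i_nak + i_pca + i_pk + i_bna + i_bca + stim
    )
    dy[1] = -(i_k1 + i_to + i_kr + i_ks + i_pk + stim - 2.0 * i_nak) * CM / (V_C * F)
    dy[2] = -(i_na + i_bna + 3.0 * i_nak + 3.0 * i_naca) * CM / (V_C * F)
    dy[3] = cai_bufc * (
        (i_leak - i_up) * V_SR / V_C
        + i_xfer
        - (i_bca + i_pca - 2.0 * i_naca) * CM / (2.0 * V_C * F)
    )
    dy[4] = cass_bufss * (
        -i_cal * CM / (2.0 * V_SS * F) + i_rel * V_SR / V_SS - i_xfer * V_C / V_SS
    )
    dy[5] = casr_bufsr * (i_up - i_rel - i_leak)
    dy[6] = -k2 * cass * rprime + K4 * (1.0 - rprime)
    dy[7] = (m_inf - m) / tau_m
    dy[8] = (h_inf - h) / tau_h
    dy[9] = (j_inf - j) / tau_j
    dy[10] = (d_inf - d) / tau_d
    dy[11] = (f_inf - f) / tau_f
    dy[12] = (f2_inf - f2) / tau_f2
    dy[13] = (fcass_inf - fcass) / tau_fcass
    dy[14] = (r_inf - r_g) / tau_r
    dy[15] = (s_inf - s_g) / tau_s
    dy[16] = (xr1_inf - xr1) / tau_xr1
    dy[17] = (xr2_inf - xr2) / tau_xr2
    dy[18] = (xs_inf - xs) / tau_xs
    return dy


def ionic_currents(y, theta, ko=5.4):
    v = y[0]
    ki, nai, cai, cass = y[1], y[2], y[3], y[4]
    m, h, j = y[7], y[8], y[9]
    d, f, f2, fcass = y[10], y[11], y[12], y[13]
    r_g, s_g = y[14], y[15]
    xr1, xr2, xs = y[16], y[17], y[18]
    (g_na, g_k1, g_to, g_kr, g_ks, g_cal, _tau_f_mult, g_bna, g_bca, g_pca, g_pk, p_nak, k_naca) = theta

    e_na = RTF * math.log(NAO / nai)
    e_k = RTF * math.log(ko / ki)
    e_ks = RTF * math.log((ko + P_KNA * NAO) / (ki + P_KNA * nai))
    e_ca = 0.5 * RTF * math.log(CAO / cai)
    vfrt = v * F / (R * T)
    vm15 = v - 15.0
    ex = 2.0 * vm15 * F / (R * T)
    a_k1 = 0.1 / (1.0 + math.exp(0.06 * (v - e_k - 200.0)))
    b_k1 = (
        3.0 * math.exp(0.0002 * (v - e_k + 100.0)) + math.exp(0.1 * (v - e_k - 10.0))
    ) / (1.0 + math.exp(-0.5 * (v - e_k)))
    return {
        "I_Na": g_na * m ** 3 * h * j * (v - e_na),
        "I_CaL": g_cal
        * d
        * f
        * f2
        * fcass
        * 4.0
        * vm15
        * F ** 2
        / (R * T)
        * (0.25 * cass * math.exp(ex) - CAO)
        / (math.exp(ex) - 1.0),
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
    "tau_f_multiplier",
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
    0.153,
    0.392,
    0.0000398,
    1.0,
    0.00029,
    0.000592,
    0.1238,
    0.0146,
    2.724,
    1000.0,
)
STATE_NAMES = (
    "V",
    "K_i",
    "Na_i",
    "Ca_i",
    "Ca_ss",
    "Ca_SR",
    "R_prime",
    "m",
    "h",
    "j",
    "d",
    "f",
    "f2",
    "fCass",
    "r",
    "s",
    "Xr1",
    "Xr2",
    "Xs",
)

# CellML initial conditions, epicardial cell.
INITIAL_STATE = np.array(
    [
        -85.23,  # V
        136.89,  # K_i
        8.604,  # Na_i
        0.000126,  # Ca_i
        0.00036,  # Ca_ss
        3.64,  # Ca_SR
        0.9073,  # R_prime
        0.00172,  # m
        0.7444,  # h
        0.7045,  # j
        3.373e-5,  # d
        0.7888,  # f
        0.9755,  # f2
        0.9953,  # fCass
        2.42e-8,  # r
        0.999998,  # s
        0.00621,  # Xr1
        0.4712,  # Xr2
        0.0095,  # Xs
    ]
)


def build() -> CellModel:
    units = {n: "nS/pF" for n in PARAMETER_NAMES}
    units["G_CaL"] = "cm^3 uF^-1 ms^-1"
    units["tau_f_multiplier"] = "dimensionless"
    units["P_NaK"] = "pA/pF"
    units["k_NaCa"] = "pA/pF"
    return CellModel(
        name="tentusscher_2006_epi",
        n_state=19,
        state_names=STATE_NAMES,
        parameter_names=PARAMETER_NAMES,
        parameter_units=units,
        defaults=ParameterVector(PARAMETER_NAMES, DEFAULTS),
        initial_state=INITIAL_STATE.copy(),
        rhs=rhs,
        ionic_currents=ionic_currents,
        default_Ko=5.4,
        supports_extracellular_potassium=True,
        reference="ten Tusscher & Panfilov, Am J Physiol Heart Circ Physiol 291:H1088-H1100 (2006)",
    )
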