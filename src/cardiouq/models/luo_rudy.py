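"""Luo & Rudy (1991) guinea-pig ventricular AP model (phase 1).

Eight states and six ionic currents, each scaled by one maximal conductance
(mS/cm^2): fast sodium ``G_Na`` (23.0), slow inward calcium ``G_si`` (0.09),
time-dependent potassium ``G_K`` (0.282), inward rectifier ``G_K1`` (0.6047),
plateau potassium ``G_Kp`` (0.0183) and background ``G_b`` (0.03921).

[K+]o enters the potassium reversal potentials and the sqrt(Ko/5.4) scalings
of I_K and I_K1, so halving/doubling-[K+]o protocols are applicable.
Intracellular Na+ and K+ are fixed (Nai 18, Ki 145 mM); Nao 140, Cao 1.8 mM.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .base import CellModel, ParameterVector

RTF = 8314.472 * 310.0 / 96485.3415  # mV at 37 C
NAI, KI, NAO = 18.0, 145.0, 140.0
PR_NAK = 0.01833


@njit(cache=True)
def rhs(y, t, theta, ko, stim):
    v, m, h, j, d, f, x, cai = y[0], y[1], y[2], y[3], y[4], y[5], y[6], y[7]
    g_na, g_si, g_k, g_k1, g_kp, g_b = theta[0], theta[1], theta[2], theta[3], theta[4], theta[5]

    e_na = RTF * math.log(NAO / NAI)
    e_k = RTF * math.log((ko + PR_NAK * NAO) / (KI + PR_NAK * NAI))
    e_k1 = RTF * math.log(ko / KI)

    i_na = g_na * m ** 3 * h * j * (v - e_na)
    e_si = 7.7 - 13.0287 * math.log(cai)
    i_si = g_si * d * f * (v - e_si)

    if v > -100.0:
        if abs(v + 77.0) > 1e-9:
            xi = 2.837 * (math.exp(0.04 * (v + 77.0)) - 1.0) / (
                (v + 77.0) * math.exp(0.04 * (v + 35.0))
            )
        else:
            xi = 2.837 * 0.04 / math.exp(0.04 * (v + 35.0))
    else:
        xi = 1.0
    i_k = g_k * math.sqrt(ko / 5.4) * x * xi * (v - e_k)

    a_k1 = 1.02 / (1.0 + math.exp(0.2385 * (v - e_k1 - 59.215)))
    b_k1 = (
        0.49124 * math.exp(0.08032 * (v - e_k1 + 5.476))
        + math.exp(0.06175 * (v - e_k1 - 594.31))
    ) / (1.0 + math.exp(-0.5143 * (v - e_k1 + 4.753)))
    i_k1 = g_k1 * math.sqrt(ko / 5.4) * (a_k1 / (a_k1 + b_k1)) * (v - e_k1)

    kp = 1.0 / (1.0 + math.exp((7.488 - v) / 5.98))
    i_kp = g_kp * kp * (v - e_k1)
    i_b = g_b * (v + 59.87)

    # gate rates
    if abs(v + 47.13) > 1e-9:
        a_m = 0.32 * (v + 47.13) / (1.0 - math.exp(-0.1 * (v + 47.13)))
    else:
        a_m = 3.2
    b_m = 0.08 * math.exp(-v / 11.0)
    if v < -40.0:
        a_h = 0.135 * math.exp(-(80.0 + v) / 6.8)
        b_h = 3.56 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.35 * v)
        a_j = (
            (-1.2714e5 * math.exp(0.2444 * v) - 3.474e-5 * math.exp(-0.04391 * v))
            * (v + 37.78)
            / (1.0 + math.exp(0.311 * (v + 79.23)))
        )
        b_j = 0.1212 * math.exp(-0.01052 * v) / (1.0 + math.exp(-0.1378 * (v + 40.14)))
    else:
        a_h = 0.0
        b_h = 1.0 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
        a_j = 0.0
        b_j = 0.3 * math.exp(-2.535e-7 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    a_d = 0.095 * math.exp(-0.01 * (v - 5.0)) / (1.0 + math.exp(-0.072 * (v - 5.0)))
    b_d = 0.07 * math.exp(-0.017 * (v + 44.0)) / (1.0 + math.exp(0.05 * (v + 44.0)))
    a_f = 0.012 * math.exp(-0.008 * (v + 28.0)) / (1.0 + math.exp(0.15 * (v + 28.0)))
    b_f = 0.0065 * math.exp(-0.02 * (v + 30.0)) / (1.0 + math.exp(-0.2 * (v + 30.0)))
    a_x = 0.0005 * math.exp(0.083 * (v + 50.0)) / (1.0 + math.exp(0.057 * (v + 50.0)))
    b_x = 0.0013 * math.exp(-0.06 * (v + 20.0)) / (1.0 + math.exp(-0.04 * (v + 20.0)))

    dy = np.empty(8)
    dy[0] = -(i_na + i_si + i_k + i_k1 + i_kp + i_b + stim)
    dy[1] = a_m * (1.0 - m) - b_m * m
    dy[2] = a_h * (1.0 - h) - b_h * h
    dy[3] = a_j * (1.0 - j) - b_j * j
    dy[4] = a_d * (1.0 - d) - b_d * d
    dy[5] = a_f * (1.0 - f) - b_f * f
    dy[6] = a_x * (1.0 - x) - b_x * x
    dy[7] = -1.0e-4 * i_si + 0.07 * (1.0e-4 - cai)
    return dy


def ionic_currents(y, theta, ko=5.4):
    v, m, h, j, d, f, x, cai = y
    g_na, g_si, g_k, g_k1, g_kp, g_b = theta
    e_na = RTF * math.log(NAO / NAI)
    e_k = RTF * math.log((ko + PR_NAK * NAO) / (KI + PR_NAK * NAI))
    e_k1 = RTF * math.log(ko / KI)
    e_si = 7.7 - 13.0287 * math.log(cai)
    if v > -100.0:
        xi = 2.837 * (math.exp(0.04 * (v + 77.0)) - 1.0) / (
            (v + 77.0) * math.exp(0.04 * (v + 35.0))
        )
    else:
        xi = 1.0
    a_k1 = 1.02 / (1.0 + math.exp(0.2385 * (v - e_k1 - 59.215)))
    b_k1 = (
        0.49124 * math.exp(0.08032 * (v - e_k1 + 5.476))
        + math.exp(0.06175 * (v - e_k1 - 594.31))
    ) / (1.0 + math.exp(-0.5143 * (v - e_k1 + 4.753)))
    kp = 1.0 / (1.0 + math.exp((7.488 - v) / 5.98))
    return {
        "I_Na": g_na * m ** 3 * h * j * (v - e_na),
        "I_si": g_si * d * f * (v - e_si),
        "I_K": g_k * math.sqrt(ko / 5.4) * x * xi * (v - e_k),
        "I_K1": g_k1 * math.sqrt(ko / 5.4) * (a_k1 / (a_k1 + b_k1)) * (v - e_k1),
        "I_Kp": g_kp * kp * (v - e_k1),
        "I_b": g_b * (v + 59.87),
    }


PARAMETER_NAMES = ("G_Na", "G_si", "G_K", "G_K1", "G_Kp", "G_b")
DEFAULTS = (23.0, 0.09, 0.282, 0.6047, 0.0183, 0.03921)
STATE_NAMES = ("V", "m", "h", "j", "d", "f", "X", "Ca_i")

# Quiescent steady state at default conductances and Ko = 5.4 mM (frozen from
# a long unstimulated integration).
INITIAL_STATE = np.array(
    [
        -8.45515781e01,
        1.66521453e-03,
        9.83319170e-01,
        9.89532172e-01,
        2.97629375e-03,
        9.99981256e-01,
        5.64093228e-03,
        1.78335417e-04,
    ]
)


def build() -> CellModel:
    return CellModel(
        name="luo_rudy_1991",
        n_state=8,
        state_names=STATE_NAMES,
        parameter_names=PARAMETER_NAMES,
        parameter_units={n: "mS/cm^2" for n in PARAMETER_NAMES},
        defaults=ParameterVector(PARAMETER_NAMES, DEFAULTS),
        initial_state=INITIAL_STATE.copy(),
        rhs=rhs,
        ionic_currents=ionic_currents,
        default_Ko=5.4,
        supports_extracellular_potassium=True,
        reference="Luo & Rudy, Circ Res 68:1501-1526 (1991)",
    )
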