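"""Beeler & Reuter (1977) mammalian ventricular AP model.

Eight states (Vm, intracellular calcium, six Hodgkin-Huxley gates) and four
ionic currents, each scaled by one maximal conductance:

* ``G_Na``   fast inward sodium current (mS/cm^2, default 4.0; the small
  background sodium conductance 0.003 mS/cm^2 is kept fixed),
* ``G_s``    slow inward (calcium) current (default 0.09),
* ``G_x1``   time-activated outward current magnitude (uA/cm^2, default 0.8),
* ``G_K1``   time-independent potassium current magnitude (default 0.35).

With a membrane capacitance of 1 uF/cm^2 the current densities in uA/cm^2
coincide numerically with pA/pF. The model has no explicit extracellular
potassium dependence.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .base import CellModel, ParameterVector

G_NAC = 0.003  # background Na conductance, mS/cm^2 (fixed)
E_NA = 50.0  # mV


@njit(cache=True)
def _gates(v):
    a_m = -(v + 47.0) / (math.exp(-0.1 * (v + 47.0)) - 1.0) if abs(v + 47.0) > 1e-9 else 10.0
    b_m = 40.0 * math.exp(-0.056 * (v + 72.0))
    a_h = 0.126 * math.exp(-0.25 * (v + 77.0))
    b_h = 1.7 / (math.exp(-0.082 * (v + 22.5)) + 1.0)
    a_j = 0.055 * math.exp(-0.25 * (v + 78.0)) / (math.exp(-0.2 * (v + 78.0)) + 1.0)
    b_j = 0.3 / (math.exp(-0.1 * (v + 32.0)) + 1.0)
    a_d = 0.095 * math.exp(-0.01 * (v - 5.0)) / (math.exp(-0.072 * (v - 5.0)) + 1.0)
    b_d = 0.07 * math.exp(-0.017 * (v + 44.0)) / (math.exp(0.05 * (v + 44.0)) + 1.0)
    a_f = 0.012 * math.exp(-0.008 * (v + 28.0)) / (math.exp(0.15 * (v + 28.0)) + 1.0)
    b_f = 0.0065 * math.exp(-0.02 * (v + 30.0)) / (math.exp(-0.2 * (v + 30.0)) + 1.0)
    a_x1 = 0.0005 * math.exp(0.083 * (v + 50.0)) / (math.exp(0.057 * (v + 50.0)) + 1.0)
    b_x1 = 0.0013 * math.exp(-0.06 * (v + 20.0)) / (math.exp(-0.04 * (v + 20.0)) + 1.0)
    return a_m, b_m, a_h, b_h, a_j, b_j, a_d, b_d, a_f, b_f, a_x1, b_x1


@njit(cache=True)
def rhs(y, t, theta, ko, stim):
    v, m, h, j, d, f, x1, cai = y[0], y[1], y[2], y[3], y[4], y[5], y[6], y[7]
    g_na, g_s, g_x1, g_k1 = theta[0], theta[1], theta[2], theta[3]

    i_na = (g_na * m ** 3 * h * j + G_NAC) * (v - E_NA)
    e_s = -82.3 - 13.0287 * math.log(cai)
    i_s = g_s * d * f * (v - e_s)
    i_x1 = x1 * g_x1 * (math.exp(0.04 * (v + 77.0)) - 1.0) / math.exp(0.04 * (v + 35.0))
    if abs(v + 23.0) > 1e-9:
        k1_b = 0.2 * (v + 23.0) / (1.0 - math.exp(-0.04 * (v + 23.0)))
    else:
        k1_b = 5.0
    i_k1 = g_k1 * (
        4.0
        * (math.exp(0.04 * (v + 85.0)) - 1.0)
        / (math.exp(0.08 * (v + 53.0)) + math.exp(0.04 * (v + 53.0)))
        + k1_b
    )

    a_m, b_m, a_h, b_h, a_j, b_j, a_d, b_d, a_f, b_f, a_x1, b_x1 = _gates(v)

    dy = np.empty(8)
    dy[0] = -(i_na + i_s + i_x1 + i_k1 + stim)
    dy[1] = a_m * (1.0 - m) - b_m * m
    dy[2] = a_h * (1.0 - h) - b_h * h
    dy[3] = a_j * (1.0 - j) - b_j * j
    dy[4] = a_d * (1.0 - d) - b_d * d
    dy[5] = a_f * (1.0 - f) - b_f * f
    dy[6] = a_x1 * (1.0 - x1) - b_x1 * x1
    dy[7] = -1.0e-7 * i_s + 0.07 * (1.0e-7 - cai)
    return dy


def ionic_currents(y, theta, ko=None):
    """Per-current decomposition in uA/cm^2 (== pA/pF at Cm = 1 uF/cm^2)."""
    v, m, h, j, d, f, x1, cai = y
    g_na, g_s, g_x1, g_k1 = theta
    e_s = -82.3 - 13.0287 * math.log(cai)
    k1_b = (
        0.2 * (v + 23.0) / (1.0 - math.exp(-0.04 * (v + 23.0)))
        if abs(v + 23.0) > 1e-9
        else 5.0
    )
    return {
        "I_Na": (g_na * m ** 3 * h * j + G_NAC) * (v - E_NA),
        "I_s": g_s * d * f * (v - e_s),
        "I_x1": x1 * g_x1 * (math.exp(0.04 * (v + 77.0)) - 1.0) / math.exp(0.04 * (v + 35.0)),
        "I_K1": g_k1
        * (
            4.0
            * (math.exp(0.04 * (v + 85.0)) - 1.0)
            / (math.exp(0.08 * (v + 53.0)) + math.exp(0.04 * (v + 53.0)))
            + k1_b
        ),
    }


PARAMETER_NAMES = ("G_Na", "G_s", "G_x1", "G_K1")
DEFAULTS = (4.0, 0.09, 0.8, 0.35)
STATE_NAMES = ("V", "m", "h", "j", "d", "f", "x1", "Ca_i")

# Quiescent steady state at default conductances (no stimulus), computed by
# integrating the unstimulated model to rest and frozen here.
INITIAL_STATE = np.array(
    [
        -8.45737561e01,
        1.09819687e-02,
        9.87721175e-01,
        9.74838139e-01,
        2.97072466e-03,
        9.99981334e-01,
        5.62865057e-03,
        1.78200722e-07,
    ]
)


def build() -> CellModel:
    return CellModel(
        name="beeler_reuter_1977",
        n_state=8,
        state_names=STATE_NAMES,
        parameter_names=PARAMETER_NAMES,
        parameter_units={
            "G_Na": "mS/cm^2",
            "G_s": "mS/cm^2",
            "G_x1": "uA/cm^2",
            "G_K1": "uA/cm^2",
        },
        defaults=ParameterVector(PARAMETER_NAMES, DEFAULTS),
        initial_state=INITIAL_STATE.copy(),
        rhs=rhs,
        ionic_currents=ionic_currents,
        default_Ko=None,
        supports_extracellular_potassium=False,
        reference="Beeler & Reuter, J Physiol 268:177-210 (1977)",
    )
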