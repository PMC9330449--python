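"""The personalized HPT-axis ODE system.

Nineteen state variables (amounts in umol; TSH in internal mU-equivalent
units):

====  =========================================================
 0    plasma T4
 1    fast-tissue T4 (liver/kidney pool)
 2    slow-tissue T4
 3    plasma T3
 4    fast-tissue T3
 5    slow-tissue T3
 6    plasma/tissue TSH
 7    lumped brain T3 (T3B)
 8    lagged brain T3 (T3B_LAG)
 9    oral T4: undissolved pill
10    oral T4: gut (absorbable)
11    oral T3: undissolved pill
12    oral T3: gut
13-18 six-stage TSH delay chain driving thyroidal secretion
====  =========================================================

TSH secretion follows a circadian-modulated Hill form,

    SR_TSH(t) = [B0 + A0 f_CIRC sin(pi t / 12 - phi)]
                * K^m / (K^m + T3B_LAG^m),

with f_CIRC = T3B_LAG^n / (T3B_LAG^n + K_circ^n) gating the oscillation
amplitude (fluctuations vanish in deep hypothyroidism) and the Hill
suppressor saturating at B0 instead of blowing up exponentially when brain
T3 collapses.  The brain T4->T3 conversion gain is a decreasing Hill
function bounded between k3 and 6 k3.

Personalization enters through the plasma and TSH distribution volumes:
nonlinear terms calibrated at the 3.2 L / 5.2 L reference volumes (the
free-hormone binding cubics, the saturable TSH degradation, and the brain
uptake normalizers) receive concentration-equivalent amounts
``q * V_ref / V_patient``, while linear fractional rates act on amounts
directly.  Thyroidal secretion rates are multiplied by the residual thyroid
function fraction ``rtf``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .parameters import ModelParameters

__all__ = [
    "N_STATES",
    "IDX",
    "rhs",
    "rhs_vector",
    "circadian_modulation",
    "tsh_secretion_rate",
    "brain_t4_to_t3_gain",
    "default_state_guess",
]

N_STATES = 19

IDX = {
    "T4p": 0, "T4fast": 1, "T4slow": 2,
    "T3p": 3, "T3fast": 4, "T3slow": 5,
    "TSHp": 6, "T3B": 7, "T3B_LAG": 8,
    "T4PILL": 9, "T4GUT": 10, "T3PILL": 11, "T3GUT": 12,
    "delay1": 13, "delay2": 14, "delay3": 15,
    "delay4": 16, "delay5": 17, "delay6": 18,
}

_KDELAY = 5.0 / 8.0


@njit(cache=True)
def _rhs_core(t, q, p, dq):  # pragma: no cover - exercised via wrappers
    # parameter unpacking (see ModelParameters.to_vector for the layout)
    S4 = p[0]; k12 = p[1]; k13 = p[2]; k31free = p[3]; k21free = p[4]
    fA = p[5]; fB = p[6]; fC = p[7]; fD = p[8]
    k4absorb = p[9]; k02 = p[10]
    VmaxD1fast = p[11]; KmD1fast = p[12]
    VmaxD1slow = p[13]; KmD1slow = p[14]
    VmaxD2slow = p[15]; KmD2slow = p[16]
    S3 = p[17]; k45 = p[18]; k46 = p[19]; k64free = p[20]; k54free = p[21]
    fa = p[22]; fb = p[23]; fc = p[24]; fd = p[25]
    k3absorb = p[26]; k05 = p[27]
    B0 = p[28]; A0 = p[29]; phi = p[30]
    kdegTSH = p[31]; VmaxTSH = p[32]; K50TSH = p[33]
    k3 = p[34]; T4P_EU = p[35]; T3P_EU = p[36]; KdegT3B = p[37]
    KLAG_HYPO = p[38]; KLAG = p[39]
    k4dissolve = p[40]; k4excrete = p[41]; k3dissolve = p[42]; k3excrete = p[43]
    Vp = p[44]; VTSH = p[45]
    Kcirc = p[46]; Ksr = p[47]; hn = p[48]; hm = p[49]; Kf4 = p[50]; hl = p[51]
    rtf = p[52]; inf4 = p[53]; inf3 = p[54]
    Vp_base = p[55]; VTSH_base = p[56]

    # mild clipping: the integrator may carry O(atol) negatives
    q1 = max(q[0], 0.0); q2 = max(q[1], 0.0); q3 = max(q[2], 0.0)
    q4 = max(q[3], 0.0); q5 = max(q[4], 0.0); q6 = max(q[5], 0.0)
    q7 = max(q[6], 0.0); q8 = max(q[7], 0.0); q9 = max(q[8], 0.0)
    q10 = max(q[9], 0.0); q11 = max(q[10], 0.0)
    q12 = max(q[11], 0.0); q13 = max(q[12], 0.0)
    q19 = max(q[18], 0.0)

    # concentration-equivalent amounts at the calibration volumes
    vr_p = Vp_base / Vp
    vr_tsh = VTSH_base / VTSH
    q1c = q1 * vr_p
    q4c = q4 * vr_p
    q7c = q7 * vr_tsh

    # free-hormone fractions (cubic in concentration-equivalent amount)
    f_free4 = fA + fB * q1c + fC * q1c * q1c + fD * q1c * q1c * q1c
    if f_free4 < 0.0:
        f_free4 = 0.0
    f_free3 = fa + fb * q4c + fc * q4c * q4c + fd * q4c * q4c * q4c
    if f_free3 < 0.0:
        f_free3 = 0.0
    q1F = f_free4 * q1
    q4F = f_free3 * q4

    # thyroidal secretion driven by the delayed TSH signal, scaled by RTF
    SR4 = rtf * S4 * q19
    SR3 = rtf * S3 * q19

    # TSH secretion: circadian amplitude gate and brain-T3 Hill suppressor
    fCIRC = q9**hn / (q9**hn + Kcirc**hn)
    suppress = Ksr**hm / (Ksr**hm + q9**hm)
    SRTSH = (B0 + A0 * fCIRC * np.sin(np.pi / 12.0 * t - phi)) * suppress

    fdegTSH = kdegTSH + VmaxTSH / (K50TSH + q7c)

    # brain T4->T3 conversion gain, bounded in [k3, 6 k3]
    f4 = k3 * (1.0 + 5.0 * Kf4**hl / (Kf4**hl + q8**hl))

    # brain-T3 lag rate: fast when brain T3 is normal, very slow when depleted
    fLAG = KLAG_HYPO + 2.0 * q8**11 / (q8**11 + KLAG**11)

    # fast-tissue D1 conversion rate (acts on q2)
    NL = VmaxD1fast / (KmD1fast + q2)

    # T4 compartments
    dq[0] = (SR4 + k12 * q2 + k13 * q3 - (k31free + k21free) * q1F
             + k4absorb * q11 + inf4)
    dq[1] = k21free * q1F - (k12 + k02 + NL) * q2
    dq[2] = (k31free * q1F
             - (k13 + VmaxD1slow / (KmD1slow + q3) + VmaxD2slow / (KmD2slow + q3)) * q3)

    # T3 compartments
    dq[3] = (SR3 + k45 * q5 + k46 * q6 - (k64free + k54free) * q4F
             + k3absorb * q13 + inf3)
    dq[4] = k54free * q4F + NL * q2 - (k45 + k05) * q5
    dq[5] = (k64free * q4F + VmaxD1slow * q3 / (KmD1slow + q3)
             + VmaxD2slow * q3 / (KmD2slow + q3) - k46 * q6)

    # TSH
    dq[6] = SRTSH - fdegTSH * q7

    # lumped brain T3 and its lag
    dq[7] = f4 * (q1c / T4P_EU) + k3 * (q4c / T3P_EU) - KdegT3B * q8
    dq[8] = fLAG * (q8 - q9)

    # oral dosing chains
    dq[9] = -k4dissolve * q10
    dq[10] = k4dissolve * q10 - (k4excrete + k4absorb) * q11
    dq[11] = -k3dissolve * q12
    dq[12] = k3dissolve * q12 - (k3excrete + k3absorb) * q13

    # TSH delay chain
    dq[13] = -_KDELAY * q[13] + q7
    dq[14] = _KDELAY * (q[13] - q[14])
    dq[15] = _KDELAY * (q[14] - q[15])
    dq[16] = _KDELAY * (q[15] - q[16])
    dq[17] = _KDELAY * (q[16] - q[17])
    dq[18] = _KDELAY * (q[17] - q[18])
    return dq


def rhs_vector(t: float, state: np.ndarray, pvec: np.ndarray) -> np.ndarray:
    """Time derivative of the 19-state system for a raw parameter vector."""
    dq = np.empty(N_STATES, dtype=np.float64)
    _rhs_core(t, np.asarray(state, dtype=np.float64), pvec, dq)
    if not np.all(np.isfinite(dq)):
        raise FloatingPointError(
            f"non-finite derivative at t={t}: state={np.asarray(state)!r}"
        )
    return dq


def rhs(
    t: float,
    state: np.ndarray,
    params: ModelParameters,
    t4_infusion: float = 0.0,
    t3_infusion: float = 0.0,
) -> np.ndarray:
    """Time derivative for a :class:`ModelParameters` set.

    Infusion rates are constant plasma inputs in umol/h; oral boluses are
    handled by the simulator as state jumps, not through the RHS.
    """
    state = np.asarray(state, dtype=np.float64)
    if state.shape != (N_STATES,):
        raise ValueError(f"state must have shape ({N_STATES},), got {state.shape}")
    if np.min(state) < -1e-6:
        raise ValueError(
            f"state has negative entries beyond integrator tolerance: min={np.min(state):g}"
        )
    return rhs_vector(t, state, params.to_vector(t4_infusion, t3_infusion))


# -- pure submodel functions (mirrors of the RHS internals) -------------------

def _hill_up(x: float, k: float, n: float) -> float:
    """x^n / (x^n + k^n), evaluated in log space to avoid overflow."""
    if x == 0.0:
        return 0.0
    t = n * (np.log(k) - np.log(x))
    if t > 700.0:
        return 0.0
    if t < -700.0:
        return 1.0
    return 1.0 / (1.0 + np.exp(t))


def circadian_modulation(t3b_lag: float, params: ModelParameters) -> float:
    """Amplitude gate f_CIRC = x^n / (x^n + K_circ^n), monotone in [0, 1]."""
    if t3b_lag < 0:
        raise ValueError(f"t3b_lag must be non-negative, got {t3b_lag}")
    return _hill_up(float(t3b_lag), params.K_circ, params.n)


def tsh_secretion_rate(t: float, t3b_lag: float, params: ModelParameters) -> float:
    """Circadian TSH secretion rate; bounded in (0, B0 + A0] for all inputs."""
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t}")
    if t3b_lag < 0:
        raise ValueError(f"t3b_lag must be non-negative, got {t3b_lag}")
    x = float(t3b_lag)
    suppress = 1.0 - _hill_up(x, params.K_SR_TSH, params.m)
    fcirc = circadian_modulation(x, params)
    return (params.B0 + params.A0 * fcirc * np.sin(np.pi / 12.0 * t - params.phi)) * suppress


def brain_t4_to_t3_gain(t3b: float, params: ModelParameters) -> float:
    """Brain T4->T3 conversion gain, decreasing from 6 k3 (depleted) to k3."""
    if t3b < 0:
        raise ValueError(f"t3b must be non-negative, got {t3b}")
    hill = 1.0 - _hill_up(float(t3b), params.K_f4, params.l)
    return params.k3 * (1.0 + 5.0 * hill)


def default_state_guess(params: ModelParameters) -> np.ndarray:
    """Rough euthyroid state used to seed steady-state computations."""
    vr_p = params.Vp / params.Vp_base
    vr_tsh = params.VTSH / params.VTSH_base
    q = np.zeros(N_STATES)
    q[0] = 0.322 * vr_p
    q[1] = 0.201
    q[2] = 0.638
    q[3] = 0.0064 * vr_p
    q[4] = 0.0095
    q[5] = 0.056
    q[6] = 1.64 * vr_tsh
    q[7] = 8.4
    q[8] = 8.4
    q[13:19] = q[6] / _KDELAY
    return q
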