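"""Fixed-step RK4 kernel for likelihood evaluation.

Pooled maximum-likelihood fitting evaluates the tumor-growth ODE for every
subject at every objective call; a compiled fixed-step integrator over a
precomputed plasma-concentration table keeps that affordable on one CPU.
The reference integrator remains scipy's adaptive LSODA (`tumor.simulate`);
tests pin the two against each other.

The single kernel integrates the 5-state resistance system; the base model
is the exact special case ``kSR = 0`` (the resistant compartment then stays
identically zero).  The simulation-only threshold effect on resistant cells
plays no role in estimation and is not implemented here.

Step size is chosen so that the stiffest rate allowed by the optimizer
bounds keeps ``rate * dt`` inside the RK4 stability region; states are
clipped at zero after each step to suppress tolerance-level undershoot.
Dose times should be multiples of the step size: the concentration kink at
dose onset then falls on a step boundary and the integrator keeps its
order (observation days and dose days in the study designs are whole or
hundredth days, which the default 0.01 d step divides exactly).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["cp_halfstep_table", "rk4_tv_at_obs", "cp_scalar", "DEFAULT_DT"]

DEFAULT_DT = 0.01  # days


@njit(cache=True)
def cp_scalar(t, dose_times, amounts, veffs, ka, ke):
    """Superposed one-compartment oral ``Cp(t)`` [ug/L] at a scalar time.

    Compiled hot path for ODE right-hand sides, where the concentration is
    evaluated once per solver step.
    """
    c = 0.0
    for i in range(dose_times.shape[0]):
        dtt = t - dose_times[i]
        if dtt >= 0.0:
            c += (amounts[i] * ka / (veffs[i] * (ka - ke))) * (
                np.exp(-ke * dtt) - np.exp(-ka * dtt))
    return c if c > 0.0 else 0.0


def cp_halfstep_table(dose_times, amounts_ug, volumes_l, ka, ke,
                      t_max: float, dt: float = DEFAULT_DT) -> np.ndarray:
    """``Cp`` [ug/L] on the half-step grid ``0, dt/2, dt, ...`` up to t_max.

    Superposed per-dose bilinear-exponential terms; computed once per subject
    and reused for every objective evaluation (PK parameters are fixed
    during PD fitting).
    """
    n_steps = int(round(t_max / dt))
    t = np.arange(2 * n_steps + 1) * (dt / 2.0)
    cp = np.zeros_like(t)
    for td, a0, veff in zip(dose_times, amounts_ug, volumes_l):
        dtt = t - td
        m = dtt >= 0
        cp[m] += (a0 * ka / (veff * (ka - ke))) * (
            np.exp(-ke * dtt[m]) - np.exp(-ka * dtt[m]))
    return np.maximum(cp, 0.0)


@njit(cache=True)
def _rhs(S, T1, T2, T3, R, c, l0, l1, k1, k2, ksr, bl0, bl1):
    gS = 2.0 * l0 * l1 * S / (2.0 * l0 * S + l1) if S > 0.0 else 0.0
    gR = 2.0 * bl0 * bl1 * R / (2.0 * bl0 * R + bl1) if R > 0.0 else 0.0
    kill = k2 * c * S
    dS = gS - kill
    dT1 = kill - k1 * T1
    dT2 = k1 * (T1 - T2)
    dT3 = k1 * (T2 - T3) - ksr * T3
    dR = gR + ksr * T3
    return dS, dT1, dT2, dT3, dR


@njit(cache=True)
def rk4_tv_at_obs(cp_half, dt, obs_steps, tv0, l0, l1, k1, k2, ksr, beta):
    """Integrate from t=0 with S(0)=tv0 and return total volume at obs steps.

    ``cp_half`` holds Cp at half-step resolution; ``obs_steps`` are sorted
    integer step indices (time = index * dt).  Returns NaN-filled output if
    the state leaves the finite range (signals the objective to reject).
    """
    n_steps = (cp_half.shape[0] - 1) // 2
    bl0 = beta * l0
    bl1 = beta * l1
    preds = np.empty(obs_steps.shape[0])
    S, T1, T2, T3, R = tv0, 0.0, 0.0, 0.0, 0.0
    j = 0
    while j < obs_steps.shape[0] and obs_steps[j] == 0:
        preds[j] = S
        j += 1
    for i in range(n_steps):
        c0 = cp_half[2 * i]
        cm = cp_half[2 * i + 1]
        c1 = cp_half[2 * i + 2]
        a1, b1, c1_, d1, e1 = _rhs(S, T1, T2, T3, R, c0, l0, l1, k1, k2, ksr, bl0, bl1)
        a2, b2, c2_, d2, e2 = _rhs(S + 0.5 * dt * a1, T1 + 0.5 * dt * b1,
                                   T2 + 0.5 * dt * c1_, T3 + 0.5 * dt * d1,
                                   R + 0.5 * dt * e1, cm, l0, l1, k1, k2, ksr, bl0, bl1)
        a3, b3, c3_, d3, e3 = _rhs(S + 0.5 * dt * a2, T1 + 0.5 * dt * b2,
                                   T2 + 0.5 * dt * c2_, T3 + 0.5 * dt * d2,
                                   R + 0.5 * dt * e2, cm, l0, l1, k1, k2, ksr, bl0, bl1)
        a4, b4, c4_, d4, e4 = _rhs(S + dt * a3, T1 + dt * b3, T2 + dt * c3_,
                                   T3 + dt * d3, R + dt * e3, c1,
                                   l0, l1, k1, k2, ksr, bl0, bl1)
        S += dt / 6.0 * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
        T1 += dt / 6.0 * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
        T2 += dt / 6.0 * (c1_ + 2.0 * c2_ + 2.0 * c3_ + c4_)
        T3 += dt / 6.0 * (d1 + 2.0 * d2 + 2.0 * d3 + d4)
        R += dt / 6.0 * (e1 + 2.0 * e2 + 2.0 * e3 + e4)
        if S < 0.0:
            S = 0.0
        if T1 < 0.0:
            T1 = 0.0
        if T2 < 0.0:
            T2 = 0.0
        if T3 < 0.0:
            T3 = 0.0
        if R < 0.0:
            R = 0.0
        tv = S + T1 + T2 + T3 + R
        if not np.isfinite(tv):
            preds[:] = np.nan
            return preds
        while j < obs_steps.shape[0] and obs_steps[j] == i + 1:
            preds[j] = tv
            j += 1
    return preds
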