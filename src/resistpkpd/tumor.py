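"""Tumor-growth-inhibition ODE models with and without acquired resistance.

Base model: proliferating cells ``S`` grow with a smooth switch from
exponential (rate ``lambda0``) to linear (rate ``lambda1``) growth; the
plasma-concentration-proportional kill ``k2 * Cp * S`` routes cells through
three transit compartments ``T1 -> T2 -> T3`` (rate ``k1``) before they
leave the tumor.  Total volume is the sum of all compartments.

Resistance model: terminally damaged cells convert to a resistant pool ``R``
at first-order rate ``kSR``; resistant cells grow with the same functional
form scaled by ``beta`` (both growth rates).  An optional threshold-triggered
drug effect on resistant cells (DER) is active only while ``Cp`` exceeds a
threshold concentration ``C_th``; it is a simulation-only device (no such
effect was identifiable from the fitted data) and is off by default.

The DER term as commonly stated, ``k2R * Cp``, carries no cell-mass factor
and would drive ``R`` negative; the default here is the mass-action form
``k2R * Cp * R`` (symmetric with the kill on sensitive cells), with
``der_form='as_printed'`` available for the zeroth-order variant (clamped at
``R = 0``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .errors import InputError, InvalidParameterError, SolverError
from .pk import PKProfile, threshold_crossings

__all__ = [
    "BaseTGIParameters",
    "ResistanceTGIParameters",
    "Trajectory",
    "growth_rate",
    "rhs_base",
    "rhs_resistance",
    "simulate",
    "tau",
    "resistant_fraction",
]


@dataclass(frozen=True)
class BaseTGIParameters:
    """Base TGI parameters: TV0 [mm3], lambda0 [1/d], lambda1 [mm3/d],
    k1 [1/d] transit rate, k2 [L/ug/d] kill slope."""

    TV0: float
    lambda0: float
    lambda1: float
    k1: float
    k2: float

    def __post_init__(self):
        for name in ("TV0", "lambda0", "lambda1", "k1"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.k2 < 0:
            raise InvalidParameterError(f"k2 must be >= 0, got {self.k2}")

    def with_(self, **kw):
        return replace(self, **kw)

    @property
    def n_states(self) -> int:
        return 4


@dataclass(frozen=True)
class ResistanceTGIParameters(BaseTGIParameters):
    """Acquired-resistance extension.

    kSR [1/d]: damaged-to-resistant conversion; beta: ratio of resistant to
    sensitive growth rates (scales both lambda0 and lambda1); k2R [L/ug/d]
    and C_th [ug/L] parameterize the simulation-only threshold drug effect
    on resistant cells, active only when ``der_enabled``.
    """

    kSR: float = 0.0
    beta: float = 1.0
    k2R: float = 0.0
    C_th: float = float("inf")
    der_enabled: bool = False
    der_form: str = "mass_action"

    def __post_init__(self):
        super().__post_init__()
        if self.kSR < 0:
            raise InvalidParameterError(f"kSR must be >= 0, got {self.kSR}")
        if self.beta <= 0:
            raise InvalidParameterError(f"beta must be > 0, got {self.beta}")
        if self.k2R < 0:
            raise InvalidParameterError(f"k2R must be >= 0, got {self.k2R}")
        if self.der_form not in ("mass_action", "as_printed"):
            raise InvalidParameterError(f"unknown der_form {self.der_form!r}")
        if self.der_enabled and not np.isfinite(self.C_th):
            raise InvalidParameterError("der_enabled requires a finite C_th")

    @property
    def n_states(self) -> int:
        return 5


def growth_rate(S: float, lambda0: float, lambda1: float):
    """Growth contribution ``2*l0*l1*S / (2*l0*S + l1)`` [mm3/d].

    A smooth switch between growth phases: tends to ``2*lambda0*S``
    (exponential) as ``S -> 0`` and saturates at ``lambda1`` (linear) as
    ``S -> inf``; the two phases contribute equally at ``S = lambda1 /
    (2*lambda0)``.
    """
    S = np.asarray(S, dtype=float)
    return 2.0 * lambda0 * lambda1 * S / (2.0 * lambda0 * S + lambda1)


def rhs_base(state, t, params: BaseTGIParameters, cp_at) -> np.ndarray:
    """Right-hand side of the base model; ``cp_at`` maps t -> Cp [ug/L]."""
    S, T1, T2, T3 = state
    cp = float(np.asarray(cp_at(t)).reshape(-1)[0])
    kill = params.k2 * cp * S
    return np.array([
        growth_rate(S, params.lambda0, params.lambda1) - kill,
        kill - params.k1 * T1,
        params.k1 * (T1 - T2),
        params.k1 * (T2 - T3),
    ])


def rhs_resistance(state, t, params: ResistanceTGIParameters, cp_at) -> np.ndarray:
    """Right-hand side of the resistance model (5 states S, T1, T2, T3, R)."""
    S, T1, T2, T3, R = state
    cp = float(np.asarray(cp_at(t)).reshape(-1)[0])
    kill = params.k2 * cp * S
    der = 0.0
    if params.der_enabled and cp > params.C_th:
        if params.der_form == "mass_action":
            der = params.k2R * cp * R
        else:  # zeroth order in R, clamped so R cannot be driven negative
            der = params.k2R * cp if R > 0 else 0.0
    dR = (growth_rate(R, params.beta * params.lambda0, params.beta * params.lambda1)
          + params.kSR * T3 - der)
    return np.array([
        growth_rate(S, params.lambda0, params.lambda1) - kill,
        kill - params.k1 * T1,
        params.k1 * (T1 - T2),
        params.k1 * (T2 - T3) - params.kSR * T3,
        dR,
    ])


@dataclass
class Trajectory:
    """Dense simulated state paths on a time grid.

    ``R`` is None for base-model trajectories.  ``TV`` is the compartment sum
    at every grid point; ``Cp`` the driving concentration.
    """

    t: np.ndarray
    S: np.ndarray
    T1: np.ndarray
    T2: np.ndarray
    T3: np.ndarray
    Cp: np.ndarray
    R: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def has_resistance(self) -> bool:
        return self.R is not None

    @property
    def TV(self) -> np.ndarray:
        tv = self.S + self.T1 + self.T2 + self.T3
        if self.R is not None:
            tv = tv + self.R
        return tv

    def tv_at(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.t, self.TV)

    def to_frame(self):
        import pandas as pd
        cols = {"time": self.t, "S": self.S, "T1": self.T1, "T2": self.T2,
                "T3": self.T3}
        if self.R is not None:
            cols["R"] = self.R
        cols["TV"] = self.TV
        cols["Cp"] = self.Cp
        if self.R is not None:
            cols["resistant_fraction"] = resistant_fraction(self)
        return pd.DataFrame(cols)


def _zero_cp(t):
    return np.zeros_like(np.atleast_1d(np.asarray(t, dtype=float)))


def simulate(params: BaseTGIParameters, pk_profile: PKProfile | None, grid,
             model: str | None = None, rtol: float = 1e-8, atol: float = 1e-10,
             method: str = "LSODA") -> Trajectory:
    """Integrate a TGI model driven by a plasma-concentration profile.

    Initial condition: ``S(0) = TV0``, all other compartments 0.  The grid is
    augmented internally with dose-event times and (when the threshold effect
    is on) with the threshold-crossing times of ``Cp``, and integration is
    restarted at those points so the solver never steps across a derivative
    discontinuity.  ``pk_profile=None`` simulates vehicle (``Cp = 0``).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise InputError("grid must be strictly increasing with >= 2 points")
    if model is None:
        model = "resistance" if isinstance(params, ResistanceTGIParameters) else "base"
    if model == "resistance" and not isinstance(params, ResistanceTGIParameters):
        raise InputError("resistance model requires ResistanceTGIParameters")
    if model == "base":
        n = 4
        rhs = rhs_base
        if isinstance(params, ResistanceTGIParameters):
            params = BaseTGIParameters(params.TV0, params.lambda0, params.lambda1,
                                       params.k1, params.k2)
    else:
        n = 5
        rhs = rhs_resistance

    cp_at = (pk_profile.concentration_scalar if pk_profile is not None
             else _zero_cp)

    breaks = set()
    if pk_profile is not None:
        breaks.update(float(t) for t in pk_profile.dose_times)
        if (model == "resistance" and params.der_enabled
                and np.isfinite(params.C_th) and len(pk_profile.dose_times)):
            breaks.update(float(t) for t in
                          threshold_crossings(pk_profile, params.C_th,
                                              (grid[0], grid[-1])))
    breaks = sorted(b for b in breaks if grid[0] < b < grid[-1])
    segments = np.concatenate([[grid[0]], breaks, [grid[-1]]])

    y = np.zeros(n)
    y[0] = params.TV0
    out = np.full((n, grid.size), np.nan)
    out[:, 0] = y
    for a, b in zip(segments[:-1], segments[1:]):
        mask = (grid > a) & (grid <= b)
        t_eval = grid[mask]
        # always evaluate at the segment end so the next segment restarts
        # from the true boundary state, not the last grid point before it
        has_b = t_eval.size and np.isclose(t_eval[-1], b)
        t_run = t_eval if has_b else np.append(t_eval, b)
        sol = solve_ivp(lambda t, s: rhs(s, t, params, cp_at), (a, b), y,
                        t_eval=t_run, method=method, rtol=rtol, atol=atol)
        if not sol.success:
            raise SolverError(
                f"TGI integration failed on [{a:.4g}, {b:.4g}] with params "
                f"{params}: {sol.message}")
        if t_eval.size:
            out[:, mask] = sol.y[:, :t_eval.size] if not has_b else sol.y
        y = np.maximum(sol.y[:, -1], 0.0)  # clip tolerance-level negativity

    out = np.maximum(out, 0.0)
    cp_grid = (pk_profile.concentration(grid) if pk_profile is not None
               else np.zeros_like(grid))
    R = out[4] if n == 5 else None
    return Trajectory(t=grid, S=out[0], T1=out[1], T2=out[2], T3=out[3],
                      Cp=np.asarray(cp_grid), R=R,
                      meta={"model": model, "rtol": rtol, "atol": atol})


def tau(k1: float) -> float:
    """Mean transit time through the three damage stages, ``3 / k1`` [d].

    Interpreted as the average time for a damaged tumor cell to be
    eradicated or converted to resistance (valid while ``kSR << k1``).
    """
    if k1 <= 0:
        raise InvalidParameterError(f"k1 must be > 0, got {k1}")
    return 3.0 / k1


def resistant_fraction(traj: Trajectory) -> np.ndarray:
    """``R / TV`` per grid point, in [0, 1]; 0 where the tumor is empty."""
    if not traj.has_resistance:
        raise InputError("trajectory has no resistant compartment (base model)")
    tv = traj.TV
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(tv > 0, traj.R / np.where(tv > 0, tv, 1.0), 0.0)
    return np.clip(frac, 0.0, 1.0)
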