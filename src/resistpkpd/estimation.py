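"""Likelihood-based parameter estimation and AIC model discrimination.

Estimators follow the scikit-learn protocol (``fit`` on an
:class:`~resistpkpd.data.ObservationTable`, fitted attributes with trailing
underscores, ``get_params``/``set_params``):

* :class:`PKCurveFit` -- one-compartment oral PK by maximum likelihood with
  a proportional residual error, pooled or per-subject ("two-stage").
* :class:`TumorGrowthFit` -- pooled maximum likelihood for the base or
  resistance tumor model with a combined (additive + proportional) residual
  error, fit sequentially after PK (individual PK parameters fixed), with
  optional categorical dose-group covariates.

Estimation is naive-pooled / two-stage rather than full nonlinear
mixed-effects: the reproducible surface here is the AIC direction, the
covariate logic and parameter recovery, none of which require random-effect
machinery.  AIC counts structural fixed effects only (residual-error
parameters are common to the compared models and drop out of the
difference); the counting convention is recorded on every fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from . import _fastode
from .data import ObservationTable
from .errors import InputError, InvalidParameterError
from .pk import PKParameters, effective_volume

__all__ = [
    "ErrorModel",
    "FitResult",
    "CovariateSpec",
    "neg_log_likelihood",
    "PKCurveFit",
    "TumorGrowthFit",
    "fit_pk",
    "fit_pd",
    "compare_models",
    "covariate_test",
    "ModelComparison",
    "CovariateTestReport",
]

_BIG = 1e12


@dataclass(frozen=True)
class ErrorModel:
    """Residual-error model: SD(f) = a + b*f.

    ``proportional`` fixes ``a = 0`` (used for PK); ``combined`` allows both
    components (used for tumor volumes).
    """

    kind: str = "combined"
    a: float = 0.0
    b: float = 0.1

    def __post_init__(self):
        if self.kind not in ("proportional", "combined"):
            raise InvalidParameterError(f"unknown error model {self.kind!r}")
        if self.a < 0 or self.b < 0:
            raise InvalidParameterError("error components must be >= 0")
        if self.kind == "proportional" and self.a != 0:
            raise InvalidParameterError("proportional error requires a = 0")

    def sd(self, f):
        return self.a + self.b * np.asarray(f, dtype=float)


def neg_log_likelihood(y, f, error: ErrorModel, blq=None, loq=None,
                       blq_mode: str = "drop") -> float:
    """Gaussian negative log-likelihood of observations ``y`` given
    predictions ``f`` under an error model.

    BLQ rows (``blq`` truthy) are dropped by default; with
    ``blq_mode='censored'`` they contribute the left-censored term
    ``-log Phi((loq - f) / sd)``.
    """
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    if y.shape != f.shape:
        raise InputError("y and f must have the same shape")
    if not np.all(np.isfinite(f)):
        return _BIG
    sd = np.maximum(error.sd(f), 1e-12)
    if blq is None:
        blq = np.zeros(y.shape, dtype=bool)
    blq = np.asarray(blq, dtype=bool)
    keep = ~blq
    nll = -np.sum(stats.norm.logpdf(y[keep], loc=f[keep], scale=sd[keep]))
    if blq_mode == "censored" and np.any(blq):
        if loq is None:
            raise InputError("censored BLQ handling requires a LOQ")
        nll -= np.sum(stats.norm.logcdf(loq, loc=f[blq], scale=sd[blq]))
    elif blq_mode not in ("drop", "censored"):
        raise InputError(f"unknown blq_mode {blq_mode!r}")
    return float(nll)


@dataclass
class FitResult:
    """Point estimates with likelihood bookkeeping.

    ``k`` counts estimated structural fixed effects (covariate categories
    included, residual-error parameters excluded); ``aic = 2k - 2 loglik``
    holds exactly by construction.
    """

    params: dict
    loglik: float
    k: int
    n_obs: int
    error_model: ErrorModel
    converged: bool
    residuals: pd.DataFrame | None = None
    data_fingerprint: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    def parameter_table(self) -> pd.DataFrame:
        rows = []
        for name, value in self.params.items():
            base, _, cat = name.partition("__")
            rows.append({"name": base, "category": cat or "all", "estimate": value})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class CovariateSpec:
    """Categorical dose-group covariate splitting one structural parameter.

    ``parameter`` is ``'kSR'`` or ``'k2'``; for ``k2`` a ``compound`` must
    be named (the split applies to that compound's slope only).  Subjects in
    ``high_groups`` get the ``<name>__high`` category value; all others the
    reference value.
    """

    parameter: str
    compound: str | None = None
    column: str = "GROUP"
    high_groups: tuple = ("high",)

    def key(self, compounds) -> str:
        if self.parameter == "k2":
            if self.compound is None:
                raise InputError("k2 covariate requires a compound")
            if self.compound not in compounds:
                raise InputError(f"compound {self.compound!r} not in dataset")
            return f"k2_{self.compound}"
        return self.parameter


# ---------------------------------------------------------------------------
# PK estimation
# ---------------------------------------------------------------------------

_PK_BOUNDS = {"ke": (0.05, 200.0), "V": (1e-3, 500.0), "I": (1e-7, 0.1),
              "b": (1e-3, 2.0)}
_PK_INIT = {"ke": 5.0, "V": 0.5, "I": 1e-3, "b": 0.2}


def _cp_superposed(t, dose_times, amounts, veffs, ka, ke):
    t = np.asarray(t, dtype=float)
    cp = np.zeros_like(t)
    for td, a0, veff in zip(dose_times, amounts, veffs):
        dtt = t - td
        m = dtt >= 0
        cp[m] += (a0 * ka / (veff * (ka - ke))) * (
            np.exp(-ke * dtt[m]) - np.exp(-ka * dtt[m]))
    return np.maximum(cp, 0.0)


class PKCurveFit(BaseEstimator):
    """ML fit of the one-compartment oral PK model to sparse concentrations.

    Parameters
    ----------
    compound : which compound's PK rows to fit (required).
    fix_ka : absorption rate held fixed [1/d] (poorly identified from sparse
        sampling; the canonical studies fix it at 55/d). Pass None to estimate.
    estimate_I : estimate the dose-dependent volume term; defaults to True
        for gefitinib and False otherwise (then ``I`` is fixed at 0 and is
        absent from the estimate vector).
    mode : 'pooled' (one parameter set) or 'per_subject' (two-stage: each
        subject fit separately; the summary is the geometric mean).
    body_weight : kg, dose-to-amount convention attached to the results.
    """

    def __init__(self, compound="erlotinib", fix_ka=55.0, estimate_I=None,
                 mode="pooled", n_starts=3, seed=0, init=None,
                 body_weight=0.025, blq_mode="drop", loq=1.0):
        self.compound = compound
        self.fix_ka = fix_ka
        self.estimate_I = estimate_I
        self.mode = mode
        self.n_starts = n_starts
        self.seed = seed
        self.init = init
        self.body_weight = body_weight
        self.blq_mode = blq_mode
        self.loq = loq

    # internal: parameter names in the estimate vector
    def _names(self):
        est_I = (self.compound == "gefitinib" if self.estimate_I is None
                 else self.estimate_I)
        names = [] if self.fix_ka is not None else ["ka"]
        names += ["ke", "V"] + (["I"] if est_I else []) + ["b"]
        return names

    def _subject_blocks(self, table: ObservationTable):
        blocks = []
        for sid in table.subjects:
            if table.compound_of(sid) != self.compound:
                continue
            obs = table.observations("pk", subject=sid)
            if obs.empty:
                continue
            regimen = table.regimen_for(sid)
            events = regimen.grouped_events()
            blocks.append({
                "id": sid,
                "t": obs["TIME"].to_numpy(float),
                "y": obs["DV"].to_numpy(float),
                "blq": obs["BLQ"].to_numpy() != 0,
                "dose_times": np.array([e[0] for e in events]),
                "doses": np.array([e[1] for e in events]),
            })
        if not blocks:
            raise InputError(f"no PK observations for compound {self.compound!r}")
        return blocks

    def _predictions_for(self, theta: dict, blocks):
        ka = theta.get("ka", self.fix_ka)
        ke, V = theta["ke"], theta["V"]
        I = theta.get("I", 0.0)
        if abs(ka - ke) < 1e-9:
            return None
        fs = []
        for blk in blocks:
            veffs = V - blk["doses"] * I
            if np.any(veffs <= 0):
                return None
            amounts = blk["doses"] * self.body_weight * 1000.0
            fs.append(_cp_superposed(blk["t"], blk["dose_times"], amounts,
                                     veffs, ka, ke))
        return fs

    def _nll(self, theta: dict, blocks) -> float:
        fs = self._predictions_for(theta, blocks)
        if fs is None:
            return _BIG
        err = ErrorModel("proportional", 0.0, theta["b"])
        total = 0.0
        for blk, f in zip(blocks, fs):
            total += neg_log_likelihood(blk["y"], f, err, blq=blk["blq"],
                                        loq=self.loq, blq_mode=self.blq_mode)
        return total

    def _concentrated(self, theta_struct: dict, blocks):
        """NLL with the proportional SD profiled out (BLQ rows dropped).

        For fixed structural parameters the ML proportional SD has the
        closed form ``b^2 = mean((y/f - 1)^2)``, which removes the
        ill-conditioned error direction from the search space.
        """
        fs = self._predictions_for(theta_struct, blocks)
        if fs is None:
            return _BIG, np.nan
        r2, logf, n = 0.0, 0.0, 0
        for blk, f in zip(blocks, fs):
            keep = ~blk["blq"] & (f > 0)
            if keep.sum() < blk["blq"].size - blk["blq"].sum():
                return _BIG, np.nan  # non-positive prediction for a real obs
            y, fk = blk["y"][keep], f[keep]
            r2 += float(np.sum((y / fk - 1.0) ** 2))
            logf += float(np.sum(np.log(fk)))
            n += int(keep.sum())
        if n == 0:
            return _BIG, np.nan
        b_hat = float(np.clip(np.sqrt(r2 / n), *_PK_BOUNDS["b"]))
        nll = (n * np.log(b_hat) + logf + 0.5 * n * np.log(2 * np.pi)
               + r2 / (2.0 * b_hat ** 2))
        return float(nll), b_hat

    def _heuristic_init(self, blocks) -> dict:
        """Crude data-driven starts: V from amount/Cmax, ke from terminal slope."""
        v0s, slopes = [], []
        for blk in blocks:
            keep = ~blk["blq"]
            t, y = blk["t"][keep], blk["y"][keep]
            if y.size == 0:
                continue
            imax = int(np.argmax(y))
            prior = blk["dose_times"][blk["dose_times"] <= t[imax] + 1e-9]
            if prior.size:
                dose = blk["doses"][np.argmin(np.abs(blk["dose_times"] - prior[-1]))]
                v0s.append(dose * self.body_weight * 1000.0 / y[imax])
            order = np.argsort(t)
            ts, ys = t[order], y[order]
            for i in range(len(ts) - 1):
                dt = ts[i + 1] - ts[i]
                if 0 < dt <= 1.0 and 0 < ys[i + 1] < ys[i]:
                    slopes.append(np.log(ys[i] / ys[i + 1]) / dt)
        init = {}
        if v0s:
            init["V"] = float(np.clip(np.median(v0s), *_PK_BOUNDS["V"]))
        if slopes:
            init["ke"] = float(np.clip(np.median(slopes), *_PK_BOUNDS["ke"]))
        return init

    def _optimize(self, blocks, rng):
        names = self._names()
        init = dict(_PK_INIT)
        bounds = dict(_PK_BOUNDS)
        if self.fix_ka is None:
            init["ka"] = 20.0
            bounds["ka"] = (0.5, 500.0)
        init.update(self._heuristic_init(blocks))
        if self.init:
            init.update(self.init)
        profile_b = self.blq_mode == "drop"
        struct = [n for n in names if n != "b"] if profile_b else names
        x0 = np.log([init[n] for n in struct])
        lb = np.log([bounds[n][0] for n in struct])
        ub = np.log([bounds[n][1] for n in struct])

        if profile_b:
            def obj(x):
                return self._concentrated(dict(zip(struct, np.exp(x))), blocks)[0]
        else:
            def obj(x):
                return self._nll(dict(zip(struct, np.exp(x))), blocks)

        best = None
        for s in range(self.n_starts):
            start = x0 if s == 0 else np.clip(x0 + rng.normal(0, 0.4, x0.size), lb, ub)
            res = optimize.minimize(obj, start, method="L-BFGS-B",
                                    bounds=list(zip(lb, ub)),
                                    options={"maxfun": 2000})
            if best is None or res.fun < best.fun:
                best = res
        # simplex polish: quasi-Newton line searches can stall on the steep
        # exponential surface
        polish = optimize.minimize(obj, best.x, method="Nelder-Mead",
                                   options={"maxfev": 800, "xatol": 1e-10,
                                            "fatol": 1e-12})
        if polish.fun < best.fun:
            best = polish
        xbest = np.clip(best.x, lb, ub)
        theta = dict(zip(struct, np.exp(xbest)))
        if profile_b:
            nll, b_hat = self._concentrated(theta, blocks)
            theta["b"] = b_hat
        else:
            nll = self._nll(theta, blocks)
        return theta, -float(nll), bool(best.success)

    def fit(self, table: ObservationTable) -> "PKCurveFit":
        blocks = self._subject_blocks(table)
        rng = np.random.default_rng(self.seed)
        names = self._names()
        if self.mode == "pooled":
            theta, loglik, ok = self._optimize(blocks, rng)
            per_subject = {blk["id"]: dict(theta) for blk in blocks}
            k = len(names)
        elif self.mode == "per_subject":
            per_subject, logliks, oks = {}, [], []
            for blk in blocks:
                th, ll, ok_i = self._optimize([blk], rng)
                per_subject[blk["id"]] = th
                logliks.append(ll)
                oks.append(ok_i)
            loglik, ok = float(np.sum(logliks)), all(oks)
            theta = {n: float(np.exp(np.mean([np.log(p[n]) for p in per_subject.values()])))
                     for n in names}
            k = len(names) * len(blocks)
        else:
            raise InputError(f"unknown mode {self.mode!r}")

        self.params_ = theta
        self.individual_params_ = pd.DataFrame.from_dict(per_subject, orient="index")
        self.loglik_ = loglik
        self.k_ = k
        self.n_obs_ = int(sum((~b["blq"]).sum() if self.blq_mode == "drop"
                              else b["t"].size for b in blocks))
        self.converged_ = ok
        self.result_ = FitResult(
            params=dict(theta), loglik=loglik, k=k, n_obs=self.n_obs_,
            error_model=ErrorModel("proportional", 0.0, theta["b"]),
            converged=ok, data_fingerprint=table.fingerprint(),
            meta={"compound": self.compound, "mode": self.mode,
                  "fixed_ka": self.fix_ka})
        return self

    def pk_parameters(self, fu: float = 1.0, MW: float = float("nan")) -> dict:
        """Per-subject :class:`PKParameters` for sequential PD fitting."""
        out = {}
        for sid, row in self.individual_params_.iterrows():
            out[sid] = PKParameters(
                ka=float(row.get("ka", self.fix_ka)), ke=float(row["ke"]),
                V=float(row["V"]), I=float(row.get("I", 0.0)), fu=fu, MW=MW,
                body_weight=self.body_weight)
        return out

    def predict(self, table: ObservationTable) -> np.ndarray:
        """Predicted concentrations for this compound's PK rows."""
        blocks = self._subject_blocks(table)
        theta = self.params_
        ka = theta.get("ka", self.fix_ka)
        preds = []
        for blk in blocks:
            row = (self.individual_params_.loc[blk["id"]]
                   if blk["id"] in self.individual_params_.index else theta)
            ke, V, I = float(row["ke"]), float(row["V"]), float(row.get("I", 0.0))
            veffs = V - blk["doses"] * I
            amounts = blk["doses"] * self.body_weight * 1000.0
            preds.append(_cp_superposed(blk["t"], blk["dose_times"], amounts,
                                        veffs, ka, ke))
        return np.concatenate(preds)


# ---------------------------------------------------------------------------
# PD (tumor) estimation
# ---------------------------------------------------------------------------

_PD_BOUNDS = {
    "lambda0": (1e-3, 5.0), "lambda1": (1.0, 500.0), "k1": (0.05, 20.0),
    "beta": (0.05, 5.0), "kSR": (1e-6, 1.0), "k2": (1e-7, 5e-3),
    "err_a": (1e-6, 100.0), "err_b": (1e-3, 2.0),
}
_PD_INIT = {
    "lambda0": 0.2, "lambda1": 40.0, "k1": 1.5, "beta": 0.8, "kSR": 5e-3,
    "k2": 1e-4, "err_a": 1.0, "err_b": 0.15,
}


def _bound_for(name):
    base = name.split("__")[0]
    base = "k2" if base.startswith("k2_") else base
    return _PD_BOUNDS[base]


def _init_for(name, init):
    if init and name in init:
        return init[name]
    base = name.split("__")[0]
    if init and base in init:
        return init[base]
    base = "k2" if base.startswith("k2_") else base
    return _PD_INIT[base]


class TumorGrowthFit(BaseEstimator):
    """Pooled ML fit of the base or acquired-resistance tumor model.

    Structure: growth rates ``lambda0``/``lambda1`` and transit rate ``k1``
    (plus ``beta`` and ``kSR`` for the resistance model) are shared across
    compounds; the kill slope ``k2`` is compound-specific; covariates split
    a parameter by dose category.  Individual PK parameters must be supplied
    (``table.attach_pk`` or the ``pk_params`` argument) -- sequential
    PK-then-PD fitting; vehicle subjects need none.

    ``tv0='baseline'`` anchors each subject's initial volume at its first
    tumor observation (excluded from the likelihood); a float fixes a common
    known TV0 and keeps all observations in the likelihood.

    The estimated parameter count ``k_`` covers structural fixed effects
    only: 5 for the base model and 7 for the resistance model in the
    two-compound no-covariate configuration, plus one per covariate split.
    """

    def __init__(self, model="base", covariates=(), init=None, bounds=None,
                 n_starts=5, seed=0, blq="drop", loq=5.0, tv0="baseline",
                 dt=_fastode.DEFAULT_DT, maxfun=1500, jitter=0.3,
                 extra_starts=(), polish=400):
        self.model = model
        self.covariates = covariates
        self.init = init
        self.bounds = bounds
        self.n_starts = n_starts
        self.seed = seed
        self.blq = blq
        self.loq = loq
        self.tv0 = tv0
        self.dt = dt
        self.maxfun = maxfun
        self.jitter = jitter
        self.extra_starts = extra_starts
        self.polish = polish

    # -- layout ------------------------------------------------------------

    def _layout(self, compounds, groups_present):
        if self.model not in ("base", "resistance"):
            raise InputError(f"unknown model {self.model!r}")
        names = ["lambda0", "lambda1", "k1"]
        if self.model == "resistance":
            names += ["beta", "kSR"]
        names += [f"k2_{c}" for c in compounds]
        split_keys = []
        for spec in self.covariates:
            key = spec.key(compounds)
            if key == "kSR" and self.model != "resistance":
                raise InputError("kSR covariate requires the resistance model")
            if key not in names:
                raise InputError(f"covariate on unknown parameter {key!r}")
            if not any(g in spec.high_groups for g in groups_present):
                raise InputError(
                    f"covariate on {key!r} has no subjects in {spec.high_groups}")
            if not any(g not in spec.high_groups and g != "vehicle"
                       for g in groups_present):
                raise InputError(f"covariate on {key!r} has an empty reference category")
            names.append(f"{key}__high")
            split_keys.append(key)
        k_structural = len(names)
        names = names + ["err_a", "err_b"]
        return names, split_keys, k_structural

    # -- data preparation --------------------------------------------------

    def _prepare(self, table: ObservationTable, pk_params):
        dt = self.dt
        compounds = sorted({table.compound_of(s) for s in table.subjects}
                           - {"vehicle"})
        groups_present = {table.group_of(s) for s in table.subjects}
        high_groups = {}
        for spec in self.covariates:
            high_groups[spec.key(compounds)] = set(spec.high_groups)

        groups = {}
        for sid in table.subjects:
            obs = table.observations("tumor", subject=sid).sort_values("TIME")
            if self.blq == "drop":
                obs = obs[obs["BLQ"] == 0]
            if obs.empty:
                continue
            compound = table.compound_of(sid)
            group = table.group_of(sid)
            regimen = table.regimen_for(sid)
            t = obs["TIME"].to_numpy(float)
            y = obs["DV"].to_numpy(float)
            blq = obs["BLQ"].to_numpy() != 0
            if self.tv0 == "baseline":
                tv0 = float(y[0]) if not blq[0] else self.loq
                t, y, blq = t[1:], y[1:], blq[1:]
                if t.size == 0:
                    continue
            else:
                tv0 = float(self.tv0)
            steps = np.round(t / dt).astype(np.int64)
            if compound == "vehicle":
                pk_key = ("vehicle",)
                cp_args = None
            else:
                if pk_params is None or sid not in pk_params:
                    raise InputError(f"no PK parameters for subject {sid!r}")
                p = pk_params[sid]
                events = regimen.grouped_events()
                cp_args = (
                    np.array([e[0] for e in events]),
                    np.array([p.amount_ug(e[1]) for e in events]),
                    np.array([effective_volume(p, e[1]) for e in events]),
                    p.ka, p.ke)
                pk_key = (p.ka, p.ke, p.V, p.I, p.body_weight)
            key = (compound, group, tuple(regimen.events), pk_key, round(tv0, 9))
            groups.setdefault(key, {"compound": compound, "group": group,
                                    "cp_args": cp_args, "tv0": tv0,
                                    "subjects": []})
            groups[key]["subjects"].append((sid, t, y, blq, steps))

        if not groups:
            raise InputError("no tumor observations to fit")
        t_max = max(s[1].max() for g in groups.values() for s in g["subjects"])
        n_steps = int(np.ceil(t_max / dt - 1e-9))
        blocks = []
        for g in groups.values():
            if g["cp_args"] is None:
                cp_half = np.zeros(2 * n_steps + 1)
            else:
                cp_half = _fastode.cp_halfstep_table(*g["cp_args"],
                                                     t_max=n_steps * dt, dt=dt)
            union = np.unique(np.concatenate([s[4] for s in g["subjects"]]))
            members = []
            for sid, t, y, blq, steps in g["subjects"]:
                idx = np.searchsorted(union, steps)
                members.append((sid, t, y, blq, idx))
            blocks.append({"compound": g["compound"], "group": g["group"],
                           "tv0": g["tv0"], "cp_half": cp_half,
                           "steps": union, "members": members})
        return blocks, compounds, groups_present, high_groups

    # -- likelihood --------------------------------------------------------

    def _predictions(self, theta: dict, blocks, high_groups):
        f_all, y_all, blq_all, ids, times = [], [], [], [], []
        for blk in blocks:
            c, g = blk["compound"], blk["group"]
            if c == "vehicle":
                k2 = 0.0
            else:
                key = f"k2_{c}"
                split = key in high_groups and g in high_groups[key]
                k2 = theta[f"{key}__high"] if split else theta[key]
            if self.model == "resistance":
                split = "kSR" in high_groups and g in high_groups["kSR"]
                ksr = theta["kSR__high"] if split else theta["kSR"]
                beta = theta["beta"]
            else:
                ksr, beta = 0.0, 1.0
            preds = _fastode.rk4_tv_at_obs(
                blk["cp_half"], self.dt, blk["steps"], blk["tv0"],
                theta["lambda0"], theta["lambda1"], theta["k1"], k2, ksr, beta)
            if not np.all(np.isfinite(preds)):
                return None
            for sid, t, y, blq, idx in blk["members"]:
                f_all.append(preds[idx])
                y_all.append(y)
                blq_all.append(blq)
                ids.extend([sid] * len(y))
                times.append(t)
        return (np.concatenate(f_all), np.concatenate(y_all),
                np.concatenate(blq_all), ids, np.concatenate(times))

    def _nll(self, theta: dict, blocks, high_groups) -> float:
        out = self._predictions(theta, blocks, high_groups)
        if out is None:
            return _BIG
        f, y, blq, _, _ = out
        err = ErrorModel("combined", theta["err_a"], theta["err_b"])
        return neg_log_likelihood(y, f, err, blq=blq, loq=self.loq,
                                  blq_mode="censored" if self.blq == "censored"
                                  else "drop")

    # -- fitting -----------------------------------------------------------

    def fit(self, table: ObservationTable, pk_params: dict | None = None
            ) -> "TumorGrowthFit":
        if pk_params is None:
            pk_params = table.pk_params
        blocks, compounds, groups_present, high_groups = self._prepare(
            table, pk_params)
        names, split_keys, k_structural = self._layout(compounds, groups_present)

        x0 = np.log([_init_for(n, self.init) for n in names])
        user_bounds = self.bounds or {}
        lb, ub = [], []
        for n in names:
            lo, hi = user_bounds.get(n, _bound_for(n))
            lb.append(np.log(lo))
            ub.append(np.log(hi))
        lb, ub = np.array(lb), np.array(ub)
        x0 = np.clip(x0, lb, ub)

        def obj(x):
            theta = dict(zip(names, np.exp(x)))
            return self._nll(theta, blocks, high_groups)

        rng = np.random.default_rng(self.seed)
        starts = [x0]
        for extra in self.extra_starts:
            xs = np.array([np.log(_init_for(n, extra)) for n in names])
            starts.append(np.clip(xs, lb, ub))
        while len(starts) < self.n_starts + len(self.extra_starts):
            starts.append(np.clip(x0 + rng.normal(0, self.jitter, x0.size),
                                  lb, ub))
        best = None
        for start in starts:
            res = optimize.minimize(obj, start, method="L-BFGS-B",
                                    bounds=list(zip(lb, ub)),
                                    options={"maxfun": self.maxfun})
            if best is None or res.fun < best.fun:
                best = res
        converged = bool(best.success)
        if self.polish:
            # simplex polish: the quasi-Newton line search can stall on this
            # surface (see PKCurveFit)
            pol = optimize.minimize(obj, best.x, method="Nelder-Mead",
                                    options={"maxfev": self.polish,
                                             "xatol": 1e-9, "fatol": 1e-10})
            if pol.fun < best.fun:
                best = pol
                converged = converged or bool(pol.success)

        theta = dict(zip(names, np.exp(np.clip(best.x, lb, ub))))
        loglik = -float(best.fun)
        f, y, blq, ids, times = self._predictions(theta, blocks, high_groups)
        err = ErrorModel("combined", theta["err_a"], theta["err_b"])
        keep = ~blq if self.blq == "drop" else np.ones(len(y), bool)
        resid = pd.DataFrame({
            "ID": np.asarray(ids)[keep], "TIME": times[keep], "DV": y[keep],
            "PRED": f[keep], "RES": y[keep] - f[keep],
            "WRES": (y[keep] - f[keep]) / np.maximum(err.sd(f[keep]), 1e-12)})
        structural = {n: v for n, v in theta.items()
                      if n not in ("err_a", "err_b")}

        self.params_ = structural
        self.error_ = err
        self.loglik_ = loglik
        self.k_ = k_structural
        self.n_obs_ = int(keep.sum()) if self.blq == "drop" else len(y)
        self.converged_ = converged
        self.residuals_ = resid
        self.result_ = FitResult(
            params=structural, loglik=loglik, k=k_structural,
            n_obs=self.n_obs_, error_model=err, converged=self.converged_,
            residuals=resid, data_fingerprint=table.fingerprint(),
            meta={"model": self.model, "compounds": compounds,
                  "covariates": [s.__dict__ for s in self.covariates],
                  "n_starts": self.n_starts, "seed": self.seed,
                  "blq": self.blq, "counting": "structural fixed effects"})
        return self

    @property
    def aic_(self) -> float:
        return self.result_.aic

    def predict(self, table: ObservationTable, pk_params: dict | None = None
                ) -> np.ndarray:
        """Model-predicted tumor volumes for the table's tumor rows."""
        if pk_params is None:
            pk_params = table.pk_params
        blocks, compounds, groups_present, high_groups = self._prepare(
            table, pk_params)
        theta = dict(self.params_, err_a=self.error_.a, err_b=self.error_.b)
        out = self._predictions(theta, blocks, high_groups)
        if out is None:
            raise InputError("prediction failed for the supplied table")
        return out[0]


# ---------------------------------------------------------------------------
# wrappers and comparisons
# ---------------------------------------------------------------------------

def fit_pk(table: ObservationTable, compound: str, **kwargs) -> PKCurveFit:
    """Fit the PK submodel for one compound (thin wrapper over PKCurveFit)."""
    return PKCurveFit(compound=compound, **kwargs).fit(table)


def fit_pd(table: ObservationTable, model: str = "base", covariates=(),
           pk_params: dict | None = None, **kwargs) -> TumorGrowthFit:
    """Fit a tumor model sequentially after PK (wrapper over TumorGrowthFit)."""
    est = TumorGrowthFit(model=model, covariates=covariates, **kwargs)
    return est.fit(table, pk_params=pk_params)


def two_stage_fit(table: ObservationTable, model: str = "base",
                  pk_params: dict | None = None, min_obs: int = 4,
                  **fit_kwargs) -> dict:
    """Two-stage PD estimation: per-subject ML fits, log-normal summary.

    Each subject is fit separately; the population estimate of every
    parameter is the geometric mean over the subjects for whom it is
    identifiable (vehicle subjects inform only the growth parameters --
    without drug there is no flux through the transit cascade, so ``k1``
    and ``k2`` contribute nothing there).  Unlike naive pooling this is
    consistent under log-normal inter-individual variability; it is the
    estimator of choice for recovery under realistic heterogeneity, while
    pooled fits carry the AIC bookkeeping for model comparison.

    Returns ``{"params": geometric means, "individual": DataFrame,
    "n_subjects": int}``.
    """
    if pk_params is None:
        pk_params = table.pk_params or {}
    defaults = dict(n_starts=1, polish=150, maxfun=400)
    defaults.update(fit_kwargs)
    records = []
    for sid in table.subjects:
        obs = table.observations("tumor", subject=sid, drop_blq=True)
        if len(obs) < min_obs:
            continue
        sub = ObservationTable(table.df[table.df["ID"] == sid], validate=False)
        try:
            fit = TumorGrowthFit(model=model, **defaults).fit(
                sub, pk_params=pk_params)
        except (InputError, InvalidParameterError):
            continue
        rec = {"ID": sid, "compound": table.compound_of(sid)}
        if table.compound_of(sid) == "vehicle":
            rec.update({k: fit.params_[k] for k in ("lambda0", "lambda1")})
        else:
            for name, value in fit.params_.items():
                rec[name.replace(f"_{rec['compound']}", "")] = value
        records.append(rec)
    if not records:
        raise InputError("no subjects with enough observations to fit")
    individual = pd.DataFrame(records).set_index("ID")
    params = {}
    for col in individual.columns:
        if col == "compound":
            continue
        vals = individual[col].dropna().to_numpy(float)
        if vals.size:
            params[col] = float(np.exp(np.mean(np.log(vals))))
    # compound-specific kill slopes summarized within compound
    for compound in sorted(set(individual["compound"]) - {"vehicle"}):
        sub = individual[individual["compound"] == compound]
        if "k2" in sub:
            vals = sub["k2"].dropna().to_numpy(float)
            if vals.size:
                params[f"k2_{compound}"] = float(np.exp(np.mean(np.log(vals))))
    params.pop("k2", None)
    return {"params": params, "individual": individual,
            "n_subjects": len(records)}


def fit_base_and_resistance(table: ObservationTable,
                            pk_params: dict | None = None, **kwargs):
    """Fit both nested models and compare them by AIC.

    The resistance fit gets an extra warm start at the base-model optimum
    (with ``kSR`` at its lower bound and ``beta = 1``), which makes the
    nesting inequality ``loglik_resistance >= loglik_base`` hold in practice
    and not just in principle.  Returns ``(fit_base, fit_resistance,
    ModelComparison)``.
    """
    base = TumorGrowthFit(model="base", **kwargs)
    base.fit(table, pk_params=pk_params)
    warm = dict(base.params_, kSR=_PD_BOUNDS["kSR"][0], beta=1.0,
                err_a=base.error_.a, err_b=base.error_.b)
    res = TumorGrowthFit(model="resistance", extra_starts=(warm,), **kwargs)
    res.fit(table, pk_params=pk_params)
    return base, res, compare_models(base, res)


@dataclass
class ModelComparison:
    aic_base: float
    aic_resistance: float
    delta_aic: float          # resistance - base; negative favors resistance
    preferred: str
    tie: bool
    residual_errors: dict

    def __str__(self):
        msg = (f"AIC base={self.aic_base:.1f}, resistance={self.aic_resistance:.1f}, "
               f"delta={self.delta_aic:+.1f} -> preferred: {self.preferred}")
        return msg + (" (tie)" if self.tie else "")


def compare_models(fit_base: TumorGrowthFit | FitResult,
                   fit_res: TumorGrowthFit | FitResult,
                   atol: float = 1e-9) -> ModelComparison:
    """AIC comparison of the base and resistance fits on the same dataset."""
    rb = fit_base.result_ if hasattr(fit_base, "result_") else fit_base
    rr = fit_res.result_ if hasattr(fit_res, "result_") else fit_res
    if rb.data_fingerprint != rr.data_fingerprint or rb.n_obs != rr.n_obs:
        raise InputError("fits are not on the same dataset")
    delta = rr.aic - rb.aic
    tie = abs(delta) <= atol
    preferred = "tie" if tie else ("resistance" if delta < 0 else "base")
    return ModelComparison(
        aic_base=rb.aic, aic_resistance=rr.aic, delta_aic=delta,
        preferred=preferred, tie=tie,
        residual_errors={"base": (rb.error_model.a, rb.error_model.b),
                         "resistance": (rr.error_model.a, rr.error_model.b)})


@dataclass
class CovariateTestReport:
    spec: CovariateSpec
    loglik_pooled: float
    loglik_split: float
    delta_loglik: float
    df: int
    p_value: float
    fit_pooled: TumorGrowthFit
    fit_split: TumorGrowthFit


def covariate_test(table: ObservationTable, model: str, spec: CovariateSpec,
                   pk_params: dict | None = None, **fit_kwargs
                   ) -> CovariateTestReport:
    """Likelihood-ratio test for a categorical dose-group covariate.

    Fits the pooled (no-split) and split configurations; the split fit is
    seeded from the pooled optimum so the nesting inequality
    ``loglik_split >= loglik_pooled`` holds by construction.
    """
    pooled = TumorGrowthFit(model=model, covariates=(), **fit_kwargs)
    pooled.fit(table, pk_params=pk_params)
    init = dict(fit_kwargs.pop("init", None) or {})
    init.update(pooled.params_)
    init["err_a"], init["err_b"] = pooled.error_.a, pooled.error_.b
    split = TumorGrowthFit(model=model, covariates=(spec,), init=init,
                           **fit_kwargs)
    split.fit(table, pk_params=pk_params)
    delta = max(split.loglik_ - pooled.loglik_, 0.0)
    df = split.k_ - pooled.k_
    p = float(stats.chi2.sf(2.0 * delta, df))
    return CovariateTestReport(spec=spec, loglik_pooled=pooled.loglik_,
                               loglik_split=split.loglik_, delta_loglik=delta,
                               df=df, p_value=p, fit_pooled=pooled,
                               fit_split=split)
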