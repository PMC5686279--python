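"""Virtual xenograft studies with the statistical structure of the real one.

The default design mirrors the in-vivo study the models were built for:
7 arms (vehicle; erlotinib and gefitinib at 5/25/100 mg/kg) of 8 mice each,
once-daily oral dosing for 14 days starting on day 3, caliper tumor volumes
over 30 days with a 5 mm3 detection limit, sparse PK sampling on the first
and last dosing day, and missingness from sacrifice at high tumor burden
plus below-limit observations (the real study lost ~7% of planned points).

Inter-individual variability is log-normal around the population fixed
effects; residual error is proportional for PK and combined (additive +
proportional) for tumor volumes.  Every study carries a ground-truth bundle
(generating parameters per subject, seed) so parameter-recovery tests need
no external data.

Randomness is keyed per subject (``default_rng([seed, subject_index])``) so
enlarging the study does not perturb earlier subjects' draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import params as canonical
from .data import ObservationTable, COLUMNS
from .dosing import daily_regimen
from .errors import InputError
from .pk import PKParameters, solve_pk
from .tumor import ResistanceTGIParameters, BaseTGIParameters, simulate

__all__ = [
    "Arm",
    "StudyDesign",
    "PopulationParameters",
    "TruthBundle",
    "sample_individuals",
    "generate_study",
    "truth_bundle",
    "true_pk_parameters",
    "missingness",
    "default_design",
    "canonical_population",
]

_GROUP_BY_DOSE = {0.0: "vehicle", 5.0: "low", 25.0: "mid", 100.0: "high"}


@dataclass(frozen=True)
class Arm:
    compound: str
    dose: float  # mg/kg, 0 for vehicle
    n: int
    group: str = ""

    def __post_init__(self):
        if self.n <= 0:
            raise InputError("each arm needs n > 0 subjects")
        if not self.group:
            g = _GROUP_BY_DOSE.get(self.dose)
            if g is None:
                raise InputError(
                    f"dose {self.dose} has no default group label; set Arm.group")
            object.__setattr__(self, "group", g)


@dataclass(frozen=True)
class StudyDesign:
    """Arms, dosing window, observation schedule and missingness mechanisms."""

    arms: tuple
    start_day: float = 3.0
    n_doses: int = 14
    tv_days: tuple = (0, 3, 5, 7, 10, 12, 14, 17, 19, 21, 24, 26, 28, 30)
    pk_offsets: tuple = (1.0 / 24, 6.0 / 24, 1.0)   # days after a monitored dose
    pk_dose_index: tuple = (0, 13)                   # which doses are PK-sampled
    loq_tv: float = 5.0      # caliper detection limit [mm3]
    loq_pk: float = 1.0      # [ug/L]
    dropout_cap: float = 2200.0   # sacrifice when true TV exceeds this [mm3]

    def __post_init__(self):
        if self.loq_tv <= 0:
            raise InputError("LOQ must be positive")
        if max(self.tv_days) < self.start_day + self.n_doses - 1:
            raise InputError("observation window must cover the dosing period")

    def regimen(self, arm: Arm):
        if arm.dose == 0:
            return daily_regimen(self.start_day, 0, 0.0, compound=arm.compound)
        return daily_regimen(self.start_day, self.n_doses, arm.dose,
                             compound=arm.compound)

    @property
    def n_subjects(self) -> int:
        return sum(a.n for a in self.arms)


def default_design(n_per_arm: int = 8) -> StudyDesign:
    """The 7-arm study design (vehicle + 2 compounds x 3 dose levels)."""
    arms = [Arm("vehicle", 0.0, n_per_arm)]
    for compound in ("erlotinib", "gefitinib"):
        for dose in (5.0, 25.0, 100.0):
            arms.append(Arm(compound, dose, n_per_arm))
    return StudyDesign(arms=tuple(arms))


@dataclass(frozen=True)
class PopulationParameters:
    """Population fixed effects, log-normal IIV magnitudes and residual errors.

    ``k2``/``k2_high`` and the PK sets are keyed by compound; ``ksr_high``
    is the high-dose covariate value of the damaged-to-resistant conversion
    rate (None disables the covariate).  ``omega`` maps parameter names
    (``TV0, lambda0, lambda1, k1, beta, kSR, k2, ke, V``) to log-SDs; a
    missing key means no variability on that parameter.
    """

    pk: dict
    k2: dict
    k2_high: dict | None = None
    tv0: float = canonical.DEFAULT_TV0
    lambda0: float = 0.217
    lambda1: float = 42.8
    k1: float = 1.52
    beta: float = 0.869
    ksr: float = 7.4e-3
    ksr_high: float | None = 1.7e-3
    omega: dict = field(default_factory=dict)
    pk_error_b: float = 0.15
    pd_error_a: float = 1.0
    pd_error_b: float = 0.136

    def fixed_effects(self, compound: str, group: str) -> dict:
        high = group == "high"
        k2 = 0.0
        if compound != "vehicle":
            table = self.k2_high if (high and self.k2_high) else self.k2
            if compound not in table:
                raise InputError(f"population has no k2 for {compound!r}")
            k2 = table[compound]
        ksr = (self.ksr_high if (high and self.ksr_high is not None)
               else self.ksr)
        return {"TV0": self.tv0, "lambda0": self.lambda0,
                "lambda1": self.lambda1, "k1": self.k1, "beta": self.beta,
                "kSR": ksr, "k2": k2}

    def scaled(self, omega_scale: float = 1.0, **overrides) -> "PopulationParameters":
        om = {k: ({c: s * omega_scale for c, s in v.items()}
                  if isinstance(v, dict) else v * omega_scale)
              for k, v in self.omega.items()}
        kw = {**asdict_shallow(self), "omega": om, **overrides}
        return PopulationParameters(**kw)


def asdict_shallow(pop: PopulationParameters) -> dict:
    return {f: getattr(pop, f) for f in pop.__dataclass_fields__}


def canonical_population(omega_scale: float = 1.0) -> PopulationParameters:
    """Population at the canonical fixed effects and IIV magnitudes."""
    om = canonical.OMEGA
    omega = {k: (v if not isinstance(v, dict) else v)  # compound-keyed left as dict
             for k, v in om.items()}
    return PopulationParameters(
        pk={"erlotinib": canonical.ERLOTINIB_PK,
            "gefitinib": canonical.GEFITINIB_PK},
        k2=dict(canonical.PD_FIXED_EFFECTS["k2"]),
        k2_high=dict(canonical.PD_FIXED_EFFECTS["k2_high"]),
        omega=omega).scaled(omega_scale)


def _omega_for(pop: PopulationParameters, name: str, compound: str) -> float:
    val = pop.omega.get(name, 0.0)
    if isinstance(val, dict):
        val = val.get(compound, 0.0)
    return float(val)


def _draw_subject(pop: PopulationParameters, compound: str, group: str,
                  rng: np.random.Generator):
    """One subject's (PKParameters, PD dict) with log-normal perturbations."""
    fe = pop.fixed_effects(compound, group)
    pd_i = {}
    for name, mu in fe.items():
        om = _omega_for(pop, name, compound)
        pd_i[name] = mu * np.exp(rng.normal(0.0, om)) if (om > 0 and mu > 0) else mu
    if compound == "vehicle":
        return None, pd_i
    base = pop.pk[compound]
    ke = base.ke * np.exp(rng.normal(0.0, _omega_for(pop, "ke", compound)))
    V = base.V * np.exp(rng.normal(0.0, _omega_for(pop, "V", compound)))
    pk_i = base.with_(ke=float(ke), V=float(V))
    return pk_i, pd_i


def sample_individuals(pop: PopulationParameters, n: int, seed: int,
                       compound: str = "erlotinib", group: str = "high"):
    """n individual parameter sets theta_i = theta * exp(eta_i), seeded.

    Returns a list of ``(PKParameters | None, dict)`` pairs; the dict holds
    the PD parameters (TV0, lambda0, lambda1, k1, beta, kSR, k2).
    """
    if n < 1:
        raise InputError("n must be >= 1")
    out = []
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        out.append(_draw_subject(pop, compound, group, rng))
    return out


def _pd_parameters(pd_i: dict, model: str):
    if model == "base":
        return BaseTGIParameters(TV0=pd_i["TV0"], lambda0=pd_i["lambda0"],
                                 lambda1=pd_i["lambda1"], k1=pd_i["k1"],
                                 k2=pd_i["k2"])
    return ResistanceTGIParameters(
        TV0=pd_i["TV0"], lambda0=pd_i["lambda0"], lambda1=pd_i["lambda1"],
        k1=pd_i["k1"], k2=pd_i["k2"], kSR=pd_i["kSR"], beta=pd_i["beta"])


@dataclass
class TruthBundle:
    """Generating ground truth for a synthetic study."""

    seed: int
    model: str
    design: dict
    fixed_effects: dict
    subjects: dict   # ID -> {"pd": {...}, "pk": {...} | None, "arm": ...}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "TruthBundle":
        with open(path) as fh:
            return cls(**json.load(fh))


def generate_study(design: StudyDesign, pop: PopulationParameters,
                   model: str = "resistance", seed: int = 0,
                   noise: bool = True):
    """Simulate one study; returns ``(ObservationTable, TruthBundle)``.

    Each subject's PK is solved analytically and drives the tumor model; the
    tumor is observed on the design's caliper days with combined residual
    error, flagged BLQ below the detection limit, and truncated after the
    first observation day on which the true volume exceeds the sacrifice
    cap.  PK samples get proportional error.  ``noise=False`` disables both
    residual errors (IIV is governed solely by ``pop.omega``).
    """
    if model not in ("base", "resistance"):
        raise InputError(f"unknown model {model!r}")
    for arm in design.arms:
        if arm.compound != "vehicle" and arm.compound not in pop.pk:
            raise InputError(f"population has no PK for {arm.compound!r}")

    rows = []
    truth_subjects = {}
    subj_index = 0
    horizon = float(max(design.tv_days))
    grid = np.union1d(np.linspace(0.0, horizon, 601),
                      np.array(design.tv_days, dtype=float))
    traj_cache: dict = {}  # identical subjects (e.g. omega = 0) share one solve
    for arm in design.arms:
        regimen = design.regimen(arm)
        for _ in range(arm.n):
            sid = f"S{subj_index + 1:03d}"
            rng = np.random.default_rng([seed, subj_index])
            pk_i, pd_i = _draw_subject(pop, arm.compound, arm.group, rng)
            pars = _pd_parameters(pd_i, model)
            key = (pars, None if pk_i is None else (pk_i.ka, pk_i.ke, pk_i.V,
                                                    pk_i.I, pk_i.body_weight),
                   regimen.events)
            if key in traj_cache:
                profile, traj = traj_cache[key]
            else:
                if pk_i is None or len(regimen) == 0:
                    profile = None
                else:
                    profile = solve_pk(pk_i, regimen, grid)
                traj = simulate(pars, profile, grid, model=model,
                                rtol=1e-8, atol=1e-10)
                traj_cache[key] = (profile, traj)

            # dose rows
            for t, d in regimen.events:
                rows.append([sid, t, 1, "", np.nan, d, 0, arm.group,
                             arm.compound])

            # tumor observations until sacrifice
            true_tv = traj.tv_at(np.array(design.tv_days, dtype=float))
            for day, tv in zip(design.tv_days, true_tv):
                if day > design.start_day and tv > design.dropout_cap:
                    break
                if noise:
                    sd = pop.pd_error_a + pop.pd_error_b * tv
                    y = tv + sd * rng.normal()
                else:
                    y = tv
                y = max(y, 0.0)
                blq = int(y < design.loq_tv)
                rows.append([sid, float(day), 0, "tumor", y, np.nan, blq,
                             arm.group, arm.compound])

            # sparse PK sampling on monitored dosing days
            if profile is not None:
                for di in design.pk_dose_index:
                    if di >= len(regimen):
                        continue
                    t0 = regimen.events[di][0]
                    for off in design.pk_offsets:
                        t = t0 + off
                        cp = float(profile.concentration(t)[0])
                        y = cp * (1.0 + pop.pk_error_b * rng.normal()) if noise else cp
                        y = max(y, 0.0)
                        blq = int(y < design.loq_pk)
                        rows.append([sid, t, 0, "pk", y, np.nan, blq,
                                     arm.group, arm.compound])

            truth_subjects[sid] = {
                "arm": {"compound": arm.compound, "dose": arm.dose,
                        "group": arm.group},
                "pd": {k: float(v) for k, v in pd_i.items()},
                "pk": None if pk_i is None else {
                    "ka": pk_i.ka, "ke": pk_i.ke, "V": pk_i.V, "I": pk_i.I,
                    "body_weight": pk_i.body_weight},
            }
            subj_index += 1

    df = pd.DataFrame(rows, columns=COLUMNS)
    df = df.sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)
    table = ObservationTable(df)
    fixed = {"tv0": pop.tv0, "lambda0": pop.lambda0, "lambda1": pop.lambda1,
             "k1": pop.k1, "beta": pop.beta, "kSR": pop.ksr,
             "kSR_high": pop.ksr_high, "k2": dict(pop.k2),
             "k2_high": dict(pop.k2_high or {})}
    bundle = TruthBundle(seed=seed, model=model,
                         design={"arms": [asdict(a) for a in design.arms],
                                 "start_day": design.start_day,
                                 "n_doses": design.n_doses,
                                 "tv_days": list(design.tv_days),
                                 "loq_tv": design.loq_tv,
                                 "dropout_cap": design.dropout_cap},
                         fixed_effects=fixed, subjects=truth_subjects)
    table.df.attrs["generator_seed"] = seed
    return table, bundle


def truth_bundle(study) -> TruthBundle:
    """The ground-truth record of a generated (table, bundle) pair."""
    if isinstance(study, tuple) and len(study) == 2 and isinstance(study[1], TruthBundle):
        return study[1]
    raise InputError("truth bundles exist only for studies made by generate_study")


def true_pk_parameters(bundle: TruthBundle) -> dict:
    """Per-subject PKParameters from a truth bundle (oracle for sequential fits)."""
    out = {}
    for sid, rec in bundle.subjects.items():
        if rec["pk"] is not None:
            out[sid] = PKParameters(**rec["pk"])
    return out


def missingness(table: ObservationTable, design: StudyDesign) -> float:
    """Fraction of planned tumor observations missing or BLQ."""
    planned = design.n_subjects * len(design.tv_days)
    obs = table.observations("tumor")
    present = len(obs[obs["BLQ"] == 0])
    return 1.0 - present / planned
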