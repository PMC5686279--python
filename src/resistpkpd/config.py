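"""Run configuration: YAML-backed, fail-closed, fully seeded.

Every pipeline task is described by a :class:`RunConfig`; unknown keys are
rejected so a typo never silently falls back to a default.  Each run writes
a manifest (config hash, seed, package version) from which the artifact is
regenerable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import yaml

from .errors import InputError

__all__ = ["RunConfig", "load_config", "config_hash", "write_manifest"]

TASKS = ("generate", "fit", "compare-models", "simulate", "regimen-compare",
         "hybrid-human")

_KNOWN_KEYS = {
    "task", "model", "seed", "out", "dataset", "n_per_arm", "noise",
    "der_form", "der_enabled", "k2R", "C_th", "blq_mode", "ci_formula",
    "n_subjects", "horizon", "omega_scale", "regimen", "regimen_b",
    "human_pk", "pk_mode", "n_starts", "compound", "high_dose", "covariates",
    "rtol", "atol", "grid_dt", "tv0",
}


@dataclass
class RunConfig:
    task: str
    model: str = "resistance"
    seed: int = 0
    out: str = "runs/out"
    dataset: str | None = None          # observations.csv path for fit tasks
    n_per_arm: int = 8
    noise: bool = True
    der_form: str = "mass_action"
    der_enabled: bool = False
    k2R: float = 0.0
    C_th: float | None = None
    blq_mode: str = "drop"
    ci_formula: str = "as_printed"
    n_subjects: int = 250
    horizon: float = 60.0
    omega_scale: float = 1.0
    regimen: dict | None = None
    regimen_b: dict | None = None
    human_pk: dict | None = None
    pk_mode: str = "per_subject"
    n_starts: int = 3
    compound: str = "erlotinib"
    high_dose: bool = True
    covariates: list = field(default_factory=list)
    rtol: float = 1e-8
    atol: float = 1e-10
    grid_dt: float = 0.05
    tv0: str | float = "baseline"

    def __post_init__(self):
        if self.task not in TASKS:
            raise InputError(f"unknown task {self.task!r}; choose from {TASKS}")
        if self.model not in ("base", "resistance"):
            raise InputError(f"unknown model {self.model!r}")
        if self.der_form not in ("mass_action", "as_printed"):
            raise InputError(f"unknown der_form {self.der_form!r}")
        if self.blq_mode not in ("drop", "censored"):
            raise InputError(f"unknown blq_mode {self.blq_mode!r}")
        if self.ci_formula not in ("as_printed", "standard"):
            raise InputError(f"unknown ci_formula {self.ci_formula!r}")


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Read a YAML config; CLI overrides win over file values.

    Unknown keys fail the run rather than being ignored.
    """
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise InputError(f"config {path} must be a mapping")
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise InputError(f"unknown config keys: {sorted(unknown)}")
    if "task" not in raw:
        raise InputError("config must set 'task'")
    return RunConfig(**raw)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_manifest(cfg: RunConfig, out_dir, extra: dict | None = None) -> None:
    from . import __version__
    manifest = {"package": "resistpkpd", "version": __version__,
                "config": asdict(cfg), "config_sha256": config_hash(cfg),
                "seed": cfg.seed}
    if extra:
        manifest.update(extra)
    with open(f"{out_dir}/manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
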