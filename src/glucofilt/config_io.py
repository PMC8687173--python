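"""Configuration files and run manifests.

Configurations are flat YAML key/value files.  Recognised keys (all
optional; omitted keys take the standard-study defaults):

``cohort``            "normal" | "t2dm"
``meals``             list of [dose_mg, start_min, rate_mg_per_min]
``horizon_min``       study length (default 1440)
``step_min``          sampling interval (default 1)
``Q_diag``            12 process-noise variances (default [1, 0.1 x 11])
``R``                 measurement-noise variance (default 16)
``P0_diag``           12 initial-covariance diagonal entries
``mc_runs``           Monte-Carlo repetitions (default 50)
``seed``              base random seed
``filters``           list drawn from {"ukf", "cqkf"}
``kappa``             unscented scaling (default 3 - n)
``cq_order``          Gauss-Laguerre order n' (default 2)
``init_mode``         "random" | "mean" filter initialisation
``noisy_truth``       whether the truth includes process noise
``substep``           internal RK4 substep, min
plus any model-parameter symbol (``VG``, ``kabs``, ...) as a field-by-field
override of the cohort profile.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .experiment import ExperimentConfig
from .model import MealEvent, MealSchedule
from .parameters import ModelParameters

__all__ = ["load_config", "write_config", "config_to_dict", "RunManifest"]

_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParameters)} - {"cohort"}
_SCALAR_KEYS = {
    "cohort": str,
    "horizon_min": float,
    "step_min": float,
    "R": float,
    "mc_runs": int,
    "seed": int,
    "kappa": float,
    "cq_order": int,
    "init_mode": str,
    "noisy_truth": bool,
    "substep": float,
}
_LIST_KEYS = {"meals", "Q_diag", "P0_diag", "filters"}


def config_to_dict(config: ExperimentConfig) -> dict:
    """Flatten an ExperimentConfig into the YAML key set."""
    d: dict = {
        "cohort": config.cohort,
        "meals": [[e.dose, e.start, e.rate] for e in config.schedule.events],
        "horizon_min": float(config.horizon),
        "step_min": float(config.dt),
        "Q_diag": np.diag(config.Q).tolist(),
        "R": float(config.R),
        "P0_diag": np.diag(config.P0).tolist(),
        "mc_runs": int(config.mc_runs),
        "seed": int(config.base_seed),
        "filters": list(config.flavours),
        "cq_order": int(config.cq_order),
        "init_mode": config.init_mode,
        "noisy_truth": bool(config.noisy_truth),
        "substep": float(config.substep),
    }
    if config.kappa is not None:
        d["kappa"] = float(config.kappa)
    d.update(config.param_overrides)
    return d


def _config_from_dict(raw: dict) -> ExperimentConfig:
    errors: list[str] = []
    known = set(_SCALAR_KEYS) | _LIST_KEYS | _PARAM_FIELDS
    unknown = set(raw) - known
    if unknown:
        errors.append(f"unknown keys: {sorted(unknown)}")

    for key in ("Q_diag", "P0_diag"):
        if key in raw and len(raw[key]) != 12:
            errors.append(f"{key} must have 12 entries, got {len(raw[key])}")
    if "meals" in raw:
        for i, entry in enumerate(raw["meals"]):
            if len(entry) != 3:
                errors.append(f"meals[{i}] must be [dose_mg, start_min, rate_mg_per_min]")
    if "filters" in raw:
        for fl in raw["filters"]:
            if fl not in ("ukf", "cqkf"):
                errors.append(f"filters entry {fl!r} not one of 'ukf', 'cqkf'")
    if "cohort" in raw and raw["cohort"] not in ("normal", "t2dm"):
        errors.append(f"cohort {raw['cohort']!r} not one of 'normal', 't2dm'")
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))

    kwargs: dict = {}
    if "cohort" in raw:
        kwargs["cohort"] = raw["cohort"]
    if "meals" in raw:
        kwargs["schedule"] = MealSchedule(
            tuple(MealEvent(dose=d, start=s, rate=r) for d, s, r in raw["meals"])
        )
    if "horizon_min" in raw:
        kwargs["horizon"] = float(raw["horizon_min"])
    if "step_min" in raw:
        kwargs["dt"] = float(raw["step_min"])
    if "Q_diag" in raw:
        kwargs["Q"] = np.diag(np.asarray(raw["Q_diag"], dtype=float))
    if "R" in raw:
        kwargs["R"] = float(raw["R"])
    if "P0_diag" in raw:
        kwargs["P0"] = np.diag(np.asarray(raw["P0_diag"], dtype=float))
    if "mc_runs" in raw:
        kwargs["mc_runs"] = int(raw["mc_runs"])
    if "seed" in raw:
        kwargs["base_seed"] = int(raw["seed"])
    if "filters" in raw:
        kwargs["flavours"] = tuple(raw["filters"])
    if "kappa" in raw:
        kwargs["kappa"] = float(raw["kappa"])
    if "cq_order" in raw:
        kwargs["cq_order"] = int(raw["cq_order"])
    if "init_mode" in raw:
        kwargs["init_mode"] = raw["init_mode"]
    if "noisy_truth" in raw:
        kwargs["noisy_truth"] = bool(raw["noisy_truth"])
    if "substep" in raw:
        kwargs["substep"] = float(raw["substep"])
    overrides = {k: float(raw[k]) for k in _PARAM_FIELDS if k in raw}
    if overrides:
        kwargs["param_overrides"] = overrides
    return ExperimentConfig(**kwargs)


def load_config(path: str | Path | None = None) -> ExperimentConfig:
    """Load a YAML configuration; missing keys take the study defaults."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("configuration file must be a YAML mapping")
        raw = loaded
    return _config_from_dict(raw)


def write_config(config: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record written alongside every CLI output set."""

    config: dict
    seeds: list[int]
    version: str = __version__
    checksums: dict[str, str] = dataclasses.field(default_factory=dict)

    def add_file(self, path: str | Path) -> None:
        p = Path(path)
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        self.checksums[p.name] = digest

    def write(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)
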