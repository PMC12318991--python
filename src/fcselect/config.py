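"""Run configuration: defaults, validation, and the run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Any

__all__ = ["RunConfig", "RunManifest", "validate_config"]

# method defaults; weighting mix, search budget, counterfactual weights
_DEFAULTS: dict[str, Any] = {
    "alphas": (0.4, 0.4, 0.2),
    "n_bins": 10,
    "task_mode": "per_task_lambda",
    "n_tasks": 8,
    "pack_size": 30,
    "t_max": 100,
    "rho": 0.9,
    "inner_cv_folds": 3,
    "transfer_floor": 0.05,
    "knowledge_transfer": True,
    "aggregate": "majority",
    "svm_C": 1.0,
    "folds": 5,
    "L": 10,
    "gamma1": 0.5,
    "gamma2": 1.0,
    "cf_target": 1,
    "cf_learning_rate": 0.05,
    "cf_max_iters": 1000,
    "cf_init_noise_sd": 0.1,
    "seed": 0,
    # synthetic cohort
    "n_rois": 20,
    "n_per_class": (40, 40),
    "planted_edges": 5,
    "effect_size": 1.5,
    "noise_sd": 0.3,
    "synth_mode": "features",
    "timeseries_length": 120,
}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    values: dict[str, Any]

    def __getattr__(self, key: str) -> Any:
        try:
            return self.values[key]
        except KeyError as exc:
            raise AttributeError(key) from exc


def validate_config(raw: dict[str, Any] | None) -> RunConfig:
    """Apply defaults, reject unknown keys, and check every range constraint."""
    raw = dict(raw or {})
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    vals = {**_DEFAULTS, **raw}
    for key in ("alphas", "n_per_class"):
        vals[key] = tuple(vals[key])

    a = vals["alphas"]
    if len(a) != 3 or abs(sum(a) - 1.0) > 1e-9:
        raise ValueError(f"alphas must be 3 weights summing to 1, got {a}")
    if not 0.0 <= vals["rho"] <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {vals['rho']}")
    for key in ("n_tasks", "t_max", "L", "folds", "n_bins", "pack_size",
                "inner_cv_folds", "cf_max_iters"):
        if int(vals[key]) < 1:
            raise ValueError(f"{key} must be a positive integer, got {vals[key]}")
    if vals["pack_size"] < 4:
        raise ValueError("pack_size must be at least 4")
    if vals["gamma1"] < 0 or vals["gamma2"] < 0:
        raise ValueError("gamma1/gamma2 must be non-negative")
    if vals["noise_sd"] <= 0:
        raise ValueError("noise_sd must be positive")
    if vals["cf_target"] not in (0, 1):
        raise ValueError("cf_target must be 0 or 1")
    return RunConfig(vals)


@dataclasses.dataclass
class RunManifest:
    config: dict[str, Any]
    stage_seeds: dict[str, int]
    stage_seconds: dict[str, float]
    output_digests: dict[str, str]
    package_version: str

    def write(self, path: Path) -> None:
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))
        tmp.replace(path)     # atomic finalisation

    @staticmethod
    def digest(path: Path) -> str:
        return hashlib.sha256(path.read_bytes()).hexdigest()


class StageTimer:
    def __init__(self) -> None:
        self.seconds: dict[str, float] = {}
        self._t0: float | None = None
        self._name: str | None = None

    def start(self, name: str) -> None:
        self._name, self._t0 = name, time.perf_counter()

    def stop(self) -> None:
        if self._name is not None and self._t0 is not None:
            self.seconds[self._name] = time.perf_counter() - self._t0
        self._name = self._t0 = None
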