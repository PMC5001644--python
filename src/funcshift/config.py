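"""Declarative run configuration for the end-to-end pipeline.

A single YAML (or dict) document drives every stage; all stochastic steps
take explicit seeds, unknown keys are rejected, and the configuration
hash is embedded in every output file so results are traceable to the
exact settings that produced them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


DEFAULTS = {
    "out_dir": "funcshift_run",
    "seeds": {"synth": None, "train": None, "cohorts": None, "cv": None},
    "structure": {"n_structures": 5, "n_residues": 60, "coordinating": 4},
    "contact": {"rule": "any_atom", "threshold": 4.5},
    "environment_level": 2,
    "kernel": {"N": 3, "m": 0, "mode": "full", "sigma": 20},
    "train": {"capacity": 1.0, "unlabeled_size": 40, "prior": None},
    "p_s": 0.1,
    "enrich": {
        "fpr": 0.01, "alpha": 0.05,
        "n_disease": 500, "n_neutral": 500, "effect": 0.05,
    },
}


def _merge(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = {}
    unknown = set(overrides) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown configuration keys at {path or 'root'}: "
                          f"{sorted(unknown)}")
    for key, default in defaults.items():
        if key in overrides and isinstance(default, dict):
            if not isinstance(overrides[key], dict):
                raise ConfigError(f"{path}{key} must be a mapping")
            out[key] = _merge(default, overrides[key], path=f"{path}{key}.")
        elif key in overrides:
            out[key] = overrides[key]
        else:
            out[key] = json.loads(json.dumps(default))  # deep copy
    return out


@dataclass
class RunConfig:
    data: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, overrides: dict) -> "RunConfig":
        cfg = cls(data=_merge(DEFAULTS, overrides or {}))
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text) or {})

    def validate(self) -> None:
        missing = [k for k, v in self.data["seeds"].items() if v is None]
        if missing:
            raise ConfigError(
                f"every stochastic step needs a seed; missing: {sorted(missing)}"
            )
        for k, v in self.data["seeds"].items():
            if not isinstance(v, int):
                raise ConfigError(f"seed {k!r} must be an integer")
        if self.data["contact"]["rule"] not in ("any_atom", "c_alpha"):
            raise ConfigError("contact.rule must be any_atom or c_alpha")
        if self.data["kernel"]["sigma"] not in (20, 40):
            raise ConfigError("kernel.sigma must be 20 or 40")

    def __getitem__(self, key):
        return self.data[key]

    @property
    def out_dir(self) -> Path:
        return Path(self.data["out_dir"])

    def to_json(self) -> str:
        return json.dumps(self.data, sort_keys=True)

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]
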