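"""Run configuration: YAML dialect, validation, manifests.

A run config is a YAML mapping with sections::

    model:                # continuous-model parameters (ModelParams fields)
      kind: continuous    # or "lattice" (LatticeConfig fields)
      D_acc: 4
      delta: 3
    ensemble:
      samples: 2000
      seed: 7
      t_max: null         # default: 10 * L^2 / (4 D)
    sweep:                # optional: parameter name -> list of values
      n_b: [0, 25, 50, 100]
    output:
      dir: results

Unknown keys are rejected (strict mode) so sweep-name typos fail loudly.
All randomness flows from ``ensemble.seed``; every run writes a manifest
(config hash, seed, package version) next to its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .lattice import LatticeConfig
from .scene import ModelParams

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    kind: str                      # "continuous" | "lattice"
    model: object                  # ModelParams | LatticeConfig
    n_samples: int = 1000
    seed: int = 0
    t_max: float | None = None
    sweep: dict = field(default_factory=dict)
    output_dir: str = "results"
    log_level: str = "INFO"

    def normalized(self) -> dict:
        return {
            "model": {"kind": self.kind, **dataclasses.asdict(self.model)},
            "ensemble": {"samples": self.n_samples, "seed": self.seed,
                         "t_max": self.t_max},
            "sweep": {k: list(v) for k, v in self.sweep.items()},
            "output": {"dir": self.output_dir, "log_level": self.log_level},
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.normalized(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def manifest(self, extra=None) -> dict:
        from . import __version__

        man = {
            "config_hash": self.config_hash(),
            "seed": self.seed,
            "package": "nksearch",
            "version": __version__,
            "config": self.normalized(),
        }
        if extra:
            man.update(extra)
        return man

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.normalized(), fh, sort_keys=False)


def _check_keys(section: dict, allowed, where: str):
    unknown = set(section) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _build(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    _check_keys(raw, {"model", "ensemble", "sweep", "output"}, "config")
    model_sec = dict(raw.get("model", {}))
    kind = model_sec.pop("kind", "continuous")
    if kind == "continuous":
        fields = {f.name for f in dataclasses.fields(ModelParams)}
        _check_keys(model_sec, fields, "model")
        try:
            model = ModelParams(**model_sec)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid model section: {exc}") from exc
    elif kind == "lattice":
        fields = {f.name for f in dataclasses.fields(LatticeConfig)}
        _check_keys(model_sec, fields, "model")
        try:
            model = LatticeConfig(**model_sec)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid model section: {exc}") from exc
    else:
        raise ConfigError(f"unknown model kind {kind!r}")

    ens = dict(raw.get("ensemble", {}))
    _check_keys(ens, {"samples", "seed", "t_max"}, "ensemble")
    sweep = dict(raw.get("sweep", {}) or {})
    valid_names = {f.name for f in dataclasses.fields(type(model))}
    for name in sweep:
        if name not in valid_names:
            raise ConfigError(f"sweep over unknown parameter {name!r}")
    out = dict(raw.get("output", {}) or {})
    _check_keys(out, {"dir", "log_level"}, "output")
    return RunConfig(
        kind=kind,
        model=model,
        n_samples=int(ens.get("samples", 1000)),
        seed=int(ens.get("seed", getattr(model, "seed", 0))),
        t_max=ens.get("t_max"),
        sweep=sweep,
        output_dir=str(out.get("dir", "results")),
        log_level=str(out.get("log_level", "INFO")),
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run config; defaults applied (L=50, D=1,
    R=0.5 — the dimensionless unit conventions)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _build(raw if raw is not None else {})


def loads_config(text: str) -> RunConfig:
    return _build(yaml.safe_load(text) or {})
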