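"""Run configuration: YAML file + flag overrides.

A config file has an ``inputs`` directory (the six TSV tables), a
``strategy`` block for the layer-construction choices, a ``model`` block
for the walk parameters, a ``seed`` and an ``output`` directory.  Missing
keys fall back to the recommended defaults; command-line flags override
file values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError
from .model import DEFAULTS

_STRATEGY_KEYS = (
    "disease_layer",
    "k",
    "delta",
    "weighted",
    "knn_mode",
    "ppi",
    "rw",
    "expr_cutoff",
    "tissue",
)
_MODEL_KEYS = ("alpha", "beta", "gamma", "epsilon", "max_iter")


@dataclass
class RunConfig:
    inputs: str | None = None
    output: str = "out"
    seed: int = 0
    strategy: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in self.strategy:
            if key not in _STRATEGY_KEYS:
                raise ParameterError(f"unknown strategy key {key!r}")
        for key in self.model:
            if key not in _MODEL_KEYS:
                raise ParameterError(f"unknown model key {key!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            inputs=raw.get("inputs"),
            output=raw.get("output", "out"),
            seed=int(raw.get("seed", 0)),
            strategy=dict(raw.get("strategy", {})),
            model=dict(raw.get("model", {})),
        )

    def model_kwargs(self) -> dict:
        """Merged strategy+model parameters with defaults filled in."""
        kwargs = dict(DEFAULTS)
        kwargs.pop("expr_cutoff", None)
        kwargs["expr_cutoff"] = DEFAULTS["expr_cutoff"]
        kwargs["tissue"] = None
        kwargs.update({k: v for k, v in self.strategy.items() if v is not None})
        kwargs.update({k: v for k, v in self.model.items() if v is not None})
        return kwargs

    def override(self, **updates) -> "RunConfig":
        """New config with non-None flag values applied on top."""
        strategy = dict(self.strategy)
        model = dict(self.model)
        out = {"inputs": self.inputs, "output": self.output, "seed": self.seed}
        for key, value in updates.items():
            if value is None:
                continue
            if key in _STRATEGY_KEYS:
                strategy[key] = value
            elif key in _MODEL_KEYS:
                model[key] = value
            elif key in out:
                out[key] = value
            else:
                raise ParameterError(f"unknown config key {key!r}")
        return RunConfig(strategy=strategy, model=model, **out)

    def to_dict(self) -> dict:
        return {
            "inputs": self.inputs,
            "output": self.output,
            "seed": self.seed,
            "strategy": dict(self.strategy),
            "model": dict(self.model),
        }

    def write_manifest(self, directory) -> Path:
        """Echo the full effective configuration for reproducibility."""
        from . import __version__

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "config": self.to_dict(),
            "effective_model_kwargs": self.model_kwargs(),
            "seed": self.seed,
            "complexwalk_version": __version__,
        }
        path = directory / "manifest.json"
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        return path
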