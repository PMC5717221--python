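"""Run configuration: strict schema, JSON/YAML round-tripping.

A run configuration is the model configuration plus ensemble size, step
count, seed, output locations and analysis toggles.  Loading is strict:
unknown keys and missing model parameters are schema errors, so a config
file always round-trips losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .channels import Scales, build_channel_set
from .exceptions import ConfigError, LgcaError
from .kernels import ModelConfig, VacfSpec

__all__ = ["RunConfig", "load_config", "save_config", "config_to_dict", "model_config_from_dict"]

_MODEL_KEYS = {"model", "b", "v", "D_rw", "beta", "vacf", "ballistic_until_valid"}
_VACF_KEYS = {"family", "C0", "Delta", "phi", "alpha"}
_RUN_KEYS = _MODEL_KEYS | {
    "n_particles", "n_steps", "seed", "output_dir",
    "analyses",
}
_ANALYSES = {"vacf", "msd", "regime", "theory_overlay"}


@dataclass(frozen=True)
class RunConfig:
    model_config: ModelConfig
    n_particles: int
    n_steps: int
    seed: int
    output_dir: Optional[str] = None
    analyses: tuple = ("vacf", "msd")

    def __post_init__(self):
        if self.n_particles < 1 or self.n_steps < 1:
            raise ConfigError("n_particles and n_steps must be >= 1")
        bad = set(self.analyses) - _ANALYSES
        if bad:
            raise ConfigError(f"unknown analyses: {sorted(bad)}")


def config_to_dict(mc: ModelConfig) -> dict:
    out = {
        "model": mc.model,
        "b": mc.channels.b,
        "v": mc.scales.v,
        "D_rw": mc.scales.D_rw,
    }
    if mc.beta is not None:
        out["beta"] = mc.beta
    if mc.vacf is not None:
        v = {"family": mc.vacf.family}
        for key in ("C0", "Delta", "phi", "alpha"):
            val = getattr(mc.vacf, key)
            if val != 0.0 or (key == "C0" and mc.vacf.family in
                              ("power_law", "piecewise_ballistic", "tanh_power_law")):
                v[key] = val
        out["vacf"] = v
    if mc.ballistic_until_valid:
        out["ballistic_until_valid"] = True
    return out


def model_config_from_dict(data: dict) -> ModelConfig:
    unknown = set(data) - _MODEL_KEYS
    if unknown:
        raise ConfigError(f"unknown model config keys: {sorted(unknown)}")
    for key in ("model", "b", "v", "D_rw"):
        if key not in data:
            raise ConfigError(f"missing required config key: {key!r}")
    model = data["model"]
    channels = build_channel_set(int(data["b"]))
    scales = Scales.from_speed_and_diffusion(
        float(data["v"]), float(data["D_rw"]), d=channels.d
    )
    vacf = None
    if "vacf" in data:
        vd = dict(data["vacf"])
        unknown = set(vd) - _VACF_KEYS
        if unknown:
            raise ConfigError(f"unknown vacf keys: {sorted(unknown)}")
        if "family" not in vd:
            raise ConfigError("vacf spec requires a 'family'")
        vacf = VacfSpec(**vd)
    if model == "persistent" and "beta" not in data:
        raise ConfigError("persistent model requires 'beta'")
    try:
        return ModelConfig(
            model=model,
            channels=channels,
            scales=scales,
            beta=data.get("beta"),
            vacf=vacf,
            ballistic_until_valid=bool(data.get("ballistic_until_valid", False)),
        )
    except LgcaError as exc:
        raise ConfigError(str(exc)) from exc


def run_config_from_dict(data: dict) -> RunConfig:
    unknown = set(data) - _RUN_KEYS
    if unknown:
        raise ConfigError(f"unknown run config keys: {sorted(unknown)}")
    for key in ("n_particles", "n_steps", "seed"):
        if key not in data:
            raise ConfigError(f"missing required config key: {key!r}")
    model_part = {k: data[k] for k in _MODEL_KEYS if k in data}
    return RunConfig(
        model_config=model_config_from_dict(model_part),
        n_particles=int(data["n_particles"]),
        n_steps=int(data["n_steps"]),
        seed=int(data["seed"]),
        output_dir=data.get("output_dir"),
        analyses=tuple(data.get("analyses", ("vacf", "msd"))),
    )


def run_config_to_dict(rc: RunConfig) -> dict:
    out = config_to_dict(rc.model_config)
    out.update(
        n_particles=rc.n_particles, n_steps=rc.n_steps, seed=rc.seed,
        analyses=list(rc.analyses),
    )
    if rc.output_dir is not None:
        out["output_dir"] = rc.output_dir
    return out


def load_config(path) -> RunConfig:
    """Load a run configuration from JSON or YAML (by file content)."""
    text = Path(path).read_text()
    try:
        data = json.loads(text)
    except json.JSONDecodeError:
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"config is neither valid JSON nor YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    return run_config_from_dict(data)


def save_config(rc: RunConfig, path):
    """Write a run configuration as JSON with full float precision."""
    Path(path).write_text(json.dumps(run_config_to_dict(rc), indent=2))
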