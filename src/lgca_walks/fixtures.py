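"""Canned seeded reference ensembles used across the test suite and the
``fixtures`` CLI subcommand.

One ensemble per model, at the parameter values of the published
theory-vs-simulation comparison: sensitivity beta = 5 for the persistent
walk; C0 = 0.5, Delta = 0.016 with exponents phi = 1 (time-correlated) and
phi = 0.1 (generalized); speed v = 16 and D_rw = 1 throughout, so
eps = 0.25 and tau = 0.015625.  With these scales the crossover time
marginally exceeds the time step, so the time-correlated ensemble runs with
the ballistic-extension mode (its first step is ballistic).

Ensembles are derived from a single seed through a SeedSequence spawn, so
regeneration is byte-identical for a given seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .channels import Scales, build_channel_set
from .config import config_to_dict
from .engine import TrajectoryEnsemble, simulate_ensemble
from .kernels import ModelConfig, VacfSpec

__all__ = ["make_fixtures", "fixture_configs"]

_THEORY_IDS = {
    "classical": {"vacf": "vacf_delta", "msd": "msd_classical"},
    "persistent": {"vacf": "vacf_persistent", "msd": "msd_persistent"},
    "time_correlated": {"vacf": "vacf_power_law", "msd": "msd_tc_power_law"},
    "generalized": {"vacf": "vacf_generalized", "msd": "msd_gtc"},
}


def fixture_configs() -> dict[str, ModelConfig]:
    cs = build_channel_set(4)
    scales = Scales.from_speed_and_diffusion(v=16.0, D_rw=1.0, d=2)
    power = lambda phi: VacfSpec(family="power_law", C0=0.5, Delta=0.016, phi=phi)
    return {
        "classical": ModelConfig(model="classical", channels=cs, scales=scales),
        "persistent": ModelConfig(model="persistent", channels=cs, scales=scales, beta=5.0),
        "time_correlated": ModelConfig(
            model="time_correlated", channels=cs, scales=scales, vacf=power(1.0),
            ballistic_until_valid=True,
        ),
        "generalized": ModelConfig(
            model="generalized", channels=cs, scales=scales, vacf=power(0.1),
        ),
    }


def make_fixtures(
    seed: int, n_particles: int = 2000, n_steps: int = 100, out_dir=None
) -> dict[str, TrajectoryEnsemble]:
    """Build the four reference ensembles; optionally write CSV + metadata.

    Per-model seeds are spawned deterministically from ``seed``.
    """
    configs = fixture_configs()
    children = np.random.SeedSequence(seed).spawn(len(configs))
    ensembles = {}
    for (name, cfg), ss in zip(configs.items(), children):
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        ensembles[name] = simulate_ensemble(cfg, n_particles, n_steps, sub_seed)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, ens in ensembles.items():
            ens.to_csv(out / f"{name}.csv")
            meta = config_to_dict(ens.config)
            meta.update(
                n_particles=ens.n_particles, n_steps=ens.n_steps, seed=ens.seed,
                parent_seed=seed, theory=_THEORY_IDS[name],
            )
            (out / f"{name}.json").write_text(json.dumps(meta, indent=2))
    return ensembles
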