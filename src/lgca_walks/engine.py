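"""Seeded Monte-Carlo simulation of ensembles of independent LGCA walkers.

Each walker starts with a uniformly drawn initial channel ``i_0`` and at
every step ``k = 1..n_steps`` draws a new channel from its model's
reorientation kernel (classical/persistent condition on ``i_{k-1}``;
time-correlated/generalized condition on ``i_0`` and ``k``), then moves one
lattice spacing along it.  Walkers never interact: the multi-particle
reorientation probability factorizes, so an ensemble of independent
single-walker lattices realizes the model exactly.

Reproducibility contract: the ensemble is a pure function of
``(config, n_particles, n_steps, seed)``.  A single PCG64 stream drives the
run; the initial-channel uniforms are drawn first (one block of
``n_particles``), then one ``(n_particles, n_steps)`` block in particle-major
(C) order, each variate consumed by an inverse-CDF categorical draw over the
channels in index order (a draw landing exactly on a CDF boundary selects
the higher index).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import KernelValidityError, ParameterError
from .kernels import (
    ModelConfig,
    VacfSpec,
    _linear_kernel_matrix,
    gtc_kernel_matrix,
    persistent_transition_matrix,
)

__all__ = ["TrajectoryEnsemble", "simulate_ensemble", "advance_step"]


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """Channel and position histories of ``n_particles`` independent walkers.

    ``channels[p, k]`` is the channel index of particle ``p`` at step ``k``
    (``k = 0`` is the initial orientation; the walker is displaced at steps
    ``1..n_steps``).  Positions are reconstructed exactly from the channels:
    ``x_k = eps * sum_{j=1}^{k} c_{i_j}``.
    """

    config: ModelConfig
    n_particles: int
    n_steps: int
    seed: int
    channels: np.ndarray = field(repr=False)

    @property
    def initial_channels(self) -> np.ndarray:
        return self.channels[:, 0]

    @cached_property
    def positions(self) -> np.ndarray:
        """Positions, shape ``(n_particles, n_steps + 1, 2)``; ``x_0 = 0``."""
        vecs = self.config.channels.vectors[self.channels[:, 1:]]
        pos = np.zeros((self.n_particles, self.n_steps + 1, 2))
        np.cumsum(self.config.scales.epsilon * vecs, axis=1, out=pos[:, 1:])
        return pos

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: (particle_id, step, channel, x, y)."""
        n, m = self.channels.shape
        pos = self.positions
        return pd.DataFrame(
            {
                "particle_id": np.repeat(np.arange(n), m),
                "step": np.tile(np.arange(m), n),
                "channel": self.channels.ravel(),
                "x": pos[:, :, 0].ravel(),
                "y": pos[:, :, 1].ravel(),
            }
        )

    def to_csv(self, path, metadata_path=None):
        """Write the trajectory table; optionally a JSON sidecar with the
        full configuration and seed."""
        self.to_frame().to_csv(path, index=False)
        if metadata_path is not None:
            from .config import config_to_dict

            meta = config_to_dict(self.config)
            meta.update(
                n_particles=self.n_particles, n_steps=self.n_steps, seed=self.seed
            )
            Path(metadata_path).write_text(json.dumps(meta, indent=2))


def advance_step(cdf_rows: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF categorical draw.

    ``cdf_rows[p]`` is the cumulative distribution over channels for
    particle ``p`` (last entry 1); ``u`` the uniform variates.  A variate
    exactly equal to a CDF boundary selects the higher index.
    """
    return np.sum(u[:, None] >= cdf_rows[:, :-1], axis=1)


def simulate_ensemble(
    config: ModelConfig, n_particles: int, n_steps: int, seed: int
) -> TrajectoryEnsemble:
    """Simulate an ensemble of independent walkers under ``config``.

    Raises :class:`KernelValidityError` (with the step index) if the
    time-correlated kernel becomes invalid and ``config.ballistic_until_valid``
    is not set.
    """
    if n_particles < 1 or n_steps < 1:
        raise ParameterError("need n_particles >= 1 and n_steps >= 1")
    cs, scales = config.channels, config.scales
    b = cs.b
    rng = np.random.default_rng(seed)
    u0 = rng.random(n_particles)
    U = rng.random((n_particles, n_steps))

    channels = np.empty((n_particles, n_steps + 1), dtype=np.int64)
    uniform_cdf = np.cumsum(np.full(b, 1.0 / b))[None, :]
    channels[:, 0] = advance_step(np.broadcast_to(uniform_cdf, (n_particles, b)), u0)

    if config.model == "classical":
        cdf = np.broadcast_to(uniform_cdf, (n_particles, b))
        for k in range(1, n_steps + 1):
            channels[:, k] = advance_step(cdf, U[:, k - 1])
    elif config.model == "persistent":
        T = persistent_transition_matrix(config.beta, cs)
        C = np.cumsum(T, axis=1)
        for k in range(1, n_steps + 1):
            channels[:, k] = advance_step(C[channels[:, k - 1]], U[:, k - 1])
    else:
        spec: VacfSpec = config.vacf
        i0 = channels[:, 0]
        for k in range(1, n_steps + 1):
            P = _kernel_matrix_at_step(config, spec, cs, scales, k)
            if P is None:  # ballistic step: keep the initial channel
                channels[:, k] = i0
                continue
            C = np.cumsum(P, axis=1)
            channels[:, k] = advance_step(C[i0], U[:, k - 1])

    return TrajectoryEnsemble(
        config=config,
        n_particles=n_particles,
        n_steps=n_steps,
        seed=seed,
        channels=channels,
    )


def _kernel_matrix_at_step(config, spec, cs, scales, k):
    """The (b, b) kernel rows (indexed by initial channel) at step k, or
    None for a ballistic step."""
    if config.model == "generalized":
        g_k = float(spec.C0 * (spec.Delta / (k * scales.tau)) ** spec.phi)
        return gtc_kernel_matrix(g_k, cs)
    # time_correlated
    if spec.family == "piecewise_ballistic" and k <= spec.omega(scales.tau):
        return None
    g_k = float(spec.g(k * scales.tau))
    if abs(g_k) > 1.0 / cs.d + 1e-12:
        if config.ballistic_until_valid:
            return None
        raise KernelValidityError(
            f"time-correlated kernel invalid at step {k}: |g(k tau)| = "
            f"{abs(g_k):.6f} > 1/d",
            step=k,
        )
    return _linear_kernel_matrix(g_k, cs)
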