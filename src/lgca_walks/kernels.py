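"""Per-step reorientation kernels for the four walk models.

Each kernel returns the probability vector ``P_{i,k}`` over the ``b``
velocity channels from which the walker's next orientation is drawn:

classical
    uniform, ``P_i = 1/b`` — the memoryless random walk.
persistent
    Boltzmann-like weighting of the alignment with the *previous*
    orientation, ``P_i ∝ exp[β (c_prev · c_i)]`` with sensitivity ``β ≥ 0``.
    β lumps the ratio of the effective reorientation-torque relaxation rate
    to the rotational diffusion constant of a crawling cell.
time_correlated
    non-homogeneous linear kernel built to reproduce a prescribed VACF
    ``g(t)`` exactly: ``P_i = (1 + d (c_{i0} · c_i) g(kτ)) / b``, conditioning
    on the *initial* orientation.  Valid only while ``|g| ≤ 1/d``; with a
    long crossover time the walk is ballistic (a degenerate vector on the
    initial channel) until the power law drops to 1.
generalized
    maximum-caliber (path-entropy) kernel with time-dependent Lagrange
    multiplier ``β(k) = d·g(kτ)``: ``P_i ∝ exp[d g(kτ) (c_{i0} · c_i)]``.
    Always a valid distribution; the *realized* VACF is the hyperbolic-
    tangent-saturated version of the target power law.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .channels import ChannelSet, Scales, alignment_matrix
from .exceptions import ConfigError, KernelValidityError, ParameterError

__all__ = [
    "VacfSpec",
    "ModelConfig",
    "classical_probabilities",
    "persistent_probabilities",
    "persistent_transition_matrix",
    "tc_probabilities",
    "gtc_probabilities",
    "validate_probabilities",
]

log = logging.getLogger(__name__)

VacfFamily = Literal[
    "delta", "exponential", "power_law", "piecewise_ballistic", "tanh_power_law"
]


@dataclass(frozen=True)
class VacfSpec:
    """A target/analytic VACF family.

    Parameters
    ----------
    family : str
        One of ``delta``, ``exponential``, ``power_law``,
        ``piecewise_ballistic``, ``tanh_power_law``.
    C0 : float
        Correlation amplitude (dimensionless; negative = anticorrelated).
    Delta : float
        Crossover time at which the power law passes through ``C0``.
    phi : float
        Power-law decay exponent (> 0).
    alpha : float
        Per-time exponential decay rate (``exponential`` family only,
        ``g(t) = exp(alpha t)`` with ``alpha <= 0``).
    """

    family: VacfFamily
    C0: float = 0.0
    Delta: float = 0.0
    phi: float = 0.0
    alpha: float = 0.0

    def __post_init__(self):
        for name in ("C0", "Delta", "phi", "alpha"):
            if not math.isfinite(getattr(self, name)):
                raise ParameterError(f"VacfSpec.{name} must be finite")
        if self.family in ("power_law", "piecewise_ballistic", "tanh_power_law"):
            if self.Delta <= 0:
                raise ParameterError("crossover time Delta must be > 0")
            if self.phi <= 0:
                raise ParameterError("decay exponent phi must be > 0")
        if self.family == "exponential" and self.alpha > 0:
            raise ParameterError("exponential VACF requires alpha <= 0")

    @property
    def t_star(self) -> float:
        """End of the ballistic phase: the time where the power law reaches 1,
        ``C0 (Delta/t*)^phi = 1``, i.e. ``t* = Delta * C0**(1/phi)``.
        Defined for the piecewise family with ``C0`` in (0, 1]."""
        if self.family != "piecewise_ballistic":
            raise ParameterError("t_star is defined for the piecewise_ballistic family")
        if not (0.0 < self.C0 <= 1.0):
            raise ParameterError("piecewise ballistic phase requires C0 in (0, 1]")
        return self.Delta * self.C0 ** (1.0 / self.phi)

    def omega(self, tau: float) -> int:
        """Ballistic step count: smallest integer with ``omega * tau >= t*``."""
        return int(math.ceil(self.t_star / tau - 1e-12))

    def g(self, t):
        """Evaluate the VACF at time(s) ``t > 0`` (``t = 0`` gives 1)."""
        t = np.asarray(t, dtype=float)
        if self.family == "delta":
            return np.where(t == 0.0, 1.0, 0.0)
        if self.family == "exponential":
            return np.exp(self.alpha * t)
        if self.family == "power_law":
            return self.C0 * (self.Delta / t) ** self.phi
        if self.family == "tanh_power_law":
            return np.tanh(self.C0 * (self.Delta / t) ** self.phi)
        # piecewise_ballistic
        ts = self.t_star
        with np.errstate(divide="ignore"):
            tail = self.C0 * (self.Delta / np.where(t > 0, t, np.inf)) ** self.phi
        return np.where(t <= ts, 1.0, tail)


@dataclass(frozen=True)
class ModelConfig:
    """Full specification of one walk model.

    ``beta`` is required for the persistent model only; ``vacf`` for the
    time-correlated and generalized models only.
    """

    model: Literal["classical", "persistent", "time_correlated", "generalized"]
    channels: ChannelSet
    scales: Scales
    beta: Optional[float] = None
    vacf: Optional[VacfSpec] = None
    ballistic_until_valid: bool = False

    def __post_init__(self):
        if self.model == "persistent":
            if self.beta is None or not math.isfinite(self.beta) or self.beta < 0:
                raise ConfigError("persistent model requires finite beta >= 0")
            if self.vacf is not None:
                raise ConfigError("persistent model takes no VACF spec")
        elif self.model in ("time_correlated", "generalized"):
            if self.vacf is None:
                raise ConfigError(f"{self.model} model requires a VACF spec")
            if self.beta is not None:
                raise ConfigError(f"{self.model} model takes no beta")
            allowed = ("power_law", "piecewise_ballistic")
            if self.model == "generalized":
                allowed = ("power_law",)
            if self.vacf.family not in allowed:
                raise ConfigError(
                    f"{self.model} model supports VACF families {allowed}, "
                    f"got {self.vacf.family!r}"
                )
            if (
                self.model == "time_correlated"
                and self.vacf.family == "power_law"
                and self.vacf.Delta > self.scales.tau
                and not self.ballistic_until_valid
            ):
                raise ConfigError(
                    "power-law time-correlated kernel requires Delta <= tau "
                    f"(Delta={self.vacf.Delta}, tau={self.scales.tau}); use the "
                    "piecewise family or enable ballistic_until_valid"
                )
        elif self.model == "classical":
            if self.beta is not None or self.vacf is not None:
                raise ConfigError("classical model takes no parameters")
        else:
            raise ConfigError(f"unknown model {self.model!r}")


def classical_probabilities(channel_set: ChannelSet) -> np.ndarray:
    """Uniform reorientation: every channel with probability ``1/b``."""
    return np.full(channel_set.b, 1.0 / channel_set.b)


def persistent_transition_matrix(beta: float, channel_set: ChannelSet) -> np.ndarray:
    """Row-stochastic ``b x b`` matrix ``T[prev, i] ∝ exp[beta (c_prev · c_i)]``.

    Row ``prev`` is the reorientation distribution given the previous
    channel; the matrix is circulant because the alignments are.
    """
    if not math.isfinite(beta):
        raise ParameterError("beta must be finite")
    if beta < 0:
        raise ParameterError("beta must be >= 0")
    A = alignment_matrix(channel_set)
    W = np.exp(beta * A)
    return W / W.sum(axis=1, keepdims=True)


def persistent_probabilities(
    prev_channel: int, beta: float, channel_set: ChannelSet
) -> np.ndarray:
    """Reorientation distribution of the persistent walk given the previous
    channel (one row of :func:`persistent_transition_matrix`)."""
    b = channel_set.b
    if not 0 <= prev_channel < b:
        raise ParameterError(f"prev_channel must be in [0, {b}), got {prev_channel}")
    return persistent_transition_matrix(beta, channel_set)[prev_channel]


def _linear_kernel_matrix(g_k: float, channel_set: ChannelSet) -> np.ndarray:
    """Rows ``i0`` of ``P_i = (1 + d (c_{i0}·c_i) g) / b`` (may contain
    negative entries; caller validates)."""
    A = alignment_matrix(channel_set)
    return (1.0 + channel_set.d * A * g_k) / channel_set.b


def tc_probabilities(
    initial_channel: int,
    k: int,
    spec: VacfSpec,
    channel_set: ChannelSet,
    scales: Scales,
    ballistic_until_valid: bool = False,
) -> np.ndarray:
    """Time-correlated kernel at step ``k >= 1`` conditioned on the initial
    channel.

    For the piecewise family, steps ``k <= omega`` are ballistic (degenerate
    vector on ``initial_channel``).  Otherwise the linear kernel is used;
    it satisfies the first-moment identity
    ``sum_i P_i (c_{i0}·c_i) = g(k tau)`` exactly, which is the defining
    construction.  If ``|g(k tau)| > 1/d`` the linear kernel has a negative
    entry: by default this raises :class:`KernelValidityError`; with
    ``ballistic_until_valid=True`` the ballistic phase is instead extended to
    the first step at which the kernel is valid (logged as a deviation).
    """
    if k < 1:
        raise ParameterError("step index k must be >= 1")
    b = channel_set.b
    if not 0 <= initial_channel < b:
        raise ParameterError(f"initial_channel must be in [0, {b})")
    if spec.family not in ("power_law", "piecewise_ballistic"):
        raise ParameterError(
            "time-correlated kernel requires a power_law or piecewise_ballistic spec"
        )
    if spec.family == "piecewise_ballistic" and k <= spec.omega(scales.tau):
        p = np.zeros(b)
        p[initial_channel] = 1.0
        return p
    g_k = float(spec.g(k * scales.tau))
    if abs(g_k) > 1.0 / channel_set.d + 1e-12:
        if ballistic_until_valid:
            log.warning(
                "linear kernel invalid at step %d (g=%.6f, |g| > 1/d); "
                "extending ballistic phase", k, g_k,
            )
            p = np.zeros(b)
            p[initial_channel] = 1.0
            return p
        raise KernelValidityError(
            f"linear kernel invalid at step {k}: g(k tau) = {g_k:.6f} "
            f"gives a negative probability (|g| > 1/d = {1.0 / channel_set.d})",
            step=k,
        )
    return _linear_kernel_matrix(g_k, channel_set)[initial_channel]


def gtc_probabilities(
    initial_channel: int,
    k: int,
    spec: VacfSpec,
    channel_set: ChannelSet,
    scales: Scales,
) -> np.ndarray:
    """Maximum-caliber kernel at step ``k >= 1``:
    ``P_i = exp[d g(k tau) (c_{i0}·c_i)] / z``.

    ``g`` is the *target* power-law VACF; the kernel is a valid distribution
    for any finite ``g`` (the realized first moment saturates at
    ``tanh`` of the Lagrange multiplier instead of overshooting).
    For ``b = 4`` the partition function is ``z = 2(1 + cosh beta(k))``.
    """
    if k < 1:
        raise ParameterError("step index k must be >= 1")
    b = channel_set.b
    if not 0 <= initial_channel < b:
        raise ParameterError(f"initial_channel must be in [0, {b})")
    if spec.family != "power_law":
        raise ParameterError("generalized kernel requires a power_law target spec")
    g_k = float(spec.C0 * (spec.Delta / (k * scales.tau)) ** spec.phi)
    if not math.isfinite(g_k):
        raise ParameterError(f"non-finite target VACF at step {k}")
    A = alignment_matrix(channel_set)
    W = np.exp(channel_set.d * g_k * A[initial_channel])
    return W / W.sum()


def gtc_kernel_matrix(g_k: float, channel_set: ChannelSet) -> np.ndarray:
    """All rows (indexed by initial channel) of the maximum-caliber kernel
    for a given target VACF value ``g_k``."""
    A = alignment_matrix(channel_set)
    W = np.exp(channel_set.d * g_k * A)
    return W / W.sum(axis=1, keepdims=True)


def validate_probabilities(p: np.ndarray, atol: float = 1e-12) -> np.ndarray:
    """Check that ``p`` is a probability vector (entries in ``[-atol, 1+atol]``
    summing to 1 within ``atol``); clip exact-zero round-off and return."""
    p = np.asarray(p, dtype=float)
    if np.any(p < -atol) or np.any(p > 1.0 + atol):
        raise KernelValidityError(f"probability entries out of [0, 1]: {p}")
    total = p.sum()
    if abs(total - 1.0) > max(atol, 1e-12 * p.size):
        raise KernelValidityError(f"probabilities sum to {total!r}, not 1")
    return np.clip(p, 0.0, 1.0)
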