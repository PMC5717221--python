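"""Exact VACF of homogeneous symmetric Markov orientation chains and the
delta / alternating / exponential trichotomy.

A walker whose orientation follows a *homogeneous, symmetric* Markov chain
over the channels (transition probability depending only on the absolute
angular difference — a circulant, reflection-symmetric matrix) can never
have a power-law VACF: the correlation is carried by the cosine Fourier mode
of the circulant chain, so ``g(k) = lambda_1^k`` with a real eigenvalue
``lambda_1``, which is a Kronecker delta (``lambda_1 = 0``), an alternating
geometric sequence (``lambda_1 < 0``) or an exponential decay
(``0 < lambda_1 <= 1``).  This is why reproducing power-law correlations
requires the non-homogeneous kernels in :mod:`lgca_walks.kernels`.

``chain_vacf`` computes the VACF by brute-force matrix powers (no spectral
shortcut), so it doubles as an independent oracle for the persistent
kernel's closed-form decay rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .channels import ChannelSet, alignment_matrix
from .exceptions import NumericsError, ParameterError
from .stats import CurveSeries

__all__ = [
    "OrientationChain",
    "chain_vacf",
    "classify_decay",
    "random_symmetric_circulant",
]


@dataclass(frozen=True)
class OrientationChain:
    """A row-stochastic transition matrix over the ``b`` channels.

    Construction verifies stochasticity and the structural symmetry
    (circulant + reflection-symmetric); asymmetric inputs are rejected
    rather than silently classified.
    """

    transition: np.ndarray = field(repr=False)
    symmetric: bool = True

    def __post_init__(self):
        P = np.asarray(self.transition, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ParameterError("transition matrix must be square")
        if np.any(P < -1e-12):
            raise ParameterError("transition matrix has negative entries")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
            raise ParameterError("transition matrix rows must sum to 1")
        object.__setattr__(self, "transition", P)
        b = P.shape[0]
        row0 = P[0]
        circulant = all(np.allclose(P[r], np.roll(row0, r), atol=1e-12) for r in range(b))
        reflect = np.allclose(row0[1:], row0[1:][::-1], atol=1e-12)
        is_sym = bool(circulant and reflect)
        if self.symmetric and not is_sym:
            raise ParameterError(
                "chain is not homogeneous-symmetric (circulant with "
                "p_j = p_{b-j}); the trichotomy does not apply"
            )
        object.__setattr__(self, "symmetric", is_sym)

    @property
    def b(self) -> int:
        return self.transition.shape[0]


def chain_vacf(chain: OrientationChain, channel_set: ChannelSet, k_max: int) -> CurveSeries:
    """Exact VACF of the chain for lags ``0..k_max`` with a uniform initial
    orientation: ``g(k) = (1/b) sum_{i0,ik} (c_{i0}·c_{ik}) [P^k]_{i0,ik}``."""
    if k_max < 1:
        raise ParameterError("k_max must be >= 1")
    if chain.b != channel_set.b:
        raise ParameterError("chain and channel set sizes differ")
    A = alignment_matrix(channel_set)
    P = chain.transition
    b = chain.b
    g = np.empty(k_max + 1)
    M = np.eye(b)
    for k in range(k_max + 1):
        g[k] = float((A * M).sum()) / b
        M = M @ P
    lags = np.arange(k_max + 1)
    return CurveSeries(lags=lags, times=lags.astype(float), value=g,
                       sem=np.zeros(k_max + 1), n=b, kind="chain_vacf")


def classify_decay(
    g: CurveSeries, delta_tol: float = 1e-12, ratio_tol: float = 1e-9
):
    """Classify an exact chain VACF as delta, alternating or exponential.

    Returns ``(label, rate)`` where ``rate`` is ``None`` for delta,
    the geometric base ``a > 0`` for alternating (``g_k = (-1)^k a^k``), and
    the exponent ``alpha = ln(ratio) <= 0`` for exponential
    (``g_k = e^{alpha k}``).  Inputs that fit none of the three classes
    within tolerance (non-symmetric or non-homogeneous chains) raise
    :class:`NumericsError`.
    """
    vals = np.asarray(g.value, dtype=float)
    if vals.size < 5:
        raise ParameterError("need g(0..k) with k_max >= 4")
    if abs(vals[0] - 1.0) > delta_tol:
        raise ParameterError("a VACF must start at g(0) = 1")
    tail = vals[1:]
    if np.all(np.abs(tail) < delta_tol):
        return "delta", None
    # for a geometric VACF the base is g(1) itself; verify g(k) = g(1)^k to
    # within an absolute tolerance (matrix powers carry ~1e-15 absolute noise,
    # so ratio tests fail spuriously once g(1)^k underflows that noise)
    lam = float(tail[0])
    k = np.arange(1, vals.size)
    predicted = np.sign(lam) ** k * np.abs(lam) ** k
    if np.any(np.abs(tail - predicted) > max(ratio_tol, 1e3 * delta_tol)):
        raise NumericsError(
            "VACF is not geometric within tolerance; the chain is not "
            "homogeneous-symmetric"
        )
    if abs(lam) > 1 + ratio_tol:
        raise NumericsError("VACF grows; not a valid correlation decay")
    if lam > 0:
        return "exponential", math.log(min(lam, 1.0))
    return "alternating", abs(lam)


def random_symmetric_circulant(b: int, rng: np.random.Generator) -> OrientationChain:
    """Draw a random homogeneous symmetric chain: nonnegative circulant
    weights with the reflection symmetry ``p_j = p_{b-j}``, normalized."""
    w = rng.random(b)
    w = w + np.roll(w[::-1], 1)  # p_j = p_{b-j}
    row0 = w / w.sum()
    P = np.stack([np.roll(row0, r) for r in range(b)])
    return OrientationChain(transition=P)
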