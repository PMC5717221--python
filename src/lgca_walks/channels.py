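"""Lattice node geometry: discrete velocity channels and physical scales.

A lattice-gas cellular automaton (LGCA) node carries ``b`` unit velocity
channels

.. math:: \\vec c_j = (\\cos 2\\pi j/b,\\; \\sin 2\\pi j/b), \\qquad j = 0,\\dots,b-1.

A walker occupies one channel per step and is translocated by one lattice
spacing ``epsilon`` along it every time step ``tau``.  The effective spatial
dimension ``d`` is 1 for the two-channel (1D) lattice and 2 otherwise; it
enters the linear reorientation kernel through the normalization identity

.. math:: \\sum_j (\\vec c_i \\cdot \\vec c_j)^2 = b/d,

which holds exactly for these regular channel sets and is what makes the
kernel reproduce a prescribed velocity autocorrelation function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidGeometryError, ParameterError

__all__ = ["ChannelSet", "Scales", "build_channel_set", "alignment_matrix"]


@dataclass(frozen=True)
class ChannelSet:
    """The ``b`` discrete velocity channels of a lattice node.

    Attributes
    ----------
    b : int
        Number of velocity channels (>= 2).
    vectors : ndarray, shape (b, 2)
        Unit vectors ``c_j`` at angles ``2*pi*j/b``.
    d : int
        Effective spatial dimension: 1 for b == 2, else 2.
    """

    b: int
    vectors: np.ndarray = field(repr=False)
    d: int

    def __post_init__(self):
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise InvalidGeometryError("channel vectors must have unit norm")


@dataclass(frozen=True)
class Scales:
    """Physical space/time scales of the walk.

    The lattice spacing ``epsilon`` and step duration ``tau`` are determined
    uniquely by the instantaneous speed ``v = epsilon/tau`` and the
    random-walk diffusion coefficient ``D_rw = epsilon**2 / (2*d*tau)``:

    ``epsilon = 2*d*D_rw / v``, ``tau = 2*d*D_rw / v**2``.
    """

    epsilon: float
    tau: float
    v: float
    D_rw: float
    d: int

    @classmethod
    def from_speed_and_diffusion(cls, v: float, D_rw: float, d: int = 2) -> "Scales":
        if not (np.isfinite(v) and np.isfinite(D_rw)) or v <= 0 or D_rw <= 0:
            raise ParameterError(f"v and D_rw must be finite and positive, got v={v}, D_rw={D_rw}")
        if d not in (1, 2):
            raise InvalidGeometryError(f"dimension must be 1 or 2, got {d}")
        epsilon = 2.0 * d * D_rw / v
        tau = 2.0 * d * D_rw / v**2
        return cls(epsilon=epsilon, tau=tau, v=v, D_rw=D_rw, d=d)

    @classmethod
    def from_lattice(cls, epsilon: float, tau: float, d: int = 2) -> "Scales":
        if epsilon <= 0 or tau <= 0:
            raise ParameterError("epsilon and tau must be positive")
        return cls(epsilon=epsilon, tau=tau, v=epsilon / tau,
                   D_rw=epsilon**2 / (2.0 * d * tau), d=d)


def build_channel_set(b: int) -> ChannelSet:
    """Construct the regular set of ``b`` unit velocity channels.

    Parameters
    ----------
    b : int
        Channel count; must be >= 2.  ``b == 2`` is the 1D lattice embedded
        on the x-axis (``d = 1``); all ``b >= 3`` are planar (``d = 2``).

    Returns
    -------
    ChannelSet
    """
    if not isinstance(b, (int, np.integer)) or b < 2:
        raise InvalidGeometryError(f"need at least 2 velocity channels, got b={b!r}")
    j = np.arange(b)
    angles = 2.0 * np.pi * j / b
    vectors = np.column_stack([np.cos(angles), np.sin(angles)])
    # snap values that are exactly representable (0, ±1, ±1/2 patterns are
    # not exact in floating point after cos/sin; round-off stays < 1e-15 and
    # is tolerated by the invariants rather than patched here)
    d = 1 if b == 2 else 2
    return ChannelSet(b=int(b), vectors=vectors, d=d)


def alignment_matrix(channel_set: ChannelSet) -> np.ndarray:
    """Pairwise channel alignments ``A[i, j] = c_i . c_j``.

    The matrix is symmetric, circulant (row r is row 0 rotated by r) and has
    unit diagonal; it is precomputed once and shared by all kernels.
    """
    V = channel_set.vectors
    A = V @ V.T
    return A
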