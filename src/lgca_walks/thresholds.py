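"""Diffusion-regime boundaries of the closed-form MSDs, located numerically.

Both time-correlated MSD families decompose as

    MSD(t) = (linear part in t) + (anomalous remainder),

and a regime transition happens where the growth exponent of the anomalous
remainder crosses a critical value: 0 where transients disappear (the
remainder stops growing), and 1 where the walk turns superdiffusive (the
remainder outgrows the linear part).  The finders below measure that
exponent directly from MSD values on a log-spaced grid, using a double
differencing scheme that annihilates the linear and constant parts of the
curve *exactly*: with grid ratio ``sigma``,

    D1(t) = R(sigma t) - R(t),      E(t) = D1(sigma t) - sigma * D1(t),

where ``R = MSD - 2 d D_rw t``.  For a pure power ``c t^p`` one gets
``E(t) = c (sigma^p - 1)(sigma^p - sigma) t^p``, so the log-log slope of
``|E|`` equals ``p`` with no contamination from ``c + b t`` components.  The
boundary exponent is then found by bisection on the VACF decay exponent
``phi``.

Near a boundary the remainder of the initial-orientation (time-correlated)
family is ``K[(t/Delta)^{1-phi} - 1]^2``, whose growth only becomes visible
once ``|1 - phi| * ln(t_max/Delta) >~ 1``; the default horizon for that
family therefore extends far beyond the crossover time (the closed forms are
analytic, so this costs nothing), keeping the location bias below the
bisection resolution times a few.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np
from scipy import stats as sps

from .channels import Scales
from .exceptions import NumericsError, ParameterError
from .kernels import VacfSpec
from .theory import msd_gtc_stationary, msd_tc

__all__ = [
    "remainder_growth_exponent",
    "tc_transient_threshold",
    "gtc_remainder_threshold",
    "gtc_superdiffusion_threshold",
]


def remainder_growth_exponent(
    msd_values: np.ndarray,
    times: np.ndarray,
    scales: Scales,
    fit_fraction: float = 0.35,
) -> float:
    """Growth exponent of the anomalous MSD remainder.

    ``times`` must be log-spaced (constant ratio).  The exponent is the OLS
    slope of ``ln |E|`` against ``ln t`` over the last ``fit_fraction`` of
    the grid (the late-time regime), where ``E`` is the linear-annihilating
    double difference described in the module docstring.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(msd_values, dtype=float)
    if t.size < 8:
        raise ParameterError("need at least 8 grid points")
    logr = np.diff(np.log(t))
    if not np.allclose(logr, logr[0], rtol=1e-8):
        raise ParameterError("times must be log-spaced with a constant ratio")
    sigma = math.exp(logr[0])
    R = y - 2.0 * scales.d * scales.D_rw * t
    D1 = R[1:] - R[:-1]
    E = D1[1:] - sigma * D1[:-1]
    tE = t[: E.size]
    # double differencing amplifies the float cancellation in R = MSD - 2dDt;
    # keep only points whose signal clears that pointwise noise floor, then
    # fit the latest such points (the late-time regime that is measurable)
    noise_floor = 64.0 * np.finfo(float).eps * np.abs(y[: E.size])
    good = np.abs(E) > noise_floor
    if good.sum() < 4:
        raise NumericsError("remainder indistinguishable from zero on this grid")
    n_fit = max(4, int(round(fit_fraction * E.size)))
    idx = np.nonzero(good)[0][-n_fit:]
    if idx.size < 4:
        raise NumericsError("too few usable late-time points for the exponent fit")
    res = sps.linregress(np.log(tE[idx]), np.log(np.abs(E[idx])))
    return float(res.slope)


def _bisect(f: Callable[[float], float], lo: float, hi: float, tol: float) -> float:
    flo, fhi = f(lo), f(hi)
    if flo == 0:
        return lo
    if fhi == 0:
        return hi
    if flo * fhi > 0:
        raise NumericsError(f"no sign change on [{lo}, {hi}] (f: {flo}, {fhi})")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if fm == 0:
            return mid
        if flo * fm < 0:
            hi = mid
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)


def tc_transient_threshold(
    scales: Scales,
    C0: float = 0.5,
    Delta: float = 0.016,
    bracket=(0.6, 1.6),
    tol: float = 1e-3,
    horizon_decades: float = 14.0,
    points_per_decade: int = 8,
) -> float:
    """Smallest VACF exponent ``phi`` at which the time-correlated walk's
    closed-form MSD has no sub- or superdiffusive transient: the anomalous
    remainder stops growing (its exponent ``max(2-2phi, 1-phi)`` crosses 0).
    """
    n = int(horizon_decades * points_per_decade) + 1
    t = Delta * np.logspace(0.0, horizon_decades, n)

    def f(phi: float) -> float:
        spec = VacfSpec(family="power_law", C0=C0, Delta=Delta, phi=phi)
        curve = msd_tc(t, spec, scales)
        return remainder_growth_exponent(curve.values, t, scales)

    return _bisect(f, *bracket, tol)


def gtc_remainder_threshold(
    scales: Scales,
    C0: float = 0.5,
    Delta: float = 0.016,
    bracket=(1.2, 3.0),
    tol: float = 1e-3,
    t_window=(1e2, 1e8),
    points_per_decade: int = 8,
) -> float:
    """Smallest ``phi`` for which the stationary generalized walk is purely
    normally diffusive at all times: the nonlinear remainder of the expanded
    MSD (which scales as ``t^{2-phi}``) stops growing with ``t``."""
    return _gtc_threshold(scales, C0, Delta, bracket, tol, t_window,
                          points_per_decade, critical=0.0)


def gtc_superdiffusion_threshold(
    scales: Scales,
    C0: float = 0.5,
    Delta: float = 0.016,
    bracket=(0.5, 1.6),
    tol: float = 1e-3,
    t_window=(1e2, 1e8),
    points_per_decade: int = 8,
) -> float:
    """Largest ``phi`` below which the stationary generalized walk's
    long-time MSD grows faster than linearly: the anomalous exponent
    ``2 - phi`` crosses 1."""
    return _gtc_threshold(scales, C0, Delta, bracket, tol, t_window,
                          points_per_decade, critical=1.0)


def _gtc_threshold(scales, C0, Delta, bracket, tol, t_window, ppd, critical):
    lo, hi = t_window
    n = int(round(math.log10(hi / lo) * ppd)) + 1
    t = np.logspace(math.log10(lo), math.log10(hi), n)

    def f(phi: float) -> float:
        spec = VacfSpec(family="power_law", C0=C0, Delta=Delta, phi=phi)
        curve = msd_gtc_stationary(t, spec, scales, method="closed")
        return remainder_growth_exponent(curve.values, t, scales) - critical

    return _bisect(f, *bracket, tol)
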