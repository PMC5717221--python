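"""Empirical estimators: VACF, MSD, diffusion coefficient, anomalous-
exponent (regime) classification and power-law VACF fitting.

The VACF estimator follows the model definition: the ensemble mean of the
dot product between the orientation at lag ``k`` and each particle's *own
initial* orientation.  A stationary time-averaged variant (all start lags
pooled) is available for data generated by time-translation-invariant
kernels; it is not the defining estimator and is labelled as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .channels import alignment_matrix
from .engine import TrajectoryEnsemble
from .exceptions import ParameterError

__all__ = [
    "CurveSeries",
    "RegimeReport",
    "PowerLawFit",
    "empirical_vacf",
    "empirical_msd",
    "estimate_diffusion_coefficient",
    "classify_regime",
    "fit_vacf_power_law",
]


@dataclass(frozen=True)
class CurveSeries:
    """A lag-indexed statistic with per-lag uncertainty.

    ``lags`` are step indices, ``times = lags * tau``; ``sem`` is the
    standard error of the ensemble mean (0 where the statistic is exact by
    construction, NaN where undefined, e.g. a single particle).
    """

    lags: np.ndarray
    times: np.ndarray
    value: np.ndarray
    sem: np.ndarray
    n: int
    kind: str = "curve"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.lags, "t": self.times, "value": self.value,
             "sem": self.sem, "n": self.n}
        )

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, kind="curve") -> "CurveSeries":
        df = pd.read_csv(path)
        required = {"k", "t", "value", "sem", "n"}
        missing = required - set(df.columns)
        if missing:
            raise ParameterError(f"curve CSV missing columns: {sorted(missing)}")
        return cls(
            lags=df["k"].to_numpy(), times=df["t"].to_numpy(),
            value=df["value"].to_numpy(), sem=df["sem"].to_numpy(),
            n=int(df["n"].iloc[0]), kind=kind,
        )


@dataclass(frozen=True)
class RegimeReport:
    """Result of MSD log-log slope classification."""

    exponent: float
    ci: Tuple[float, float]
    label: str  # subdiffusive | normal | superdiffusive
    window: Tuple[float, float]


@dataclass(frozen=True)
class PowerLawFit:
    """Weighted log-log fit of a power-law VACF ``g(t) = A t^{-phi}``.

    Only the lumped amplitude ``A = C0 * Delta**phi`` is identifiable from a
    single power law; ``C0`` and ``Delta`` cannot be separated.
    """

    amplitude: float
    phi: float
    amplitude_ci: Tuple[float, float]
    phi_ci: Tuple[float, float]
    n_lags: int
    residual_structure: bool  # True when systematic curvature flags a bad model


def _ensemble_check(ensemble: TrajectoryEnsemble, min_particles: int = 2):
    if ensemble.n_particles < min_particles:
        raise ParameterError(f"need at least {min_particles} particles")


def empirical_vacf(ensemble: TrajectoryEnsemble) -> CurveSeries:
    """VACF estimate ``g_hat(k) = <c_{i_0} . c_{i_k}>`` over particles.

    ``g_hat(0) = 1`` exactly with zero SEM.
    """
    _ensemble_check(ensemble)
    A = alignment_matrix(ensemble.config.channels)
    dots = A[ensemble.channels[:, [0]], ensemble.channels]
    value = dots.mean(axis=0)
    sem = dots.std(axis=0, ddof=1) / math.sqrt(ensemble.n_particles)
    k = np.arange(ensemble.n_steps + 1)
    return CurveSeries(
        lags=k, times=k * ensemble.config.scales.tau, value=value, sem=sem,
        n=ensemble.n_particles, kind="vacf",
    )


def empirical_msd(ensemble: TrajectoryEnsemble) -> CurveSeries:
    """MSD estimate ``<|x_k - x_0|^2>`` over particles (x_0 = 0)."""
    if ensemble.n_particles == 1:
        r2 = np.sum(ensemble.positions[0] ** 2, axis=1)
        k = np.arange(ensemble.n_steps + 1)
        return CurveSeries(
            lags=k, times=k * ensemble.config.scales.tau, value=r2,
            sem=np.full_like(r2, np.nan), n=1, kind="msd",
        )
    r2 = np.sum(ensemble.positions**2, axis=2)
    value = r2.mean(axis=0)
    sem = r2.std(axis=0, ddof=1) / math.sqrt(ensemble.n_particles)
    k = np.arange(ensemble.n_steps + 1)
    return CurveSeries(
        lags=k, times=k * ensemble.config.scales.tau, value=value, sem=sem,
        n=ensemble.n_particles, kind="msd",
    )


def estimate_diffusion_coefficient(
    msd: CurveSeries, d: int, window: Optional[Tuple[float, float]] = None,
    r2_threshold: float = 0.98,
):
    """Diffusion coefficient from the MSD-slope definition.

    Least-squares slope of MSD against time over ``window`` (default: the
    full positive-time range), divided by ``2 d``.  Returns
    ``(D, (lo, hi), nonlinear_flag)`` where the 95% CI comes from the slope
    standard error and the flag is set when the linear fit explains less
    than ``r2_threshold`` of the variance (e.g. a ballistic curve).
    """
    t, y = np.asarray(msd.times, float), np.asarray(msd.value, float)
    if window is None:
        mask = t > 0
    else:
        lo, hi = window
        if hi <= lo or hi <= 0:
            raise ParameterError("window must be a positive interval")
        mask = (t >= lo) & (t <= hi)
    if mask.sum() < 5:
        raise ParameterError("need at least 5 lags in the fit window")
    res = sps.linregress(t[mask], y[mask])
    tcrit = sps.t.ppf(0.975, mask.sum() - 2)
    D = res.slope / (2 * d)
    half = tcrit * res.stderr / (2 * d)
    return D, (D - half, D + half), bool(res.rvalue**2 < r2_threshold)


def classify_regime(
    msd: CurveSeries, window: Optional[Tuple[float, float]] = None,
    tol: float = 0.05,
) -> RegimeReport:
    """Fit the MSD scaling exponent ``<r^2> ~ t^phi`` by OLS on log-log axes
    and label the diffusion regime.

    ``normal`` when the 95% CI overlaps ``[1 - tol, 1 + tol]``, otherwise
    ``subdiffusive`` or ``superdiffusive`` by which side the CI lies on.
    The tolerance band absorbs the small systematic slope biases of finite
    ensembles (the OLS CI alone is too sharp a test because MSD errors are
    correlated across lags).
    """
    t, y = np.asarray(msd.times, float), np.asarray(msd.value, float)
    if window is None:
        mask = t > 0
    else:
        mask = (t >= window[0]) & (t <= window[1])
    mask &= t > 0
    if mask.sum() < 8:
        raise ParameterError("need at least 8 lags in the regime window")
    if np.any(y[mask] <= 0):
        raise ParameterError("nonpositive MSD values in regime window")
    res = sps.linregress(np.log(t[mask]), np.log(y[mask]))
    tcrit = sps.t.ppf(0.975, mask.sum() - 2)
    lo, hi = res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr
    if lo <= 1.0 + tol and hi >= 1.0 - tol:
        label = "normal"
    elif hi < 1.0:
        label = "subdiffusive"
    else:
        label = "superdiffusive"
    tw = (float(t[mask].min()), float(t[mask].max()))
    return RegimeReport(exponent=res.slope, ci=(lo, hi), label=label, window=tw)


def fit_vacf_power_law(
    vacf: CurveSeries, min_lag: int = 1, max_lag: Optional[int] = None,
    snr_min: float = 0.0,
) -> PowerLawFit:
    """Fit ``g(t) = A t^{-phi}`` by weighted nonlinear least squares.

    The fit runs in *linear* space (log-space fitting is biased low at
    low-SNR lags because ``E[log g_hat] < log E[g_hat]``); a log-log
    regression only seeds the optimizer.  Points enter unweighted — the
    per-lag variance of this estimator is nearly lag-independent, and
    weighting by the *estimated* SEMs biases the exponent because sample
    mean and sample variance are correlated — while a pooled (median) SEM
    sets the absolute error scale for the confidence intervals.  Lags are used when ``min_lag <= k <= max_lag``,
    the value is positive and (optionally) ``value > snr_min * sem``; exact
    lags (sem 0) are excluded from a noisy fit since they come from
    deterministic (ballistic) steps, unless the whole curve is noiseless,
    in which case an unweighted fit is used.

    Returns the lumped amplitude ``A = C0 Delta^phi`` and exponent ``phi``
    with 95% CIs.  ``residual_structure`` is True when a quadratic term in
    ``log t`` improves the fit significantly (a symptom of, e.g., an
    exponential-decay input).
    """
    k = np.asarray(vacf.lags)
    t = np.asarray(vacf.times, float)
    y = np.asarray(vacf.value, float)
    sem = np.asarray(vacf.sem, float)
    hi = max_lag if max_lag is not None else k.max()
    # negative noisy values stay in the fit: censoring them would bias the
    # exponent (the truncation removes only downward noise)
    mask = (k >= min_lag) & (k <= hi) & (t > 0) & np.isfinite(sem) & np.isfinite(y)
    if snr_min > 0:
        mask &= y > snr_min * sem
    noiseless = bool(np.all(sem[mask] == 0))
    if not noiseless:
        mask &= sem > 0
    if mask.sum() < 8 or (y[mask] > 0).sum() < 4:
        raise ParameterError(
            "need at least 8 usable VACF lags (4 positive); for nonpositive "
            "correlations consider the delta or alternating families"
        )
    tm, ym = t[mask], y[mask]
    lt = np.log(tm)
    # seed the nonlinear fit with a log-log regression on the positive lags
    pos = ym > 0
    Xp = np.column_stack([np.ones(pos.sum()), lt[pos]])
    beta0 = np.linalg.solve(Xp.T @ Xp, Xp.T @ np.log(ym[pos]))
    p0 = [math.exp(beta0[0]), -beta0[1]]

    from scipy.optimize import curve_fit

    model = lambda tt, A, phi: A * tt ** (-phi)
    if noiseless:
        sigma = None
    else:
        sigma = np.full(ym.shape, float(np.median(sem[mask])))
    popt, pcov = curve_fit(
        model, tm, ym, p0=p0, sigma=sigma,
        absolute_sigma=sigma is not None, maxfev=10000,
    )
    A, phi = float(popt[0]), float(popt[1])
    se = np.sqrt(np.diag(pcov))
    tcrit = sps.t.ppf(0.975, mask.sum() - 2)

    # curvature check: quadratic trend of the (weighted) residuals against
    # log t, significant at ~3 sigma, flags a non-power-law input
    resid = ym - model(tm, A, phi)
    # noiseless inputs have no error scale; use relative residuals there
    z = resid / sem[mask] if not noiseless else resid / model(tm, A, phi)
    X2 = np.column_stack([np.ones_like(lt), lt, lt**2])
    cov2 = np.linalg.inv(X2.T @ X2)
    b2 = cov2 @ (X2.T @ z)
    if noiseless:
        # error scale from the residuals left *after* the quadratic fit, so
        # the curvature being tested does not inflate its own denominator
        zq = z - X2 @ b2
        scale = math.sqrt(float(zq @ zq) / max(mask.sum() - 3, 1)) or 1.0
        z_quad = abs(b2[2]) / (math.sqrt(cov2[2, 2]) * scale)
        structured = z_quad > 3 and abs(b2[2]) > 1e-8
    else:
        z_quad = abs(b2[2]) / math.sqrt(cov2[2, 2])
        structured = z_quad > 3

    return PowerLawFit(
        amplitude=A, phi=phi,
        amplitude_ci=(A - tcrit * se[0], A + tcrit * se[0]),
        phi_ci=(phi - tcrit * se[1], phi + tcrit * se[1]),
        n_lags=int(mask.sum()), residual_structure=bool(structured),
    )


def stationary_vacf(ensemble: TrajectoryEnsemble, max_lag: Optional[int] = None) -> CurveSeries:
    """Time-averaged VACF: pools all start times ``m`` of
    ``<c_{i_m} . c_{i_{m+k}}>``.  Appropriate only for walks with
    time-translation-invariant correlations (classical, persistent,
    pairwise-coupled generalized); the initial-orientation models are
    non-stationary and should use :func:`empirical_vacf`."""
    _ensemble_check(ensemble)
    A = alignment_matrix(ensemble.config.channels)
    ch = ensemble.channels
    n_steps = ensemble.n_steps
    K = max_lag if max_lag is not None else n_steps
    value = np.empty(K + 1)
    sem = np.empty(K + 1)
    for k in range(K + 1):
        dots = A[ch[:, : n_steps + 1 - k], ch[:, k:]]
        per_particle = dots.mean(axis=1)
        value[k] = per_particle.mean()
        sem[k] = per_particle.std(ddof=1) / math.sqrt(ensemble.n_particles)
    lags = np.arange(K + 1)
    return CurveSeries(
        lags=lags, times=lags * ensemble.config.scales.tau, value=value, sem=sem,
        n=ensemble.n_particles, kind="vacf_stationary",
    )
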