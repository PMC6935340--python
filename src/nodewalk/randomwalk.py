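"""Random walk with drift for an ordered hazard-ratio series.

The model for the ordered hazard ratios H_t is

    H_t - H_{t-1} = mu + a_t,        a_t white noise,

so the first differences are a constant drift mu plus uncorrelated shocks,
and the levels integrate them:

    H_t = mu * t + H_0 + (a_1 + ... + a_t).

This module provides differencing, the drift / innovation-variance
estimators, the sample autocorrelation function, the portmanteau (Ljung-Box
or Box-Pierce) white-noise test, the integrated reconstruction, and a bundled
fit over a :class:`~nodewalk.hr_sweep.HazardRatioSeries`.

The sweep's retained points are re-indexed consecutively by default (unit
steps between successive retained cutoffs): the cutoff axis is a surrogate
ordering, not a physical time scale, and skipped cutoffs would otherwise
create irregular spacing. ``per_percent=True`` instead divides each
difference by the actual cutoff gap, giving drift per percentage point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import NumericalError
from .hr_sweep import HazardRatioSeries

__all__ = [
    "DriftFit",
    "AcfResult",
    "PortmanteauResult",
    "RandomWalkFit",
    "difference_series",
    "estimate_drift",
    "acf",
    "portmanteau_test",
    "reconstruct_series",
    "fit_random_walk",
]


@dataclass(frozen=True)
class DriftFit:
    """Drift and innovation-variance estimates of the differenced series."""

    mu: float          # drift per unit step (hazard-ratio units)
    sigma2: float      # innovation variance (sample variance of residuals, n-1)
    residuals: np.ndarray
    h0: float          # anchor level for reconstruction (first series value)
    n_diffs: int


@dataclass(frozen=True)
class AcfResult:
    """Sample autocorrelations rho_k for k = 0..max_lag."""

    rho: np.ndarray
    n: int


@dataclass(frozen=True)
class PortmanteauResult:
    """Joint test that the first ``lags`` autocorrelations vanish."""

    Q: float
    df: int
    p: float
    variant: str
    lags: int


@dataclass(frozen=True)
class RandomWalkFit:
    """Bundle of drift fit, ACF and portmanteau test for one series."""

    drift: DriftFit
    acf: AcfResult
    portmanteau: PortmanteauResult
    per_percent: bool = False
    log_scale: bool = False
    cutoffs: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_json(self, path, extra: dict | None = None) -> None:
        payload = {
            "mu": self.drift.mu,
            "sigma2": self.drift.sigma2,
            "h0": self.drift.h0,
            "n": self.drift.n_diffs + 1,
            "lags": self.portmanteau.lags,
            "variant": self.portmanteau.variant,
            "Q": self.portmanteau.Q,
            "df": self.portmanteau.df,
            "p": self.portmanteau.p,
            "acf": self.acf.rho.tolist(),
            "residuals": self.drift.residuals.tolist(),
            "per_percent": self.per_percent,
            "log_scale": self.log_scale,
            "cutoffs": np.asarray(self.cutoffs).tolist(),
        }
        if extra:
            payload.update(extra)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def difference_series(H) -> np.ndarray:
    """First differences ``H[i+1] - H[i]`` (length n-1)."""
    H = np.asarray(H, dtype=float)
    if H.ndim != 1 or H.size < 2:
        raise NumericalError("need a 1-D series of length >= 2 to difference")
    return np.diff(H)


def estimate_drift(differences, h0: float = np.nan) -> DriftFit:
    """Estimate drift and innovation variance from the differenced series.

    ``mu`` is the sample mean of the differences (which telescopes to
    ``(H_last - H_first)/(n-1)``); residuals are the centred differences and
    ``sigma2`` their sample variance with denominator n-1.
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or d.size < 2:
        raise NumericalError("need >= 2 differences to estimate drift and variance")
    if not np.all(np.isfinite(d)):
        raise NumericalError("differences must be finite")
    mu = float(d.mean())
    resid = d - mu
    sigma2 = float(resid @ resid / (d.size - 1))
    return DriftFit(mu=mu, sigma2=sigma2, residuals=resid, h0=float(h0), n_diffs=d.size)


def acf(x, max_lag: int) -> AcfResult:
    """Sample autocorrelation function up to ``max_lag``.

    rho_k = sum_{t=k+1..n} (x_t - xbar)(x_{t-k} - xbar) / sum (x_t - xbar)^2.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if max_lag < 0:
        raise NumericalError("max_lag must be >= 0")
    if n < max_lag + 2:
        raise NumericalError(f"series of length {n} too short for max_lag={max_lag}")
    xc = x - x.mean()
    denom = xc @ xc
    if denom == 0.0:
        raise NumericalError("zero-variance series: autocorrelation undefined")
    rho = np.empty(max_lag + 1)
    rho[0] = 1.0
    for k in range(1, max_lag + 1):
        rho[k] = (xc[k:] @ xc[:-k]) / denom
    return AcfResult(rho=rho, n=n)


def portmanteau_test(residuals, lags: int = 10, variant: str = "ljung-box") -> PortmanteauResult:
    """Portmanteau white-noise test on the first ``lags`` autocorrelations.

    Ljung-Box: Q = n(n+2) sum_k rho_k^2/(n-k); Box-Pierce: Q = n sum_k rho_k^2.
    The null distribution is chi-square with ``lags`` degrees of freedom; no
    degrees-of-freedom correction is applied because only a mean was removed,
    not ARMA parameters.
    """
    if variant not in ("ljung-box", "box-pierce"):
        raise NumericalError(f"unknown portmanteau variant {variant!r}")
    if lags < 1:
        raise NumericalError("lags must be >= 1")
    x = np.asarray(residuals, dtype=float)
    n = x.size
    if n <= lags + 1:
        raise NumericalError(f"series of length {n} too short for {lags} lags")
    rho = acf(x, lags).rho[1:]
    if variant == "ljung-box":
        Q = n * (n + 2) * float(np.sum(rho**2 / (n - np.arange(1, lags + 1))))
    else:
        Q = n * float(np.sum(rho**2))
    p = float(stats.chi2.sf(Q, lags))
    return PortmanteauResult(Q=float(Q), df=lags, p=p, variant=variant, lags=lags)


def reconstruct_series(mu: float, h0: float, residuals) -> np.ndarray:
    """Integrated series H_t = mu*t + H_0 + cumulative sum of residuals.

    Returns length ``len(residuals)+1`` with H_0 at index 0; inverts the
    difference/drift decomposition exactly.
    """
    a = np.asarray(residuals, dtype=float)
    if not (np.isfinite(mu) and np.isfinite(h0) and np.all(np.isfinite(a))):
        raise NumericalError("non-finite inputs to reconstruction")
    t = np.arange(a.size + 1)
    cum = np.concatenate([[0.0], np.cumsum(a)])
    return mu * t + h0 + cum


def fit_random_walk(
    series,
    lags: int | None = None,
    variant: str = "ljung-box",
    per_percent: bool = False,
    log_scale: bool = False,
) -> RandomWalkFit:
    """Fit the drift model to a hazard-ratio series and test its residuals.

    ``series`` may be a :class:`HazardRatioSeries` or a plain 1-D array of
    ordered levels. Default lag count is ``min(10, n_diffs // 5)`` (at least
    1). A zero-variance residual sequence (pure drift) is surfaced as a
    :class:`~nodewalk.errors.NumericalError` from the ACF, not hidden.
    """
    if isinstance(series, HazardRatioSeries):
        H = series.hr
        cutoffs = series.cutoffs
    else:
        H = np.asarray(series, dtype=float)
        cutoffs = np.arange(H.size, dtype=float)
    if log_scale:
        H = np.log(H)
    if lags is None:
        lags = max(1, min(10, (H.size - 1) // 5))
    if H.size < lags + 3:
        raise NumericalError(
            f"series of length {H.size} too short for a {lags}-lag white-noise test"
        )
    d = difference_series(H)
    if per_percent:
        gaps = np.diff(cutoffs)
        if np.any(gaps <= 0):
            raise NumericalError("cutoffs must be strictly increasing for per-percent drift")
        d = d / gaps
    drift = estimate_drift(d, h0=H[0])
    # a (numerically) pure-drift series leaves no innovations to diagnose;
    # surface the degeneracy instead of testing rounding noise
    scale = max(float(np.max(np.abs(H))), abs(drift.mu))
    if np.sqrt(drift.sigma2) <= 1e-10 * scale:
        raise NumericalError(
            "residual variance is zero (pure drift): white-noise diagnostics undefined"
        )
    rho = acf(drift.residuals, lags)
    pm = portmanteau_test(drift.residuals, lags=lags, variant=variant)
    return RandomWalkFit(
        drift=drift,
        acf=rho,
        portmanteau=pm,
        per_percent=per_percent,
        log_scale=log_scale,
        cutoffs=cutoffs,
    )
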