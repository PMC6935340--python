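"""Cox proportional-hazards regression from first principles.

Implements the partial log-likelihood with Efron (default) or Breslow
corrections for tied event times, its analytic score and observed
information, and a Newton-Raphson maximiser with step-halving. The model has
no baseline-hazard estimate, stratification or time-varying effects: it is
exactly the adjusted proportional-hazards model the hazard-ratio sweep needs.

Notation. With subjects sorted by observed time, linear predictor
``eta_i = x_i . beta`` and weights ``w_i = exp(eta_i)``, each distinct event
time u with d tied events contributes (Efron)

    sum_{i in D(u)} eta_i - sum_{l=0}^{d-1} log( S0(u) - (l/d) s0(u) )

where S0 sums w over the risk set {t_i >= u} and s0 over the tied events
D(u); Breslow uses S0 alone. Score and information follow by differentiating
through the weighted sums S1, S2 (first and second moments of x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDesignError, NumericalError

__all__ = ["CoxFit", "HazardRatioCI", "partial_loglik", "fit_cox", "hazard_ratio_ci"]

#: |beta_j| beyond which the likelihood is treated as monotone (separation).
MONOTONE_BOUND = 15.0


@dataclass(frozen=True)
class CoxFit:
    """Result of one Newton-Raphson Cox fit."""

    beta: np.ndarray
    covariance: np.ndarray
    loglik: float
    loglik_null: float
    n_events: int
    converged: bool
    iterations: int
    monotone_flags: np.ndarray  # per-coefficient separation warnings

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


@dataclass(frozen=True)
class HazardRatioCI:
    """A hazard ratio with its Wald confidence bounds."""

    hr: float
    lo: float
    hi: float
    level: float


def _prepare(times, events, X):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = times.shape[0]
    if events.shape[0] != n or X.shape[0] != n:
        raise NumericalError("times, events and X must have matching lengths")
    if np.any(times <= 0):
        raise NumericalError("times must be positive")
    if not np.isin(events, (0, 1)).all():
        raise NumericalError("events must be 0/1")
    if int(events.sum()) == 0:
        raise NumericalError("no events: partial likelihood undefined")
    order = np.argsort(times, kind="stable")
    return times[order], events[order].astype(bool), X[order]


class _TieStructure:
    """Precomputed indexing for the event-time groups of one dataset.

    With subjects in ascending time order, events are contiguous per distinct
    event time; ``reduceat`` boundaries give the tied-event sums, and one
    elementary log-denominator term exists per event (Efron index l = 0..d-1
    within its group; Breslow zeroes the fractions).
    """

    def __init__(self, times: np.ndarray, events: np.ndarray, ties: str):
        if ties not in ("efron", "breslow"):
            raise NumericalError(f"unknown tie method {ties!r}")
        self.ev_idx = np.flatnonzero(events)
        ev_times = times[self.ev_idx]
        bnd = np.r_[0, np.flatnonzero(np.diff(ev_times) != 0) + 1]
        self.boundaries = bnd
        self.ngroups = bnd.size
        d = np.diff(np.r_[bnd, self.ev_idx.size])
        self.g_of_term = np.repeat(np.arange(self.ngroups), d)
        l = np.arange(self.ev_idx.size) - bnd[self.g_of_term]
        if ties == "efron":
            self.frac = l / d[self.g_of_term]
        else:
            self.frac = np.zeros(self.ev_idx.size)
        # with no tied event times (or Breslow) all fractions vanish and the
        # tied-event sums drop out of every formula
        self.has_ties = bool(self.frac.any())
        # first subject with t >= each group's event time (risk-set start)
        self.risk_start = np.searchsorted(times, ev_times[bnd], side="left")

    def group_sum(self, values: np.ndarray) -> np.ndarray:
        """Sum rows of ``values`` (indexed by subject) over tied-event groups."""
        ev_rows = values[self.ev_idx]
        flat = ev_rows.reshape(ev_rows.shape[0], -1)
        out = np.add.reduceat(flat, self.boundaries, axis=0)
        return out.reshape((self.ngroups,) + ev_rows.shape[1:])


def _suffix_at_groups(values: np.ndarray, risk_start: np.ndarray) -> np.ndarray:
    """Suffix sums of ``values`` evaluated at the risk-set start indices.

    Segment sums between consecutive risk-set boundaries (reduceat) followed
    by a reverse cumulative sum over groups; subjects before the first event
    time belong to no risk set and are never touched.
    """
    flat = values.reshape(values.shape[0], -1)
    seg = np.add.reduceat(flat, risk_start, axis=0)
    out = np.cumsum(seg[::-1], axis=0)[::-1]
    return out.reshape((risk_start.size,) + values.shape[1:])


def _cox_quantities(beta, X, ts: _TieStructure, want_derivs=True):
    """Partial log-likelihood and, optionally, score and observed information."""
    eta = X @ beta
    # guard against overflow during wild Newton trial steps
    w = np.exp(np.clip(eta, -500, 500))

    S0 = _suffix_at_groups(w, ts.risk_start)
    denom = S0[ts.g_of_term]
    if ts.has_ties:
        denom = denom - ts.frac * ts.group_sum(w)[ts.g_of_term]
    loglik = eta[ts.ev_idx].sum() - np.sum(np.log(denom))
    if not want_derivs:
        return loglik, None, None

    wX = w[:, None] * X
    S1 = _suffix_at_groups(wX, ts.risk_start)
    num1 = S1[ts.g_of_term]
    if ts.has_ties:
        num1 = num1 - ts.frac[:, None] * ts.group_sum(wX)[ts.g_of_term]
    z = num1 / denom[:, None]
    score = X[ts.ev_idx].sum(axis=0) - z.sum(axis=0)

    wXX = wX[:, :, None] * X[:, None, :]
    S2 = _suffix_at_groups(wXX, ts.risk_start)
    num2 = S2[ts.g_of_term]
    if ts.has_ties:
        num2 = num2 - ts.frac[:, None, None] * ts.group_sum(wXX)[ts.g_of_term]
    info = (num2 / denom[:, None, None]).sum(axis=0) - np.einsum("ij,ik->jk", z, z)
    return loglik, score, info


def partial_loglik(beta, times, events, X, ties: str = "efron") -> float:
    """Cox partial log-likelihood at ``beta`` (Efron or Breslow tie handling)."""
    times, events, X = _prepare(times, events, X)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    ts = _TieStructure(times, events, ties)
    ll, _, _ = _cox_quantities(beta, X, ts, want_derivs=False)
    return float(ll)


def fit_cox(
    times,
    events,
    X,
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 50,
    beta_init=None,
) -> CoxFit:
    """Maximise the partial likelihood by Newton-Raphson with step-halving.

    Convergence requires the score sup-norm to fall below ``tol``. Any
    coefficient wandering past :data:`MONOTONE_BOUND` marks a monotone
    (unbounded) likelihood; the fit stops and returns with the per-coefficient
    flags set rather than raising, so a caller sweeping many models can skip
    the degenerate ones.

    Raises
    ------
    DegenerateDesignError
        If a covariate column is constant (no contrast to estimate).
    NumericalError
        If there are no events or inputs are inconsistent.
    """
    times, events, X = _prepare(times, events, X)
    n, p = X.shape
    const = np.flatnonzero(np.ptp(X, axis=0) == 0)
    if const.size:
        raise DegenerateDesignError(
            f"covariate column(s) {const.tolist()} are constant across subjects"
        )

    ts = _TieStructure(times, events, ties)
    beta = np.zeros(p) if beta_init is None else np.asarray(beta_init, dtype=float).copy()
    ll, score, info = _cox_quantities(beta, X, ts)
    ll0 = ll if beta_init is None else _cox_quantities(
        np.zeros(p), X, ts, want_derivs=False
    )[0]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(score)) < tol:
            converged = True
            it -= 1
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # step-halving: reject genuine log-likelihood decreases, but allow
        # rounding-level wobble (|ll| can be ~1e4, so exact non-decrease is
        # not representable near the optimum)
        slack = 1e-10 * max(1.0, abs(ll))
        scale = 1.0
        for _ in range(30):
            trial = beta + scale * step
            ll_trial, _, _ = _cox_quantities(trial, X, ts, want_derivs=False)
            if ll_trial >= ll - slack:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll, score, info = _cox_quantities(beta, X, ts)
        if np.any(np.abs(beta) > MONOTONE_BOUND):
            break
    else:
        it = max_iter
    if not converged and np.max(np.abs(score)) < tol:
        converged = True

    flags = np.abs(beta) > MONOTONE_BOUND
    if converged and not flags.any():
        cov = np.linalg.inv(info)
        cov = (cov + cov.T) / 2.0
    else:
        cov = np.full((p, p), np.nan)
    return CoxFit(
        beta=beta,
        covariance=cov,
        loglik=float(ll),
        loglik_null=float(ll0),
        n_events=int(events.sum()),
        converged=bool(converged and not flags.any()),
        iterations=it,
        monotone_flags=flags,
    )


def hazard_ratio_ci(fit: CoxFit, j: int = 0, level: float = 0.95) -> HazardRatioCI:
    """Wald confidence interval for ``exp(beta_j)`` on the log scale."""
    if not fit.converged:
        raise NumericalError("hazard ratio CI requires a converged fit")
    if not 0 <= j < fit.beta.size:
        raise NumericalError(f"coefficient index {j} out of range")
    if not 0.0 < level < 1.0:
        raise NumericalError(f"level must be in (0,1), got {level}")
    b = fit.beta[j]
    se = fit.se[j]
    z = stats.norm.ppf(0.5 + level / 2.0)
    return HazardRatioCI(
        hr=float(np.exp(b)),
        lo=float(np.exp(b - z * se)),
        hi=float(np.exp(b + z * se)),
        level=level,
    )
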