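"""Proportional-hazards partial-likelihood solver.

Implements the Cox model by direct Newton–Raphson maximisation of the
partial likelihood, with Breslow's approximation for tied event times
(Efron available via ``ties="efron"``) and optional stratification: the
log partial likelihood, gradient and information are computed within each
stratum and summed, so each stratum keeps its own baseline hazard.

Standard errors come from the observed information at the maximum; the
per-covariate Wald statistic is beta / se and its two-sided p-value uses
the standard normal reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CoxModelResult", "fit_cox", "cox_loglik"]

#: |beta| beyond which a fit is treated as monotone likelihood (perfect
#: or near-perfect separation of event order by the covariate).  On the
#: log-hazard-per-expression-unit scale anything beyond this is not a
#: believable finite effect.
MONOTONE_BOUND = 10.0


@dataclass
class CoxModelResult:
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    flagged: bool  # monotone likelihood or singular information
    n: int
    n_events: int

    @property
    def wald(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def p_values(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.wald))

    def ci(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        z = stats.norm.ppf(0.5 + level / 2.0)
        return self.beta - z * self.se, self.beta + z * self.se


def _stratum_quantities(beta, X, time, event, ties):
    """(loglik, gradient, information) for one stratum.

    Samples are sorted by descending time so the risk set at each event
    time is a prefix; tied times share one risk set (handled by grouping).
    """
    order = np.argsort(-time, kind="stable")
    X = X[order]
    time = time[order]
    event = event[order].astype(bool)
    n, p = X.shape

    eta = X @ beta
    eta = np.clip(eta, -700, 700)  # overflow guard; bound check flags these fits
    w = np.exp(eta)
    wX = w[:, None] * X
    # cumulative risk-set sums in descending-time order
    cs0 = np.cumsum(w)
    cs1 = np.cumsum(wX, axis=0)
    cs2 = np.cumsum(w[:, None, None] * (X[:, :, None] * X[:, None, :]), axis=0)

    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))

    # walk unique times; risk set = everything up to the last tied index
    i = 0
    while i < n:
        j = i
        while j + 1 < n and time[j + 1] == time[i]:
            j += 1
        deaths = np.nonzero(event[i : j + 1])[0] + i
        d = len(deaths)
        if d > 0:
            s0, s1, s2 = cs0[j], cs1[j], cs2[j]
            xsum = X[deaths].sum(axis=0)
            if ties == "breslow" or d == 1:
                loglik += eta[deaths].sum() - d * np.log(s0)
                mu = s1 / s0
                grad += xsum - d * mu
                info += d * (s2 / s0 - np.outer(mu, mu))
            elif ties == "efron":
                wd = w[deaths].sum()
                wd1 = wX[deaths].sum(axis=0)
                wd2 = (w[deaths, None, None] * (X[deaths, :, None] * X[deaths, None, :])).sum(axis=0)
                loglik += eta[deaths].sum()
                for ell in range(d):
                    f = ell / d
                    a0 = s0 - f * wd
                    a1 = s1 - f * wd1
                    a2 = s2 - f * wd2
                    loglik -= np.log(a0)
                    mu = a1 / a0
                    grad_term = mu
                    grad -= grad_term
                    info += a2 / a0 - np.outer(mu, mu)
                grad += xsum
            else:
                raise ValueError(f"unknown ties method {ties!r}")
        i = j + 1
    return loglik, grad, info


def cox_loglik(beta, X, time, event, strata=None, ties="breslow") -> float:
    """Log partial likelihood at ``beta`` (used by grid-search oracles)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    ll, _, _ = _quantities(beta, *_prepare(X, time, event, strata), ties)
    return ll


def _prepare(X, time, event, strata):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if strata is None:
        strata = np.zeros(len(time), dtype=int)
    else:
        _, strata = np.unique(np.asarray(strata), return_inverse=True)
    if not (len(X) == len(time) == len(event) == len(strata)):
        raise ValueError("X, time, event, strata must have equal length")
    return X, time, event, strata


def _quantities(beta, X, time, event, strata, ties):
    ll = 0.0
    grad = np.zeros(X.shape[1])
    info = np.zeros((X.shape[1], X.shape[1]))
    for s in np.unique(strata):
        m = strata == s
        l, g, i = _stratum_quantities(beta, X[m], time[m], event[m], ties)
        ll += l
        grad += g
        info += i
    return ll, grad, info


def fit_cox(
    X,
    time,
    event,
    strata=None,
    ties: str = "breslow",
    max_iter: int = 60,
    tol: float = 1e-10,
) -> CoxModelResult:
    """Fit the proportional-hazards model by Newton's method.

    Parameters
    ----------
    X : (n,) or (n, p) array
        Covariates; must not be constant within the fit.
    time, event : (n,) arrays
        Follow-up time (years) and event indicator {0, 1}.
    strata : optional (n,) array
        Stratum labels; partial likelihood is computed within strata and
        summed.
    ties : {"breslow", "efron"}
    """
    X, time, event, strata = _prepare(X, time, event, strata)
    n, p = X.shape
    n_events = int(np.sum(event == 1))
    if n_events < 2:
        raise ValueError(f"need >=2 events, got {n_events}")
    if np.any(np.nanstd(X, axis=0) == 0):
        raise ValueError("degenerate covariate (constant within cohort)")
    if not np.isfinite(X).all():
        raise ValueError("covariates must be finite")

    # covariate centring improves conditioning; beta is unaffected
    center = X.mean(axis=0)
    Xc = X - center

    beta = np.zeros(p)
    ll, grad, info = _quantities(beta, Xc, time, event, strata, ties)
    converged = False
    flagged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            flagged = True
            break
        # step-halving to guarantee ascent
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, grad_new, info_new = _quantities(cand, Xc, time, event, strata, ties)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if np.abs(grad).max() < tol * max(1.0, abs(ll)) or np.abs(factor * step).max() < 1e-12:
            converged = True
            break

    if np.abs(beta).max() > MONOTONE_BOUND:
        flagged = True

    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
        if not np.isfinite(se).all() or (se <= 0).any():
            flagged = True
            se = np.where(np.isfinite(se) & (se > 0), se, np.inf)
    except np.linalg.LinAlgError:
        flagged = True
        se = np.full(p, np.inf)

    return CoxModelResult(
        beta=beta,
        se=se,
        loglik=float(ll),
        converged=converged,
        flagged=flagged,
        n=n,
        n_events=n_events,
    )
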