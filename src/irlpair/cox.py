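"""Cox proportional-hazards primitives used by the signature stages.

`fit_univariate_many` fits one single-covariate Cox model per column of a
covariate matrix by Newton maximization of the Efron partial likelihood,
vectorized across covariates — fast enough to screen every candidate pair
in one call.  `breslow_loglik` evaluates the unpenalized Breslow partial
log-likelihood at a fixed coefficient vector; the lasso stage uses it to
score held-out folds on the same tie convention as the coordinate-descent
solver it wraps.

Multivariate refits elsewhere in the package go through lifelines (also
Efron); the screen here is deliberately self-contained so its estimates can
be cross-checked against lifelines in the test suite.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

_MAX_ABS_BETA = 15.0  # beyond this the partial likelihood is flat: separation


def _sorted_survival(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    order = np.argsort(time, kind="mergesort")
    return time[order], event[order], order


def _event_groups(t_sorted: np.ndarray, e_sorted: np.ndarray):
    """(risk-set start index, indices of tied deaths) per distinct event time."""
    groups = []
    n = len(t_sorted)
    i = 0
    while i < n:
        j = i
        while j < n and t_sorted[j] == t_sorted[i]:
            j += 1
        deaths = np.arange(i, j)[e_sorted[i:j]]
        if len(deaths):
            groups.append((i, deaths))
        i = j
    return groups


def efron_loglik_grad_hess(beta: np.ndarray, X_sorted: np.ndarray, groups):
    """Efron partial log-likelihood, gradient and Hessian per covariate.

    All inputs are in time-sorted order; `beta` has one entry per column of
    `X_sorted`.  Returns (ll, grad, hess) arrays of shape (P,).
    """
    eta = X_sorted * beta  # (n, P)
    # guard overflow: eta bounded by |beta| * max|x|; indicators keep it tame
    w = np.exp(eta)
    wx = w * X_sorted
    wxx = wx * X_sorted
    # suffix sums: S*_R at row i sums rows i..n-1 (risk set of the i-th time)
    c0 = np.cumsum(w[::-1], axis=0)[::-1]
    c1 = np.cumsum(wx[::-1], axis=0)[::-1]
    c2 = np.cumsum(wxx[::-1], axis=0)[::-1]
    P = X_sorted.shape[1]
    ll = np.zeros(P)
    grad = np.zeros(P)
    hess = np.zeros(P)
    for start, deaths in groups:
        d = len(deaths)
        s0r, s1r, s2r = c0[start], c1[start], c2[start]
        ll += eta[deaths].sum(axis=0)
        grad += X_sorted[deaths].sum(axis=0)
        if d == 1:
            phi0, phi1, phi2 = s0r, s1r, s2r
            ll -= np.log(phi0)
            grad -= phi1 / phi0
            hess -= phi2 / phi0 - (phi1 / phi0) ** 2
        else:
            s0d = w[deaths].sum(axis=0)
            s1d = wx[deaths].sum(axis=0)
            s2d = wxx[deaths].sum(axis=0)
            for l in range(d):
                f = l / d
                phi0 = s0r - f * s0d
                phi1 = s1r - f * s1d
                phi2 = s2r - f * s2d
                ll -= np.log(phi0)
                grad -= phi1 / phi0
                hess -= phi2 / phi0 - (phi1 / phi0) ** 2
    return ll, grad, hess


def fit_univariate_many(X: pd.DataFrame, time, event, tol: float = 1e-9,
                        max_iter: int = 60) -> pd.DataFrame:
    """One single-covariate Cox fit per column, Efron ties, Newton updates.

    Returns a frame indexed by column with ``beta``, ``se``, ``hr``,
    ``hr_lower``, ``hr_upper`` (95% Wald), ``z``, ``p`` and ``converged``.
    Constant columns and fits drifting to separation are flagged
    ``converged=False`` with NaN estimates (callers drop them, loudly).
    """
    t_sorted, e_sorted, order = _sorted_survival(time, event)
    Xs = X.to_numpy(dtype=float)[order]
    groups = _event_groups(t_sorted, e_sorted)
    if not groups:
        raise ValueError("no observed events; cannot fit Cox models")
    P = Xs.shape[1]
    beta = np.zeros(P)
    active = np.ptp(Xs, axis=0) > 0
    n_const = int((~active).sum())
    if n_const:
        log.warning("%d constant covariates skipped in uni-Cox screen", n_const)
    converged = np.zeros(P, dtype=bool)
    for _ in range(max_iter):
        idx = active & ~converged
        if not idx.any():
            break
        ll, grad, hess = efron_loglik_grad_hess(beta[idx], Xs[:, idx], groups)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(hess < 0, grad / -hess, 0.0)
        step = np.clip(step, -2.0, 2.0)  # damp early overshoot
        newb = beta[idx] + step
        moved = np.zeros(P)
        moved[idx] = newb
        done = np.zeros(P, dtype=bool)
        done[idx] = np.abs(step) < tol
        beta[idx] = newb
        converged |= done
        # separation: likelihood keeps improving as |beta| grows
        sep = np.abs(beta) > _MAX_ABS_BETA
        active &= ~sep
    diverged = active & ~converged
    if diverged.any():
        log.warning("%d uni-Cox fits did not converge", int(diverged.sum()))
    ok = converged.copy()
    _, _, hess = efron_loglik_grad_hess(beta, Xs, groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(-1.0 / hess)
    beta_out = np.where(ok, beta, np.nan)
    se = np.where(ok, se, np.nan)
    z = beta_out / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    halfwidth = 1.959963984540054 * se
    out = pd.DataFrame({
        "beta": beta_out,
        "se": se,
        "hr": np.exp(beta_out),
        "hr_lower": np.exp(beta_out - halfwidth),
        "hr_upper": np.exp(beta_out + halfwidth),
        "z": z,
        "p": p,
        "converged": ok,
    }, index=X.columns)
    return out


def breslow_loglik(beta: np.ndarray, X: np.ndarray, time, event) -> float:
    """Unpenalized Breslow partial log-likelihood at a fixed beta."""
    t_sorted, e_sorted, order = _sorted_survival(time, event)
    eta = (np.asarray(X, dtype=float) @ np.asarray(beta, dtype=float))[order]
    shift = eta.max() if len(eta) else 0.0
    w = np.exp(eta - shift)
    c0 = np.cumsum(w[::-1])[::-1]
    ll = 0.0
    for start, deaths in _event_groups(t_sorted, e_sorted):
        # Breslow: every tied death shares the full risk-set denominator
        ll += eta[deaths].sum() - len(deaths) * (np.log(c0[start]) + shift)
    return float(ll)
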