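"""Newton–Raphson Cox proportional-hazards solver (Efron tie handling).

The gene-selection stage fits one small multivariate Cox model per gene
per cross-validation fold — hundreds of thousands of fits per study — so
the partial-likelihood maximization is implemented here as a compact
Newton solver and JIT-compiled with numba. lifelines is used elsewhere in
the package for one-off multivariate fits; the two routes are
cross-checked against each other (and against brute-force likelihood
maximization) in the test suite.

With no tied event times Efron's and Breslow's likelihoods coincide; the
simulator produces continuous times, so ties only arise in constructed
fixtures, which the Efron path handles exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

MAX_ABS_BETA = 40.0  # larger estimates are treated as separation / divergence


@njit(cache=True)
def _loglik_grad_hess(X, evt, grp_start, grp_end, beta, want_derivs):
    """Efron partial log-likelihood (+ gradient, information) at ``beta``.

    Rows of ``X`` must be sorted by ascending time; ``grp_start[k]:grp_end[k]``
    delimit the k-th tied-time group. Returns (loglik, grad, info).
    """
    n, p = X.shape
    lp = X @ beta
    w = np.exp(lp)
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    for k in range(len(grp_start) - 1, -1, -1):
        a, b = grp_start[k], grp_end[k]
        d = 0
        s0t = 0.0
        s1t = np.zeros(p)
        s2t = np.zeros((p, p))
        for i in range(a, b):
            wi = w[i]
            S0 += wi
            for r in range(p):
                S1[r] += wi * X[i, r]
                for c in range(p):
                    S2[r, c] += wi * X[i, r] * X[i, c]
            if evt[i]:
                d += 1
                ll += lp[i]
                s0t += wi
                for r in range(p):
                    grad[r] += X[i, r]
                    s1t[r] += wi * X[i, r]
                    for c in range(p):
                        s2t[r, c] += wi * X[i, r] * X[i, c]
        for l in range(d):
            phi = l / d
            den = S0 - phi * s0t
            ll -= np.log(den)
            if want_derivs:
                for r in range(p):
                    v1r = S1[r] - phi * s1t[r]
                    grad[r] -= v1r / den
                    for c in range(p):
                        v2 = S2[r, c] - phi * s2t[r, c]
                        v1c = S1[c] - phi * s1t[c]
                        info[r, c] += v2 / den - (v1r * v1c) / (den * den)
    return ll, grad, info


@njit(cache=True)
def _newton(X, evt, grp_start, grp_end, max_iter, tol):
    """Damped Newton maximization. Returns (beta, var_diag, converged).

    A coefficient with monotone partial likelihood (separation) never
    meets the step-size criterion, but the log-likelihood plateaus; the
    plateau is accepted as converged so that the *other* coefficients
    (e.g. the gene term in a per-gene model whose nuisance covariate
    separates) keep valid estimates and standard errors. Divergence of
    every coefficient past ``MAX_ABS_BETA`` aborts as non-converged.
    """
    n, p = X.shape
    beta = np.zeros(p)
    ll, grad, info = _loglik_grad_hess(X, evt, grp_start, grp_end, beta, True)
    converged = False
    improvement = 0.0
    for _ in range(max_iter):
        for r in range(p):  # tiny ridge guards near-singular information
            info[r, r] += 1e-10
        delta = np.linalg.solve(info, grad)
        step = 1.0
        accepted = False
        for _h in range(30):
            cand = beta + step * delta
            ll_new, g_new, i_new = _loglik_grad_hess(
                X, evt, grp_start, grp_end, cand, True
            )
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                improvement = ll_new - ll
                beta = cand
                ll, grad, info = ll_new, g_new, i_new
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        if np.max(np.abs(step * delta)) < tol or improvement < 1e-10:
            converged = True
            break
        if np.max(np.abs(beta)) > 5.0 * MAX_ABS_BETA:
            break
    var = np.full(p, np.nan)
    if converged:
        for r in range(p):
            info[r, r] += 1e-10
        cov = np.linalg.inv(info)
        for r in range(p):
            var[r] = cov[r, r]
    return beta, var, converged


@njit(cache=True)
def _newton_per_gene(genes, Z, evt, grp_start, grp_end, max_iter, tol):
    """Fit gene + shared covariates for every gene row of ``genes``.

    genes: (G, n) matrix (already sorted to match Z's row order).
    Returns (beta_gene, se_gene, converged) arrays of length G.
    """
    G, n = genes.shape
    q = Z.shape[1]
    p = q + 1
    beta_out = np.full(G, np.nan)
    se_out = np.full(G, np.nan)
    conv = np.zeros(G, dtype=np.bool_)
    X = np.empty((n, p))
    for j in range(n):
        for c in range(q):
            X[j, 1 + c] = Z[j, c]
    for g in range(G):
        m = 0.0
        for j in range(n):
            m += genes[g, j]
        m /= n
        v = 0.0
        for j in range(n):
            v += (genes[g, j] - m) ** 2
        if v <= 0.0:
            continue  # zero-variance gene: flagged non-convergent
        for j in range(n):
            X[j, 0] = genes[g, j]
        beta, var, ok = _newton(X, evt, grp_start, grp_end, max_iter, tol)
        # the gene term itself must be bounded and estimable; a separated
        # nuisance covariate does not disqualify the gene
        if ok and np.isfinite(var[0]) and var[0] > 0 and abs(beta[0]) <= MAX_ABS_BETA:
            beta_out[g] = beta[0]
            se_out[g] = np.sqrt(var[0])
            conv[g] = True
    return beta_out, se_out, conv


@dataclass
class CoxFit:
    """Result of a single Cox partial-likelihood fit."""

    coef: np.ndarray
    se: np.ndarray
    p: np.ndarray
    loglik: float
    converged: bool
    names: list


def _sort_and_group(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    order = np.argsort(time, kind="stable")
    t = time[order]
    # tied-time group boundaries
    starts = [0]
    for i in range(1, len(t)):
        if t[i] != t[i - 1]:
            starts.append(i)
    grp_start = np.array(starts, dtype=np.int64)
    grp_end = np.append(grp_start[1:], len(t)).astype(np.int64)
    return order, grp_start, grp_end


def cox_fit(X, time, event, names=None, max_iter=60, tol=1e-9) -> CoxFit:
    """Fit a Cox proportional-hazards model by Efron partial likelihood.

    Parameters
    ----------
    X : (n, p) array-like of covariates.
    time, event : survival time and 0/1 event indicator per row.

    Raises
    ------
    LungsigError if there are no events.
    """
    from .containers import LungsigError

    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    event = np.asarray(event).astype(np.bool_)
    if not event.any():
        raise LungsigError("Cox fit requires at least one event")
    order, gs, ge = _sort_and_group(time, event)
    Xs = np.ascontiguousarray(X[order])
    es = event[order]
    beta, var, ok = _newton(Xs, es, gs, ge, max_iter, tol)
    ll, _, _ = _loglik_grad_hess(Xs, es, gs, ge, beta, False)
    se = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    return CoxFit(coef=beta, se=se, p=p, loglik=float(ll), converged=bool(ok), names=list(names))


def cox_fit_per_gene(genes, Z, time, event, max_iter=60, tol=1e-8):
    """Per-gene Cox fits: each model is [gene, covariates in Z] jointly.

    Parameters
    ----------
    genes : (G, n) array, one row per gene.
    Z : (n, q) shared covariate matrix (q may be 0).

    Returns
    -------
    coef, p, converged : arrays of length G. Non-convergent or
    zero-variance genes have ``converged=False`` and NaN coef/p.
    """
    from .containers import LungsigError

    genes = np.ascontiguousarray(np.asarray(genes, dtype=float))
    Z = np.ascontiguousarray(np.asarray(Z, dtype=float).reshape(genes.shape[1], -1))
    event = np.asarray(event).astype(np.bool_)
    if not event.any():
        raise LungsigError("Cox fit requires at least one event")
    order, gs, ge = _sort_and_group(time, event)
    beta, se, conv = _newton_per_gene(
        genes[:, order], Z[order], event[order], gs, ge, max_iter, tol
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[~conv] = np.nan
    return beta, p, conv
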