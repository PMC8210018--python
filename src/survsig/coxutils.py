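"""Cox partial-likelihood primitives shared by the regression machinery.

The Breslow approximation is used for tied event times throughout; survival
times from the synthetic generator are continuous, so ties only arise in
user data, where Breslow and Efron differ negligibly at the tie densities
seen in expression cohorts.
"""

from __future__ import annotations

import numpy as np


class CoxFitError(RuntimeError):
    """A partial-likelihood fit failed to converge or was degenerate."""


def _risk_order(time: np.ndarray):
    """Sort descending by time; tied times share one risk-set boundary."""
    order = np.argsort(-time, kind="stable")
    ts = time[order]
    # last index (in descending order) whose time equals ts[i]: the risk set
    # for an event at ts[i] is rows 0..boundary[i]
    boundary = np.searchsorted(-ts, -ts, side="right") - 1
    return order, boundary


def breslow_loglik(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                   beta: np.ndarray) -> np.ndarray | float:
    """Breslow partial log-likelihood.

    ``beta`` may be a vector (p,) or a matrix (p, L) of L coefficient
    vectors evaluated simultaneously (one pass over the risk sets).
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    beta = np.asarray(beta, dtype=float)
    single = beta.ndim == 1
    B = beta[:, None] if single else beta

    order, boundary = _risk_order(time)
    Xs = X[order]
    ev = event[order]
    eta = Xs @ B                              # (n, L)
    # numerically stable log of cumulative sums of exp(eta) down the risk sets
    shift = eta.max(axis=0, keepdims=True)
    cum = np.cumsum(np.exp(eta - shift), axis=0)
    log_denom = np.log(cum[boundary]) + shift  # (n, L)
    ll = (eta[ev] - log_denom[ev]).sum(axis=0)
    return float(ll[0]) if single else ll


def breslow_gradient_hessian(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                             beta: np.ndarray):
    """(loglik, gradient, hessian-of-loglik) for the Breslow partial likelihood."""
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    n, p = X.shape

    order, boundary = _risk_order(time)
    Xs = X[order]
    ev = event[order]
    eta = Xs @ beta
    shift = eta.max()
    w = np.exp(eta - shift)
    S0 = np.cumsum(w)[boundary]                               # (n,)
    S1 = np.cumsum(w[:, None] * Xs, axis=0)[boundary]         # (n, p)
    S2 = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]),
                   axis=0)[boundary]                          # (n, p, p)

    ll = float((eta[ev] - (np.log(S0[ev]) + shift)).sum())
    m = S1[ev] / S0[ev, None]                                 # (d, p)
    grad = (Xs[ev] - m).sum(axis=0)
    hess = -(S2[ev] / S0[ev, None, None] - m[:, :, None] * m[:, None, :]).sum(axis=0)
    return ll, grad, hess


def newton_cox(X: np.ndarray, time: np.ndarray, event: np.ndarray,
               ridge: float = 0.0, beta0: np.ndarray | None = None,
               tol: float = 1e-9, max_iter: int = 50) -> np.ndarray:
    """Newton–Raphson maximizer of the (optionally L2-penalized) partial likelihood.

    The objective is loglik(beta) - ridge/2 * n * ||beta||^2, i.e. ``ridge``
    is on the same per-observation scale as the LASSO penalty weight.
    ``ridge = 0`` gives the ordinary unpenalized Cox fit.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not np.asarray(event, dtype=bool).any():
        raise CoxFitError("no events: partial likelihood is flat")
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()

    def objective(b):
        return breslow_loglik(X, time, event, b) - 0.5 * ridge * n * float(b @ b)

    obj = objective(beta)
    for _ in range(max_iter):
        ll, grad, hess = breslow_gradient_hessian(X, time, event, beta)
        grad = grad - ridge * n * beta
        hess = hess - ridge * n * np.eye(p)
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise CoxFitError(f"singular information matrix: {exc}") from exc
        if not np.isfinite(step).all():
            raise CoxFitError("non-finite Newton step")
        # step-halving line search
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            cand_obj = objective(cand)
            if np.isfinite(cand_obj) and cand_obj >= obj - 1e-12:
                break
            scale /= 2.0
        else:
            raise CoxFitError("line search failed")
        beta = beta + scale * step
        improved = cand_obj - obj
        obj = cand_obj
        if np.max(np.abs(grad)) < tol or (0 <= improved < tol):
            if np.max(np.abs(beta)) > 50:
                raise CoxFitError("diverging coefficients (likely separation)")
            return beta
    raise CoxFitError("Newton-Raphson did not converge")


def ridge_cox_path(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                   lams: np.ndarray) -> np.ndarray:
    """Warm-started ridge Cox fits along a penalty grid.

    Returns coefficients with shape (p, len(lams)); ``lams`` should be
    ordered from strongest to weakest penalty for effective warm starts.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    out = np.empty((p, len(lams)))
    beta = np.zeros(p)
    for k, lam in enumerate(lams):
        beta = newton_cox(X, time, event, ridge=float(lam), beta0=beta)
        out[:, k] = beta
    return out


def stratified_event_folds(event: np.ndarray, n_folds: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Fold labels balancing events and censored samples across folds.

    Small event counts make plain random folds unstable for partial
    likelihood cross-validation; dealing each status round-robin after an
    independent shuffle keeps every fold populated with events.
    """
    event = np.asarray(event, dtype=bool)
    n = len(event)
    folds = np.empty(n, dtype=int)
    for mask in (event, ~event):
        idx = np.flatnonzero(mask)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % n_folds
    return folds
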