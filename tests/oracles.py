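"""Independent brute-force oracles used to check the package's survival math.

Everything here is deliberately written from the textbook definitions with
plain Python loops — no shared code with the package and no vectorized
shortcuts — so agreement with the package is a genuine two-route check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def two_pass_variance(x) -> float:
    """Sample variance (ddof=1) via the explicit two-pass formula."""
    x = list(map(float, x))
    n = len(x)
    mean = sum(x) / n
    return sum((v - mean) ** 2 for v in x) / (n - 1)


def cox_neg_loglik(beta, X, time, event):
    """Negative Breslow partial log-likelihood by explicit risk-set loops."""
    beta = np.asarray(beta, dtype=float)
    n = len(time)
    ll = 0.0
    for i in range(n):
        if not event[i]:
            continue
        eta_i = float(X[i] @ beta)
        denom = 0.0
        for j in range(n):
            if time[j] >= time[i]:
                denom += np.exp(float(X[j] @ beta))
        ll += eta_i - np.log(denom)
    return -ll


def cox_fit_bruteforce(X, time, event) -> np.ndarray:
    """Unpenalized Cox coefficients by numerical optimization of the
    loop-written partial likelihood.

    Columns are rescaled internally for optimizer conditioning; the result
    is mapped back, so the returned coefficients are on the input scale.
    """
    X = np.asarray(X, dtype=float)
    scale = X.std(axis=0, ddof=1)
    Z = X / scale
    res = minimize(cox_neg_loglik, np.zeros(X.shape[1]),
                   args=(Z, np.asarray(time, float), np.asarray(event, bool)),
                   method="BFGS", options={"gtol": 1e-9, "maxiter": 500})
    assert res.success or np.max(np.abs(res.jac)) < 1e-5, res.message
    return res.x / scale


def km_bruteforce(time, event):
    """Product-limit estimate by direct multiplication over event times.

    Returns (times, survival) at the distinct event times, plus the median
    (smallest time with S <= 0.5, or None).
    """
    time = list(map(float, time))
    event = list(map(int, event))
    distinct = sorted({t for t, e in zip(time, event) if e == 1})
    s = 1.0
    times, survival = [], []
    for t in distinct:
        n_risk = sum(1 for tj in time if tj >= t)
        d = sum(1 for tj, ej in zip(time, event) if tj == t and ej == 1)
        s *= (n_risk - d) / n_risk
        times.append(t)
        survival.append(s)
    median = None
    for t, s_t in zip(times, survival):
        if s_t <= 0.5:
            median = t
            break
    return np.array(times), np.array(survival), median


def logrank_bruteforce(time1, event1, time2, event2):
    """Unweighted two-group log-rank chi-square by hand arithmetic."""
    t1 = list(map(float, time1)); e1 = list(map(int, event1))
    t2 = list(map(float, time2)); e2 = list(map(int, event2))
    all_times = sorted({t for t, e in zip(t1 + t2, e1 + e2) if e == 1})
    O_minus_E = 0.0
    V = 0.0
    for t in all_times:
        n1 = sum(1 for tj in t1 if tj >= t)
        n2 = sum(1 for tj in t2 if tj >= t)
        d1 = sum(1 for tj, ej in zip(t1, e1) if tj == t and ej == 1)
        d2 = sum(1 for tj, ej in zip(t2, e2) if tj == t and ej == 1)
        n = n1 + n2
        d = d1 + d2
        if n < 2:
            continue
        expected1 = d * n1 / n
        O_minus_E += d1 - expected1
        V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1) if n > 1 else 0.0
    return O_minus_E ** 2 / V


def youden_best_cutoff(scores, outcome):
    """Exhaustive mid-point threshold scan maximizing J = sens + spec - 1."""
    scores = list(map(float, scores))
    outcome = list(map(int, outcome))
    uniq = sorted(set(scores))
    best_j, best_c = -np.inf, None
    for a, b in zip(uniq[:-1], uniq[1:]):
        c = (a + b) / 2
        tp = sum(1 for s, o in zip(scores, outcome) if s > c and o == 1)
        fn = sum(1 for s, o in zip(scores, outcome) if s <= c and o == 1)
        tn = sum(1 for s, o in zip(scores, outcome) if s <= c and o == 0)
        fp = sum(1 for s, o in zip(scores, outcome) if s > c and o == 0)
        j = tp / (tp + fn) + tn / (tn + fp) - 1
        if j > best_j:
            best_j, best_c = j, c
    return best_c, best_j
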