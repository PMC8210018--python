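"""Bootstrap-resampled LASSO Cox regression (signature identification).

The core idea: rather than one penalized fit over all N features — fragile
under high dimensionality and collinearity — draw B random groups of G
features, vet each group for internal collinearity, fit a 10-fold
cross-validated LASSO Cox model per group, and aggregate each feature's
fitted coefficients across the iterations in which it was sampled.

With uniform sampling the number of times a feature enters the analysis is
Binomial(B, G/N), with expectation

    f = B * G / N

so a target per-feature coverage f is reached by choosing the iteration
count B = f * N / G; coverage f = N/G (i.e. B = (N/G)^2) gives every
feature a stable aggregate without inflating runtime.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .coxutils import CoxFitError, breslow_loglik, newton_cox, ridge_cox_path, \
    stratified_event_folds
from .io import ExpressionMatrix, Signature, SurvivalTable, align

logger = logging.getLogger("survsig")

MAX_GROUP_RETRIES = 100


@dataclass(frozen=True)
class BootstrapPlan:
    """Sampling design of one bootstrap regression run."""

    N: int                  # total feature count entering the bootstrap
    G: int                  # features per iteration
    B: int                  # iterations
    P: float = 0.3          # tolerated fraction of correlated pairs per group
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 < self.G <= self.N:
            raise ValueError(f"need 1 < G <= N, got G={self.G}, N={self.N}")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0 <= self.P <= 1:
            raise ValueError("P must lie in [0, 1]")

    @property
    def expected_frequency(self) -> float:
        """Expected per-feature sampling count f = B*G/N."""
        return self.B * self.G / self.N


def plan_bootstrap(N: int, G: int, B: int | None = None,
                   P: float = 0.3, seed: int = 0) -> BootstrapPlan:
    """Build a sampling plan; when B is omitted, B = ceil((N/G)^2).

    That default targets an expected per-feature coverage of N/G draws.
    """
    if G > N:
        raise ValueError(f"group size G={G} exceeds feature count N={N}")
    if B is None:
        B = math.ceil((N / G) ** 2)
    plan = BootstrapPlan(N=N, G=G, B=B, P=P, seed=seed)
    logger.info(
        "bootstrap plan: N=%d G=%d B=%d, expected per-feature frequency %.1f",
        plan.N, plan.G, plan.B, plan.expected_frequency,
    )
    return plan


def _iteration_rng(plan: BootstrapPlan, iteration: int) -> np.random.Generator:
    # counter-based stream: reproducible and independent per iteration
    return np.random.default_rng([plan.seed, iteration])


def sample_group(plan: BootstrapPlan, iteration: int, features,
                 flagged_pairs: set | None = None,
                 rng: np.random.Generator | None = None) -> list | None:
    """Draw G distinct features uniformly; redraw while too collinear.

    A draw is rejected when the fraction of its C(G,2) pairs flagged as
    correlated exceeds the plan's tolerance P.  Returns ``None`` when the
    retry bound is exhausted (the iteration is then skipped).
    """
    features = list(features)
    if len(features) != plan.N:
        raise ValueError(f"plan expects {plan.N} features, got {len(features)}")
    rng = rng or _iteration_rng(plan, iteration)
    flagged_pairs = flagged_pairs or set()
    n_pairs = plan.G * (plan.G - 1) // 2
    for _ in range(MAX_GROUP_RETRIES):
        idx = rng.choice(plan.N, size=plan.G, replace=False)
        group = [features[i] for i in idx]
        if not flagged_pairs:
            return group
        n_flagged = sum(
            1 for a in range(plan.G) for b in range(a + 1, plan.G)
            if frozenset((group[a], group[b])) in flagged_pairs
        )
        if n_flagged / n_pairs <= plan.P:
            return group
    logger.warning("iteration %d: correlated-group retry bound exhausted; skipping",
                   iteration)
    return None


@dataclass(frozen=True)
class LassoFit:
    """One per-iteration penalized Cox fit (coefficients on the input scale)."""

    features: list
    lam: float
    coefficients: np.ndarray
    cv_folds: int = 10

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.features):
            raise ValueError("coefficient/feature length mismatch")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")


def _lambda_grid(Xs, y, n_lambdas: int, lambda_min_ratio: float) -> np.ndarray:
    """Geometric penalty grid anchored at the smallest all-zero lambda."""
    path = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=n_lambdas, alpha_min_ratio=lambda_min_ratio,
        fit_baseline_model=False,
    )
    path.fit(Xs, y)
    return np.asarray(path.alphas_)


def _l1_path(Xs, y, lams) -> np.ndarray:
    est = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=list(lams),
                                 fit_baseline_model=False)
    with warnings.catch_warnings():
        # the strongest grid point is all-zero by construction
        warnings.simplefilter("ignore", UserWarning)
        est.fit(Xs, y)
    coefs = np.asarray(est.coef_)
    fitted = np.asarray(est.alphas_)
    if len(fitted) != len(lams):
        # coxnet may drop degenerate path points; align by value
        full = np.zeros((Xs.shape[1], len(lams)))
        pos = {round(float(a), 12): k for k, a in enumerate(fitted)}
        for k, lam in enumerate(lams):
            j = pos.get(round(float(lam), 12))
            if j is not None:
                full[:, k] = coefs[:, j]
        coefs = full
    return coefs


def fit_lasso_cox(expr: ExpressionMatrix, surv: SurvivalTable,
                  penalty: str = "l1", lam: float | None = None,
                  n_lambdas: int = 50, lambda_min_ratio: float = 1e-3,
                  cv_folds: int = 10,
                  rng: np.random.Generator | None = None) -> LassoFit:
    """Cross-validated penalized Cox fit on one feature group.

    Features are standardized internally (the L1 penalty is scale
    sensitive); coefficients are mapped back to the input expression scale.
    The penalty weight is chosen by maximizing the 10-fold cross-validated
    partial log-likelihood (Verweij–van Houwelingen form) over a geometric
    grid; ties prefer the stronger penalty.  ``lam`` forces a fixed penalty
    instead (``lam=0`` is the unpenalized fit).  ``penalty="l2"`` swaps in a
    ridge fit over the same grid — implemented for shrinkage-profile
    comparison, not for signature building.
    """
    if penalty not in ("l1", "l2"):
        raise ValueError(f"unknown penalty {penalty!r}")
    if expr.n_samples < 10:
        raise CoxFitError("at least 10 samples required for the 10-fold CV fit")
    X = expr.data.to_numpy(dtype=float)
    time = surv.time.to_numpy(dtype=float)
    event = surv.status.to_numpy(dtype=float).astype(bool)
    rng = rng or np.random.default_rng(0)

    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (X - mean) / sd_safe
    y = Surv.from_arrays(event, time)

    def l1_at(lams):
        return _l1_path(Xs, y, lams)

    def l2_at(lams):
        return ridge_cox_path(Xs, time, event, lams)

    path_fn = l1_at if penalty == "l1" else l2_at

    try:
        if lam is not None:
            if lam < 0:
                raise ValueError("lambda must be non-negative")
            if lam == 0:
                beta_std = newton_cox(Xs, time, event, ridge=0.0)
            else:
                beta_std = path_fn(np.array([lam]))[:, 0]
            chosen = float(lam)
        else:
            lams = _lambda_grid(Xs, y, n_lambdas, lambda_min_ratio)
            folds = stratified_event_folds(event, cv_folds, rng)
            cv_score = np.zeros(len(lams))
            for k in range(cv_folds):
                tr = folds != k
                beta_tr = path_fn(lams) if tr.all() else _fit_fold(
                    path_fn, penalty, Xs[tr], time[tr], event[tr], lams)
                # Verweij–van Houwelingen: held-out contribution of fold k
                ll_all = breslow_loglik(Xs, time, event, beta_tr)
                ll_tr = breslow_loglik(Xs[tr], time[tr], event[tr], beta_tr)
                cv_score += ll_all - ll_tr
            best = int(np.flatnonzero(cv_score == cv_score.max())[0])
            chosen = float(lams[best])
            beta_std = path_fn(lams)[:, best]
    except (ArithmeticError, ValueError, np.linalg.LinAlgError, CoxFitError) as exc:
        raise CoxFitError(f"penalized Cox fit failed: {exc}") from exc

    coef = beta_std / sd_safe
    coef[sd == 0] = 0.0
    if not np.isfinite(coef).all():
        raise CoxFitError("non-finite coefficients")
    return LassoFit(features=expr.feature_ids, lam=chosen,
                    coefficients=coef, cv_folds=cv_folds)


def _fit_fold(path_fn, penalty, Xtr, ttr, etr, lams):
    if penalty == "l1":
        ytr = Surv.from_arrays(etr, ttr)
        return _l1_path(Xtr, ytr, lams)
    return ridge_cox_path(Xtr, ttr, etr, lams)


def run_bootstrap_regression(expr: ExpressionMatrix, surv: SurvivalTable,
                             plan: BootstrapPlan, penalty: str = "l1",
                             corr_rho: float = 0.8, corr_alpha: float = 0.05,
                             flagged_pairs: set | None = None,
                             collect_fits: bool = False,
                             ) -> Signature | tuple[Signature, list[LassoFit]]:
    """Aggregate per-iteration penalized fits into a Signature.

    Each feature's signature coefficient is the mean of its fitted
    coefficients over the iterations in which it was sampled, zero-shrunk
    values included; ``times_sampled``/``times_nonzero`` record the
    selection metadata.  Features never sampled are absent.  Feature order
    is canonicalized (sorted) before sampling, so permuting input columns
    never changes the result.
    """
    from .preflight import spearman_pair_flags

    expr_sorted = expr.subset_features(sorted(expr.feature_ids))
    expr_sorted, surv = align(expr_sorted, surv)
    features = expr_sorted.feature_ids
    if len(features) != plan.N:
        raise ValueError(f"plan expects N={plan.N} features, matrix has {len(features)}")

    if flagged_pairs is None:
        flagged_pairs = (
            spearman_pair_flags(expr_sorted, rho_min=corr_rho, alpha=corr_alpha)
            if plan.P < 1 else set()
        )

    coef_sum = {}
    n_sampled = {}
    n_nonzero = {}
    fits: list[LassoFit] = []
    n_skipped = 0
    for it in range(plan.B):
        rng = _iteration_rng(plan, it)
        group = sample_group(plan, it, features, flagged_pairs, rng=rng)
        if group is None:
            n_skipped += 1
            continue
        sub = expr_sorted.subset_features(group)
        try:
            fit = fit_lasso_cox(sub, surv, penalty=penalty, rng=rng)
        except CoxFitError as exc:
            logger.warning("iteration %d skipped: %s", it, exc)
            n_skipped += 1
            continue
        if collect_fits:
            fits.append(fit)
        for f, c in zip(fit.features, fit.coefficients):
            coef_sum[f] = coef_sum.get(f, 0.0) + float(c)
            n_sampled[f] = n_sampled.get(f, 0) + 1
            n_nonzero[f] = n_nonzero.get(f, 0) + int(c != 0.0)
    if n_skipped == plan.B:
        raise RuntimeError("all bootstrap iterations were skipped")
    if n_skipped:
        logger.info("%d of %d iterations skipped", n_skipped, plan.B)

    rows = [
        (f, coef_sum[f] / n_sampled[f], n_sampled[f], n_nonzero[f])
        for f in n_sampled
    ]
    df = pd.DataFrame(rows, columns=["feature", "coefficient",
                                     "times_sampled", "times_nonzero"])
    df = df.sort_values(
        by=["coefficient", "feature"],
        key=lambda s: -s.abs() if s.name == "coefficient" else s,
    ).reset_index(drop=True)
    sig = Signature(df)
    return (sig, fits) if collect_fits else sig


def filter_signature(sig: Signature, cutoff: float) -> Signature:
    """Retain entries with |coefficient| >= cutoff, preserving order."""
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    keep = sig.entries["coefficient"].abs() >= cutoff
    if not keep.any():
        raise ValueError(
            f"coefficient cutoff {cutoff} removed every signature entry; "
            "try a lower cutoff"
        )
    return Signature(sig.entries[keep].reset_index(drop=True))
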