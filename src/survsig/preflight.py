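"""Gatekeeping checks applied before the bootstrap regression.

Four screens decide which samples and features enter the penalized
regression: a cohort-viability rule (enough samples and features for the
bootstrap / 10-fold cross-validation to be meaningful), an endpoint
variability rule (both statuses represented), a variance filter, and a
univariate proportional-hazards (Schoenfeld) screen.  A Spearman
correlation flagger supports the per-iteration collinearity vetting of the
bootstrap itself.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import proportional_hazard_test
from scipy import stats

from .io import ExpressionMatrix, SurvivalTable

logger = logging.getLogger("survsig")

#: fewer features than this and the attribute bootstrap is pointless
MIN_FEATURES_BOOTSTRAP = 20
#: fewer samples than this and no 10-fold CV Cox fit is viable
MIN_SAMPLES = 10


class CohortDecision(Enum):
    BOOTSTRAP = "bootstrap"
    SINGLE_REGRESSION = "single-regression"
    REJECT = "reject"


@dataclass(frozen=True)
class ViabilityResult:
    decision: CohortDecision
    reason: str


@dataclass
class FilterReport:
    """Audit trail of the pre-regression feature filters."""

    n_features_in: int = 0
    removed_low_variance: list = field(default_factory=list)
    removed_schoenfeld: list = field(default_factory=list)
    n_features_out: int = 0
    cohort_ok: bool = True
    cohort_reason: str = ""

    def validate(self) -> None:
        assert self.n_features_out == (
            self.n_features_in
            - len(self.removed_low_variance)
            - len(self.removed_schoenfeld)
        )
        assert not set(self.removed_low_variance) & set(self.removed_schoenfeld)

    def to_frame(self) -> pd.DataFrame:
        rows = [(f, "low-variance") for f in self.removed_low_variance]
        rows += [(f, "schoenfeld") for f in self.removed_schoenfeld]
        return pd.DataFrame(rows, columns=["feature", "removed_because"])

    def summary(self) -> str:
        return (
            f"features in: {self.n_features_in}\n"
            f"removed (low variance): {len(self.removed_low_variance)}\n"
            f"removed (proportional-hazards screen): {len(self.removed_schoenfeld)}\n"
            f"features out: {self.n_features_out}\n"
            f"cohort: {'ok' if self.cohort_ok else 'rejected'} {self.cohort_reason}"
        )


def check_cohort_viability(expr: ExpressionMatrix, surv: SurvivalTable) -> ViabilityResult:
    """Decide between bootstrap mode, a single regression, or rejection.

    At least 10 samples are required (each iteration runs a 10-fold
    cross-validated fit); with fewer than 20 features the bootstrap brings
    nothing and a single regression over all features is run instead.
    """
    n_samples = expr.n_samples
    n_features = expr.n_features
    if n_samples < MIN_SAMPLES:
        return ViabilityResult(
            CohortDecision.REJECT,
            f"minimum of {MIN_SAMPLES} samples required, got {n_samples}",
        )
    if n_features < MIN_FEATURES_BOOTSTRAP:
        return ViabilityResult(
            CohortDecision.SINGLE_REGRESSION,
            f"fewer than {MIN_FEATURES_BOOTSTRAP} features ({n_features}); "
            "single regression over all features",
        )
    return ViabilityResult(
        CohortDecision.BOOTSTRAP,
        f"{n_samples} samples, {n_features} features",
    )


def endpoint_variability_check(surv: SurvivalTable, min_per_status: int = 2) -> ViabilityResult:
    """Reject cohorts whose endpoint barely varies (too few events or censorings)."""
    if surv.n_events < min_per_status or surv.n_censored < min_per_status:
        return ViabilityResult(
            CohortDecision.REJECT,
            f"endpoint not variable enough: {surv.n_events} events, "
            f"{surv.n_censored} censored (need >= {min_per_status} of each)",
        )
    return ViabilityResult(CohortDecision.BOOTSTRAP, "endpoint variability ok")


def variance_filter(expr: ExpressionMatrix, cutoff: float = 0.01
                    ) -> tuple[ExpressionMatrix, list]:
    """Drop features whose sample variance falls below ``cutoff``.

    The boundary case (variance exactly equal to the cutoff) is retained.
    """
    if cutoff < 0:
        raise ValueError("variance cutoff must be non-negative")
    var = expr.data.var(axis=0, ddof=1)
    removed = var.index[var < cutoff].tolist()
    kept = var.index[var >= cutoff].tolist()
    if not kept:
        raise ValueError(
            f"variance filter at cutoff {cutoff} removed all "
            f"{expr.n_features} features"
        )
    return expr.subset_features(kept), removed


def schoenfeld_screen(expr: ExpressionMatrix, surv: SurvivalTable,
                      alpha: float = 0.05, time_transform: str = "km"
                      ) -> tuple[list, list, pd.Series]:
    """Univariate proportional-hazards screen over every feature.

    Each feature is fitted in its own univariate Cox model; the scaled
    Schoenfeld residuals are tested for correlation with transformed time
    (Kaplan–Meier-scaled time by default).  Features with test p < ``alpha``
    violate the proportional-hazards assumption and are removed, as are
    features whose Cox fit fails numerically.
    """
    kept, removed = [], []
    pvalues = {}
    base = pd.DataFrame({"time": surv.time, "status": surv.status})
    for feat in expr.feature_ids:
        df = base.copy()
        df["x"] = expr.data[feat].to_numpy(dtype=float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = CoxPHFitter().fit(df, "time", "status")
                res = proportional_hazard_test(cph, df, time_transform=time_transform)
            p = float(np.asarray(res.p_value).ravel()[0])
        except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("PH screen: Cox fit failed for %r (%s); removing", feat, exc)
            removed.append(feat)
            pvalues[feat] = np.nan
            continue
        pvalues[feat] = p
        if p < alpha:
            removed.append(feat)
        else:
            kept.append(feat)
    return kept, removed, pd.Series(pvalues, name="schoenfeld_p")


def spearman_pair_flags(expr: ExpressionMatrix, features=None,
                        rho_min: float = 0.8, alpha: float = 0.05) -> set:
    """Feature pairs with |Spearman rho| > ``rho_min`` and p < ``alpha``.

    Returned as a set of frozensets so lookups are order-free.
    """
    feats = list(features) if features is not None else expr.feature_ids
    if len(feats) < 2:
        return set()
    data = expr.data.loc[:, feats].to_numpy(dtype=float)
    rho, p = stats.spearmanr(data)
    if np.ndim(rho) == 0:       # scipy collapses the 2-feature case to scalars
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    flagged = set()
    iu = np.triu_indices(len(feats), k=1)
    for i, j in zip(*iu):
        if abs(rho[i, j]) > rho_min and p[i, j] < alpha:
            flagged.add(frozenset((feats[i], feats[j])))
    return flagged


def apply_preflight(expr: ExpressionMatrix, surv: SurvivalTable,
                    variance_cutoff: float = 0.01,
                    schoenfeld_alpha: float = 0.05,
                    time_transform: str = "km",
                    min_per_status: int = 2,
                    ) -> tuple[ExpressionMatrix, FilterReport, ViabilityResult]:
    """Run viability + variance + PH screens in order; returns the surviving matrix."""
    report = FilterReport(n_features_in=expr.n_features)
    viability = check_cohort_viability(expr, surv)
    if viability.decision is CohortDecision.REJECT:
        report.cohort_ok = False
        report.cohort_reason = viability.reason
        report.n_features_out = expr.n_features
        return expr, report, viability
    endpoint = endpoint_variability_check(surv, min_per_status=min_per_status)
    if endpoint.decision is CohortDecision.REJECT:
        report.cohort_ok = False
        report.cohort_reason = endpoint.reason
        report.n_features_out = expr.n_features
        return expr, report, endpoint
    report.cohort_reason = viability.reason

    expr, low_var = variance_filter(expr, variance_cutoff)
    report.removed_low_variance = low_var
    kept, removed_ph, _ = schoenfeld_screen(
        expr, surv, alpha=schoenfeld_alpha, time_transform=time_transform
    )
    report.removed_schoenfeld = removed_ph
    if not kept:
        raise ValueError("proportional-hazards screen removed every feature")
    expr = expr.subset_features(kept)
    report.n_features_out = expr.n_features
    report.validate()
    # the bootstrap/single decision can flip after filtering
    final = check_cohort_viability(expr, surv)
    return expr, report, final
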