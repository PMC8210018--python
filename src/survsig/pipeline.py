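"""High-level orchestration: regression -> signature -> survival validation.

These functions chain the module-level operations exactly the way the CLI
exposes them; library users can call the underlying pieces directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io import ExpressionMatrix, Signature, SurvivalTable, align
from .multivariate import (CovariableFrequency, MultivariateResult,
                           bootstrap_covariable_frequency, fit_multivariate_cox,
                           univariate_screen)
from .preflight import CohortDecision, FilterReport, apply_preflight
from .regression import filter_signature, plan_bootstrap, run_bootstrap_regression
from .scoring import SurvivalResult, analyze_survival, compute_risk_score

logger = logging.getLogger("survsig")


@dataclass
class RegressionOutput:
    signature: Signature
    report: FilterReport
    mode: str                    # "bootstrap" | "single-regression"


@dataclass
class SurvivalOutput:
    result: SurvivalResult
    multivariate: MultivariateResult | None = None
    covariable_frequency: CovariableFrequency | None = None


def run_regression(expr: ExpressionMatrix, surv: SurvivalTable,
                   group_size: int = 10, iterations: int | None = None,
                   corr_fraction: float = 0.3, variance_cutoff: float = 0.01,
                   corr_rho: float = 0.8, corr_alpha: float = 0.05,
                   schoenfeld_alpha: float = 0.05, seed: int = 0,
                   log2: bool = False, penalty: str = "l1") -> RegressionOutput:
    """Module I: preflight filters, then the bootstrap LASSO regression."""
    if log2:
        expr = expr.log2_transform()
    expr, surv = align(expr, surv)
    expr, report, viability = apply_preflight(
        expr, surv, variance_cutoff=variance_cutoff,
        schoenfeld_alpha=schoenfeld_alpha,
    )
    if viability.decision is CohortDecision.REJECT:
        raise ValueError(f"cohort rejected: {viability.reason}")
    if viability.decision is CohortDecision.SINGLE_REGRESSION:
        logger.info("single-regression mode: %s", viability.reason)
        plan = plan_bootstrap(N=expr.n_features, G=expr.n_features, B=1,
                              P=1.0, seed=seed)
        mode = "single-regression"
    else:
        plan = plan_bootstrap(N=expr.n_features, G=group_size, B=iterations,
                              P=corr_fraction, seed=seed)
        mode = "bootstrap"
    sig = run_bootstrap_regression(expr, surv, plan, penalty=penalty,
                                   corr_rho=corr_rho, corr_alpha=corr_alpha)
    return RegressionOutput(signature=sig, report=report, mode=mode)


def run_survival(expr: ExpressionMatrix, surv: SurvivalTable, sig: Signature,
                 cutoff_method: str = "median", alpha: float = 0.05,
                 signature_cutoff: float | None = None,
                 clinical: pd.DataFrame | None = None,
                 multivariate: bool = False, screen_threshold: float = 0.2,
                 bootstrap_covariables: bool = False, cycles: int = 100,
                 seed: int = 0, log2: bool = False,
                 exposed: str = "low") -> SurvivalOutput:
    """Module II: score the signature and test its prognostic value."""
    if log2:
        expr = expr.log2_transform()
    expr, surv = align(expr, surv)
    if signature_cutoff is not None:
        sig = filter_signature(sig, signature_cutoff)
    result = analyze_survival(expr, surv, sig, cutoff_method=cutoff_method,
                              alpha=alpha, exposed=exposed)
    out = SurvivalOutput(result=result)
    if multivariate:
        if clinical is None:
            clinical = surv.covariates
        if clinical is None or clinical.empty:
            raise ValueError("multivariate analysis requires clinical covariates")
        clinical = clinical.loc[surv.sample_ids]
        screen = univariate_screen(surv, clinical, threshold=screen_threshold)
        kept = clinical[screen.kept] if screen.kept else None
        out.multivariate = fit_multivariate_cox(
            surv, kept, result.score_table, exposed=exposed,
            screened_out=screen.screened_out,
        )
        if bootstrap_covariables and screen.kept:
            out.covariable_frequency = bootstrap_covariable_frequency(
                surv, clinical[screen.kept], result.score_table,
                cycles=cycles, seed=seed, exposed=exposed,
            )
    return out


def run_complete(expr: ExpressionMatrix, surv: SurvivalTable,
                 signature_cutoff: float | None = None,
                 validation: tuple[ExpressionMatrix, SurvivalTable] | None = None,
                 **kwargs) -> tuple[RegressionOutput, SurvivalOutput]:
    """Chain module I and module II.

    The signature is built on ``(expr, surv)``; survival testing uses the
    optional ``validation`` cohort when given (external validation),
    otherwise the same cohort.
    """
    reg_keys = {"group_size", "iterations", "corr_fraction", "variance_cutoff",
                "corr_rho", "corr_alpha", "schoenfeld_alpha", "seed", "log2",
                "penalty"}
    reg_kwargs = {k: v for k, v in kwargs.items() if k in reg_keys}
    surv_kwargs = {k: v for k, v in kwargs.items() if k not in reg_keys}
    if "seed" in reg_kwargs:
        surv_kwargs.setdefault("seed", reg_kwargs["seed"])
    if "log2" in reg_kwargs:
        surv_kwargs.setdefault("log2", reg_kwargs["log2"])
    reg = run_regression(expr, surv, **reg_kwargs)
    vex, vsu = validation if validation is not None else (expr, surv)
    sout = run_survival(vex, vsu, reg.signature,
                        signature_cutoff=signature_cutoff, **surv_kwargs)
    return reg, sout


def train_validation_split(expr: ExpressionMatrix, surv: SurvivalTable,
                           validation_fraction: float = 0.3, seed: int = 0):
    """Random patient split into training and validation cohorts."""
    import numpy as np

    expr, surv = align(expr, surv)
    ids = np.asarray(surv.sample_ids, dtype=object)
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    n_val = int(round(validation_fraction * len(ids)))
    if n_val < 1 or n_val >= len(ids):
        raise ValueError("validation fraction leaves an empty cohort")
    val, train = sorted(ids[:n_val]), sorted(ids[n_val:])
    return ((expr.subset_samples(train), surv.subset_samples(train)),
            (expr.subset_samples(val), surv.subset_samples(val)))
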