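"""Signature-based risk scoring and univariate survival analysis.

Given a signature (feature -> coefficient C) and an expression matrix E,
each sample receives the linear risk score

    score_s = sum_f C_f * E_{s,f}

The cohort is stratified into 'low' and 'high' score groups at the score
median (default) or at the Youden-optimal cut-point of an ROC curve of the
score against event status.  Group prognosis is then compared by log-rank
test, Kaplan–Meier curves and a Cox hazard ratio, after a Schoenfeld check
that the score itself respects proportional hazards.

Hazard ratios are reported with the low-score group as the exposed level,
so a protective low score yields HR < 1 (high scores = worse prognosis).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import proportional_hazard_test
from scipy.special import expit

from .io import ExpressionMatrix, Signature, SurvivalTable

logger = logging.getLogger("survsig")


def compute_risk_score(expr: ExpressionMatrix, sig: Signature) -> pd.Series:
    """Per-sample risk score: the dot product of coefficients and expression."""
    missing = [f for f in sig.features if f not in expr.data.columns]
    if missing:
        raise KeyError(f"signature features absent from expression matrix: {missing}")
    coef = sig.coefficients
    scores = expr.data.loc[:, coef.index].to_numpy(dtype=float) @ coef.to_numpy()
    out = pd.Series(scores, index=expr.data.index, name="score")
    if not np.isfinite(out).all():
        raise ValueError("non-finite risk score")
    return out


@dataclass(frozen=True)
class ScoreTable:
    """Scores, the stratification cutoff and the low/high group labels."""

    table: pd.DataFrame          # columns: score, group
    cutoff: float
    cutoff_method: str           # "median" | "roc-youden"
    roc: pd.DataFrame | None = None   # threshold, sensitivity, specificity, j

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    @property
    def scores(self) -> pd.Series:
        return self.table["score"]

    def sample_ids(self, group: str) -> list:
        return self.table.index[self.table["group"] == group].tolist()


def _roc_points(scores: np.ndarray, outcome: np.ndarray,
                thresholds: np.ndarray, bandwidth: float | None) -> pd.DataFrame:
    """Sensitivity/specificity at each threshold.

    ``bandwidth`` None gives the exact empirical ROC; otherwise each
    indicator 1{score > c} is replaced by a nearest-neighbour smoothed
    kernel weight (logistic kernel, bandwidth on the score scale).
    """
    pos = scores[outcome == 1]
    neg = scores[outcome == 0]
    if bandwidth is None:
        sens = np.array([(pos > c).mean() for c in thresholds])
        spec = np.array([(neg <= c).mean() for c in thresholds])
    else:
        sens = expit((pos[:, None] - thresholds[None, :]) / bandwidth).mean(axis=0)
        spec = 1.0 - expit((neg[:, None] - thresholds[None, :]) / bandwidth).mean(axis=0)
    return pd.DataFrame({
        "threshold": thresholds,
        "sensitivity": sens,
        "specificity": spec,
        "j": sens + spec - 1.0,
    })


def stratify(scores: pd.Series, method: str = "median",
             surv: SurvivalTable | None = None,
             smoothing: str = "nne", bandwidth: float | None = None) -> ScoreTable:
    """Split samples into 'low'/'high' score groups.

    ``median``: cutoff is the sample median; scores <= cutoff are 'low'.
    ``roc-youden``: cutoff maximizes Youden's J = sensitivity + specificity
    - 1 for classifying event status (requires ``surv``); by default the
    ROC is nearest-neighbour smoothed with bandwidth sd(score) * n^(-1/5),
    ``smoothing="none"`` uses the exact empirical ROC.
    """
    if len(scores) < 4:
        raise ValueError("at least 4 samples required for stratification")
    s = scores.to_numpy(dtype=float)
    if np.ptp(s) == 0:
        raise ValueError("all scores identical; no stratification possible")
    roc = None
    if method == "median":
        cutoff = float(np.median(s))
    elif method == "roc-youden":
        if surv is None:
            raise ValueError("roc-youden stratification requires survival data")
        outcome = surv.status.loc[scores.index].to_numpy(dtype=float)
        if outcome.min() == outcome.max():
            raise ValueError("roc-youden needs both event and censored samples")
        uniq = np.unique(s)
        thresholds = (uniq[:-1] + uniq[1:]) / 2.0
        if smoothing == "nne":
            h = bandwidth if bandwidth is not None else (
                s.std(ddof=1) * len(s) ** (-1 / 5)
            )
        elif smoothing == "none":
            h = None
        else:
            raise ValueError(f"unknown smoothing {smoothing!r}")
        roc = _roc_points(s, outcome, thresholds, h)
        best = roc["j"].to_numpy()
        cutoff = float(thresholds[np.flatnonzero(best == best.max())[0]])
    else:
        raise ValueError(f"unknown stratification method {method!r}")
    group = pd.Series(np.where(s > cutoff, "high", "low"), index=scores.index,
                      name="group")
    if group.nunique() < 2:
        raise ValueError("stratification produced a single group")
    table = pd.DataFrame({"score": scores, "group": group})
    return ScoreTable(table=table, cutoff=cutoff, cutoff_method=method, roc=roc)


@dataclass(frozen=True)
class SchoenfeldCheck:
    status: str          # "ok" | "warn"
    p: float | None

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def score_schoenfeld_check(scores: pd.Series, surv: SurvivalTable,
                           alpha: float = 0.05,
                           time_transform: str = "km") -> SchoenfeldCheck:
    """Proportional-hazards check of the continuous score (warn, don't stop)."""
    df = pd.DataFrame({
        "time": surv.time.loc[scores.index],
        "status": surv.status.loc[scores.index],
        "score": scores,
    })
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter().fit(df, "time", "status")
            res = proportional_hazard_test(cph, df, time_transform=time_transform)
        p = float(np.asarray(res.p_value).ravel()[0])
    except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
        logger.warning("score PH check: Cox fit failed (%s)", exc)
        return SchoenfeldCheck("warn", None)
    if p < alpha:
        logger.warning(
            "score violates the proportional-hazards assumption "
            "(Schoenfeld p = %.3g < %g); interpret hazard ratios with care", p, alpha,
        )
        return SchoenfeldCheck("warn", p)
    return SchoenfeldCheck("ok", p)


def logrank_test(score_table: ScoreTable, surv: SurvivalTable) -> tuple[float, float]:
    """Two-group (Mantel–Haenszel) log-rank test of low vs high score."""
    low = score_table.sample_ids("low")
    high = score_table.sample_ids("high")
    if not low or not high:
        raise ValueError("log-rank test requires two non-empty groups")
    res = _ll_logrank(
        surv.time.loc[low], surv.time.loc[high],
        event_observed_A=surv.status.loc[low],
        event_observed_B=surv.status.loc[high],
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve for one group."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float | None      # None when S(t) never reaches 0.5

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times,
            "survival": self.survival,
            "at_risk": self.at_risk,
        })


def km_estimate(time: pd.Series, status: pd.Series) -> KMCurve:
    """Kaplan–Meier estimate with at-risk counts and median survival."""
    kmf = KaplanMeierFitter()
    kmf.fit(time, status)
    sf = kmf.survival_function_
    tbl = kmf.event_table
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = tbl["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    return KMCurve(times=times, survival=surv, at_risk=at_risk, median=median)


@dataclass(frozen=True)
class HazardRatio:
    hr: float | None
    ci_low: float | None
    ci_high: float | None
    p: float | None
    estimable: bool
    note: str = ""


def univariate_hr(score_table: ScoreTable, surv: SurvivalTable,
                  exposed: str = "low") -> HazardRatio:
    """Cox hazard ratio of the binary score group.

    With ``exposed="low"`` (default) the reported HR is for the low-score
    group, so HR < 1 means low scores are protective / high scores carry
    worse prognosis.  ``exposed="high"`` inverts the convention.
    """
    if exposed not in ("low", "high"):
        raise ValueError("exposed must be 'low' or 'high'")
    groups = score_table.groups
    df = pd.DataFrame({
        "time": surv.time.loc[groups.index],
        "status": surv.status.loc[groups.index],
        "exposed": (groups == exposed).astype(float),
    })
    for g in ("low", "high"):
        ids = score_table.sample_ids(g)
        if surv.status.loc[ids].sum() == 0:
            return HazardRatio(None, None, None, None, False,
                               note=f"no events in the {g}-score group")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter().fit(df, "time", "status",
                                    fit_options={"precision": 1e-9})
    except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
        return HazardRatio(None, None, None, None, False, note=str(exc))
    row = cph.summary.loc["exposed"]
    return HazardRatio(
        hr=float(row["exp(coef)"]),
        ci_low=float(row["exp(coef) lower 95%"]),
        ci_high=float(row["exp(coef) upper 95%"]),
        p=float(row["p"]),
        estimable=True,
    )


@dataclass(frozen=True)
class SurvivalResult:
    """Everything the univariate survival analysis produces."""

    score_table: ScoreTable
    schoenfeld: SchoenfeldCheck
    logrank_stat: float
    logrank_p: float
    hazard_ratio: HazardRatio
    n_low: int
    n_high: int
    median_low: float | None
    median_high: float | None
    km_low: KMCurve
    km_high: KMCurve

    def summary_frame(self) -> pd.DataFrame:
        hr = self.hazard_ratio
        return pd.DataFrame([{
            "cutoff_method": self.score_table.cutoff_method,
            "cutoff": self.score_table.cutoff,
            "n_low": self.n_low,
            "n_high": self.n_high,
            "median_survival_low": self.median_low,
            "median_survival_high": self.median_high,
            "hazard_ratio_low_vs_high": hr.hr,
            "hr_ci_low": hr.ci_low,
            "hr_ci_high": hr.ci_high,
            "hr_p": hr.p,
            "logrank_stat": self.logrank_stat,
            "logrank_p": self.logrank_p,
            "schoenfeld_status": self.schoenfeld.status,
            "schoenfeld_p": self.schoenfeld.p,
        }])


def analyze_survival(expr: ExpressionMatrix, surv: SurvivalTable, sig: Signature,
                     cutoff_method: str = "median", alpha: float = 0.05,
                     exposed: str = "low", smoothing: str = "nne") -> SurvivalResult:
    """Score, stratify and compare survival between score groups."""
    scores = compute_risk_score(expr, sig)
    check = score_schoenfeld_check(scores, surv, alpha=alpha)
    st = stratify(scores, method=cutoff_method, surv=surv, smoothing=smoothing)
    stat, p = logrank_test(st, surv)
    hr = univariate_hr(st, surv, exposed=exposed)
    low = st.sample_ids("low")
    high = st.sample_ids("high")
    km_low = km_estimate(surv.time.loc[low], surv.status.loc[low])
    km_high = km_estimate(surv.time.loc[high], surv.status.loc[high])
    return SurvivalResult(
        score_table=st, schoenfeld=check, logrank_stat=stat, logrank_p=p,
        hazard_ratio=hr, n_low=len(low), n_high=len(high),
        median_low=km_low.median, median_high=km_high.median,
        km_low=km_low, km_high=km_high,
    )
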