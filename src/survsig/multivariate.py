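"""Multivariate extension: clinical covariates alongside the signature score.

Clinical covariates are first screened in univariate Cox models; those
passing a lenient p-value threshold join the score group indicator in a
joint Cox model (forest-plot material).  A patient-oriented bootstrap then
estimates, over repeated resamples, how often each covariate remains
associated with the endpoint — its "relevance frequency".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .io import SurvivalTable
from .scoring import ScoreTable

logger = logging.getLogger("survsig")

SCORE_TERM = "score_group"


def _is_categorical(col: pd.Series) -> bool:
    return not pd.api.types.is_numeric_dtype(col)


def _reference_level(col: pd.Series):
    # most frequent level; ties broken by level name for determinism
    counts = col.value_counts()
    top = counts[counts == counts.max()].index
    return sorted(map(str, top))[0]


def _design_columns(covariates: pd.DataFrame, names: list) -> tuple[pd.DataFrame, dict]:
    """Dummy-code categoricals against their most frequent level."""
    pieces = []
    meta = {}
    for name in names:
        col = covariates[name]
        if _is_categorical(col):
            col = col.astype(str).where(col.notna())
            ref = _reference_level(col.dropna())
            levels = sorted(l for l in col.dropna().unique() if l != ref)
            block = pd.DataFrame(
                {f"{name}={lvl}": (col == lvl).astype(float) for lvl in levels},
                index=col.index,
            )
            block[col.isna()] = np.nan
            meta[name] = {"kind": "categorical", "reference": ref, "levels": levels}
            pieces.append(block)
        else:
            meta[name] = {"kind": "numeric"}
            pieces.append(col.astype(float).to_frame(name))
    design = pd.concat(pieces, axis=1) if pieces else pd.DataFrame(index=covariates.index)
    return design, meta


@dataclass(frozen=True)
class ScreenResult:
    kept: list
    screened_out: dict          # name -> univariate p
    dropped: list               # degenerate covariates (single level etc.)
    pvalues: dict


def univariate_screen(surv: SurvivalTable, covariates: pd.DataFrame,
                      threshold: float = 0.2) -> ScreenResult:
    """Keep covariates whose univariate Cox Wald p falls below ``threshold``.

    Categorical covariates are dummy-coded against their most frequent
    level; the covariate's p is the smallest Wald p among its levels.
    Complete cases per covariate.  The signature score never passes through
    this screen — it always enters the final model, being the quantity
    under evaluation.
    """
    kept, screened_out, dropped, pvalues = [], {}, [], {}
    for name in covariates.columns:
        col = covariates[name]
        valid = col.dropna()
        if valid.nunique() < 2:
            logger.warning("covariate %r has a single level; dropped", name)
            dropped.append(name)
            continue
        design, _ = _design_columns(covariates, [name])
        df = pd.DataFrame({"time": surv.time, "status": surv.status}).join(design)
        df = df.dropna()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = CoxPHFitter().fit(df, "time", "status")
            p = float(cph.summary["p"].min())
        except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("univariate screen: fit failed for %r (%s); dropped",
                           name, exc)
            dropped.append(name)
            continue
        pvalues[name] = p
        if p < threshold:
            kept.append(name)
        else:
            screened_out[name] = p
    return ScreenResult(kept=kept, screened_out=screened_out, dropped=dropped,
                        pvalues=pvalues)


@dataclass(frozen=True)
class MultivariateResult:
    """Joint Cox model of the score group and the screened covariates."""

    terms: pd.DataFrame          # covariate, level, hr, ci_low, ci_high, p, reference
    model_n: int
    screened_out: dict = field(default_factory=dict)

    def term_p(self, covariate: str) -> float:
        rows = self.terms[(self.terms["covariate"] == covariate)
                          & ~self.terms["reference"]]
        return float(rows["p"].min())


def fit_multivariate_cox(surv: SurvivalTable, covariates: pd.DataFrame | None,
                         score_table: ScoreTable, exposed: str = "low",
                         screened_out: dict | None = None) -> MultivariateResult:
    """Joint Cox fit of score group + covariates on complete cases.

    The score enters as the binary group indicator (1 = ``exposed`` group,
    default low), matching the univariate hazard-ratio convention.
    Reference levels of categorical covariates appear in the term table
    with HR fixed at 1.
    """
    names = list(covariates.columns) if covariates is not None else []
    if names:
        design, meta = _design_columns(covariates, names)
    else:
        design, meta = pd.DataFrame(index=surv.time.index), {}
    groups = score_table.groups
    df = pd.DataFrame({
        "time": surv.time.loc[groups.index],
        "status": surv.status.loc[groups.index],
        SCORE_TERM: (groups == exposed).astype(float),
    })
    df = df.join(design, how="left").dropna()
    if df.shape[0] < 10:
        raise ValueError(f"only {df.shape[0]} complete cases; too few to fit")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter().fit(df, "time", "status",
                                    fit_options={"precision": 1e-9})
    except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
        raise RuntimeError(
            f"multivariate Cox fit failed (covariates: {names}): {exc}"
        ) from exc

    rows = []
    summ = cph.summary

    def _append(term, covariate, level):
        row = summ.loc[term]
        rows.append({
            "covariate": covariate, "level": level,
            "hr": float(row["exp(coef)"]),
            "ci_low": float(row["exp(coef) lower 95%"]),
            "ci_high": float(row["exp(coef) upper 95%"]),
            "p": float(row["p"]), "reference": False,
        })

    _append(SCORE_TERM, SCORE_TERM, f"{exposed} score")
    for name in names:
        info = meta[name]
        if info["kind"] == "numeric":
            _append(name, name, "")
        else:
            rows.append({
                "covariate": name, "level": info["reference"], "hr": 1.0,
                "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                "reference": True,
            })
            for lvl in info["levels"]:
                _append(f"{name}={lvl}", name, lvl)
    return MultivariateResult(
        terms=pd.DataFrame(rows), model_n=int(df.shape[0]),
        screened_out=screened_out or {},
    )


@dataclass(frozen=True)
class CovariableFrequency:
    """Per-covariate relevance frequency over the patient bootstrap."""

    cycles_run: int
    cycles_used: int
    eligible: dict               # covariate -> cycles in which it entered a model
    relevant: dict               # covariate -> cycles with term p < p_threshold
    frequency: dict              # relevant / eligible
    plotted: list                # covariates with frequency >= plot_threshold

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "covariate": c,
                "eligible_cycles": self.eligible[c],
                "relevant_cycles": self.relevant.get(c, 0),
                "frequency": self.frequency[c],
                "plotted": c in self.plotted,
            }
            for c in sorted(self.eligible)
        ]
        return pd.DataFrame(rows)


def bootstrap_covariable_frequency(
    surv: SurvivalTable, covariates: pd.DataFrame, score_table: ScoreTable,
    cycles: int = 100, seed: int = 0, exposed: str = "low",
    p_threshold: float = 0.05, min_retained: float = 0.7,
    min_minority: float = 0.2, min_covariables: int = 2,
    plot_threshold: float = 0.25, resample: bool = True,
) -> CovariableFrequency:
    """Patient-oriented bootstrap of covariate relevance.

    Per cycle: patients are resampled with replacement; rows with missing
    values in the tested covariates are removed; the cycle is used only if
    the remaining data still cover at least ``min_retained`` (70%) of the
    original patients, and at least ``min_covariables`` (2) covariates are
    eligible — a categorical covariate is eligible only when its minority
    category holds at least ``min_minority`` (20%) of the cycle's rows.
    The multivariate model (score + eligible covariates) is fitted and a
    covariate counts as relevant when its term p < ``p_threshold``.  After
    all cycles the relevance frequency is relevant/eligible cycles, and
    covariates at or above ``plot_threshold`` (25%) make the plot list.
    """
    rng = np.random.default_rng(seed)
    ids = np.asarray(surv.sample_ids, dtype=object)
    n = len(ids)
    eligible: dict = {}
    relevant: dict = {}
    cycles_used = 0
    for _ in range(cycles):
        take = rng.integers(0, n, size=n) if resample else np.arange(n)
        cyc_ids = ids[take]
        cov = covariates.loc[cyc_ids]
        ok_rows = cov.notna().all(axis=1).to_numpy()
        cyc_ids = cyc_ids[ok_rows]
        # null removal must leave the cycle with >= 70% of the original
        # cohort size (a with-replacement resample holds ~63% distinct
        # patients, so the rule counts retained rows, not distinct ids)
        if len(cyc_ids) < min_retained * n:
            continue
        cov = covariates.loc[cyc_ids]
        cyc_eligible = []
        for name in covariates.columns:
            col = cov[name]
            if _is_categorical(col):
                freqs = col.astype(str).value_counts(normalize=True)
                if len(freqs) < 2 or freqs.min() < min_minority:
                    continue
            elif col.nunique() < 2:
                continue
            cyc_eligible.append(name)
        if len(cyc_eligible) < min_covariables:
            continue
        # rebuild per-cycle tables with unique row labels for the resample
        labels = pd.Index([f"r{k}" for k in range(len(cyc_ids))])
        surv_c = SurvivalTable(
            pd.Series(surv.time.loc[cyc_ids].to_numpy(), index=labels, name="time"),
            pd.Series(surv.status.loc[cyc_ids].to_numpy(), index=labels, name="status"),
        )
        cov_c = pd.DataFrame(cov.to_numpy(), index=labels, columns=cov.columns)
        for name in covariates.columns:
            if not _is_categorical(covariates[name]):
                cov_c[name] = pd.to_numeric(cov_c[name])
        st_tab = score_table.table.loc[cyc_ids]
        st_c = ScoreTable(
            table=pd.DataFrame(
                {"score": st_tab["score"].to_numpy(), "group": st_tab["group"].to_numpy()},
                index=labels,
            ),
            cutoff=score_table.cutoff, cutoff_method=score_table.cutoff_method,
        )
        try:
            fit = fit_multivariate_cox(surv_c, cov_c[cyc_eligible], st_c,
                                       exposed=exposed)
        except (RuntimeError, ValueError) as exc:
            logger.debug("bootstrap cycle skipped: %s", exc)
            continue
        cycles_used += 1
        for name in cyc_eligible:
            eligible[name] = eligible.get(name, 0) + 1
            if fit.term_p(name) < p_threshold:
                relevant[name] = relevant.get(name, 0) + 1
    if cycles_used == 0:
        raise RuntimeError("no bootstrap cycle satisfied the eligibility filters")
    frequency = {c: relevant.get(c, 0) / eligible[c] for c in eligible}
    plotted = sorted(c for c, f in frequency.items() if f >= plot_threshold)
    return CovariableFrequency(
        cycles_run=cycles, cycles_used=cycles_used, eligible=eligible,
        relevant=relevant, frequency=frequency, plotted=plotted,
    )
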