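"""Textual and graphical outputs.

Every plot is written together with a machine-readable TSV twin carrying
exactly the plotted numbers; the TSVs are the source of truth and are
always emitted, even when image rendering fails or is disabled.  Files are
named ``<prefix>.<artifact>.{tsv,png,svg}`` and a run manifest JSON lists
everything with checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .io import Signature, SurvivalTable
from .multivariate import CovariableFrequency, MultivariateResult
from .scoring import ScoreTable, SurvivalResult

logger = logging.getLogger("survsig")


def top10_lollipop_data(sig: Signature, n_top: int = 10) -> pd.DataFrame:
    """The ten largest-|coefficient| signature entries, deterministically ranked.

    Ties in |coefficient| are broken by feature identifier so repeated runs
    produce identical plots.
    """
    if len(sig) == 0:
        raise ValueError("empty signature")
    df = sig.entries.copy()
    df["abs_coefficient"] = df["coefficient"].abs()
    df = df.sort_values(["abs_coefficient", "feature"],
                        ascending=[False, True], kind="mergesort")
    out = df.head(n_top).drop(columns="abs_coefficient").reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def _emit(df: pd.DataFrame, prefix: str, artifact: str, render) -> list[Path]:
    """Write the TSV twin, then best-effort render PNG + SVG."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv = prefix.with_name(f"{prefix.name}.{artifact}.tsv")
    df.to_csv(tsv, sep="\t", index=False)
    written = [tsv]
    if render is None:
        return written
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fig = render()
            for ext in ("png", "svg"):
                path = prefix.with_name(f"{prefix.name}.{artifact}.{ext}")
                fig.savefig(path, dpi=150, bbox_inches="tight")
                written.append(path)
            plt.close(fig)
    except Exception as exc:  # rendering must never corrupt numeric output
        logger.warning("rendering %s failed (%s); TSV twin kept", artifact, exc)
    return written


def lollipop_plot(sig: Signature, prefix: str) -> list[Path]:
    data = top10_lollipop_data(sig)

    def render():
        fig, ax = plt.subplots(figsize=(6, 4))
        y = np.arange(len(data))[::-1]
        ax.hlines(y, 0, data["coefficient"], color="grey", lw=1)
        ax.plot(data["coefficient"], y, "o", color="firebrick")
        ax.set_yticks(y, data["feature"])
        ax.axvline(0, color="black", lw=0.5)
        ax.set_xlabel("signature coefficient")
        ax.set_title("top signature features")
        return fig

    return _emit(data, prefix, "lollipop", render)


def coefficient_histogram(sig: Signature, prefix: str, bins: int = 40) -> list[Path]:
    coefs = sig.entries["coefficient"].to_numpy()
    counts, edges = np.histogram(coefs, bins=bins)
    data = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": counts})

    def render():
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge",
               color="steelblue", edgecolor="white")
        ax.set_xlabel("signature coefficient")
        ax.set_ylabel("features")
        ax.set_title("coefficient distribution")
        return fig

    return _emit(data, prefix, "coefficient_histogram", render)


def km_plot(result: SurvivalResult, prefix: str) -> list[Path]:
    frames = []
    for name, curve in (("low", result.km_low), ("high", result.km_high)):
        df = curve.as_frame()
        df.insert(0, "group", name)
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)

    def render():
        fig, ax = plt.subplots(figsize=(6, 4.5))
        for name, curve, color in (("low", result.km_low, "tab:blue"),
                                   ("high", result.km_high, "tab:red")):
            ax.step(curve.times, curve.survival, where="post",
                    label=f"{name} score (n={int(curve.at_risk[0])})", color=color)
        ax.set_ylim(0, 1.02)
        ax.set_xlabel("follow-up time (days)")
        ax.set_ylabel("survival probability")
        hr = result.hazard_ratio
        hr_txt = (f"HR={hr.hr:.2f} [{hr.ci_low:.2f}-{hr.ci_high:.2f}]"
                  if hr.estimable else "HR non-estimable")
        ax.set_title(f"{hr_txt}, log-rank p={result.logrank_p:.3g}")
        ax.legend()
        return fig

    return _emit(data, prefix, "kaplan_meier", render)


def schoenfeld_plot(scores: pd.Series, surv: SurvivalTable, prefix: str) -> list[Path]:
    """Scaled Schoenfeld residuals of the score against event time."""
    from lifelines import CoxPHFitter

    df = pd.DataFrame({
        "time": surv.time.loc[scores.index],
        "status": surv.status.loc[scores.index],
        "score": scores,
    })
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter().fit(df, "time", "status")
            resid = cph.compute_residuals(df, "scaled_schoenfeld")
    except Exception as exc:
        logger.warning("Schoenfeld residual computation failed: %s", exc)
        return []
    event_times = df.loc[resid.index, "time"]
    data = pd.DataFrame({
        "time": event_times.to_numpy(),
        "scaled_schoenfeld_residual": resid["score"].to_numpy(),
    }).sort_values("time").reset_index(drop=True)

    def render():
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(data["time"], data["scaled_schoenfeld_residual"], "o",
                ms=3, alpha=0.6)
        ax.axhline(0, color="black", lw=0.5)
        ax.set_xlabel("event time (days)")
        ax.set_ylabel("scaled Schoenfeld residual (score)")
        ax.set_title("proportional-hazards diagnostic")
        return fig

    return _emit(data, prefix, "schoenfeld", render)


def forest_plot(result: MultivariateResult, prefix: str) -> list[Path]:
    data = result.terms.copy()

    def render():
        plot = data[~data["reference"]]
        fig, ax = plt.subplots(figsize=(6, 0.5 * len(plot) + 1.5))
        y = np.arange(len(plot))[::-1]
        ax.errorbar(plot["hr"], y,
                    xerr=[plot["hr"] - plot["ci_low"], plot["ci_high"] - plot["hr"]],
                    fmt="s", color="black", capsize=3)
        labels = [f"{c} {l}".strip() for c, l in zip(plot["covariate"], plot["level"])]
        ax.set_yticks(y, labels)
        ax.axvline(1, color="grey", ls="--", lw=0.8)
        ax.set_xscale("log")
        ax.set_xlabel("hazard ratio (95% CI)")
        ax.set_title(f"multivariate Cox model (n={result.model_n})")
        return fig

    return _emit(data, prefix, "forest", render)


def roc_plot(score_table: ScoreTable, prefix: str) -> list[Path]:
    if score_table.roc is None:
        logger.info("no ROC data (median stratification); skipping ROC plot")
        return []
    data = score_table.roc.copy()

    def render():
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        fpr = 1 - data["specificity"]
        ax.plot(fpr, data["sensitivity"], "-", color="tab:red")
        ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
        best = data.loc[data["j"].idxmax()]
        ax.plot(1 - best["specificity"], best["sensitivity"], "o", color="black")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"ROC, Youden cutoff = {score_table.cutoff:.4g}")
        return fig

    return _emit(data, prefix, "roc", render)


def covariable_frequency_plot(freq: CovariableFrequency, prefix: str) -> list[Path]:
    data = freq.as_frame()

    def render():
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.bar(data["covariate"], data["frequency"], color="seagreen")
        ax.axhline(0.25, color="grey", ls="--", lw=0.8)
        ax.set_ylabel("relevance frequency")
        ax.set_ylim(0, 1)
        ax.set_title(f"covariate relevance over {freq.cycles_used} bootstrap cycles")
        plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
        return fig

    return _emit(data, prefix, "covariable_frequency", render)


def write_manifest(prefix: str, files: list) -> Path:
    prefix = Path(prefix)
    entries = []
    for f in files:
        f = Path(f)
        if not f.exists():
            continue
        digest = hashlib.sha256(f.read_bytes()).hexdigest()
        entries.append({"file": f.name, "sha256": digest, "bytes": f.stat().st_size})
    path = prefix.with_name(f"{prefix.name}.manifest.json")
    path.write_text(json.dumps({"outputs": entries}, indent=2))
    return path
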