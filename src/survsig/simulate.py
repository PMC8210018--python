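"""Synthetic survival cohorts with known ground truth.

The generator emulates the statistical structure the pipeline assumes in
real expression cohorts: log-normal expression-scale features, a handful
of truly prognostic features among many nulls, blocks of collinear
features (shared latent factor), planted low-variance features, and
right-censored Weibull proportional-hazards survival times with a
calibrated censoring fraction.

Survival model: given standardized latent feature values z_f and planted
log-hazard coefficients beta_f, the linear predictor is eta = sum beta_f
z_f and event times follow a Weibull baseline (shape k, scale lambda days)
under proportional hazards:

    T = lambda * (-log U / exp(eta))**(1/k),   U ~ Uniform(0, 1)

Censoring is administrative-uniform, C ~ Uniform(0, c_max), with c_max
solved on the drawn sample so the realized censoring fraction matches the
target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SurvivalTable


def feature_name(i: int) -> str:
    return f"G{i:04d}"


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth description of a synthetic cohort."""

    n_samples: int
    n_features: int
    true_effects: dict = field(default_factory=dict)   # feature name -> beta
    collinear_blocks: list = field(default_factory=list)  # (size, target spearman rho)
    n_low_variance: int = 0
    weibull_shape: float = 1.2
    weibull_scale: float = 800.0       # days; cancer-cohort follow-up scale
    censoring_fraction: float = 0.3
    seed: int = 0
    expression_log_mean: float = np.log(10.0)
    expression_log_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.censoring_fraction < 1:
            raise ValueError("censoring_fraction must lie in [0, 1)")
        if len(self.true_effects) > self.n_features:
            raise ValueError("more planted effects than features")

    @classmethod
    def with_planted(cls, n_samples: int, n_features: int, n_true: int = 0,
                     beta: float = 0.8, **kwargs) -> "SyntheticSpec":
        """Convenience constructor planting ``n_true`` effects of size ``beta``.

        Effects alternate in sign and land on the first features.
        """
        effects = {
            feature_name(i): beta * (1 if i % 2 == 0 else -1)
            for i in range(n_true)
        }
        return cls(n_samples=n_samples, n_features=n_features,
                   true_effects=effects, **kwargs)


def _pearson_for_spearman(rho_s: float) -> float:
    """Bivariate-normal Pearson r achieving Spearman rho_s."""
    r = 2.0 * np.sin(np.pi * rho_s / 6.0)
    if not -1 < r < 1:
        raise ValueError(f"infeasible Spearman target {rho_s}")
    return r


def _latent_matrix(spec: SyntheticSpec, rng: np.random.Generator
                   ) -> tuple[np.ndarray, dict]:
    """Standard-normal latent features; collinear blocks share a factor."""
    n, p = spec.n_samples, spec.n_features
    z = rng.standard_normal((n, p))
    blocks = {}
    next_free = len(spec.true_effects)  # blocks start after planted effects
    for b, (size, rho_s) in enumerate(spec.collinear_blocks):
        r = _pearson_for_spearman(rho_s)
        # equicorrelated construction: z_j = sqrt(r)*factor + sqrt(1-r)*noise
        if r <= 0:
            raise ValueError("collinear blocks need a positive rho target")
        members = list(range(next_free, next_free + size))
        if members[-1] >= p - spec.n_low_variance:
            raise ValueError("collinear blocks overflow the feature count")
        factor = rng.standard_normal(n)
        for j in members:
            z[:, j] = np.sqrt(r) * factor + np.sqrt(1 - r) * rng.standard_normal(n)
        blocks[f"block{b}"] = [feature_name(j) for j in members]
        next_free = members[-1] + 1
    return z, blocks


def _calibrate_censoring(T: np.ndarray, u: np.ndarray, target: float
                         ) -> tuple[np.ndarray, float]:
    """Find c_max so that mean(C < T) with C = u*c_max hits ``target``."""
    if target == 0:
        return np.full_like(T, np.inf), np.inf
    lo, hi = 1e-6, float(T.max()) * 1e3

    def frac(cmax):
        return float((u * cmax < T).mean())

    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    cmax = np.sqrt(lo * hi)
    return u * cmax, cmax


def generate_cohort(spec: SyntheticSpec
                    ) -> tuple[ExpressionMatrix, SurvivalTable, dict]:
    """Expression matrix, survival table and truth record for one cohort."""
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features
    names = [feature_name(i) for i in range(p)]
    samples = [f"S{i:04d}" for i in range(n)]

    z, blocks = _latent_matrix(spec, rng)

    # expression scale: log-normal for regular features, near-constant for
    # the planted low-variance tail
    expr = np.exp(spec.expression_log_mean + spec.expression_log_sd * z)
    low_var = names[p - spec.n_low_variance:] if spec.n_low_variance else []
    for j in range(p - spec.n_low_variance, p):
        expr[:, j] = np.clip(1.0 + 0.01 * z[:, j], 0.0, None)

    # hazard is linear in the standardized expression values — the covariates
    # the downstream Cox models actually see
    expr_std = (expr - expr.mean(axis=0)) / expr.std(axis=0, ddof=1)
    beta = np.zeros(p)
    for fname, b in spec.true_effects.items():
        beta[names.index(fname)] = b
    eta = expr_std @ beta

    u_event = rng.uniform(size=n)
    T = spec.weibull_scale * (-np.log(u_event) / np.exp(eta)) ** (1.0 / spec.weibull_shape)
    u_cens = rng.uniform(size=n)
    C, cmax = _calibrate_censoring(T, u_cens, spec.censoring_fraction)
    time = np.minimum(T, C)
    status = (T <= C).astype(float)
    time = np.maximum(time, 1e-8)

    em = ExpressionMatrix(pd.DataFrame(expr, index=samples, columns=names))
    st = SurvivalTable(
        pd.Series(time, index=pd.Index(samples), name="time"),
        pd.Series(status, index=pd.Index(samples), name="status"),
    )
    truth = {
        "beta": dict(spec.true_effects),
        "eta": pd.Series(eta, index=samples),
        "blocks": blocks,
        "low_variance": low_var,
        "censoring_cmax": cmax,
        "realized_censoring": float(1 - status.mean()),
        "latent": pd.DataFrame(z, index=samples, columns=names),
    }
    return em, st, truth


def generate_clinical(surv: SurvivalTable, eta: pd.Series | None = None,
                      seed: int = 0, minority_fraction: float = 0.1,
                      confounder_rho: float = 0.0,
                      missing_fraction: float = 0.0) -> pd.DataFrame:
    """Clinical covariate table matched to a generated cohort.

    Emits a balanced binary covariate (``sex``), an imbalanced one
    (``rare_group``, minority share ``minority_fraction``), numeric ``age``,
    and — when ``confounder_rho`` > 0 and the truth linear predictor is
    supplied — a numeric ``confounder`` correlated with it.  Missing cells
    are introduced completely at random at rate ``missing_fraction``.
    """
    rng = np.random.default_rng(seed)
    ids = surv.sample_ids
    n = len(ids)
    out = pd.DataFrame(index=pd.Index(ids))
    out["sex"] = np.where(rng.uniform(size=n) < 0.5, "female", "male")
    out["rare_group"] = np.where(rng.uniform(size=n) < minority_fraction,
                                 "rare", "common")
    out["age"] = np.round(rng.normal(60, 10, size=n), 1)
    if confounder_rho:
        if eta is None:
            raise ValueError("confounder requires the truth linear predictor")
        e = eta.loc[ids].to_numpy(dtype=float)
        sd = e.std(ddof=0)
        ez = (e - e.mean()) / (sd if sd > 0 else 1.0)
        out["confounder"] = (confounder_rho * ez
                             + np.sqrt(1 - confounder_rho**2) * rng.standard_normal(n))
    if missing_fraction:
        for col in out.columns:
            mask = rng.uniform(size=n) < missing_fraction
            out.loc[mask, col] = np.nan
    return out
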