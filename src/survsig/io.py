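"""Reading, writing and validation of the TSV tables the pipeline consumes.

Three table kinds circulate between the two analysis stages:

* an expression matrix (samples x genes/transcripts, TPM/FPKM-scale values),
* a survival table (follow-up time in days, event status, optional clinical
  covariates),
* a signature table (feature -> aggregated Cox regression coefficient, with
  bookkeeping on how often each feature was sampled during the bootstrap).

All files are plain tab-separated text with a mandatory header row, UTF-8
encoded, '.' as the decimal separator and no quoting.  Identifiers may not
contain tabs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("survsig")

Orientation = Literal["samples-in-rows", "features-in-rows"]


class ValidationError(ValueError):
    """A table violates one of the structural invariants."""


def _duplicates(index: pd.Index) -> list:
    return index[index.duplicated()].unique().tolist()


@dataclass(frozen=True)
class ExpressionMatrix:
    """Samples x features grid of non-negative expression values.

    ``data`` is indexed by sample identifier with one column per feature.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        dup_s = _duplicates(df.index)
        if dup_s:
            raise ValidationError(f"duplicate sample identifiers: {dup_s}")
        dup_f = _duplicates(df.columns)
        if dup_f:
            raise ValidationError(f"duplicate feature identifiers: {dup_f}")
        for col in df.columns:
            if not pd.api.types.is_numeric_dtype(df[col]):
                bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
                raise ValidationError(
                    f"non-numeric expression value in feature {col!r}, "
                    f"sample(s) {bad.tolist()[:5]}"
                )
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite expression value at sample {df.index[r]!r}, "
                f"feature {df.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative expression value at sample {df.index[r]!r}, "
                f"feature {df.columns[c]!r}"
            )

    @property
    def sample_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def feature_ids(self) -> list:
        return self.data.columns.tolist()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def subset_features(self, features: Sequence) -> "ExpressionMatrix":
        missing = [f for f in features if f not in self.data.columns]
        if missing:
            raise KeyError(f"features not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[:, list(features)])

    def subset_samples(self, samples: Sequence) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(samples)])

    def log2_transform(self) -> "ExpressionMatrix":
        """Return a log2(x + 1)-transformed copy (optional analysis scale)."""
        return ExpressionMatrix(np.log2(self.data + 1.0))


@dataclass(frozen=True)
class SurvivalTable:
    """Per-sample follow-up time (days), event status and optional covariates.

    ``status`` is 1 when the event (e.g. death) occurred and 0 when the
    sample was right-censored.
    """

    time: pd.Series
    status: pd.Series
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        dup = _duplicates(self.time.index)
        if dup:
            raise ValidationError(f"duplicate sample identifiers: {dup}")
        if not self.time.index.equals(self.status.index):
            raise ValidationError("time and status indexed by different samples")
        t = pd.to_numeric(self.time, errors="coerce")
        if t.isna().any():
            raise ValidationError(
                f"missing or non-numeric follow-up time for "
                f"{self.time.index[t.isna()].tolist()[:5]}"
            )
        if (t <= 0).any():
            raise ValidationError(
                f"non-positive follow-up time for "
                f"{self.time.index[t <= 0].tolist()[:5]}"
            )
        s = pd.to_numeric(self.status, errors="coerce")
        if s.isna().any() or not s.isin([0, 1]).all():
            bad = self.status.index[s.isna() | ~s.isin([0, 1])]
            raise ValidationError(
                f"event status outside {{0, 1}} for {bad.tolist()[:5]}"
            )
        if self.covariates is not None:
            if not self.covariates.index.equals(self.time.index):
                raise ValidationError("covariates indexed by different samples")
            n_missing = int(self.covariates.isna().sum().sum())
            if n_missing:
                logger.info("survival table has %d missing covariate cells", n_missing)

    @property
    def sample_ids(self) -> list:
        return self.time.index.tolist()

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    @property
    def n_censored(self) -> int:
        return int((1 - self.status).sum())

    def subset_samples(self, samples: Sequence) -> "SurvivalTable":
        idx = list(samples)
        cov = self.covariates.loc[idx] if self.covariates is not None else None
        return SurvivalTable(self.time.loc[idx], self.status.loc[idx], cov)

    def frame(self) -> pd.DataFrame:
        """Time/status (and covariates) as one DataFrame."""
        df = pd.DataFrame({"time": self.time, "status": self.status})
        if self.covariates is not None:
            df = df.join(self.covariates)
        return df


@dataclass(frozen=True)
class Signature:
    """Ordered feature -> coefficient map with bootstrap selection metadata.

    ``entries`` columns: feature, coefficient, times_sampled, times_nonzero.
    A feature that was never sampled does not appear.
    """

    entries: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        df = self.entries
        required = {"feature", "coefficient", "times_sampled", "times_nonzero"}
        if not required.issubset(df.columns):
            raise ValidationError(
                f"signature missing columns: {sorted(required - set(df.columns))}"
            )
        dup = df["feature"][df["feature"].duplicated()].tolist()
        if dup:
            raise ValidationError(f"duplicate signature features: {dup}")
        if not pd.api.types.is_numeric_dtype(df["coefficient"]):
            raise ValidationError("non-numeric signature coefficient")
        if (df["times_nonzero"] > df["times_sampled"]).any():
            raise ValidationError("times_nonzero exceeds times_sampled")
        if (df["times_sampled"] <= 0).any():
            raise ValidationError("feature with times_sampled = 0 must be absent")

    @classmethod
    def from_items(cls, items: Sequence[tuple]) -> "Signature":
        """Build from (feature, coefficient[, times_sampled, times_nonzero])."""
        rows = []
        for item in items:
            f, c, *rest = item
            ts = rest[0] if len(rest) > 0 else 1
            tn = rest[1] if len(rest) > 1 else int(c != 0)
            rows.append((f, float(c), int(ts), int(tn)))
        return cls(
            pd.DataFrame(
                rows, columns=["feature", "coefficient", "times_sampled", "times_nonzero"]
            )
        )

    @property
    def features(self) -> list:
        return self.entries["feature"].tolist()

    @property
    def coefficients(self) -> pd.Series:
        return self.entries.set_index("feature")["coefficient"]

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup = pd.Index(header)
    dup = dup[dup.duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"{path}: duplicate column identifiers: {dup}")
    return pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)


def read_expression(path, orientation: Orientation = "samples-in-rows") -> ExpressionMatrix:
    """Read an expression TSV (header row, identifier first column).

    ``orientation`` says whether rows are samples (default) or features;
    the result is always samples-in-rows.
    """
    raw = _read_tsv(path)
    dup_r = _duplicates(raw.index)
    if dup_r:
        raise ValidationError(f"{path}: duplicate row identifiers: {dup_r}")
    dup_c = _duplicates(raw.columns)
    if dup_c:
        raise ValidationError(f"{path}: duplicate column identifiers: {dup_c}")
    if orientation == "features-in-rows":
        raw = raw.T
    elif orientation != "samples-in-rows":
        raise ValueError(f"unknown orientation: {orientation!r}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric cell at row {raw.index[r]!r}, "
            f"column {raw.columns[c]!r}: {raw.iat[r, c]!r}"
        )
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: missing expression value at row {raw.index[r]!r}, "
            f"column {raw.columns[c]!r}"
        )
    numeric.index.name = None
    numeric.columns.name = None
    return ExpressionMatrix(numeric)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="sample")


def read_survival(path, time_col: str = "time", status_col: str = "status") -> SurvivalTable:
    """Read a survival TSV; extra columns are kept as clinical covariates."""
    raw = _read_tsv(path)
    for col in (time_col, status_col):
        if col not in raw.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    time = pd.to_numeric(raw[time_col], errors="coerce")
    status = pd.to_numeric(raw[status_col], errors="coerce")
    extra = raw.drop(columns=[time_col, status_col])
    covariates = None
    if not extra.empty:
        covariates = extra.apply(_maybe_numeric)
    st = SurvivalTable(
        time.rename("time"), status.rename("status").astype("Int64").astype(float), covariates
    )
    return st


def _maybe_numeric(col: pd.Series) -> pd.Series:
    converted = pd.to_numeric(col, errors="coerce")
    if converted.notna().sum() == col.notna().sum():
        return converted
    return col


def write_survival(surv: SurvivalTable, path) -> None:
    surv.frame().to_csv(path, sep="\t", index_label="sample")


def read_signature(path) -> Signature:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", header=0)
    for col in ("feature", "coefficient"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    coef = pd.to_numeric(df["coefficient"], errors="coerce")
    if coef.isna().any():
        bad = df["feature"][coef.isna()].tolist()[:5]
        raise ValidationError(f"{path}: non-numeric coefficient for {bad}")
    df["coefficient"] = coef
    if "times_sampled" not in df.columns:
        df["times_sampled"] = 1
    if "times_nonzero" not in df.columns:
        df["times_nonzero"] = (coef != 0).astype(int)
    return Signature(
        df[["feature", "coefficient", "times_sampled", "times_nonzero"]].copy()
    )


def write_signature(sig: Signature, path) -> None:
    sig.entries.to_csv(path, sep="\t", index=False)


def align(expr: ExpressionMatrix, surv: SurvivalTable) -> tuple[ExpressionMatrix, SurvivalTable]:
    """Inner-join the two tables on sample identifier.

    Samples present in only one table are dropped with a logged warning.
    The joined tables are returned in sorted sample order so results do not
    depend on input row order.
    """
    common = sorted(set(expr.sample_ids) & set(surv.sample_ids))
    if not common:
        raise ValidationError("expression and survival tables share no samples")
    dropped = (set(expr.sample_ids) | set(surv.sample_ids)) - set(common)
    if dropped:
        logger.warning(
            "dropping %d sample(s) absent from one table: %s",
            len(dropped), sorted(dropped)[:10],
        )
    return expr.subset_samples(common), surv.subset_samples(common)
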