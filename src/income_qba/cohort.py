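"""Cohort data model: record schema, validation, cross-tabulations, and I/O.

The package's bulk container for a cohort is a :class:`pandas.DataFrame`
with the columns in :data:`COHORT_COLUMNS`.  Exposure quintiles are coded
1..5 with 1 = lowest income and 5 = highest income; the outcome stratum is
coded 0 = survived 5 years, 1 = died within 5 years.  :class:`CohortRecord`
is the typed row view used for record-level construction and tests.

A :class:`CrossTab` holds the observed-by-true quintile counts within each
outcome stratum — the shape in which validation data are published — and can
be expanded into a record-level cohort (and back) so that every downstream
step runs identically on printed counts and on microdata.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

QUINTILES = (1, 2, 3, 4, 5)
STRATUM_SURVIVED = 0
STRATUM_DIED = 1
STRATA = (STRATUM_SURVIVED, STRATUM_DIED)

#: canonical cohort column order
COHORT_COLUMNS = ("id", "observed_q", "true_q", "died_5y", "age", "sex", "rural", "region")

#: columns required for covariate-adjusted models
COVARIATE_COLUMNS = ("age", "sex", "rural")


class CohortValidationError(ValueError):
    """Raised when cohort records or cross-tabulated counts are invalid."""


@dataclass(frozen=True)
class CohortRecord:
    """One person: observed (and optionally true) income quintile, outcome, covariates."""

    id: object
    observed_q: int
    died_5y: int
    true_q: int | None = None
    age: float | None = None
    sex: int | None = None
    rural: int | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        if self.observed_q not in QUINTILES:
            raise CohortValidationError(f"observed_q must be in 1..5, got {self.observed_q!r}")
        if self.true_q is not None and self.true_q not in QUINTILES:
            raise CohortValidationError(f"true_q must be in 1..5 or None, got {self.true_q!r}")
        if self.died_5y not in (0, 1):
            raise CohortValidationError(f"died_5y must be 0/1, got {self.died_5y!r}")
        if self.age is not None and not self.age > 0:
            raise CohortValidationError(f"age must be positive, got {self.age!r}")


def records_to_frame(records: Iterable[CohortRecord]) -> pd.DataFrame:
    """Assemble :class:`CohortRecord` objects into the canonical DataFrame."""
    rows = [
        (r.id, r.observed_q, r.true_q, r.died_5y, r.age, r.sex, r.rural, r.region)
        for r in records
    ]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def validate_cohort(df: pd.DataFrame, require_true: bool = False,
                    require_covariates: bool = False) -> pd.DataFrame:
    """Validate a cohort DataFrame against the schema; returns the frame unchanged.

    Raises :class:`CohortValidationError` naming offending rows/columns.
    """
    for col in ("observed_q", "died_5y"):
        if col not in df.columns:
            raise CohortValidationError(f"missing required column {col!r}")
    bad = df.index[~df["observed_q"].isin(QUINTILES)]
    if len(bad):
        raise CohortValidationError(
            f"observed_q outside 1..5 in rows {list(bad[:10])} "
            f"(values {df.loc[bad[:10], 'observed_q'].tolist()})"
        )
    bad = df.index[~df["died_5y"].isin((0, 1))]
    if len(bad):
        raise CohortValidationError(f"died_5y not 0/1 in rows {list(bad[:10])}")
    if "true_q" in df.columns:
        present = df["true_q"].notna()
        bad = df.index[present & ~df["true_q"].isin(QUINTILES)]
        if len(bad):
            raise CohortValidationError(
                f"true_q outside 1..5 in rows {list(bad[:10])} "
                f"(values {df.loc[bad[:10], 'true_q'].tolist()})"
            )
    if require_true:
        if "true_q" not in df.columns:
            raise CohortValidationError("true_q column required but absent")
        missing = df.index[df["true_q"].isna()]
        if len(missing):
            raise CohortValidationError(
                f"true_q missing for records {list(missing[:10])}"
                + ("..." if len(missing) > 10 else "")
            )
    if require_covariates:
        for col in COVARIATE_COLUMNS:
            if col not in df.columns or df[col].isna().any():
                raise CohortValidationError(
                    f"covariate {col!r} absent or incomplete; covariate-adjusted "
                    "operations cannot run on records expanded from printed counts"
                )
        if (df["age"] <= 0).any():
            raise CohortValidationError("age must be positive")
    return df


@dataclass(frozen=True)
class CrossTab:
    """Observed-by-true quintile counts per outcome stratum.

    ``counts[y, j-1, k-1]`` is the number of people in outcome stratum ``y``
    (0 = survived, 1 = died) with observed quintile ``j`` and true quintile
    ``k``.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (2, 5, 5):
            raise CohortValidationError(f"counts must be 2x5x5, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                raise CohortValidationError("counts must be integers")
            arr = arr.astype(np.int64)
        if (arr < 0).any():
            raise CohortValidationError("counts must be non-negative")
        object.__setattr__(self, "counts", arr.astype(np.int64))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CrossTab) and np.array_equal(self.counts, other.counts)

    def stratum(self, y: int) -> np.ndarray:
        """5x5 observed-by-true counts for outcome stratum ``y``."""
        return self.counts[y]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with columns stratum, observed_q, true_q, count."""
        y, j, k = np.meshgrid(STRATA, QUINTILES, QUINTILES, indexing="ij")
        return pd.DataFrame({
            "stratum": y.ravel(),
            "observed_q": j.ravel(),
            "true_q": k.ravel(),
            "count": self.counts.ravel(),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CrossTab":
        counts = np.zeros((2, 5, 5), dtype=np.int64)
        for _, row in df.iterrows():
            counts[int(row["stratum"]), int(row["observed_q"]) - 1,
                   int(row["true_q"]) - 1] = int(row["count"])
        return cls(counts)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CrossTab":
        return cls.from_frame(pd.read_csv(path))


def expand_crosstab(tab: CrossTab) -> pd.DataFrame:
    """Expand cross-tabulated counts into one record per counted person.

    The returned cohort has ``observed_q``, ``true_q`` and ``died_5y`` set and
    all covariates absent (NaN): printed validation tables carry no
    individual covariate information, and downstream covariate-adjusted
    operations refuse such records rather than imputing.
    """
    reps = tab.counts.ravel()
    y, j, k = np.meshgrid(STRATA, QUINTILES, QUINTILES, indexing="ij")
    observed = np.repeat(j.ravel(), reps)
    true = np.repeat(k.ravel(), reps)
    died = np.repeat(y.ravel(), reps)
    df = pd.DataFrame({
        "id": np.arange(observed.size),
        "observed_q": observed.astype(np.int64),
        "true_q": true.astype(np.int64),
        "died_5y": died.astype(np.int64),
        "age": np.nan,
        "sex": np.nan,
        "rural": np.nan,
        "region": None,
    })
    return df


def tabulate(records: pd.DataFrame) -> CrossTab:
    """Cross-tabulate a cohort with known true exposure; inverse of expansion."""
    validate_cohort(records, require_true=True)
    counts = np.zeros((2, 5, 5), dtype=np.int64)
    grouped = records.groupby(["died_5y", "observed_q", "true_q"]).size()
    for (y, j, k), n in grouped.items():
        counts[int(y), int(j) - 1, int(k) - 1] = n
    return CrossTab(counts)


_DEFAULT_MAPPING = {c: c for c in COHORT_COLUMNS}


def read_cohort(path: str | Path,
                column_mapping: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a delimited cohort file, validating codes.

    ``column_mapping`` maps canonical names (``observed_q``, ``died_5y``, ...)
    to the file's column headers; unmapped optional columns are treated as
    absent.  Invalid category codes raise with the offending row numbers
    (1-based, excluding the header).
    """
    mapping = dict(_DEFAULT_MAPPING)
    if column_mapping:
        mapping.update(column_mapping)
    raw = pd.read_csv(path)
    for canonical in ("observed_q", "died_5y"):
        if mapping[canonical] not in raw.columns:
            raise CohortValidationError(
                f"required column {mapping[canonical]!r} (for {canonical!r}) "
                f"not found in {path}"
            )
    df = pd.DataFrame(index=raw.index)
    for canonical in COHORT_COLUMNS:
        src = mapping.get(canonical)
        df[canonical] = raw[src] if src in raw.columns else (
            None if canonical in ("id", "region") else np.nan
        )
    if df["id"].isna().all():
        df["id"] = np.arange(len(df))
    for col in ("observed_q", "true_q"):
        vals = df[col]
        present = vals.notna()
        numeric = pd.to_numeric(vals[present], errors="coerce")
        nonint = numeric.isna() | (numeric != numeric.round())
        bad_rows = (vals[present].index[nonint | ~numeric.isin(QUINTILES)] + 1).tolist()
        if bad_rows:
            raise CohortValidationError(
                f"column {col!r}: invalid quintile codes at data rows {bad_rows[:10]}"
            )
        df.loc[present, col] = numeric.astype(np.int64)
    validate_cohort(df)
    return df


def write_cohort(records: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort DataFrame as CSV with canonical columns."""
    out = records.reindex(columns=COHORT_COLUMNS)
    out.to_csv(path, index=False)
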