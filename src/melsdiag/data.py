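"""Long-format data container and design-matrix assembly.

Intensive longitudinal data (EMA diaries, daily logs, activity monitors)
arrive as one row per subject-visit: a subject label, a continuous
response, and time-varying covariates that may enter the mean (location)
model, the within-subject variance (scale) model, or both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LongDataset",
    "StandardizationRecord",
    "read_long_csv",
    "standardize_covariate",
    "build_design",
]


class ConfigurationError(ValueError):
    """A requested column or option does not match the data."""


@dataclass(frozen=True)
class StandardizationRecord:
    """Mean/SD used to z-score a covariate; invertible transform."""

    column: str
    mean: float
    std: float

    def __post_init__(self) -> None:
        if not self.std > 0:
            raise ValueError(f"standardization SD for {self.column!r} must be > 0")

    def inverse(self, values: np.ndarray) -> np.ndarray:
        """Map standardized values back to the original scale."""
        return np.asarray(values) * self.std + self.mean


@dataclass
class LongDataset:
    """Long-format observations grouped by subject.

    Parameters
    ----------
    df : DataFrame with one row per subject-visit.
    subject_col : name of the subject identifier column.
    response_col : name of the continuous response column.

    Rows need not be contiguous by subject; subjects are indexed in
    order of first appearance and row order within subject is preserved.
    """

    df: pd.DataFrame
    subject_col: str = "subject"
    response_col: str = "y"
    standardizations: dict[str, StandardizationRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in (self.subject_col, self.response_col):
            if col not in self.df.columns:
                raise ConfigurationError(f"column {col!r} not found in data")
        y = self.df[self.response_col].to_numpy()
        if not np.issubdtype(np.asarray(y).dtype, np.number):
            bad = self.df.index[
                pd.to_numeric(self.df[self.response_col], errors="coerce").isna()
            ]
            raise ValueError(
                f"non-numeric response in column {self.response_col!r}, "
                f"first offending row index: {bad[0] if len(bad) else '?'}"
            )
        if not np.all(np.isfinite(y.astype(float))):
            raise ValueError("response contains non-finite values")
        # subject codes in order of first appearance
        subj = self.df[self.subject_col]
        self._subject_ids = list(dict.fromkeys(subj.tolist()))
        code_of = {s: k for k, s in enumerate(self._subject_ids)}
        self._codes = subj.map(code_of).to_numpy(dtype=np.int64)

    # -- basic properties ------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self._subject_ids)

    @property
    def subject_ids(self) -> list:
        return list(self._subject_ids)

    @property
    def subject_codes(self) -> np.ndarray:
        """Integer code per row, 0..N-1 in order of first appearance."""
        return self._codes

    @property
    def n_obs(self) -> int:
        return len(self.df)

    @property
    def obs_per_subject(self) -> np.ndarray:
        return np.bincount(self._codes, minlength=self.n_subjects)

    @property
    def y(self) -> np.ndarray:
        return self.df[self.response_col].to_numpy(dtype=float)

    def covariate(self, column: str) -> np.ndarray:
        if column not in self.df.columns:
            raise ConfigurationError(f"column {column!r} not found in data")
        return self.df[column].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def read_long_csv(
    path,
    subject_col: str = "subject",
    response_col: str = "y",
    covariate_cols: list[str] | None = None,
) -> LongDataset:
    """Read a long-format CSV (header row required) into a LongDataset.

    Rows with a missing value in any mapped column are dropped with a
    logged count; analyses use complete observations only.
    """
    df = pd.read_csv(path)
    needed = [subject_col, response_col] + list(covariate_cols or [])
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing mapped column(s) in {path}: {missing}")
    n0 = len(df)
    df = df.dropna(subset=needed).reset_index(drop=True)
    if len(df) < n0:
        logger.info("dropped %d incomplete row(s) while reading %s", n0 - len(df), path)
    resp = pd.to_numeric(df[response_col], errors="coerce")
    if resp.isna().any():
        row = int(df.index[resp.isna()][0])
        raise ValueError(f"non-numeric response at data row {row} of {path}")
    df[response_col] = resp
    return LongDataset(df, subject_col=subject_col, response_col=response_col)


def standardize_covariate(
    data: LongDataset, column: str
) -> tuple[LongDataset, StandardizationRecord]:
    """Z-score a covariate over all retained observations (pooled).

    Returns a new dataset with the column replaced by its z-score and a
    record holding the mean/SD so the transform can be inverted.
    """
    x = data.covariate(column)
    mean = float(np.mean(x))
    std = float(np.std(x, ddof=1))
    if not std > 0:
        raise ValueError(f"covariate {column!r} is degenerate (zero SD)")
    rec = StandardizationRecord(column=column, mean=mean, std=std)
    df = data.df.copy()
    df[column] = (x - mean) / std
    out = LongDataset(
        df,
        subject_col=data.subject_col,
        response_col=data.response_col,
        standardizations={**data.standardizations, column: rec},
    )
    return out, rec


def build_design(
    data: LongDataset,
    location_cols: list[str] | None,
    scale_cols: list[str] | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble location and scale design matrices with leading intercepts.

    Returns (X, W): X is n_obs x (1+p), W is n_obs x (1+r); the first
    column of each is all ones.
    """
    n = data.n_obs
    ones = np.ones((n, 1))
    loc = [ones] + [data.covariate(c)[:, None] for c in (location_cols or [])]
    sca = [ones] + [data.covariate(c)[:, None] for c in (scale_cols or [])]
    return np.hstack(loc), np.hstack(sca)
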