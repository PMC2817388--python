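"""Raw percent/count table -> binary analysis matrix and binary outcome.

Every predictor is dichotomised a priori at the median of its observed
values (1 iff strictly greater), remaining missing cells are singly
imputed with the most common observed value, and the outcome is the
indicator of a week-36 CD4 count strictly above 450 cells/uL.  The
outcome is never imputed: subjects missing it are dropped (and logged).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import CD4_WEEK36

__all__ = [
    "EmptyColumnError",
    "MissingOutcomeError",
    "AnalysisMatrix",
    "OutcomeVector",
    "average_replicates",
    "dichotomize_at_median",
    "impute_mode",
    "dichotomize_outcome",
    "build_analysis_matrix",
]

CD4_THRESHOLD = 450.0


class EmptyColumnError(ValueError):
    """A column with no observed values cannot be dichotomised/imputed."""


class MissingOutcomeError(ValueError):
    """Raised when the outcome column is absent or entirely missing."""


@dataclass
class AnalysisMatrix:
    """n x p binary design matrix with its dichotomisation provenance.

    ``medians`` records the observed-value median used per column;
    ``imputations`` logs every (row, column, imputed value) triple.
    """

    X: pd.DataFrame
    medians: dict[str, float]
    imputations: list[tuple[int, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = self.X.to_numpy()
        if np.isnan(arr.astype(float)).any():
            raise ValueError("analysis matrix must have no missing entries")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("analysis matrix entries must be 0/1")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def variable_names(self) -> list[str]:
        return list(self.X.columns)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.X.to_csv(path, index=False)
        sidecar = path.with_suffix(".meta.json")
        with open(sidecar, "w") as fh:
            json.dump(
                {
                    "medians": self.medians,
                    "imputations": [list(t) for t in self.imputations],
                },
                fh,
                indent=1,
            )


@dataclass
class OutcomeVector:
    """Binary response: 1 iff CD4 count > 450 cells/uL at week 36."""

    y: np.ndarray
    threshold: float = CD4_THRESHOLD

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("outcome values must be 0/1")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def n_responders(self) -> int:
        return int(self.y.sum())


def average_replicates(acquisitions: np.ndarray | list) -> np.ndarray:
    """Average replicate acquisitions per subject, ignoring missing ones.

    ``acquisitions`` is (n_replicates, n_subjects); a subject with no
    observed acquisition yields NaN (treated as missing downstream, not an
    error).
    """
    import warnings

    arr = np.asarray(acquisitions, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    with warnings.catch_warnings():
        # all-missing subjects legitimately yield NaN, not an error
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmean(arr, axis=0)
    return out


def dichotomize_at_median(column: np.ndarray | pd.Series) -> tuple[np.ndarray, float]:
    """1 iff strictly greater than the median of observed values.

    Missing stays missing (NaN).  Ties at the median map to 0 — the
    strictly-greater rule.  Returns (binary column with NaN, median).
    """
    col = np.asarray(column, dtype=float)
    observed = col[~np.isnan(col)]
    if observed.size == 0:
        raise EmptyColumnError("cannot dichotomise an all-missing column")
    med = float(np.median(observed))
    out = np.where(np.isnan(col), np.nan, (col > med).astype(float))
    return out, med


def impute_mode(column: np.ndarray | pd.Series) -> tuple[np.ndarray, list[int]]:
    """Fill missing binary cells with the most common observed value.

    An exact 0/1 tie among observed values imputes 0.  Returns the filled
    column and the imputed row indices.
    """
    col = np.asarray(column, dtype=float)
    miss = np.isnan(col)
    observed = col[~miss]
    if observed.size == 0:
        raise EmptyColumnError("cannot impute an all-missing column")
    ones = int(observed.sum())
    fill = 1.0 if ones > observed.size - ones else 0.0
    out = np.where(miss, fill, col)
    return out, [int(i) for i in np.flatnonzero(miss)]


def dichotomize_outcome(cd4_week36: np.ndarray | pd.Series) -> OutcomeVector:
    """Indicator of CD4 count strictly greater than 450 cells/uL."""
    arr = np.asarray(cd4_week36, dtype=float)
    if np.isnan(arr).any():
        raise MissingOutcomeError("outcome contains missing values")
    if (arr < 0).any():
        raise ValueError("CD4 counts must be nonnegative")
    return OutcomeVector(y=(arr > CD4_THRESHOLD).astype(int))


def build_analysis_matrix(
    raw: pd.DataFrame,
    outcome_column: str = CD4_WEEK36,
    drop_missing_outcome: bool = True,
) -> tuple[AnalysisMatrix, OutcomeVector, list[int]]:
    """Full preprocessing of a raw table containing the outcome column.

    Returns the binary matrix over all non-outcome columns, the binary
    outcome, and the row indices dropped for a missing outcome.
    """
    if outcome_column not in raw.columns:
        raise MissingOutcomeError(f"outcome column {outcome_column!r} not found")
    out_raw = raw[outcome_column].to_numpy(dtype=float)
    dropped: list[int] = []
    keep = ~np.isnan(out_raw)
    if not keep.all():
        if not drop_missing_outcome:
            raise MissingOutcomeError("outcome contains missing values")
        dropped = list(np.flatnonzero(~keep))
    raw = raw.loc[keep].reset_index(drop=True)

    predictors = [c for c in raw.columns if c != outcome_column]
    cols: dict[str, np.ndarray] = {}
    medians: dict[str, float] = {}
    imputations: list[tuple[int, str, int]] = []
    for name in predictors:
        binary, med = dichotomize_at_median(raw[name])
        filled, rows = impute_mode(binary)
        cols[name] = filled.astype(int)
        medians[name] = med
        imputations.extend((r, name, int(filled[r])) for r in rows)

    X = pd.DataFrame(cols, columns=predictors)
    matrix = AnalysisMatrix(X=X, medians=medians, imputations=imputations)
    y = dichotomize_outcome(raw[outcome_column])
    return matrix, y, dropped
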