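"""Datasets, feature standardisation and outcome dichotomisation.

A :class:`LabelledDataset` couples a numeric feature matrix with a numeric
outcome, a dichotomisation threshold and the derived binary outcome.
Features are standardised (zero mean, unit variance) before any penalised
fit; the :class:`StandardisationState` captures the affine transform so it
can be replayed on new data at prediction time.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

DIRECTIONS = ("gt", "le")

#: columns whose sample standard deviation falls below this are treated as
#: constant and excluded from modelling
_ZERO_SD_TOL = 1e-12


def dichotomise(y: np.ndarray, c: float, direction: str = "gt") -> np.ndarray:
    """Convert a numeric outcome to 0/1 classes at threshold ``c``.

    ``direction="gt"`` assigns class 1 where ``y > c`` (strict inequality,
    so ``y == c`` falls in class 0); ``direction="le"`` assigns class 1
    where ``y <= c``.
    """
    y = np.asarray(y, dtype=float)
    if not np.isfinite(c):
        raise ValueError("threshold c must be finite")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    if direction == "gt":
        return (y > c).astype(np.int64)
    return (y <= c).astype(np.int64)


@dataclass
class StandardisationState:
    """Column means/sds of the training matrix plus dropped (constant) columns.

    ``means`` and ``sds`` have length p (original column count); ``sds`` of
    dropped columns are recorded as observed but never used as divisors.
    """

    means: np.ndarray
    sds: np.ndarray
    dropped_columns: np.ndarray

    @property
    def n_features_in(self) -> int:
        return self.means.shape[0]

    @property
    def retained_columns(self) -> np.ndarray:
        mask = np.ones(self.n_features_in, dtype=bool)
        mask[self.dropped_columns] = False
        return np.flatnonzero(mask)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Apply the training-set affine transform; returns retained columns only."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in:
            raise ValueError(
                f"expected {self.n_features_in} feature columns, got {X.shape[1]}"
            )
        keep = self.retained_columns
        return (X[:, keep] - self.means[keep]) / self.sds[keep]

    def inverse_transform(self, Xstd: np.ndarray) -> np.ndarray:
        """Reconstruct the original-scale matrix (dropped columns as constants)."""
        Xstd = np.asarray(Xstd, dtype=float)
        keep = self.retained_columns
        if Xstd.shape[1] != keep.shape[0]:
            raise ValueError("column count does not match retained features")
        out = np.tile(self.means, (Xstd.shape[0], 1))
        out[:, keep] = Xstd * self.sds[keep] + self.means[keep]
        return out


def standardise(X: np.ndarray) -> tuple[np.ndarray, StandardisationState]:
    """Standardise columns to zero mean and unit variance (n-1 denominator).

    Zero-variance columns are dropped from the returned matrix and recorded
    in ``state.dropped_columns``. Raises if every column is constant.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-d matrix")
    if X.shape[0] < 2:
        raise ValueError("standardisation needs at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains missing or non-finite values")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    dropped = np.flatnonzero(sds <= _ZERO_SD_TOL)
    if dropped.shape[0] == X.shape[1]:
        raise ValueError("no informative features")
    state = StandardisationState(means=means, sds=sds, dropped_columns=dropped)
    return state.transform(X), state


@dataclass
class LabelledDataset:
    """Feature matrix, numeric outcome, threshold and derived binary outcome."""

    X: np.ndarray
    y: np.ndarray
    c: float
    direction: str = "gt"
    feature_names: Optional[Sequence[str]] = None
    z: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-d matrix")
        if self.y.ndim != 1 or self.y.shape[0] != self.X.shape[0]:
            raise ValueError("y must be a vector with one entry per row of X")
        if self.X.shape[0] < 1:
            raise ValueError("empty dataset")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains missing or non-finite values")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y contains missing or non-finite values")
        if self.feature_names is not None:
            self.feature_names = list(self.feature_names)
            if len(self.feature_names) != self.X.shape[1]:
                raise ValueError("feature_names length does not match X")
        self.z = dichotomise(self.y, self.c, self.direction)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def has_both_classes(self) -> bool:
        return bool(self.z.min() == 0 and self.z.max() == 1)

    def require_both_classes(self) -> None:
        if not self.has_both_classes():
            raise ValueError(
                "binary outcome is single-class after dichotomisation; "
                "fitting requires both classes"
            )

    def subset(self, idx: np.ndarray) -> "LabelledDataset":
        return LabelledDataset(
            X=self.X[idx],
            y=self.y[idx],
            c=self.c,
            direction=self.direction,
            feature_names=self.feature_names,
        )


def _delimiter_for(path: str, delimiter: Optional[str]) -> str:
    if delimiter is not None:
        return delimiter
    ext = os.path.splitext(path)[1].lower()
    return "\t" if ext in (".tsv", ".tab", ".txt") else ","


def load_features(path: str, delimiter: Optional[str] = None) -> pd.DataFrame:
    """Read a feature table: header row of names, one row per sample."""
    return pd.read_csv(path, sep=_delimiter_for(path, delimiter))


def load_dataset(
    features_path: str,
    c: float,
    outcome_column: Optional[str] = None,
    outcome_path: Optional[str] = None,
    direction: str = "gt",
    delimiter: Optional[str] = None,
) -> LabelledDataset:
    """Build a :class:`LabelledDataset` from CSV/TSV files.

    The outcome is either a named column of the feature table
    (``outcome_column``) or a separate single-column file (``outcome_path``).
    The delimiter is inferred from the extension unless given explicitly.
    """
    table = load_features(features_path, delimiter)
    if (outcome_column is None) == (outcome_path is None):
        raise ValueError("give exactly one of outcome_column or outcome_path")
    if outcome_column is not None:
        if outcome_column not in table.columns:
            raise ValueError(f"outcome column {outcome_column!r} not in feature table")
        y = table[outcome_column].to_numpy(dtype=float)
        table = table.drop(columns=[outcome_column])
    else:
        ytab = pd.read_csv(outcome_path, sep=_delimiter_for(outcome_path, delimiter))
        if ytab.shape[1] != 1:
            raise ValueError("outcome file must contain exactly one column")
        y = ytab.iloc[:, 0].to_numpy(dtype=float)
    return LabelledDataset(
        X=table.to_numpy(dtype=float),
        y=y,
        c=c,
        direction=direction,
        feature_names=list(table.columns),
    )
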