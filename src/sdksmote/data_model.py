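"""Core dataset container and class-balance accounting.

An imbalanced binary dataset is a numeric feature matrix with a categorical
label vector holding exactly two distinct values.  The *minority* label is
always declared by the caller — real datasets label their rare class with
strings ("die", "imU") or integers interchangeably, so nothing is inferred
from the label values themselves.

The balance (equilibrium) rate of a dataset is

    E = l / m

where ``l`` is the minority count and ``m`` the majority count.  ``E`` close
to 1 means the classes are nearly balanced; oversampling raises ``E`` toward
a caller-chosen target ``E'``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "BalanceReport",
    "validate_dataset",
    "balance_report",
    "read_csv_dataset",
]


@dataclass(frozen=True)
class LabeledDataset:
    """A validated binary-labelled feature table.

    Attributes
    ----------
    features : (n_samples, n_features) float ndarray
        Dense real-valued feature matrix. Integer input is promoted to float
        because every downstream step is Euclidean geometry on reals.
    labels : (n_samples,) object ndarray
        Opaque categorical labels; exactly two distinct values present.
    minority_label : Any
        The declared minority class; must occur in ``labels`` and be no more
        frequent than the other class.
    feature_names : tuple of str, optional
        Column names carried through from CSV input for round-tripping.
    """

    features: np.ndarray
    labels: np.ndarray
    minority_label: Any
    feature_names: tuple = field(default=None)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def minority_mask(self) -> np.ndarray:
        return self.labels == self.minority_label

    @property
    def majority_mask(self) -> np.ndarray:
        return ~self.minority_mask

    @property
    def majority_label(self) -> Any:
        other = self.labels[self.majority_mask]
        return other[0]

    @property
    def minority_count(self) -> int:
        return int(self.minority_mask.sum())

    @property
    def majority_count(self) -> int:
        return int(self.majority_mask.sum())

    @property
    def minority_indices(self) -> np.ndarray:
        return np.flatnonzero(self.minority_mask)

    @property
    def majority_indices(self) -> np.ndarray:
        return np.flatnonzero(self.majority_mask)

    def minority_features(self) -> np.ndarray:
        return self.features[self.minority_mask]

    def majority_features(self) -> np.ndarray:
        return self.features[self.majority_mask]


@dataclass(frozen=True)
class BalanceReport:
    """Class counts and the equilibrium rate E = l/m."""

    l: int
    m: int

    @property
    def E(self) -> float:
        return self.l / self.m

    @property
    def minority_fraction(self) -> float:
        """Minority share of the whole dataset, l/(l+m)."""
        return self.l / (self.l + self.m)

    def as_dict(self) -> dict:
        return {
            "l": self.l,
            "m": self.m,
            "E": self.E,
            "minority_fraction": self.minority_fraction,
        }


def validate_dataset(
    features,
    labels,
    minority_label,
    *,
    feature_names=None,
    allow_swap: bool = False,
) -> LabeledDataset:
    """Validate raw arrays into a :class:`LabeledDataset`.

    Raises
    ------
    ValueError
        On non-rectangular/non-finite features, length mismatch, more or
        fewer than two observed classes, an absent minority label, or a
        declared minority that outnumbers the other class (unless
        ``allow_swap=True``, in which case the roles are swapped with a
        warning — never silently).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D rectangular matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features: NaN or Inf values present")

    y = np.asarray(labels, dtype=object).ravel()
    if y.shape[0] != X.shape[0]:
        raise ValueError(
            f"labels length {y.shape[0]} does not match {X.shape[0]} feature rows"
        )

    classes = pd.unique(y)
    if len(classes) > 2:
        raise ValueError(
            f"unsupported multiclass: found {len(classes)} distinct labels"
        )
    if len(classes) < 2:
        raise ValueError("label not found: need two classes present")
    if minority_label not in classes:
        raise ValueError(f"label not found: {minority_label!r} absent from labels")

    n_min = int((y == minority_label).sum())
    n_maj = int(y.shape[0]) - n_min
    if n_min == 0 or n_maj == 0:
        raise ValueError("label not found: a class has zero samples")
    if n_min > n_maj:
        if not allow_swap:
            raise ValueError(
                f"declared minority {minority_label!r} has {n_min} samples, more "
                f"than the other class ({n_maj}); pass allow_swap=True to swap"
            )
        other = classes[classes != minority_label][0]
        warnings.warn(
            f"declared minority {minority_label!r} outnumbers {other!r}; "
            "swapping minority role",
            stacklevel=2,
        )
        minority_label = other

    names = tuple(feature_names) if feature_names is not None else None
    return LabeledDataset(X, y, minority_label, names)


def balance_report(dataset: LabeledDataset) -> BalanceReport:
    """Equilibrium rate report: E = l/m on exact integer counts."""
    return BalanceReport(l=dataset.minority_count, m=dataset.majority_count)


def read_csv_dataset(
    path,
    label_col: str,
    minority_label: str,
    *,
    delimiter: str = ",",
    allow_swap: bool = False,
) -> LabeledDataset:
    """Read a headered CSV into a dataset.

    The label column is selected by name and read as strings (so a shell
    argument like ``--minority-label 1`` matches a numeric-looking column);
    all remaining columns are parsed as numbers.
    """
    df = pd.read_csv(path, sep=delimiter)
    if label_col not in df.columns:
        raise ValueError(f"label column {label_col!r} not in header {list(df.columns)}")
    y = df[label_col].astype(str).to_numpy(dtype=object)
    feats = df.drop(columns=[label_col])
    try:
        X = feats.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric feature column: {exc}") from exc
    return validate_dataset(
        X, y, str(minority_label),
        feature_names=feats.columns, allow_swap=allow_swap,
    )
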