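"""Dataset preprocessing: strand augmentation, filtering, normalization,
response thresholding, oversampling and splitting.

Two input families are handled.  Labelled sequence sets (the binding-site
task) are augmented with the reverse, complement and reverse complement of
every record — exactly quadrupling the set, duplicates kept, labels
inherited.  Numeric feature tables (the recombination-frequency task) go
through: low-variance column removal, per-column min-max scaling to
[0, 1], thresholding of the response into binary labels, oversampling of
the minority class with replacement, and a seeded 4:1 train/validation
split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.model_selection import train_test_split
from sklearn.utils import check_random_state, resample

from .encoding import DnaSequence, _as_sequence

__all__ = [
    "LabelledSequenceSet",
    "reverse",
    "complement",
    "reverse_complement",
    "augment",
    "LowVarianceFilter",
    "low_variance_filter",
    "minmax_normalize",
    "MinMaxNormalizer",
    "binarize_by_threshold",
    "oversample_balance",
    "train_validation_split",
]


@dataclass
class LabelledSequenceSet:
    """Sequences with binary labels and a provenance tag per record."""

    records: list[tuple[DnaSequence, int]]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = [(_as_sequence(s), int(y)) for s, y in self.records]
        if not self.provenance:
            self.provenance = ["original"] * len(self.records)
        if len(self.provenance) != len(self.records):
            raise ValueError("provenance must align with records")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sequences(self) -> list[str]:
        return [s.bases for s, _ in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.asarray([y for _, y in self.records], dtype=int)


def reverse(seq) -> DnaSequence:
    return DnaSequence(_as_sequence(seq).bases[::-1])


def complement(seq) -> DnaSequence:
    return DnaSequence(str(Seq(_as_sequence(seq).bases).complement()))


def reverse_complement(seq) -> DnaSequence:
    return DnaSequence(str(Seq(_as_sequence(seq).bases).reverse_complement()))


def augment(data: LabelledSequenceSet) -> LabelledSequenceSet:
    """Originals plus reverse, complement and reverse-complement copies.

    Output has exactly ``4 * len(data)`` records (no deduplication, so a
    palindrome still contributes four records) and every derived record
    inherits its source label.
    """
    transforms = [
        ("original", lambda s: s),
        ("reverse", reverse),
        ("complement", complement),
        ("reverse_complement", reverse_complement),
    ]
    records: list[tuple[DnaSequence, int]] = []
    provenance: list[str] = []
    for tag, fn in transforms:
        for seq, label in data.records:
            records.append((fn(seq), label))
            provenance.append(tag)
    return LabelledSequenceSet(records=records, provenance=provenance)


class LowVarianceFilter(BaseEstimator, TransformerMixin):
    """Drop columns whose modal value covers more than a fraction of rows.

    A column is removed when its most frequent value accounts for
    *strictly* more than ``identical_fraction`` of the samples (default
    0.8, i.e. "over 80% of values the same"); a column at exactly the
    fraction is kept.

    Attributes
    ----------
    kept_features_ : list of column names that survive
    dropped_features_ : list of column names removed
    """

    def __init__(self, identical_fraction: float = 0.8):
        self.identical_fraction = identical_fraction

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        if X.shape[0] == 0:
            raise ValueError("cannot fit on an empty table")
        n = X.shape[0]
        dropped, kept = [], []
        for col in X.columns:
            mode_count = X[col].value_counts(dropna=False).iloc[0]
            if mode_count / n > self.identical_fraction:
                dropped.append(col)
            else:
                kept.append(col)
        if not kept:
            warnings.warn("all features dropped by low-variance filter")
        self.kept_features_ = kept
        self.dropped_features_ = dropped
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.kept_features_]


def low_variance_filter(
    table: pd.DataFrame,
    identical_fraction: float = 0.8,
    feature_columns: list[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Filter feature columns; non-feature columns pass through untouched.

    Returns the filtered table and the list of dropped column names.
    """
    cols = list(feature_columns) if feature_columns is not None else list(table.columns)
    flt = LowVarianceFilter(identical_fraction).fit(table[cols])
    keep = [c for c in table.columns if c not in set(flt.dropped_features_)]
    return table[keep], flt.dropped_features_


def minmax_normalize(
    table: pd.DataFrame, columns: list[str] | None = None
) -> pd.DataFrame:
    """Per-column linear rescaling (x - min) / (max - min) to [0, 1].

    Constant columns map to 0 with a warning — they should already have
    been removed by the low-variance filter.
    """
    out = table.copy()
    for col in columns if columns is not None else table.columns:
        x = out[col].astype(float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            warnings.warn(f"constant column {col!r} normalized to 0")
            out[col] = 0.0
        else:
            out[col] = (x - lo) / (hi - lo)
    return out


class MinMaxNormalizer(BaseEstimator, TransformerMixin):
    """Min-max scaler that freezes training-set extrema for later data."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.min_ = X.min(axis=0)
        self.range_ = X.max(axis=0) - self.min_
        self.constant_mask_ = self.range_ == 0
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        rng = np.where(self.constant_mask_, 1.0, self.range_)
        out = (X - self.min_) / rng
        out[:, self.constant_mask_] = 0.0
        return out


def binarize_by_threshold(response, threshold: float = 0.46) -> np.ndarray:
    """Label 1 where the (normalized) response strictly exceeds the threshold.

    The default 0.46 is the recombination-frequency cut separating active
    from inactive variants; ties fall to the negative class.
    """
    return (np.asarray(response, dtype=float) > threshold).astype(int)


def oversample_balance(
    table: pd.DataFrame, label_column: str, seed: int = 0
) -> pd.DataFrame:
    """Resample the minority class with replacement until classes balance.

    Majority-class rows are never discarded; minority rows are drawn with
    replacement (seeded) until the two class counts are equal.
    """
    counts = table[label_column].value_counts()
    if len(counts) < 2:
        raise ValueError("oversampling requires both classes present")
    if len(counts) > 2:
        raise ValueError("only binary labels are supported")
    minority_label = counts.idxmin()
    n_needed = counts.max() - counts.min()
    if n_needed == 0:
        return table.copy()
    minority = table[table[label_column] == minority_label]
    extra = resample(
        minority, replace=True, n_samples=n_needed, random_state=check_random_state(seed)
    )
    return pd.concat([table, extra], ignore_index=True)


def train_validation_split(
    table: pd.DataFrame, ratio: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded uniform 4:1 split; train size is ``floor(ratio * n)``.

    The two parts are disjoint and exhaustive.
    """
    if len(table) < 5:
        raise ValueError("need at least 5 samples to split 4:1")
    n_train = int(np.floor(ratio * len(table)))
    train, val = train_test_split(
        table, train_size=n_train, random_state=seed, shuffle=True
    )
    return train, val
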