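"""Combined binary encoding of short DNA sequences.

Each sequence of length ``L`` is represented as the concatenation of

* a positional one-hot block of length ``4 * L`` (A=1000, T=0100, C=0010,
  G=0001 per position), and
* a trinucleotide presence block of length ``4**3 = 64``: a stride-1
  window of width 3 is slid across the sequence and every observed
  triplet sets its indicator to 1 (presence, not count).

For the canonical 14-bp binding-site sequences this yields 56 + 64 = 120
binary features.  Triplet indices follow lexicographic order over
(A, C, G, T), so feature ``AAA`` is index 0 and ``TTT`` is index 63.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "DnaSequence",
    "EncodedVector",
    "InvalidAlphabetError",
    "one_hot_encode",
    "multibase_encode",
    "combined_encode",
    "kmer_names",
    "onehot_names",
    "combined_feature_names",
    "SequenceEncoder",
]

ALPHABET = ("A", "C", "G", "T")

# one-hot codes, in the order the rows are written out
_ONEHOT = {
    "A": (1, 0, 0, 0),
    "T": (0, 1, 0, 0),
    "C": (0, 0, 1, 0),
    "G": (0, 0, 0, 1),
}

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


class InvalidAlphabetError(ValueError):
    """Raised when a sequence contains a character outside {A, C, G, T}."""


def _clean(bases: str) -> str:
    """Uppercase, map RNA U->T with a warning, reject anything else."""
    s = str(bases).upper()
    if "U" in s:
        warnings.warn("RNA base U encountered; converting U -> T", stacklevel=3)
        s = s.replace("U", "T")
    for pos, ch in enumerate(s):
        if ch not in _ONEHOT:
            raise InvalidAlphabetError(
                f"invalid character {ch!r} at position {pos}; "
                f"sequences must be over {{A, C, G, T}}"
            )
    return s


@dataclass(frozen=True)
class DnaSequence:
    """A validated nucleotide string over {A, C, G, T}.

    Input is uppercased on ingest; ``U`` is converted to ``T`` with a
    warning; any other non-ACGT character is rejected.
    """

    bases: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", _clean(self.bases))

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases


@dataclass(frozen=True)
class EncodedVector:
    """One-hot block, trinucleotide block, and their concatenation."""

    onehot_block: np.ndarray
    multibase_block: np.ndarray
    combined: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "combined",
            np.concatenate([self.onehot_block, self.multibase_block]),
        )


def _as_sequence(seq) -> DnaSequence:
    return seq if isinstance(seq, DnaSequence) else DnaSequence(str(seq))


def one_hot_encode(seq) -> np.ndarray:
    """Encode each base as its 4-bit indicator; output length ``4 * L``.

    The popcount of the result is exactly ``L``: one bit per position.
    """
    s = _as_sequence(seq).bases
    out = np.zeros(4 * len(s), dtype=np.int8)
    for i, ch in enumerate(s):
        out[4 * i : 4 * i + 4] = _ONEHOT[ch]
    return out


def kmer_index(kmer: str) -> int:
    """Lexicographic index of a k-mer over (A, C, G, T)."""
    idx = 0
    for ch in kmer:
        idx = 4 * idx + _BASE_INDEX[ch]
    return idx


def multibase_encode(
    seq, window: int = 3, stride: int = 1, counts: bool = False
) -> np.ndarray:
    """Sliding-window k-mer indicator vector of length ``4**window``.

    Every k-mer observed in a width-``window`` frame advanced by
    ``stride`` sets its feature to 1 (or increments it when
    ``counts=True``); unobserved k-mers stay 0.
    """
    s = _as_sequence(seq).bases
    if window < 1 or window > len(s):
        raise ValueError(
            f"window must satisfy 1 <= window <= sequence length "
            f"({window} vs L={len(s)})"
        )
    if stride < 1:
        raise ValueError("stride must be >= 1")
    out = np.zeros(4**window, dtype=np.int32 if counts else np.int8)
    for start in range(0, len(s) - window + 1, stride):
        j = kmer_index(s[start : start + window])
        if counts:
            out[j] += 1
        else:
            out[j] = 1
    return out


def combined_encode(seq, window: int = 3, stride: int = 1) -> EncodedVector:
    """One-hot block followed by the k-mer presence block.

    For a 14-bp sequence with the default width-3 window the combined
    vector has 4*14 + 64 = 120 entries.
    """
    s = _as_sequence(seq)
    return EncodedVector(
        onehot_block=one_hot_encode(s),
        multibase_block=multibase_encode(s, window=window, stride=stride),
    )


def kmer_names(window: int = 3) -> list[str]:
    """All k-mers in lexicographic order over (A, C, G, T)."""
    return ["".join(p) for p in itertools.product(ALPHABET, repeat=window)]


def onehot_names(length: int) -> list[str]:
    """Column names ``oh_<pos>_<base>`` for the one-hot block."""
    order = ("A", "T", "C", "G")  # matches the bit order of the code table
    return [f"oh_{pos}_{b}" for pos in range(length) for b in order]


def combined_feature_names(length: int, window: int = 3) -> list[str]:
    return onehot_names(length) + kmer_names(window)


class SequenceEncoder(BaseEstimator, TransformerMixin):
    """Transform equal-length DNA strings into combined binary features.

    Parameters
    ----------
    window : int, default=3
        K-mer width for the multi-base block (3 mirrors the codon width).
    stride : int, default=1
        Step of the sliding frame.
    counts : bool, default=False
        Emit k-mer counts instead of presence indicators.

    Attributes
    ----------
    length_ : int
        Sequence length seen during fit; all inputs must match it.
    feature_names_ : list of str
        ``oh_<pos>_<base>`` columns followed by k-mer columns.
    """

    def __init__(self, window: int = 3, stride: int = 1, counts: bool = False):
        self.window = window
        self.stride = stride
        self.counts = counts

    def fit(self, X, y=None):
        seqs = [_as_sequence(s) for s in X]
        if not seqs:
            raise ValueError("cannot fit on an empty sequence collection")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"sequences must share one length, got {sorted(lengths)}")
        self.length_ = lengths.pop()
        if self.window > self.length_:
            raise ValueError("window exceeds sequence length")
        self.feature_names_ = combined_feature_names(self.length_, self.window)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "length_"):
            raise AttributeError("SequenceEncoder is not fitted")
        rows = []
        for s in X:
            seq = _as_sequence(s)
            if len(seq) != self.length_:
                raise ValueError(
                    f"sequence length {len(seq)} != fitted length {self.length_}"
                )
            rows.append(
                np.concatenate(
                    [
                        one_hot_encode(seq),
                        multibase_encode(
                            seq, self.window, self.stride, counts=self.counts
                        ),
                    ]
                )
            )
        return np.asarray(rows, dtype=float)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)
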