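"""Synthetic desk-scale datasets for both prediction tasks.

``simulate_tfbs`` emulates a binding-site collection: fixed-length
sequences (default 14 bp) where positives carry a degenerate consensus
motif (default the SP1 GC-box ``GGGCGG``) at a random offset, each motif
position mutated independently with a small probability, and negatives
are uniform random sequences screened against the exact consensus.

``simulate_attc`` emulates a recombination-site mutant library as a
numeric feature table: a handful of low-variance nuisance columns (one
value repeated in over 80% of rows, guaranteed to be caught by the
low-variance filter), a sparse set of informative standard-normal
columns, the rest pure noise, and a recombination-frequency response in
[0, 1] driven by a logistic function of the informative columns plus
Gaussian noise.  Column names mimic the folding-energy / positional
entropy / base-pairing-probability families of real structural feature
tables; only the statistical roles are emulated, not the thermodynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import ALPHABET, DnaSequence
from .prep import LabelledSequenceSet

__all__ = ["TfbsSimConfig", "AttcSimConfig", "simulate_tfbs", "simulate_attc"]


@dataclass
class TfbsSimConfig:
    """Planted-motif sequence generator settings."""

    n_positive: int = 300
    n_negative: int = 300
    length: int = 14
    motif: str = "GGGCGG"
    mutation_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.motif = DnaSequence(self.motif).bases
        if len(self.motif) > self.length:
            raise ValueError("motif longer than sequence length")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation probability must be in [0, 1]")


@dataclass
class AttcSimConfig:
    """Feature-table generator settings for the recombination task."""

    n_samples: int = 2000
    n_features: int = 292
    n_low_variance: int = 14
    n_informative: int = 10
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_low_variance + self.n_informative > self.n_features:
            raise ValueError(
                "n_low_variance + n_informative must not exceed n_features"
            )


def _random_seq(rng: np.random.RandomState, length: int) -> str:
    return "".join(rng.choice(ALPHABET, size=length))


def _mutate(rng: np.random.RandomState, motif: str, p: float) -> str:
    out = []
    for ch in motif:
        if rng.random_sample() < p:
            out.append(rng.choice([b for b in ALPHABET if b != ch]))
        else:
            out.append(ch)
    return "".join(out)


def simulate_tfbs(config: TfbsSimConfig) -> LabelledSequenceSet:
    """Generate labelled sequences with the motif planted in positives.

    Positives embed a per-position-mutated copy of the consensus at a
    uniform random offset inside otherwise random background; negatives
    are random sequences rejected while they contain the exact consensus.
    With ``mutation_prob = 0`` every positive contains the consensus
    verbatim.  Fully seeded: identical configs give identical sets.
    """
    rng = np.random.RandomState(config.seed)
    records: list[tuple[str, int]] = []
    k = len(config.motif)
    for _ in range(config.n_positive):
        background = _random_seq(rng, config.length)
        offset = rng.randint(0, config.length - k + 1)
        planted = _mutate(rng, config.motif, config.mutation_prob)
        seq = background[:offset] + planted + background[offset + k :]
        records.append((seq, 1))
    for _ in range(config.n_negative):
        seq = _random_seq(rng, config.length)
        while config.motif in seq:
            seq = _random_seq(rng, config.length)
        records.append((seq, 0))
    return LabelledSequenceSet(records=records)


def _attc_feature_names(n: int, rng: np.random.RandomState) -> list[str]:
    """Structural-feature-style column names (cosmetic only)."""
    fixed = ["Boltz_dG_u", "pfold", "MFE_freq_u", "dG_ratio_BOT_TOP_u"]
    names = list(fixed[: min(4, n)])
    pos = 0
    while len(names) < n:
        cycle = len(names) % 3
        if cycle == 0:
            names.append(f"pos_entr_{pos}_u")
        elif cycle == 1:
            i, j = pos, pos + rng.randint(10, 40)
            names.append(f"bp_proba_{i}_{j}_u")
        else:
            names.append(f"base_{pos}")
        pos += 1
    return names[:n]


def simulate_attc(config: AttcSimConfig) -> pd.DataFrame:
    """Generate the mutant-library-style feature table with its response.

    Returns a DataFrame with a ``sample_id`` column, the feature columns,
    and a ``response`` column in [0, 1].  The sidecar ground truth
    (informative / low-variance column names) is attached under
    ``df.attrs["ground_truth"]``.
    """
    rng = np.random.RandomState(config.seed)
    n, d = config.n_samples, config.n_features
    X = rng.normal(size=(n, d))

    # low-variance nuisance columns: one value in exactly 90% of rows,
    # strictly above the 80% filter cut regardless of n
    lv_idx = np.arange(config.n_low_variance)
    n_repeat = int(np.ceil(0.9 * n))
    for j in lv_idx:
        rows = rng.choice(n, size=n_repeat, replace=False)
        X[rows, j] = rng.normal()  # single repeated value per column

    info_idx = np.arange(config.n_low_variance, config.n_low_variance + config.n_informative)
    coefs = rng.uniform(0.5, 1.5, size=config.n_informative) * rng.choice(
        [-1, 1], size=config.n_informative
    )
    linear = X[:, info_idx] @ coefs
    response = 1.0 / (1.0 + np.exp(-linear))
    response = np.clip(response + rng.normal(scale=config.noise_sd, size=n), 0.0, 1.0)

    names = _attc_feature_names(d, rng)
    df = pd.DataFrame(X, columns=names)
    df.insert(0, "sample_id", [f"mut_{i:05d}" for i in range(n)])
    df["response"] = response
    df.attrs["ground_truth"] = {
        "low_variance_features": [names[j] for j in lv_idx],
        "informative_features": [names[j] for j in info_idx],
        "coefficients": coefs.tolist(),
        "seed": config.seed,
    }
    return df
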