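"""Baseline composition features: dipeptide composition and Chou's PseAAC.

Dipeptide composition is the 400-dimensional frequency vector of the
ordered adjacent residue pairs (L-1 overlapping pairs for a length-L
sequence), normalized to sum to one.

Pseudo-amino-acid composition (type I) augments the 20 residue
frequencies with lambda sequence-order correlation factors

    theta_j = 1/(L-j) * sum_i Theta(R_i, R_{i+j}),   j = 1..lambda

where Theta averages the squared differences of three standardized
physicochemical scales (hydrophobicity, hydrophilicity, side-chain
mass) between the two residues.  All 20 + lambda components share one
normalization,

    p_u = f_u / (sum f + w sum theta)       for u <= 20
    p_u = w theta_{u-20} / (sum f + w sum theta)   otherwise,

so the vector sums to one.  Defaults lambda = 20, w = 0.05.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from gcgrloc.io import STANDARD_AMINO_ACIDS

# Physicochemical scales indexed by residue, in STANDARD_AMINO_ACIDS
# (alphabetical) order.  Hydrophobicity: Tanford-style consensus values;
# hydrophilicity: Hopp-Woods; side-chain mass in daltons.  These are the
# scales conventionally used for type-I pseudo-amino-acid composition.
_HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
    "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
    "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
    "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
}
_HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
    "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
    "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
    "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
}
_SIDE_CHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0,
    "G": 1.0, "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0,
    "M": 75.0, "N": 58.0, "P": 42.0, "Q": 72.0, "R": 101.0,
    "S": 31.0, "T": 45.0, "V": 43.0, "W": 130.0, "Y": 107.0,
}

DIPEPTIDES = tuple(a + b for a, b in itertools.product(STANDARD_AMINO_ACIDS, repeat=2))
_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AMINO_ACIDS)}
_DP_INDEX = {dp: i for i, dp in enumerate(DIPEPTIDES)}


def _standardize(scale: dict[str, float]) -> np.ndarray:
    """Zero-mean, unit-variance (population) normalization over the 20 residues."""
    v = np.array([scale[aa] for aa in STANDARD_AMINO_ACIDS])
    return (v - v.mean()) / v.std()

_SCALES = np.stack([
    _standardize(_HYDROPHOBICITY),
    _standardize(_HYDROPHILICITY),
    _standardize(_SIDE_CHAIN_MASS),
])  # shape (3, 20)


@dataclass(frozen=True)
class FeatureVector:
    """Named real-valued features for one protein."""

    id: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("names and values must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.values)


def dipeptide_composition(sequence: str, record_id: str = "") -> FeatureVector:
    """Frequencies of the 400 ordered adjacent residue pairs (sum to 1)."""
    seq = sequence.upper()
    if len(seq) < 2:
        raise ValueError("dipeptide composition needs a sequence of length >= 2")
    counts = np.zeros(400)
    for i in range(len(seq) - 1):
        counts[_DP_INDEX[seq[i : i + 2]]] += 1
    values = counts / counts.sum()
    names = tuple(f"dp_{dp}" for dp in DIPEPTIDES)
    return FeatureVector(id=record_id, names=names, values=values)


def pseaac(
    sequence: str,
    lam: int = 20,
    weight: float = 0.05,
    record_id: str = "",
) -> FeatureVector:
    """Type-I pseudo-amino-acid composition of length 20 + ``lam``.

    ``lam`` = 0 degenerates to plain amino-acid composition.  Raises
    ``ValueError`` when the sequence is not longer than ``lam``.
    """
    seq = sequence.upper()
    L = len(seq)
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if L <= lam:
        raise ValueError(f"sequence length {L} must exceed lambda={lam}")
    if not 0 < weight < 1:
        raise ValueError("weight must lie in (0, 1)")
    idx = np.array([_AA_INDEX[aa] for aa in seq])
    freqs = np.bincount(idx, minlength=20) / L
    thetas = np.empty(lam)
    for j in range(1, lam + 1):
        diffs = _SCALES[:, idx[:-j]] - _SCALES[:, idx[j:]]
        thetas[j - 1] = float(np.mean(diffs**2, axis=0).mean())
    denom = freqs.sum() + weight * thetas.sum()
    values = np.concatenate([freqs / denom, weight * thetas / denom])
    names = tuple(f"pse_{aa}" for aa in STANDARD_AMINO_ACIDS) + tuple(
        f"pse_theta{j}" for j in range(1, lam + 1)
    )
    return FeatureVector(id=record_id, names=names, values=values)
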