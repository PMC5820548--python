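"""Classical (Type-1) Pseudo Amino Acid Composition.

A sequence of length L is encoded as a (20 + λ)-vector: the 20 amino-acid
occurrence frequencies plus λ sequence-order correlation factors θ_j, all
normalized by the same denominator Σf_i + w·Σθ_j so the vector sums to 1.
θ_j averages, over all residue pairs at lag j, the mean squared difference of
three standardized residue indices: hydrophobicity, hydrophilicity and
side-chain mass.  Defaults λ=50 and w=0.15 give a 70-dimensional vector and
require L ≥ 51.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from .sequence_io import AMINO_ACIDS

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class PseaacParams:
    """Tier count λ and sequence-order weight w (paper-stated valid range)."""

    lam: int = 50
    w: float = 0.15

    def __post_init__(self) -> None:
        if self.lam < 1:
            raise ValueError("lambda must be >= 1")
        if not 0.05 <= self.w <= 0.70:
            raise ValueError("w must lie in [0.05, 0.70]")


class ResidueIndexTable:
    """Standardized hydrophobicity / hydrophilicity / side-chain mass indices.

    Each raw column is standardized to zero mean and unit (population)
    standard deviation over the 20 amino acids.
    """

    def __init__(self, raw: np.ndarray, residues: str = AMINO_ACIDS) -> None:
        raw = np.asarray(raw, dtype=float)
        if raw.shape != (20, 3):
            raise ValueError("expected a 20x3 index table")
        self.residues = residues
        self.raw = raw
        mean = raw.mean(axis=0)
        sd = raw.std(axis=0)  # population SD over the 20 residues
        self.standardized = (raw - mean) / sd

    def row(self, residue: str) -> np.ndarray:
        return self.standardized[_AA_INDEX[residue]]


@lru_cache(maxsize=1)
def load_index_table() -> ResidueIndexTable:
    text = (
        resources.files("cancerlectin.data")
        .joinpath("pseaac_indices.tsv")
        .read_text()
    )
    rows = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        res, h1, h2, m = line.split("\t")
        rows[res] = (float(h1), float(h2), float(m))
    raw = np.array([rows[a] for a in AMINO_ACIDS])
    return ResidueIndexTable(raw)


def tier_correlation(
    sequence: str, j: int, table: ResidueIndexTable | None = None
) -> float:
    """θ_j: mean over lag-j pairs of the averaged squared index differences."""
    table = table or load_index_table()
    L = len(sequence)
    if not 1 <= j <= L - 1:
        raise ValueError(
            f"tier {j} needs sequence length >= {j + 1}, got L={L}"
        )
    idx = np.array([_AA_INDEX[c] for c in sequence])
    props = table.standardized[idx]  # (L, 3)
    diff = props[: L - j] - props[j:]
    return float(np.mean(np.sum(diff**2, axis=1) / 3.0))


def encode_pseaac(
    sequence: str, lam: int = 50, w: float = 0.15
) -> np.ndarray:
    """The (20+λ)-dimensional PseAAC vector (sums to 1).

    The first 20 slots hold f_u / (Σf + wΣθ); the remaining λ hold
    wθ_j / (Σf + wΣθ).  Frequencies are used for f_u, so Σf = 1.  Requires
    L ≥ λ+1.  Any w ≥ 0 is accepted here (w→0 recovers plain composition);
    :class:`PseaacParams` enforces the conventional 0.05–0.70 range.
    """
    L = len(sequence)
    if L <= lam:
        raise ValueError(
            f"PseAAC with lambda={lam} requires length >= {lam + 1}, got {L}"
        )
    if w < 0:
        raise ValueError("w must be non-negative")
    table = load_index_table()
    freqs = np.zeros(20)
    for c in sequence:
        freqs[_AA_INDEX[c]] += 1
    freqs /= L
    thetas = np.array([tier_correlation(sequence, j, table) for j in range(1, lam + 1)])
    denom = freqs.sum() + w * thetas.sum()
    return np.concatenate([freqs, w * thetas]) / denom


def pseaac_feature_names(lam: int = 50) -> list[str]:
    return [f"pseaac.f.{a}" for a in AMINO_ACIDS] + [
        f"pseaac.theta.{j}" for j in range(1, lam + 1)
    ]
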