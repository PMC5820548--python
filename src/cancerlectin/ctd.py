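"""Composition/Transition/Distribution (CTD) sequence descriptors.

Each of seven physicochemical properties (hydrophobicity, normalized van der
Waals volume, polarity, polarizability, charge, secondary structure, solvent
accessibility) partitions the 20 amino acids into three groups.  Per property
the encoder emits:

* composition — the fraction of residues in each group (3);
* transition — the frequency of dipeptides crossing each unordered group
  pair (3);
* distribution — the sequence positions (as fractions of L) at which the
  first, 25%, 50%, 75% and last residue of each group occur (15).

7 × (3 + 3 + 15) = 147 features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from .sequence_io import AA_SET

_QUANTILE_TAGS = ("first", "q25", "q50", "q75", "q100")
_QUANTILES = (0.25, 0.5, 0.75)


@dataclass(frozen=True)
class PropertyGrouping:
    """Three disjoint residue groups covering the 20 amino acids."""

    name: str
    groups: tuple[frozenset, frozenset, frozenset]

    def __post_init__(self) -> None:
        union = set().union(*self.groups)
        if union != set(AA_SET):
            raise ValueError(f"{self.name}: groups do not cover the alphabet")
        if sum(len(g) for g in self.groups) != 20:
            raise ValueError(f"{self.name}: groups overlap")

    def group_of(self, residue: str) -> int:
        """1-based group index of a residue."""
        for i, g in enumerate(self.groups, start=1):
            if residue in g:
                return i
        raise KeyError(residue)


@lru_cache(maxsize=1)
def load_groupings() -> tuple[PropertyGrouping, ...]:
    """The seven packaged physicochemical groupings, in canonical row order."""
    text = (
        resources.files("cancerlectin.data").joinpath("ctd_groups.tsv").read_text()
    )
    out = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, g1, g2, g3 = line.split("\t")
        out.append(
            PropertyGrouping(name, (frozenset(g1), frozenset(g2), frozenset(g3)))
        )
    if len(out) != 7:
        raise ValueError(f"expected 7 properties, found {len(out)}")
    return tuple(out)


def composition(sequence: str, grouping: PropertyGrouping) -> np.ndarray:
    """Per-group residue fractions (N1/L, N2/L, N3/L); sums to 1."""
    L = len(sequence)
    if L < 1:
        raise ValueError("composition requires a non-empty sequence")
    counts = np.zeros(3)
    for c in sequence:
        counts[grouping.group_of(c) - 1] += 1
    return counts / L


def transition(
    sequence: str, grouping: PropertyGrouping, denominator: str = "L"
) -> np.ndarray:
    """Cross-group dipeptide frequencies ((N12+N21), (N13+N31), (N23+N32)).

    The default denominator is the sequence length L; ``denominator="L-1"``
    uses the number of dipeptides instead.
    """
    L = len(sequence)
    if L < 2:
        raise ValueError("transition requires length >= 2")
    if denominator == "L":
        denom = L
    elif denominator == "L-1":
        denom = L - 1
    else:
        raise ValueError(f"denominator must be 'L' or 'L-1', got {denominator!r}")
    pair_counts = {(1, 2): 0, (1, 3): 0, (2, 3): 0}
    labels = [grouping.group_of(c) for c in sequence]
    for a, b in zip(labels, labels[1:]):
        if a != b:
            pair_counts[(min(a, b), max(a, b))] += 1
    return np.array(
        [pair_counts[(1, 2)], pair_counts[(1, 3)], pair_counts[(2, 3)]], dtype=float
    ) / denom


def distribution(sequence: str, grouping: PropertyGrouping) -> np.ndarray:
    """Fractional positions of the first/25%/50%/75%/last residue per group.

    Quantile residues are indexed with a ceiling rule: the residue at rank
    ⌈q·N⌉ among the N ordered occurrences of the group.  A group absent from
    the sequence contributes five zeros.  Positions are 1-based before
    division by L, so every value lies in (0, 1] (or is 0 for absent groups)
    and is non-decreasing within a group's 5-tuple.
    """
    L = len(sequence)
    if L < 1:
        raise ValueError("distribution requires a non-empty sequence")
    out = np.zeros(15)
    for gi in range(3):
        positions = [
            i + 1 for i, c in enumerate(sequence) if grouping.group_of(c) == gi + 1
        ]
        n = len(positions)
        if n == 0:
            continue
        ranks = [1] + [math.ceil(q * n) for q in _QUANTILES] + [n]
        out[gi * 5 : gi * 5 + 5] = [positions[r - 1] / L for r in ranks]
    return out


def encode_ctd(sequence: str, denominator: str = "L") -> np.ndarray:
    """The full 147-dimensional CTD vector, property-major, blocks C|T|D."""
    if len(sequence) < 2:
        raise ValueError("CTD encoding requires length >= 2")
    parts = []
    for grouping in load_groupings():
        parts.append(composition(sequence, grouping))
        parts.append(transition(sequence, grouping, denominator=denominator))
        parts.append(distribution(sequence, grouping))
    vec = np.concatenate(parts)
    assert vec.shape == (147,)
    return vec


def ctd_feature_names() -> list[str]:
    """Stable names like ``hydrophobicity.T.g1g3`` / ``charge.D.g2.q50``."""
    names = []
    for grouping in load_groupings():
        p = grouping.name
        names += [f"{p}.C.g{i}" for i in (1, 2, 3)]
        names += [f"{p}.T.g1g2", f"{p}.T.g1g3", f"{p}.T.g2g3"]
        for gi in (1, 2, 3):
            names += [f"{p}.D.g{gi}.{tag}" for tag in _QUANTILE_TAGS]
    return names
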