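"""Intrinsic-disorder summary features.

Per-residue disorder scores in [0,1] (e.g. from VSL2 or any per-residue
disorder predictor) are summarised into 28 features: global mean and SD,
counts and min/max lengths of disordered / ordered segments at a decision
threshold (default 0.5), and the mean disorder score of each of the 20
amino-acid types.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sequence_io import AMINO_ACIDS, AA_SET

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


class DisorderParseError(ValueError):
    pass


@dataclass
class DisorderTrack:
    """Per-residue disorder scores aligned to a sequence."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise ValueError("scores must be 1-D")
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValueError("disorder scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.scores)


def read_disorder(path: str | Path, expected_length: int) -> DisorderTrack:
    """Read a tab-separated (position, residue, score) disorder file.

    Positions must run contiguously 1..L with L == expected_length and every
    score in [0,1].
    """
    path = Path(path)
    scores = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise DisorderParseError(f"{path}:{lineno}: expected 3 columns")
        try:
            pos, score = int(parts[0]), float(parts[2])
        except ValueError as exc:
            raise DisorderParseError(f"{path}:{lineno}: {exc}") from exc
        if pos != len(scores) + 1:
            raise DisorderParseError(
                f"{path}:{lineno}: position {pos} not contiguous"
            )
        if not 0.0 <= score <= 1.0:
            raise DisorderParseError(
                f"{path}:{lineno}: score {score} outside [0, 1]"
            )
        scores.append(score)
    if len(scores) != expected_length:
        raise DisorderParseError(
            f"{path}: {len(scores)} scores for expected length {expected_length}"
        )
    return DisorderTrack(np.array(scores))


def segment_lengths(scores: np.ndarray, threshold: float) -> tuple[list[int], list[int]]:
    """Lengths of maximal disordered (score >= threshold) and ordered runs.

    The runs tile the sequence with alternating labels.
    """
    disordered: list[int] = []
    ordered: list[int] = []
    current_label = None
    run = 0
    for s in scores:
        label = s >= threshold
        if label == current_label:
            run += 1
        else:
            if current_label is not None:
                (disordered if current_label else ordered).append(run)
            current_label = label
            run = 1
    if current_label is not None:
        (disordered if current_label else ordered).append(run)
    return disordered, ordered


def encode_disorder(
    track: DisorderTrack, sequence: str, threshold: float = 0.5
) -> np.ndarray:
    """The 28-dimensional disorder feature vector.

    Order: mean, SD (population), #disordered segments, #ordered segments,
    min/max disordered-segment length, min/max ordered-segment length (0 when
    no segment of that kind exists), then the mean score per amino-acid type
    (0 for residue types absent from the sequence).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie strictly between 0 and 1")
    scores = track.scores
    if len(scores) != len(sequence):
        raise ValueError(
            f"track length {len(scores)} does not match sequence length "
            f"{len(sequence)}"
        )
    dis, order = segment_lengths(scores, threshold)
    per_aa = np.zeros(20)
    for a in set(sequence):
        if a not in AA_SET:
            raise ValueError(f"invalid residue {a!r}")
        mask = np.array([c == a for c in sequence])
        per_aa[_AA_INDEX[a]] = scores[mask].mean()
    head = [
        scores.mean(),
        scores.std(),  # population SD
        len(dis),
        len(order),
        min(dis) if dis else 0,
        max(dis) if dis else 0,
        min(order) if order else 0,
        max(order) if order else 0,
    ]
    vec = np.concatenate([head, per_aa])
    assert vec.shape == (28,)
    return vec


def disorder_feature_names() -> list[str]:
    return [
        "diso.mean",
        "diso.sd",
        "diso.nseg.d",
        "diso.nseg.o",
        "diso.minlen.d",
        "diso.maxlen.d",
        "diso.minlen.o",
        "diso.maxlen.o",
    ] + [f"diso.aamean.{a}" for a in AMINO_ACIDS]
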