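"""PSSM parsing and evolutionary-profile features.

A PSI-BLAST ASCII PSSM (``-out_ascii_pssm``) supplies one row of 20 log-odds
substitution scores per residue.  Scores are squashed to (0,1) with a sigmoid
and summarised as:

* PSSM-AAC — the 20 column means (global substitution propensity per
  residue type);
* PsePSSM  — the lag-j autocovariance of each column for j = 1..γ
  (sequence-order information), 20·γ values (100 at the default γ=5).

Concatenated: a 120-dimensional profile feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sequence_io import AMINO_ACIDS, AA_SET

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


class PssmParseError(ValueError):
    """Raised when a PSSM file does not follow the PSI-BLAST ASCII dialect."""


@dataclass
class ProfileMatrix:
    """L×20 raw log-odds scores with columns in canonical residue order."""

    residues: str
    raw: np.ndarray

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.shape != (len(self.residues), 20):
            raise ValueError(
                f"score matrix shape {self.raw.shape} does not match "
                f"sequence length {len(self.residues)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def scaled(self) -> np.ndarray:
        return scale_sigmoid(self.raw)


def scale_sigmoid(x: np.ndarray) -> np.ndarray:
    """Elementwise logistic squashing 1/(1+e^(−x)) into (0,1)."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def parse_pssm(path: str | Path) -> ProfileMatrix:
    """Parse a PSI-BLAST ASCII PSSM file.

    Uses the first 20-column block (log-odds); the weighted-percentage block
    and trailing K/lambda statistics are ignored.  Columns are remapped from
    the file's header order to the canonical alphabetical residue order.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    col_order: list[str] | None = None
    rows: list[list[int]] = []
    residues: list[str] = []
    expected_pos = 1
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if col_order is None:
            # header: >= 20 single-letter residue tokens
            if len(tokens) >= 20 and all(
                len(t) == 1 and t in AA_SET for t in tokens[:20]
            ):
                col_order = tokens[:20]
                if sorted(col_order) != sorted(AMINO_ACIDS):
                    raise PssmParseError(
                        f"{path}:{lineno}: header does not list the 20 amino acids"
                    )
            continue
        if len(tokens) >= 2 and tokens[0].isdigit() and tokens[1] in AA_SET:
            pos = int(tokens[0])
            if pos != expected_pos:
                raise PssmParseError(
                    f"{path}:{lineno}: position {pos}, expected {expected_pos}"
                )
            score_tokens = tokens[2:22]
            if len(score_tokens) < 20:
                raise PssmParseError(
                    f"{path}:{lineno}: only {len(score_tokens)} score columns"
                )
            try:
                scores = [int(t) for t in score_tokens]
            except ValueError as exc:
                raise PssmParseError(
                    f"{path}:{lineno}: non-integer score: {exc}"
                ) from exc
            residues.append(tokens[1])
            rows.append(scores)
            expected_pos += 1
        elif rows:
            break  # trailing statistics block
    if col_order is None:
        raise PssmParseError(f"{path}: no residue-column header found")
    if not rows:
        raise PssmParseError(f"{path}: no score rows found")
    raw = np.array(rows, dtype=float)
    # remap file column order -> canonical order
    remap = [col_order.index(a) for a in AMINO_ACIDS]
    return ProfileMatrix(residues="".join(residues), raw=raw[:, remap])


def pssm_aac(profile: ProfileMatrix) -> np.ndarray:
    """Column means of the sigmoid-scaled matrix; 20 values in (0,1)."""
    return profile.scaled.mean(axis=0)


def pse_pssm(profile: ProfileMatrix, gamma: int = 5) -> np.ndarray:
    """Lag-j autocovariances of each scaled column, k-major then j.

    For residue type k and lag j:
    (1/(L−j)) Σ_i (E_{i,k} − Ē_k)(E_{i+j,k} − Ē_k), with Ē_k the column mean
    over the whole sequence.
    """
    L = profile.length
    if not 1 <= gamma < L:
        raise ValueError(f"gamma={gamma} requires profile length > {gamma}")
    E = profile.scaled
    centered = E - E.mean(axis=0)
    out = np.empty(20 * gamma)
    for k in range(20):
        col = centered[:, k]
        for j in range(1, gamma + 1):
            out[k * gamma + (j - 1)] = np.dot(col[: L - j], col[j:]) / (L - j)
    return out


def encode_profile(profile: ProfileMatrix, gamma: int = 5) -> np.ndarray:
    """[PSSM-AAC (20) | PsePSSM (20·γ)] — 120 values at the default γ=5."""
    return np.concatenate([pssm_aac(profile), pse_pssm(profile, gamma=gamma)])


def profile_feature_names(gamma: int = 5) -> list[str]:
    names = [f"pssm.aac.{a}" for a in AMINO_ACIDS]
    for a in AMINO_ACIDS:
        names += [f"psepssm.{a}.lag{j}" for j in range(1, gamma + 1)]
    return names


def pseudo_profile(sequence: str) -> ProfileMatrix:
    """A sequence-derived stand-in profile built from BLOSUM62 rows.

    Each position's 20 scores are the BLOSUM62 substitution scores of the
    observed residue.  This is an approximation for demonstrations when no
    PSI-BLAST profile is available; it carries no alignment information.
    """
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    raw = np.array(
        [[blosum[res][a] for a in AMINO_ACIDS] for res in sequence], dtype=float
    )
    return ProfileMatrix(residues=sequence, raw=raw)
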