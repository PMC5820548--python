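"""Reading and validation of labeled protein sequences and feature matrices.

Datasets are supplied as two FASTA files — one of positives (cancerlectins,
label 1) and one of negatives (noncancerlectins, label 0).  Sequences are
sanitized to the 20-letter amino-acid alphabet before encoding; feature
matrices travel as CSV with a stable ``id, <features...>[, synthetic], label``
column layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Canonical residue order used for every per-residue feature block.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)

#: Ambiguity / non-standard codes removed (or rejected) during sanitization.
NONSTANDARD_RESIDUES = frozenset("BZXUOJ")


class SequenceError(ValueError):
    """Raised for malformed FASTA input or invalid sequences."""


@dataclass(frozen=True)
class ProteinRecord:
    """A validated amino-acid sequence with identifier and binary label."""

    id: str
    sequence: str
    label: int

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - AA_SET
        if bad:
            raise SequenceError(
                f"record {self.id!r}: invalid residues {sorted(bad)}"
            )
        if self.label not in (0, 1):
            raise SequenceError(f"record {self.id!r}: label must be 0 or 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """An ordered collection of records with at least stable iteration order."""

    records: list[ProteinRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        dupes = []
        for rec in self.records:
            if rec.id in seen:
                dupes.append(rec.id)
            seen.add(rec.id)
        if dupes:
            raise SequenceError(f"duplicate record ids: {sorted(set(dupes))}")

    @property
    def n_positive(self) -> int:
        return sum(r.label == 1 for r in self.records)

    @property
    def n_negative(self) -> int:
        return sum(r.label == 0 for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def sanitize_sequence(raw: str, policy: str = "drop") -> tuple[str, int]:
    """Uppercase *raw* and handle non-standard residues (B, Z, X, U, O, J).

    policy="drop" deletes them (returning the count removed); "strict"
    raises on the first one.  Anything outside both alphabets is always an
    error.
    """
    seq = raw.strip().upper().replace("*", "").replace("-", "")
    unknown = set(seq) - AA_SET - NONSTANDARD_RESIDUES
    if unknown:
        raise SequenceError(f"unrecognised residue codes {sorted(unknown)}")
    nonstd = [c for c in seq if c in NONSTANDARD_RESIDUES]
    if nonstd:
        if policy == "strict":
            raise SequenceError(
                f"non-standard residues {sorted(set(nonstd))} present "
                "(strict policy)"
            )
        if policy != "drop":
            raise SequenceError(f"unknown sanitization policy {policy!r}")
        seq = "".join(c for c in seq if c in AA_SET)
    return seq, len(nonstd)


def read_fasta(path: str | Path, label: int, policy: str = "drop") -> list[ProteinRecord]:
    """Read one FASTA file into records that all carry *label*.

    Records appear in file order.  Sequences are sanitized with
    :func:`sanitize_sequence`; a sequence that becomes empty, a duplicate id,
    or an empty/malformed file is an error.
    """
    path = Path(path)
    if not path.exists():
        raise SequenceError(f"FASTA file not found: {path}")
    records: list[ProteinRecord] = []
    try:
        entries = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # biopython names the offending content
        raise SequenceError(f"{path}: malformed FASTA: {exc}") from exc
    if not entries:
        raise SequenceError(f"{path}: no FASTA records found")
    for entry in entries:
        seq, n_removed = sanitize_sequence(str(entry.seq), policy=policy)
        if n_removed:
            logger.warning(
                "record %s: removed %d non-standard residue(s)", entry.id, n_removed
            )
        if not seq:
            raise SequenceError(
                f"record {entry.id!r}: sequence empty after sanitization"
            )
        records.append(ProteinRecord(id=entry.id, sequence=seq, label=label))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SequenceError(f"{path}: duplicate record ids {dupes}")
    return records


def load_dataset(
    positives: str | Path, negatives: str | Path, policy: str = "drop"
) -> LabeledDataset:
    """Read the positive (label 1) and negative (label 0) FASTA files."""
    recs = read_fasta(positives, label=1, policy=policy)
    recs += read_fasta(negatives, label=0, policy=policy)
    return LabeledDataset(recs)


@dataclass
class FeatureMatrix:
    """An n×d numeric matrix with named columns, ids, labels and provenance.

    ``synthetic`` flags rows created by oversampling; real rows are False.
    """

    values: np.ndarray
    feature_names: list[str]
    ids: list[str]
    labels: np.ndarray
    synthetic: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, d = self.values.shape
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.feature_names) != d:
            raise ValueError(f"{len(self.feature_names)} names for {d} columns")
        if len(set(self.feature_names)) != d:
            raise ValueError("feature names must be unique")
        if len(self.ids) != n or len(self.labels) != n:
            raise ValueError("ids/labels length mismatch")
        if self.synthetic is None:
            self.synthetic = np.zeros(n, dtype=bool)
        self.synthetic = np.asarray(self.synthetic, dtype=bool)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> tuple[int, int]:
        """(n_negative, n_positive)."""
        return int(np.sum(self.labels == 0)), int(np.sum(self.labels == 1))

    def select_features(self, indices) -> "FeatureMatrix":
        indices = list(indices)
        return replace(
            self,
            values=self.values[:, indices],
            feature_names=[self.feature_names[i] for i in indices],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "id", self.ids)
        if self.synthetic.any():
            df["synthetic"] = self.synthetic.astype(int)
        df["label"] = self.labels
        return df


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a CSV with header = feature names, first column id, last label.

    Floats are written with shortest round-trip repr, so values survive
    :func:`read_feature_matrix` losslessly.
    """
    df = matrix.to_frame()
    df.to_csv(path, index=False)


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    """Inverse of :func:`write_feature_matrix`."""
    df = pd.read_csv(path)
    if df.columns[0] != "id" or df.columns[-1] != "label":
        raise ValueError(f"{path}: expected 'id' first and 'label' last column")
    ids = df["id"].astype(str).tolist()
    labels = df["label"].to_numpy()
    synthetic = None
    feat_cols = list(df.columns[1:-1])
    if "synthetic" in feat_cols:
        synthetic = df["synthetic"].to_numpy(dtype=bool)
        feat_cols.remove("synthetic")
    values = df[feat_cols].to_numpy(dtype=float) if feat_cols else np.empty((len(df), 0))
    return FeatureMatrix(
        values=values,
        feature_names=feat_cols,
        ids=ids,
        labels=labels,
        synthetic=synthetic,
    )
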