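"""Self-contained synthetic datasets for exercising the whole pipeline.

Sequences are drawn i.i.d. from class-specific residue-frequency profiles
(the positive class shifts probability mass toward hydrophobic residues by a
controllable *separation*), companion PSSM files are written in the
PSI-BLAST ASCII dialect with an elevated score at each observed residue plus
integer noise, and disorder tracks are smoothed random walks centred on a
class-specific mean.  Everything is deterministic given the seed and the
generated files parse with the package's own readers.

These fixtures emulate compositional class bias only; they make no attempt
to mimic real lectin domain structure, alignment-derived conservation, or
realistic disorder architecture.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sequence_io import AMINO_ACIDS

#: Hydrophobic residues that receive extra probability mass in positives.
HYDROPHOBIC = "CFILMVW"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic labeled dataset.

    ``separation`` is the total probability mass moved onto hydrophobic
    residues in the positive class (0 = identical class profiles).  The
    minimum length of 56 keeps every encoder's precondition satisfied
    (PseAAC λ=50 needs L ≥ 51, PsePSSM γ=5 needs L ≥ 6).
    """

    n_per_class: int = 50
    length_min: int = 56
    length_max: int = 120
    separation: float = 0.15
    pssm_delta: int = 4
    pssm_noise: int = 2
    disorder_mean_pos: float = 0.55
    disorder_mean_neg: float = 0.45
    disorder_sd: float = 0.1  # per-protein spread of the disorder baseline
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_min < 56:
            raise ValueError("length_min must be >= 56")
        if self.length_max < self.length_min:
            raise ValueError("length_max < length_min")
        if not 0 <= self.separation <= 0.5:
            raise ValueError("separation must lie in [0, 0.5]")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.pssm_noise < 0:
            raise ValueError("pssm_noise must be >= 0")


def class_profiles(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """(positive, negative) residue-frequency profiles, each summing to 1."""
    neg = np.full(20, 1 / 20)
    pos = neg.copy()
    hydro = np.array([a in HYDROPHOBIC for a in AMINO_ACIDS])
    pos[hydro] += spec.separation / hydro.sum()
    pos[~hydro] -= spec.separation / (~hydro).sum()
    if (pos < 0).any():
        raise ValueError("separation too large: negative frequencies")
    return pos / pos.sum(), neg


def _write_fasta(path: Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_pssm(path: Path, sequence: str, raw: np.ndarray) -> None:
    """Write an L×20 raw score matrix in the PSI-BLAST ASCII layout."""
    header_aa = " ".join(f"{a:>3}" for a in AMINO_ACIDS)
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted "
            "observed percentages rounded down, information per position, "
            "and relative weight of gapless real matches to pseudocounts\n"
        )
        fh.write("           " + header_aa + "  " + header_aa + "\n")
        for i, res in enumerate(sequence):
            scores = " ".join(f"{int(v):>3d}" for v in raw[i])
            # weighted-percentage block: rounded pseudo-percentages; ignored
            # by the parser but present so the dialect is complete
            pos_frac = np.clip(raw[i] - raw[i].min(), 0, None)
            pct = (
                100 * pos_frac / pos_frac.sum() if pos_frac.sum() else np.zeros(20)
            )
            pct_str = " ".join(f"{int(v):>3d}" for v in pct)
            fh.write(
                f"{i + 1:>5d} {res} {scores}  {pct_str}  "
                f"{0.35:5.2f} {1.00:8.2f}\n"
            )
        fh.write("\n")
        fh.write("                      K         Lambda\n")
        fh.write("Standard Ungapped    0.1347     0.3176\n")
        fh.write("Standard Gapped      0.0410     0.2670\n")
        fh.write("PSI Ungapped         0.1347     0.3176\n")
        fh.write("PSI Gapped           0.0410     0.2670\n")


def write_disorder(path: Path, sequence: str, scores: np.ndarray) -> None:
    with open(path, "w") as fh:
        for i, (res, s) in enumerate(zip(sequence, scores), start=1):
            fh.write(f"{i}\t{res}\t{s:.6f}\n")


def _disorder_track(
    rng: np.random.Generator, L: int, mean: float, sd: float
) -> np.ndarray:
    """Moving-average (window 5) of uniform noise around a per-protein mean.

    The protein's baseline is drawn around the class mean with spread *sd*,
    so class membership biases but does not determine the disorder level.
    """
    baseline = float(np.clip(rng.normal(mean, sd), 0.05, 0.95))
    raw = baseline + rng.uniform(-0.45, 0.45, size=L + 4)
    kernel = np.ones(5) / 5
    smooth = np.convolve(raw, kernel, mode="valid")
    return np.clip(smooth, 0.0, 1.0)


@dataclass
class DatasetPaths:
    positives: Path
    negatives: Path
    pssm_dir: Path
    disorder_dir: Path
    labels: Path


def generate_dataset(
    spec: SyntheticSpec,
    outdir: str | Path,
    n_positive: int | None = None,
    n_negative: int | None = None,
) -> DatasetPaths:
    """Write FASTAs, PSSM files, disorder tracks and a label manifest.

    ``n_positive`` / ``n_negative`` override the per-class counts (used for
    imbalanced designs); both default to ``spec.n_per_class``.
    """
    outdir = Path(outdir)
    pssm_dir = outdir / "pssm"
    diso_dir = outdir / "diso"
    pssm_dir.mkdir(parents=True, exist_ok=True)
    diso_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    pos_profile, neg_profile = class_profiles(spec)
    aa = np.array(list(AMINO_ACIDS))

    n_pos = spec.n_per_class if n_positive is None else n_positive
    n_neg = spec.n_per_class if n_negative is None else n_negative
    plan = [("pos", n_pos, pos_profile, spec.disorder_mean_pos, 1),
            ("neg", n_neg, neg_profile, spec.disorder_mean_neg, 0)]
    fastas: dict[str, list[tuple[str, str]]] = {"pos": [], "neg": []}
    label_rows = []
    for tag, n, profile, diso_mean, label in plan:
        for i in range(n):
            rid = f"{tag}_{i:04d}"
            L = int(rng.integers(spec.length_min, spec.length_max + 1))
            seq = "".join(rng.choice(aa, size=L, p=profile))
            fastas[tag].append((rid, seq))
            label_rows.append((rid, label))
            raw = rng.integers(
                -spec.pssm_noise, spec.pssm_noise + 1, size=(L, 20)
            ).astype(float)
            for p, res in enumerate(seq):
                raw[p, AMINO_ACIDS.index(res)] += spec.pssm_delta
            write_pssm(pssm_dir / f"{rid}.pssm", seq, raw)
            write_disorder(
                diso_dir / f"{rid}.diso",
                seq,
                _disorder_track(rng, L, diso_mean, spec.disorder_sd),
            )
    paths = DatasetPaths(
        positives=outdir / "positives.fasta",
        negatives=outdir / "negatives.fasta",
        pssm_dir=pssm_dir,
        disorder_dir=diso_dir,
        labels=outdir / "labels.tsv",
    )
    _write_fasta(paths.positives, fastas["pos"])
    _write_fasta(paths.negatives, fastas["neg"])
    with open(paths.labels, "w") as fh:
        fh.write("id\tlabel\n")
        for rid, label in label_rows:
            fh.write(f"{rid}\t{label}\n")
    return paths


def make_imbalanced(
    spec: SyntheticSpec, ratio: float, outdir: str | Path
) -> DatasetPaths:
    """Generate a dataset whose positive (minority) fraction is *ratio*.

    The total count stays 2·n_per_class; positives become round(ratio·total)
    and negatives make up the remainder.
    """
    if not 0 < ratio < 0.5:
        raise ValueError("ratio must lie strictly between 0 and 0.5")
    total = 2 * spec.n_per_class
    n_pos = int(round(ratio * total))
    if n_pos < 2:
        raise ValueError("ratio leaves too few minority samples")
    return generate_dataset(spec, outdir, n_positive=n_pos, n_negative=total - n_pos)
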