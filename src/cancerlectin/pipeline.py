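"""End-to-end orchestration: encode → balance → select → train/evaluate.

A :class:`RunConfig` captures every knob with defaults matching the method's
stated operating point (λ=50, w=0.15, γ=5, 5 folds, Relief threshold 0,
SMOTE to exact balance).  :func:`run_pipeline` materialises a run directory
with the feature matrix, the balanced matrix, the Relief ranking, the SFS
trace, the evaluation report, ROC points, plots and a manifest; re-running
with the same config and seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .ctd import ctd_feature_names, encode_ctd
from .disorder import disorder_feature_names, encode_disorder, read_disorder
from .evaluation import RfParams, cross_validate
from .pseaac import encode_pseaac, pseaac_feature_names
from .pssm import encode_profile, parse_pssm, profile_feature_names, pseudo_profile
from .selection import SfsTrace, relief_scores, sfs_select
from .sequence_io import (
    FeatureMatrix,
    LabeledDataset,
    ProteinRecord,
    load_dataset,
    write_feature_matrix,
)
from .smote import SmoteParams, smote_balance

logger = logging.getLogger(__name__)

ENCODERS = ("ctd", "pseaac", "pssm", "disorder")


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the method's stated values."""

    positives: str | None = None
    negatives: str | None = None
    pssm_dir: str | None = None
    disorder_dir: str | None = None
    outdir: str = "run"
    nonstandard: str = "drop"  # or "strict"
    skip: tuple[str, ...] = ()
    lam: int = 50
    w: float = 0.15
    gamma: int = 5
    disorder_threshold: float = 0.5
    transition_denominator: str = "L"
    pssm_fallback: str = "strict"  # or "pseudo"
    disorder_fallback: str = "strict"  # or "neutral"
    smote_mode: str = "pre_split"
    smote_k: int = 5
    relief_k: int = 10
    relief_m: int | None = None
    sfs_candidates: int | None = None  # cap on SFS candidate pool (Relief order)
    sfs_cap: int | None = None  # cap on number of SFS additions
    sfs_trees: int = 30
    folds: int = 5
    trees: int = 100
    seed: int = 0
    plots: bool = True

    def __post_init__(self) -> None:
        bad = set(self.skip) - set(ENCODERS)
        if bad:
            raise ValueError(f"unknown encoder(s) to skip: {sorted(bad)}")

    def enabled_encoders(self) -> tuple[str, ...]:
        return tuple(e for e in ENCODERS if e not in self.skip)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending records."""


def encode_records(
    dataset: LabeledDataset | list[ProteinRecord], config: RunConfig
) -> FeatureMatrix:
    """Encode every record with the enabled feature blocks.

    Column order is fixed: CTD (147) | PseAAC (20+λ) | profile (20+20γ) |
    disorder (28), restricted to the enabled encoders.  Records whose PSSM
    or disorder companion file is missing are dropped under the "strict"
    fallback (with a warning) or encoded from a sequence-derived
    pseudo-profile / neutral 0.5 track under the demo fallbacks.
    """
    records = list(dataset)
    enabled = config.enabled_encoders()
    names: list[str] = []
    if "ctd" in enabled:
        names += ctd_feature_names()
    if "pseaac" in enabled:
        names += pseaac_feature_names(config.lam)
    if "pssm" in enabled:
        names += profile_feature_names(config.gamma)
    if "disorder" in enabled:
        names += disorder_feature_names()

    rows, ids, labels = [], [], []
    dropped: list[str] = []
    for rec in records:
        blocks = []
        try:
            if "ctd" in enabled:
                blocks.append(
                    encode_ctd(rec.sequence, denominator=config.transition_denominator)
                )
            if "pseaac" in enabled:
                blocks.append(encode_pseaac(rec.sequence, lam=config.lam, w=config.w))
            if "pssm" in enabled:
                profile = None
                path = (
                    Path(config.pssm_dir) / f"{rec.id}.pssm"
                    if config.pssm_dir
                    else None
                )
                if path is not None and path.exists():
                    profile = parse_pssm(path)
                    if profile.residues != rec.sequence:
                        logger.warning(
                            "record %s: PSSM residues differ from sequence", rec.id
                        )
                elif config.pssm_fallback == "pseudo":
                    logger.warning(
                        "record %s: no PSSM file, using BLOSUM62 pseudo-profile",
                        rec.id,
                    )
                    profile = pseudo_profile(rec.sequence)
                else:
                    logger.warning("record %s: no PSSM file, dropped", rec.id)
                    dropped.append(rec.id)
                    continue
                blocks.append(encode_profile(profile, gamma=config.gamma))
            if "disorder" in enabled:
                path = (
                    Path(config.disorder_dir) / f"{rec.id}.diso"
                    if config.disorder_dir
                    else None
                )
                if path is not None and path.exists():
                    track = read_disorder(path, expected_length=len(rec.sequence))
                elif config.disorder_fallback == "neutral":
                    logger.warning(
                        "record %s: no disorder file, using neutral 0.5 track",
                        rec.id,
                    )
                    from .disorder import DisorderTrack

                    track = DisorderTrack(np.full(len(rec.sequence), 0.5))
                else:
                    logger.warning("record %s: no disorder file, dropped", rec.id)
                    dropped.append(rec.id)
                    continue
                blocks.append(
                    encode_disorder(
                        track, rec.sequence, threshold=config.disorder_threshold
                    )
                )
        except ValueError as exc:
            raise PipelineError(f"encoding failed for record {rec.id!r}: {exc}") from exc
        rows.append(np.concatenate(blocks))
        ids.append(rec.id)
        labels.append(rec.label)
    if dropped:
        logger.warning("dropped %d record(s) without companion files", len(dropped))
    if not rows:
        raise PipelineError("no records survived encoding")
    return FeatureMatrix(
        values=np.vstack(rows),
        feature_names=names,
        ids=ids,
        labels=np.array(labels),
    )


def _write_relief(path: Path, ranking) -> None:
    with open(path, "w") as fh:
        fh.write("feature\tscore\tretained\n")
        for i in ranking.order:
            fh.write(
                f"{ranking.feature_names[i]}\t{ranking.scores[i]:.10g}\t"
                f"{int(ranking.scores[i] > 0)}\n"
            )


def _write_trace(path: Path, trace: SfsTrace) -> None:
    with open(path, "w") as fh:
        fh.write("step\tfeature\tcv_accuracy\n")
        for s, (name, acc) in enumerate(zip(trace.feature_names, trace.accuracies), 1):
            fh.write(f"{s}\t{name}\t{acc:.10g}\n")


def _plot_selection_curve(path: Path, trace: SfsTrace) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(range(1, len(trace.accuracies) + 1), trace.accuracies, marker="o", ms=3)
    ax.axvline(trace.selected_size, ls="--", color="grey")
    ax.set_xlabel("number of features")
    ax.set_ylabel("cross-validated accuracy")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_roc(path: Path, fpr, tpr, auc: float) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(fpr, tpr, label=f"AUC = {auc:.3f}")
    ax.plot([0, 1], [0, 1], ls=":", color="grey")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages and populate ``config.outdir``.

    Writes features.csv, balanced.csv, relief.tsv, sfs_trace.tsv,
    report.json, roc.tsv, optional plots and manifest.json.  Returns the run
    directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not config.positives or not config.negatives:
        raise PipelineError("config.positives and config.negatives are required")

    dataset = load_dataset(
        config.positives, config.negatives, policy=config.nonstandard
    )
    fm = encode_records(dataset, config)
    write_feature_matrix(fm, outdir / "features.csv")

    if config.smote_mode == "off":
        balanced = fm
    else:
        balanced = smote_balance(fm, SmoteParams(k=config.smote_k, seed=config.seed))
    write_feature_matrix(balanced, outdir / "balanced.csv")

    ranking = relief_scores(
        balanced, k=config.relief_k, m=config.relief_m, seed=config.seed
    )
    _write_relief(outdir / "relief.tsv", ranking)
    candidates = list(ranking.retained)
    if not candidates:
        raise PipelineError("Relief retained no features (all scores <= 0)")
    if config.sfs_candidates is not None:
        candidates = candidates[: config.sfs_candidates]

    trace = sfs_select(
        balanced,
        candidates,
        folds=config.folds,
        trees=config.sfs_trees,
        seed=config.seed,
        cap=config.sfs_cap,
    )
    _write_trace(outdir / "sfs_trace.tsv", trace)

    selected = balanced.select_features(trace.selected_features)
    report = cross_validate(
        selected,
        rf=RfParams(trees=config.trees, seed=config.seed),
        folds=config.folds,
        smote_mode="off",  # matrix is already balanced upstream
        seed=config.seed,
    )
    with open(outdir / "roc.tsv", "w") as fh:
        fh.write("fpr\ttpr\n")
        for x, y in zip(report.fpr, report.tpr):
            fh.write(f"{x:.10g}\t{y:.10g}\n")

    report_dict = {
        "n_records": len(dataset),
        "n_after_balance": balanced.n_samples,
        "n_features_total": fm.n_features,
        "n_relief_retained": int(len(ranking.retained)),
        "n_selected": trace.selected_size,
        "selected_features": trace.feature_names[: trace.selected_size],
        "sfs_peak_accuracy": trace.selected_accuracy,
        "evaluation": report.to_dict(),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report_dict, fh, indent=2, sort_keys=True)

    if config.plots:
        _plot_selection_curve(outdir / "selection_curve.png", trace)
        _plot_roc(outdir / "roc.png", report.fpr, report.tpr, report.auc)

    manifest = {
        "package_version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
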