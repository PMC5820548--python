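"""Random-Forest evaluation under stratified 5-fold cross-validation.

Metrics follow the standard confusion-matrix definitions:

    Sn  = TP/(TP+FN)            Sp  = TN/(TN+FP)
    Acc = (TP+TN)/n             MCC = (TP·TN − FP·FN)/√(∏ marginals)

with MCC defined as 0 when any marginal is zero.  The ROC curve plots
sensitivity against 1−specificity over a sweep of ensemble vote-fraction
thresholds, using out-of-fold scores pooled over all folds; AUC is the
trapezoidal area.  SMOTE can be applied to the whole matrix before the split
(``pre_split``, mirroring a balance-then-cross-validate protocol), inside
each training fold only (``per_fold``, leakage-safe), or not at all
(``off``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .sequence_io import FeatureMatrix
from .smote import SmoteParams, smote_balance


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("at least one sample must be evaluated")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class Metrics:
    sn: float
    sp: float
    acc: float
    mcc: float


def metrics(counts: ConfusionCounts) -> Metrics:
    """Sn/Sp/Acc/MCC from confusion counts (MCC=0 on a zero marginal)."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / counts.n
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return Metrics(sn=sn, sp=sp, acc=acc, mcc=float(mcc))


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def roc_points(y_true: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) arrays over all distinct score thresholds, plus endpoints.

    A sample is called positive when its score is >= the threshold; the
    returned points are sorted so both coordinates are non-decreasing.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes")
    fpr = [0.0]
    tpr = [0.0]
    for thr in sorted(set(scores), reverse=True):
        pred = scores >= thr
        tpr.append(np.sum(pred & (y_true == 1)) / n_pos)
        fpr.append(np.sum(pred & (y_true == 0)) / n_neg)
    return np.array(fpr), np.array(tpr)


def auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def auc_rank(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the Mann–Whitney U statistic (midranks handle ties).

    Kept as an independent route for cross-checking the trapezoidal area.
    """
    y_true = np.asarray(y_true)
    ranks = rankdata(scores)
    n_pos = int(np.sum(y_true == 1))
    n_neg = len(y_true) - n_pos
    u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


@dataclass(frozen=True)
class RfParams:
    trees: int = 100
    max_features: str | int | float = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trees < 1:
            raise ValueError("trees must be >= 1")


@dataclass
class EvalReport:
    """Per-fold and pooled cross-validation results."""

    fold_metrics: list[Metrics]
    fold_counts: list[ConfusionCounts]
    pooled_counts: ConfusionCounts
    pooled: Metrics
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    fold_assignment: np.ndarray  # fold index per evaluated row
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "pooled": vars(self.pooled),
            "auc": self.auc,
            "pooled_counts": vars(self.pooled_counts),
            "per_fold": [vars(m) for m in self.fold_metrics],
            "fold_assignment": self.fold_assignment.tolist(),
            "config": self.config,
        }


def _vote_fraction(clf: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Fraction of trees voting for the positive class."""
    votes = np.stack([tree.predict(X) for tree in clf.estimators_])
    return votes.mean(axis=0)


def cross_validate(
    matrix: FeatureMatrix,
    rf: RfParams | None = None,
    folds: int = 5,
    smote_mode: str = "pre_split",
    smote_k: int = 5,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold CV of a Random Forest with optional SMOTE.

    Predictions use the ensemble vote fraction with a 0.5 threshold (ties
    called negative); ROC/AUC come from the pooled out-of-fold vote
    fractions.  Deterministic given the seed.
    """
    rf = rf or RfParams()
    if smote_mode not in ("pre_split", "per_fold", "off"):
        raise ValueError(f"unknown smote_mode {smote_mode!r}")
    if smote_mode == "pre_split":
        matrix = smote_balance(matrix, SmoteParams(k=smote_k, seed=seed))
    y = matrix.labels
    X = matrix.values
    n = len(y)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(f"need at least {folds} samples per class")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_assignment = np.full(n, -1, dtype=int)
    scores = np.zeros(n)
    preds = np.zeros(n, dtype=int)
    fold_counts: list[ConfusionCounts] = []
    for f, (tr, te) in enumerate(skf.split(X, y)):
        X_tr, y_tr = X[tr], y[tr]
        if smote_mode == "per_fold":
            train_fm = FeatureMatrix(
                values=X_tr,
                feature_names=list(matrix.feature_names),
                ids=[matrix.ids[i] for i in tr],
                labels=y_tr,
            )
            train_fm = smote_balance(train_fm, SmoteParams(k=smote_k, seed=seed + f))
            X_tr, y_tr = train_fm.values, train_fm.labels
        clf = RandomForestClassifier(
            n_estimators=rf.trees,
            max_features=rf.max_features,
            random_state=rf.seed + f,
            n_jobs=1,
        )
        clf.fit(X_tr, y_tr)
        frac = _vote_fraction(clf, X[te])
        scores[te] = frac
        preds[te] = (frac > 0.5).astype(int)
        fold_assignment[te] = f
        fold_counts.append(confusion(y[te], preds[te]))

    pooled_counts = fold_counts[0]
    for c in fold_counts[1:]:
        pooled_counts = pooled_counts + c
    fpr, tpr = roc_points(y, scores)
    report = EvalReport(
        fold_metrics=[metrics(c) for c in fold_counts],
        fold_counts=fold_counts,
        pooled_counts=pooled_counts,
        pooled=metrics(pooled_counts),
        fpr=fpr,
        tpr=tpr,
        auc=auc_trapezoid(fpr, tpr),
        fold_assignment=fold_assignment,
        config={
            "trees": rf.trees,
            "max_features": rf.max_features,
            "folds": folds,
            "smote_mode": smote_mode,
            "smote_k": smote_k,
            "seed": seed,
        },
    )
    return report


#: Classifier factories for the comparison harness.  Names follow the
#: closest scikit-learn analogues of the usual protein-function baselines.
CLASSIFIERS: dict[str, Callable[[int], object]] = {
    "rf": lambda seed: RandomForestClassifier(n_estimators=100, random_state=seed),
    "adaboost": lambda seed: AdaBoostClassifier(random_state=seed),
    "decision_tree": lambda seed: DecisionTreeClassifier(random_state=seed),
    "nearest_neighbor": lambda seed: KNeighborsClassifier(n_neighbors=1),
    "logistic": lambda seed: LogisticRegression(max_iter=2000),
    "naive_bayes": lambda seed: GaussianNB(),
    "dummy": lambda seed: DummyClassifier(strategy="most_frequent"),
}


def _generic_scores(clf, X_te) -> np.ndarray:
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(X_te)[:, list(clf.classes_).index(1)]
    if hasattr(clf, "decision_function"):
        return clf.decision_function(X_te)
    return clf.predict(X_te).astype(float)


def compare_classifiers(
    matrix: FeatureMatrix,
    names: list[str],
    folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate several classifiers under identical stratified folds.

    Returns one row per requested name with pooled Sn/Sp/Acc/MCC and AUC.
    """
    unknown = [n for n in names if n not in CLASSIFIERS]
    if unknown:
        raise ValueError(
            f"unknown classifier(s) {unknown}; supported: {sorted(CLASSIFIERS)}"
        )
    y = matrix.labels
    X = matrix.values
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    rows = []
    for name in names:
        scores = np.zeros(len(y))
        preds = np.zeros(len(y), dtype=int)
        for f, (tr, te) in enumerate(splits):
            clf = CLASSIFIERS[name](seed + f)
            clf.fit(X[tr], y[tr])
            preds[te] = clf.predict(X[te])
            scores[te] = _generic_scores(clf, X[te])
        m = metrics(confusion(y, preds))
        fpr, tpr = roc_points(y, scores)
        rows.append(
            {
                "classifier": name,
                "sn": m.sn,
                "sp": m.sp,
                "acc": m.acc,
                "mcc": m.mcc,
                "auc": auc_trapezoid(fpr, tpr),
            }
        )
    return pd.DataFrame(rows)


def random_subset_baseline(
    matrix: FeatureMatrix,
    n_features: int,
    rounds: int = 10,
    folds: int = 5,
    rf: RfParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Control experiment: CV metrics of randomly drawn feature subsets.

    Draws *rounds* random subsets of size *n_features* (labels untouched),
    evaluates each with :func:`cross_validate` (SMOTE off — the input is
    expected to be balanced already), and returns one row per round plus the
    mean.  Used to show that a selected subset beats chance subsets.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(rounds):
        subset = rng.choice(matrix.n_features, size=n_features, replace=False)
        rep = cross_validate(
            matrix.select_features(subset),
            rf=rf,
            folds=folds,
            smote_mode="off",
            seed=seed + r,
        )
        rows.append(
            {
                "round": r,
                "sn": rep.pooled.sn,
                "sp": rep.pooled.sp,
                "acc": rep.pooled.acc,
                "mcc": rep.pooled.mcc,
                "auc": rep.auc,
            }
        )
    df = pd.DataFrame(rows)
    mean = df.drop(columns="round").mean().to_dict()
    mean["round"] = -1
    return pd.concat([df, pd.DataFrame([mean])], ignore_index=True)
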