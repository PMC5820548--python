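"""Two-step feature selection: ReliefF relevance filter, then SFS wrapper.

Step 1 ranks features by a ReliefF relevance score and keeps those with a
strictly positive score.  Step 2 runs a greedy Sequential Forward Selection
over the retained candidates, at each step adding the feature whose
inclusion maximizes cross-validated Random-Forest accuracy, and finally
keeping the prefix with the highest accuracy seen anywhere along the trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .sequence_io import FeatureMatrix


@dataclass
class ReliefRanking:
    """Per-feature relevance scores, their rank order, and the retained set."""

    scores: np.ndarray
    feature_names: list[str]
    order: np.ndarray = field(init=False)  # indices, best score first
    retained: np.ndarray = field(init=False)  # score > 0, in rank order

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        # stable sort: ties broken by lower feature index
        self.order = np.argsort(-self.scores, kind="stable")
        self.retained = np.array(
            [i for i in self.order if self.scores[i] > 0], dtype=int
        )


def relief_scores(
    matrix: FeatureMatrix,
    k: int = 10,
    m: int | None = None,
    seed: int = 0,
) -> ReliefRanking:
    """ReliefF relevance score per feature (binary classes).

    Features are min-max scaled internally so diffs are comparable across
    features; a constant feature has zero range and scores exactly 0.  For
    each of m sampled instances (default: all n) the k nearest same-class
    hits and k nearest other-class misses contribute
    ``mean_miss_diff/m − mean_hit_diff/m`` to each feature's score.
    """
    X = matrix.values
    y = matrix.labels
    n, d = X.shape
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("ReliefF here requires exactly two classes")
    if min(np.sum(y == c) for c in classes) < 2:
        raise ValueError("need at least 2 samples per class")

    span = X.max(axis=0) - X.min(axis=0)
    nonconst = span > 0
    Xs = np.zeros_like(X)
    Xs[:, nonconst] = (X[:, nonconst] - X.min(axis=0)[nonconst]) / span[nonconst]

    rng = np.random.default_rng(seed)
    if m is None or m >= n:
        sample = np.arange(n)
    else:
        sample = rng.choice(n, size=m, replace=False)
    m_eff = len(sample)

    scores = np.zeros(d)
    for i in sample:
        dists = np.linalg.norm(Xs - Xs[i], axis=1)
        dists[i] = np.inf
        same = np.flatnonzero(y == y[i])
        other = np.flatnonzero(y != y[i])
        same = same[same != i]
        k_hit = min(k, len(same))
        k_miss = min(k, len(other))
        hits = same[np.argsort(dists[same], kind="stable")[:k_hit]]
        misses = other[np.argsort(dists[other], kind="stable")[:k_miss]]
        hit_diff = np.abs(Xs[hits] - Xs[i]).mean(axis=0)
        miss_diff = np.abs(Xs[misses] - Xs[i]).mean(axis=0)
        scores += (miss_diff - hit_diff) / m_eff
    return ReliefRanking(scores=scores, feature_names=list(matrix.feature_names))


@dataclass
class SfsTrace:
    """The greedy forward-selection trace and the chosen prefix."""

    features: list[int]  # feature indices in addition order
    accuracies: list[float]  # CV accuracy after each addition
    feature_names: list[str]

    @property
    def selected_size(self) -> int:
        return int(np.argmax(self.accuracies)) + 1

    @property
    def selected_features(self) -> list[int]:
        return self.features[: self.selected_size]

    @property
    def selected_accuracy(self) -> float:
        return max(self.accuracies)


def _cv_accuracy(X, y, splits, trees, seed) -> float:
    correct = 0
    for f, (tr, te) in enumerate(splits):
        clf = RandomForestClassifier(
            n_estimators=trees, random_state=seed + f, n_jobs=1
        )
        clf.fit(X[tr], y[tr])
        correct += int(np.sum(clf.predict(X[te]) == y[te]))
    return correct / len(y)


def sfs_select(
    matrix: FeatureMatrix,
    candidates,
    folds: int = 5,
    trees: int = 100,
    seed: int = 0,
    cap: int | None = None,
) -> SfsTrace:
    """Greedy SFS over *candidates* (feature indices, best Relief rank first).

    The stratified fold splits are computed once from (labels, seed) and
    reused at every step so accuracies are comparable along the trace.  Ties
    in accuracy are broken toward the earlier candidate in the given order
    (i.e. the better Relief rank).  ``cap`` limits the number of additions
    (default: all candidates).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidates must be non-empty")
    if cap is not None and cap < 1:
        raise ValueError("cap must be >= 1")
    n_steps = len(candidates) if cap is None else min(cap, len(candidates))

    y = matrix.labels
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))

    chosen: list[int] = []
    accs: list[float] = []
    remaining = list(candidates)
    for _ in range(n_steps):
        best_acc, best_feat = -1.0, None
        for feat in remaining:  # order = relief rank → ties favor better rank
            X = matrix.values[:, chosen + [feat]]
            acc = _cv_accuracy(X, y, splits, trees, seed)
            if acc > best_acc:
                best_acc, best_feat = acc, feat
        chosen.append(best_feat)
        accs.append(best_acc)
        remaining.remove(best_feat)
    return SfsTrace(
        features=chosen,
        accuracies=accs,
        feature_names=[matrix.feature_names[i] for i in chosen],
    )
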