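"""Synthetic Minority Oversampling Technique (SMOTE) in feature space.

Minority-class rows are interpolated with their k nearest minority
neighbours (Euclidean): each synthetic row is x + u·(x_nn − x) with u drawn
uniformly from [0,1].  Oversampling continues until the class counts are
exactly equal; original rows are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .sequence_io import FeatureMatrix


@dataclass(frozen=True)
class SmoteParams:
    k: int = 5
    seed: int = 0
    standardize: bool = False  # z-score features for the distance computation only

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def smote_balance(
    matrix: FeatureMatrix, params: SmoteParams | None = None
) -> FeatureMatrix:
    """Append synthetic minority rows until the two classes are balanced.

    Base minority samples are visited in a seeded random cyclic order; for
    each, one of its k nearest minority neighbours is chosen uniformly and a
    point is drawn uniformly on the connecting segment.  Deterministic given
    the seed.  Already-balanced input is returned unchanged (zero synthetic
    rows).
    """
    params = params or SmoteParams()
    labels = matrix.labels
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"SMOTE requires exactly 2 classes, got {len(classes)}")
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    if n_needed == 0:
        return replace(matrix)
    min_idx = np.flatnonzero(labels == minority)
    n_min = len(min_idx)
    if n_min <= params.k:
        raise ValueError(
            f"minority class has {n_min} samples; needs > k={params.k} "
            "(use a smaller k)"
        )
    X_min = matrix.values[min_idx]
    X_dist = X_min
    if params.standardize:
        sd = X_min.std(axis=0)
        sd[sd == 0] = 1.0
        X_dist = (X_min - X_min.mean(axis=0)) / sd
    nn = NearestNeighbors(n_neighbors=params.k + 1).fit(X_dist)
    neighbors = nn.kneighbors(X_dist, return_distance=False)[:, 1:]  # drop self

    rng = np.random.default_rng(params.seed)
    base_order = rng.permutation(n_min)
    synth_rows = np.empty((n_needed, matrix.n_features))
    for s in range(n_needed):
        base = base_order[s % n_min]
        nbr = neighbors[base, rng.integers(params.k)]
        u = rng.uniform()
        synth_rows[s] = X_min[base] + u * (X_min[nbr] - X_min[base])

    values = np.vstack([matrix.values, synth_rows])
    new_ids = list(matrix.ids) + [f"synthetic_{s}" for s in range(n_needed)]
    new_labels = np.concatenate([labels, np.full(n_needed, minority, dtype=int)])
    new_flags = np.concatenate(
        [matrix.synthetic, np.ones(n_needed, dtype=bool)]
    )
    return FeatureMatrix(
        values=values,
        feature_names=list(matrix.feature_names),
        ids=new_ids,
        labels=new_labels,
        synthetic=new_flags,
    )
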