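"""Distinctness of test conditions from training conditions.

The distinctness of a test condition i given a training set R is the harmonic
mean of its min-max normalized Euclidean distances to all training conditions:

    eta(E_i, R) = |R| / sum_{j in R} 1 / D(E_i, E_j)

The harmonic mean is dominated by the closest training samples, so a single
near-duplicate in the training set drives the score toward zero.  A whole
K-fold collection is scored by averaging eta over all |C| conditions, each
scored once as a test sample against its fold's training set.

Distances are min-max normalized using the global extremes over all
off-diagonal pairs of the full condition set, computed once before any split,
so scores are comparable across partitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .datatypes import (
    ConditionMatrix,
    PairwiseDistances,
    Partition,
    PartitionCollection,
)

__all__ = [
    "compute_pairwise_distances",
    "normalize_distance",
    "sample_distinctness",
    "partition_distinctness",
    "collection_distinctness",
    "distinctness_table",
    "PartitionDistinctness",
]


def compute_pairwise_distances(
    conditions: ConditionMatrix, *, zscore_features: bool = False
) -> PairwiseDistances:
    """Euclidean distances between all condition pairs, min-max normalized.

    Parameters
    ----------
    conditions
        The conditions-by-features matrix.
    zscore_features
        If True, z-score each feature across conditions before computing
        distances (zero-variance features are dropped). Distances are computed
        on the matrix as given by default.
    """
    X = conditions.values
    if zscore_features:
        sd = X.std(axis=0)
        keep = sd > 0
        if not keep.any():
            raise ValueError("all features have zero variance; cannot z-score")
        X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    raw = squareform(pdist(X, metric="euclidean"))
    return PairwiseDistances.from_raw(raw)


def normalize_distance(d: float, d_min: float, d_max: float) -> float:
    """Min-max normalize one distance: (d - d_min) / (d_max - d_min)."""
    if not d_max > d_min:
        raise ValueError(f"d_max ({d_max}) must exceed d_min ({d_min})")
    if d < d_min or d > d_max:
        raise ValueError(f"d = {d} outside [d_min, d_max] = [{d_min}, {d_max}]")
    return (d - d_min) / (d_max - d_min)


def sample_distinctness(
    test_index: int,
    train_indices: Iterable[int],
    distances: PairwiseDistances,
) -> float:
    """Harmonic mean of normalized distances from one test condition to a training set.

    Returns 0.0 when any normalized distance is exactly zero (an exact
    duplicate, or the globally closest pair spanning test and train): that is
    the limit of the harmonic mean, and a test sample indistinguishable from a
    training sample has zero distinctness.
    """
    train = np.fromiter((int(i) for i in train_indices), dtype=int)
    if train.size == 0:
        raise ValueError("training set must be non-empty")
    test_index = int(test_index)
    if test_index in train:
        raise ValueError(f"test condition {test_index} is in the training set")
    if test_index >= distances.n or (train >= distances.n).any():
        raise ValueError("condition index out of range for the distance matrix")
    row = distances.normalized[test_index, train]
    if (row == 0.0).any():
        return 0.0
    return float(train.size / np.sum(1.0 / row))


@dataclass(frozen=True)
class PartitionDistinctness:
    """Per-test-condition distinctness scores of one partition.

    ``per_test`` is ordered by ascending test index (``test_indices``).
    """

    test_indices: np.ndarray
    per_test: np.ndarray
    mean: float
    median: float


def partition_distinctness(
    partition: Partition, distances: PairwiseDistances
) -> PartitionDistinctness:
    """Score every test condition of a partition against its training set."""
    partition.validate_against(distances.n)
    test = partition.test_array
    train = partition.train_array
    sub = distances.normalized[np.ix_(test, train)]
    with np.errstate(divide="ignore"):
        inv = 1.0 / sub  # zero distances become inf and dominate the sum
    denom = inv.sum(axis=1)
    # a zero distance makes the denominator infinite and eta exactly 0
    per_test = np.where(np.isinf(denom), 0.0, train.size / denom)
    return PartitionDistinctness(
        test_indices=test,
        per_test=per_test,
        mean=float(per_test.mean()),
        median=float(np.median(per_test)),
    )


def collection_distinctness(
    collection: PartitionCollection, distances: PairwiseDistances
) -> float:
    """Average distinctness of all test samples across an exhaustive K-fold collection.

    Each of the |C| conditions is scored exactly once, as a test sample against
    its fold's training set; the score is the unweighted mean over all |C|.
    Only defined for exhaustive collections (kinds ``rcv`` and ``ccv``).
    """
    if collection.kind == "sacv":
        raise ValueError(
            "collection distinctness divides by |C| and requires exhaustive folds; "
            "sacv collections are not exhaustive — score individual partitions "
            "with partition_distinctness instead"
        )
    if collection.n_conditions != distances.n:
        raise ValueError(
            f"collection covers {collection.n_conditions} conditions but the "
            f"distance matrix has {distances.n}"
        )
    scores = np.concatenate(
        [partition_distinctness(p, distances).per_test for p in collection]
    )
    assert scores.size == collection.n_conditions
    return float(scores.mean())


def distinctness_table(
    collection: PartitionCollection,
    distances: PairwiseDistances,
    condition_ids: Iterable[str],
) -> pd.DataFrame:
    """Long-format per-test-condition scores: condition_id, fold_index, eta."""
    ids = list(condition_ids)
    rows = []
    for fold, p in enumerate(collection):
        scored = partition_distinctness(p, distances)
        for idx, eta in zip(scored.test_indices, scored.per_test):
            rows.append({"condition_id": ids[idx], "fold_index": fold, "eta": eta})
    return pd.DataFrame(rows, columns=["condition_id", "fold_index", "eta"])
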