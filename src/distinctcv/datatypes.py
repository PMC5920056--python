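"""Core data containers.

The central objects are a conditions-by-features expression matrix
(:class:`ConditionMatrix`), its companion conditions-by-genes target matrix
(:class:`TargetMatrix`), the pairwise condition distances with their global
min-max normalization (:class:`PairwiseDistances`), and train/test splits
(:class:`Partition`, :class:`PartitionCollection`).

All containers are immutable and validate their invariants on construction,
so downstream code can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConditionMatrix",
    "TargetMatrix",
    "PairwiseDistances",
    "Partition",
    "PartitionCollection",
    "PARTITION_KINDS",
]

PARTITION_KINDS = ("rcv", "ccv", "sacv")


def _as_unique_ids(ids: Iterable[str], what: str) -> tuple[str, ...]:
    out = tuple(str(x) for x in ids)
    if len(set(out)) != len(out):
        dupes = sorted({x for x in out if out.count(x) > 1})
        raise ValueError(f"duplicate {what}: {dupes[:5]}")
    return out


@dataclass(frozen=True)
class ConditionMatrix:
    """Expression of predictor features (e.g. transcription factors) per condition.

    Rows are conditions (samples), columns are features. Values must be finite;
    identifiers must be unique.
    """

    values: np.ndarray
    condition_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    context_labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self, "condition_ids", _as_unique_ids(self.condition_ids, "condition ids")
        )
        object.__setattr__(
            self, "feature_ids", _as_unique_ids(self.feature_ids, "feature ids")
        )
        if values.ndim != 2:
            raise ValueError(f"expected a 2-d matrix, got shape {values.shape}")
        n, f = values.shape
        if n < 2:
            raise ValueError(f"need at least 2 conditions, got {n}")
        if f < 1:
            raise ValueError("need at least 1 feature")
        if len(self.condition_ids) != n:
            raise ValueError(
                f"{len(self.condition_ids)} condition ids for {n} rows"
            )
        if len(self.feature_ids) != f:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {f} columns")
        if not np.isfinite(values).all():
            bad = int(np.size(values) - np.isfinite(values).sum())
            raise ValueError(f"{bad} non-finite expression values")
        if self.context_labels is not None:
            labels = tuple(str(x) for x in self.context_labels)
            if len(labels) != n:
                raise ValueError("context_labels length must match n_conditions")
            object.__setattr__(self, "context_labels", labels)

    @property
    def n_conditions(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, context_labels: Optional[Sequence[str]] = None
    ) -> "ConditionMatrix":
        """Build from a conditions-by-features DataFrame (index = condition ids)."""
        return cls(
            values=df.to_numpy(dtype=float),
            condition_ids=tuple(map(str, df.index)),
            feature_ids=tuple(map(str, df.columns)),
            context_labels=tuple(context_labels) if context_labels is not None else None,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.condition_ids), columns=list(self.feature_ids)
        )


@dataclass(frozen=True)
class TargetMatrix:
    """Expression of target genes per condition, row-aligned with a ConditionMatrix."""

    values: np.ndarray
    condition_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self, "condition_ids", _as_unique_ids(self.condition_ids, "condition ids")
        )
        object.__setattr__(self, "gene_ids", _as_unique_ids(self.gene_ids, "gene ids"))
        if values.ndim != 2:
            raise ValueError(f"expected a 2-d matrix, got shape {values.shape}")
        if values.shape[0] != len(self.condition_ids):
            raise ValueError("condition_ids length must match number of rows")
        if values.shape[1] != len(self.gene_ids):
            raise ValueError("gene_ids length must match number of columns")
        if not np.isfinite(values).all():
            raise ValueError("non-finite target values")

    @property
    def n_conditions(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def check_aligned(self, conditions: ConditionMatrix) -> None:
        """Raise unless condition order is identical to the companion matrix."""
        if self.condition_ids != conditions.condition_ids:
            raise ValueError(
                "target matrix condition order differs from the condition matrix"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TargetMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            condition_ids=tuple(map(str, df.index)),
            gene_ids=tuple(map(str, df.columns)),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.condition_ids), columns=list(self.gene_ids)
        )


class DegenerateGeometryError(ValueError):
    """All condition pairs are equidistant; min-max normalization is undefined."""


@dataclass(frozen=True)
class PairwiseDistances:
    """Raw Euclidean condition distances with their global min-max normalization.

    ``d_min``/``d_max`` are the extremes over all *off-diagonal* pairs of the full
    condition set, computed once and reused for every partition so that
    distinctness scores are comparable across partitions. ``normalized`` maps
    off-diagonal entries into [0, 1] via (d - d_min) / (d_max - d_min); the
    diagonal is kept at 0.
    """

    raw: np.ndarray
    d_min: float
    d_max: float
    normalized: np.ndarray

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw, dtype=float)
        norm = np.asarray(self.normalized, dtype=float)
        object.__setattr__(self, "raw", raw)
        object.__setattr__(self, "normalized", norm)
        if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
            raise ValueError("distance matrix must be square")
        if raw.shape[0] < 2:
            raise ValueError("need at least 2 conditions")
        if not np.allclose(raw, raw.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diagonal(raw) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(raw < 0):
            raise ValueError("distances must be non-negative")
        if not self.d_max > self.d_min:
            raise DegenerateGeometryError(
                "d_max must exceed d_min; all condition pairs are equidistant, "
                "min-max normalization is undefined for this degenerate geometry"
            )
        off = ~np.eye(raw.shape[0], dtype=bool)
        if norm.shape != raw.shape or np.any(norm[off] < 0) or np.any(norm[off] > 1):
            raise ValueError("normalized distances must lie in [0, 1]")

    @classmethod
    def from_raw(cls, raw: np.ndarray) -> "PairwiseDistances":
        """Derive the global extremes and normalized matrix from raw distances.

        Self-distances (the zero diagonal) are excluded when locating
        ``d_min``/``d_max``: including them would force d_min = 0 for every
        dataset and change all scores.
        """
        raw = np.asarray(raw, dtype=float)
        if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
            raise ValueError("distance matrix must be square")
        n = raw.shape[0]
        if n < 2:
            raise ValueError(f"need at least 2 conditions, got {n}")
        off = ~np.eye(n, dtype=bool)
        d_min = float(raw[off].min())
        d_max = float(raw[off].max())
        if not d_max > d_min:
            raise DegenerateGeometryError(
                "all off-diagonal condition pairs are equidistant "
                f"(distance {d_min:g}); min-max normalization is undefined"
            )
        normalized = (raw - d_min) / (d_max - d_min)
        np.fill_diagonal(normalized, 0.0)
        return cls(raw=raw, d_min=d_min, d_max=d_max, normalized=normalized)

    @property
    def n(self) -> int:
        return self.raw.shape[0]


@dataclass(frozen=True)
class Partition:
    """One train/test split: disjoint, non-empty index sets."""

    test_indices: frozenset[int]
    train_indices: frozenset[int]

    def __post_init__(self) -> None:
        test = frozenset(int(i) for i in self.test_indices)
        train = frozenset(int(i) for i in self.train_indices)
        object.__setattr__(self, "test_indices", test)
        object.__setattr__(self, "train_indices", train)
        if not test:
            raise ValueError("test set must be non-empty")
        if not train:
            raise ValueError("training set must be non-empty")
        if test & train:
            raise ValueError(f"test and training sets overlap: {sorted(test & train)[:5]}")
        if any(i < 0 for i in test | train):
            raise ValueError("condition indices must be non-negative")

    @property
    def test_array(self) -> np.ndarray:
        """Test indices in ascending order."""
        return np.array(sorted(self.test_indices), dtype=int)

    @property
    def train_array(self) -> np.ndarray:
        return np.array(sorted(self.train_indices), dtype=int)

    def validate_against(self, n_conditions: int) -> None:
        top = max(self.test_indices | self.train_indices)
        if top >= n_conditions:
            raise ValueError(
                f"partition references condition index {top} "
                f"but only {n_conditions} conditions exist"
            )


@dataclass(frozen=True)
class PartitionCollection:
    """An ordered list of partitions of one condition set.

    ``rcv`` and ``ccv`` collections are exhaustive K-folds: test sets are
    mutually exclusive and cover every condition, and each train set is the
    complement of its test set.  ``sacv`` collections only require every test
    set to have the same size.
    """

    partitions: tuple[Partition, ...]
    kind: str
    n_conditions: int

    def __post_init__(self) -> None:
        partitions = tuple(self.partitions)
        object.__setattr__(self, "partitions", partitions)
        if self.kind not in PARTITION_KINDS:
            raise ValueError(f"kind must be one of {PARTITION_KINDS}, got {self.kind!r}")
        if not partitions:
            raise ValueError("collection must contain at least one partition")
        for p in partitions:
            p.validate_against(self.n_conditions)
        everything = frozenset(range(self.n_conditions))
        if self.kind in ("rcv", "ccv"):
            seen: set[int] = set()
            for i, p in enumerate(partitions):
                if p.test_indices & seen:
                    raise ValueError(f"fold {i} overlaps an earlier test fold")
                seen |= p.test_indices
                if p.train_indices != everything - p.test_indices:
                    raise ValueError(
                        f"fold {i}: training set must be the complement of the test set"
                    )
            if seen != everything:
                missing = sorted(everything - seen)
                raise ValueError(
                    f"{self.kind} folds must be exhaustive; "
                    f"missing conditions {missing[:5]}"
                )
        else:  # sacv
            sizes = {len(p.test_indices) for p in partitions}
            if len(sizes) > 1:
                raise ValueError(
                    f"sacv partitions must share one test-set size, got {sorted(sizes)}"
                )

    @property
    def k(self) -> int:
        return len(self.partitions)

    def __iter__(self):
        return iter(self.partitions)

    def __len__(self) -> int:
        return len(self.partitions)
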