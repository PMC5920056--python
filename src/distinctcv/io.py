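"""Reading and writing the tool's file formats.

Expression and target matrices travel as tab-separated text (first row =
feature/gene ids, first column = condition ids; gzip transparent); a
``transpose`` flag accepts the features-by-conditions dialect common to
public expression exports.  Partition collections travel as JSON keyed by
condition ids, so files remain meaningful when matrices are re-ordered.
Missing values are rejected rather than imputed — every downstream formula
assumes complete vectors.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import ConditionMatrix, Partition, PartitionCollection, TargetMatrix
from .evaluation import EvaluationResult

__all__ = [
    "read_expression",
    "read_targets",
    "write_expression",
    "write_targets",
    "read_partitions",
    "write_partitions",
    "write_results",
]


def _read_matrix(path: str | Path, transpose: bool) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if transpose:
        df = df.T
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row ids {dupes[:5]}")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate column ids {dupes[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at "
            f"row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return numeric.astype(float)


def read_expression(path: str | Path, transpose: bool = False) -> ConditionMatrix:
    """Parse a conditions-by-features TSV (``transpose=True`` for the flipped dialect)."""
    return ConditionMatrix.from_dataframe(_read_matrix(path, transpose))


def read_targets(path: str | Path, transpose: bool = False) -> TargetMatrix:
    """Parse a conditions-by-genes TSV."""
    return TargetMatrix.from_dataframe(_read_matrix(path, transpose))


def write_expression(matrix: ConditionMatrix, path: str | Path) -> None:
    matrix.to_dataframe().to_csv(path, sep="\t", index_label="condition_id")


def write_targets(matrix: TargetMatrix, path: str | Path) -> None:
    matrix.to_dataframe().to_csv(path, sep="\t", index_label="condition_id")


def write_partitions(
    collection: PartitionCollection,
    condition_ids: Sequence[str],
    path: str | Path,
    seed: Optional[int] = None,
    meta: Optional[dict] = None,
) -> None:
    """Serialize a collection as JSON with test folds listed by condition id."""
    ids = list(condition_ids)
    if len(ids) != collection.n_conditions:
        raise ValueError("condition id list does not match the collection size")
    payload = {
        "kind": collection.kind,
        "n_conditions": collection.n_conditions,
        "folds": [[ids[i] for i in p.test_array] for p in collection],
        "seed": seed,
        "meta": meta or {},
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_partitions(
    path: str | Path, condition_ids: Sequence[str]
) -> tuple[PartitionCollection, dict]:
    """Load a partition JSON and re-index it against the given condition ids.

    Exhaustiveness and disjointness of rcv/ccv folds are re-validated; an
    unknown condition id is an error. Returns the collection and the file's
    metadata dict.
    """
    path = Path(path)
    payload = json.loads(path.read_text())
    ids = list(condition_ids)
    index = {cid: i for i, cid in enumerate(ids)}
    kind = payload.get("kind")
    n = payload.get("n_conditions")
    if n != len(ids):
        raise ValueError(
            f"{path}: file lists {n} conditions but the matrix has {len(ids)}"
        )
    folds = []
    for fold in payload["folds"]:
        unknown = [cid for cid in fold if cid not in index]
        if unknown:
            raise ValueError(f"{path}: unknown condition ids {unknown[:5]}")
        folds.append(frozenset(index[cid] for cid in fold))
    everything = frozenset(range(len(ids)))
    partitions = tuple(
        Partition(test_indices=fold, train_indices=everything - fold) for fold in folds
    )
    collection = PartitionCollection(partitions=partitions, kind=kind, n_conditions=len(ids))
    return collection, payload.get("meta", {})


def write_results(result: EvaluationResult, path: str | Path) -> None:
    """Write the long results table (gene, partition, method, pcc, rmsd, distinctness)."""
    result.to_table().to_csv(path, sep="\t", index=False)
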