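"""Expression-prediction regressors and accuracy metrics over CV partitions.

Each target gene is an independent regression task: predict its expression in
a condition from the expression of all predictor features (TFs) in that
condition.  Three regressors are supported — LARS (active-set size tuned by
inner 5-fold CV), Elastic Net (penalty strength and mixing tuned by inner
5-fold CV) and RBF-kernel support vector regression (fixed conventional
defaults).  Features and targets are z-scored with training-fold statistics
only, and predictions are returned on the original target scale, so test
targets never enter fitting or normalization.

Accuracy is measured per gene as the Pearson correlation between predicted and
measured expression — pooled over the out-of-fold predictions of an exhaustive
collection, or on a single partition's test set — plus the test-set RMSD.
Undefined correlations (constant vectors, tiny test sets) are reported as
missing with a warning, never silently zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV, Lars
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .datatypes import ConditionMatrix, Partition, PartitionCollection, TargetMatrix
from .distinctness import PairwiseDistances, partition_distinctness

__all__ = [
    "RegressionSpec",
    "EvaluationResult",
    "fit_predict_partition",
    "evaluate_collection",
    "evaluate_heldout",
    "pooled_cv_accuracy",
    "partition_accuracy",
    "compare_methods",
    "distinctness_accuracy_correlation",
]

METHODS = ("lars", "elastic_net", "svr_rbf")

_DEFAULT_ALPHAS = tuple(np.logspace(-8, 2, 20))


@dataclass(frozen=True)
class RegressionSpec:
    """Which regressor to fit and how to tune it.

    ``lars_active_sizes`` is the inner-CV grid for the number of active
    predictors; ``enet_alphas``/``enet_l1_ratios`` the Elastic Net penalty
    grid (ties resolve toward the stronger penalty). SVR uses fixed defaults:
    regularization 1.0, kernel width 1/n_features, tube 0.1.
    """

    method: str
    inner_cv_folds: int = 5
    lars_active_sizes: tuple[int, ...] = (1, 2, 5, 10, 20, 50)
    enet_alphas: tuple[float, ...] = _DEFAULT_ALPHAS
    enet_l1_ratios: tuple[float, ...] = (0.1, 0.5, 0.9)
    enet_tol: float = 1e-6
    enet_max_iter: int = 5000
    svr_c: float = 1.0
    svr_gamma: float | str = "auto"  # 'auto' = 1 / n_features
    svr_epsilon: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.inner_cv_folds < 2:
            raise ValueError("inner_cv_folds must be at least 2")
        if self.method == "lars" and not self.lars_active_sizes:
            raise ValueError("lars_active_sizes grid must be non-empty")
        if self.method == "elastic_net" and (
            not self.enet_alphas or not self.enet_l1_ratios
        ):
            raise ValueError("elastic net grid must be non-empty")


def _tune_lars_size(
    X: np.ndarray, y: np.ndarray, spec: RegressionSpec
) -> int:
    """Inner-CV selection of the LARS active-set size; ties go to the sparser model."""
    max_size = min(X.shape[1], X.shape[0] - 1)
    sizes = sorted({min(int(k), max_size) for k in spec.lars_active_sizes if k >= 1})
    if len(sizes) == 1:
        return sizes[0]
    kf = KFold(n_splits=spec.inner_cv_folds, shuffle=True, random_state=spec.seed % 2**32)
    best_size, best_mse = sizes[0], np.inf
    for size in sizes:
        mses = []
        for tr, va in kf.split(X):
            model = Lars(n_nonzero_coefs=size)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X[tr], y[tr])
            resid = y[va] - model.predict(X[va])
            mses.append(float(np.mean(resid**2)))
        mse = float(np.mean(mses))
        if mse < best_mse:  # strict: equal scores keep the smaller active set
            best_size, best_mse = size, mse
    return best_size


def _fit_predict_standardized(
    Xz: np.ndarray, yz: np.ndarray, Xt: np.ndarray, spec: RegressionSpec
) -> np.ndarray:
    if spec.method == "lars":
        size = _tune_lars_size(Xz, yz, spec)
        model = Lars(n_nonzero_coefs=size)
    elif spec.method == "elastic_net":
        model = ElasticNetCV(
            alphas=sorted(spec.enet_alphas, reverse=True),
            l1_ratio=list(spec.enet_l1_ratios),
            cv=KFold(
                n_splits=spec.inner_cv_folds,
                shuffle=True,
                random_state=spec.seed % 2**32,
            ),
            tol=spec.enet_tol,
            max_iter=spec.enet_max_iter,
        )
    else:  # svr_rbf
        model = SVR(
            kernel="rbf", C=spec.svr_c, gamma=spec.svr_gamma, epsilon=spec.svr_epsilon
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Xz, yz)
    return model.predict(Xt)


def fit_predict_partition(
    train_features: np.ndarray,
    train_target: np.ndarray,
    test_features: np.ndarray,
    spec: RegressionSpec,
    *,
    standardize: bool = True,
) -> np.ndarray:
    """Fit the specified regressor on a training fold and predict the test fold.

    With ``standardize=True`` (default) features and target are z-scored using
    training-fold statistics, zero-variance features are dropped with a
    warning, and predictions are inverse-transformed to the original target
    scale. ``standardize=False`` supports callers that pre-scaled globally.
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_target, dtype=float).ravel()
    Xt = np.asarray(test_features, dtype=float)
    if X.ndim != 2 or Xt.ndim != 2 or X.shape[1] != Xt.shape[1]:
        raise ValueError("train and test feature dimensions disagree")
    if X.shape[0] != y.size:
        raise ValueError("train features and target lengths disagree")
    if X.shape[0] < spec.inner_cv_folds:
        raise ValueError(
            f"training fold has {X.shape[0]} conditions, fewer than the "
            f"{spec.inner_cv_folds} inner CV folds"
        )

    if standardize:
        y_sd = float(y.std())
        if y_sd == 0:
            raise ValueError(
                "zero-variance target on the training fold; z-scoring is undefined"
            )
        y_mu = float(y.mean())
        sd = X.std(axis=0)
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance feature(s) "
                "on this training fold"
            )
        if not keep.any():
            # intercept-only model: predict the training mean
            return np.full(Xt.shape[0], y_mu)
        mu = X[:, keep].mean(axis=0)
        Xz = (X[:, keep] - mu) / sd[keep]
        Xtz = (Xt[:, keep] - mu) / sd[keep]
        yz = (y - y_mu) / y_sd
        pred = _fit_predict_standardized(Xz, yz, Xtz, spec)
        return pred * y_sd + y_mu

    return _fit_predict_standardized(X, y, Xt, spec)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation, NaN when undefined (constant input)."""
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def partition_accuracy(
    partition: Partition,
    targets: TargetMatrix,
    predictions: np.ndarray,
) -> pd.DataFrame:
    """Per-gene test-set PCC and RMSD for one partition.

    ``predictions`` has one row per test condition (ascending test index) and
    one column per gene, on the original target scale. PCC is recorded as
    missing for test sets smaller than 3 or constant vectors; RMSD is always
    returned.
    """
    test = partition.test_array
    preds = np.asarray(predictions, dtype=float)
    if preds.shape != (test.size, targets.n_genes):
        raise ValueError(
            f"predictions shape {preds.shape} does not cover the test set "
            f"({test.size} conditions x {targets.n_genes} genes)"
        )
    truth = targets.values[test]
    rmsd = np.sqrt(np.mean((preds - truth) ** 2, axis=0))
    if test.size < 3:
        pcc = np.full(targets.n_genes, np.nan)
        warnings.warn("test set smaller than 3; PCC recorded as missing")
    else:
        pcc = np.array([_pearson(preds[:, g], truth[:, g]) for g in range(targets.n_genes)])
        n_missing = int(np.isnan(pcc).sum())
        if n_missing:
            warnings.warn(f"{n_missing} undefined test-set correlation(s) recorded as missing")
    return pd.DataFrame({"pcc": pcc, "rmsd": rmsd}, index=list(targets.gene_ids))


def pooled_cv_accuracy(
    collection: PartitionCollection,
    targets: TargetMatrix,
    predictions: dict[int, np.ndarray],
) -> pd.Series:
    """Per-gene Pearson correlation between measured values and pooled out-of-fold predictions.

    ``predictions`` maps each partition index to its test-fold prediction
    matrix (rows ordered by ascending test index). Requires an exhaustive
    collection, so every condition is predicted exactly once per gene.
    """
    if collection.kind == "sacv":
        raise ValueError("pooled accuracy requires an exhaustive (rcv/ccv) collection")
    pooled = np.full((collection.n_conditions, targets.n_genes), np.nan)
    for i, p in enumerate(collection):
        if i not in predictions:
            raise ValueError(f"missing predictions for partition {i}")
        test = p.test_array
        preds = np.asarray(predictions[i], dtype=float)
        if preds.shape != (test.size, targets.n_genes):
            raise ValueError(f"predictions for partition {i} have shape {preds.shape}")
        pooled[test] = preds
    if np.isnan(pooled).any():
        raise ValueError("pooled predictions do not cover every condition")
    pcc = np.array(
        [_pearson(pooled[:, g], targets.values[:, g]) for g in range(targets.n_genes)]
    )
    n_missing = int(np.isnan(pcc).sum())
    if n_missing:
        warnings.warn(f"{n_missing} undefined pooled correlation(s) recorded as missing")
    return pd.Series(pcc, index=list(targets.gene_ids), name="pooled_pcc")


@dataclass
class EvaluationResult:
    """Predictions and accuracies of one regressor over one partition collection."""

    method: str
    collection: PartitionCollection
    gene_ids: tuple[str, ...]
    predictions: dict[int, np.ndarray]
    per_partition: pd.DataFrame  # columns: partition, gene_id, pcc, rmsd
    pooled_pcc: Optional[pd.Series] = None
    distinctness_mean: Optional[pd.Series] = None

    def partition_metric(self, metric: str) -> pd.DataFrame:
        """Pivot a per-partition metric into a partitions-by-genes table."""
        return self.per_partition.pivot(index="partition", columns="gene_id", values=metric)[
            list(self.gene_ids)
        ]

    def to_table(self) -> pd.DataFrame:
        """Long results table: gene_id, partition_id, method, pcc, rmsd, distinctness_mean."""
        out = self.per_partition.rename(columns={"partition": "partition_id"}).copy()
        out.insert(2, "method", self.method)
        if self.distinctness_mean is not None:
            out["distinctness_mean"] = out["partition_id"].map(self.distinctness_mean)
        else:
            out["distinctness_mean"] = np.nan
        return out[["gene_id", "partition_id", "method", "pcc", "rmsd", "distinctness_mean"]]


def evaluate_collection(
    conditions: ConditionMatrix,
    targets: TargetMatrix,
    collection: PartitionCollection,
    spec: RegressionSpec,
    distances: Optional[PairwiseDistances] = None,
    *,
    global_zscore: bool = False,
) -> EvaluationResult:
    """Train/predict every (partition, gene) task and collect accuracy metrics.

    Genes are independent tasks; execution order does not affect results.
    With ``global_zscore=True`` features and targets are z-scored once over
    all conditions before CV (a deliberately leaky variant for replication
    studies) instead of per training fold.
    """
    targets.check_aligned(conditions)
    X = conditions.values
    Y = targets.values
    y_mu = np.zeros(targets.n_genes)
    y_sd = np.ones(targets.n_genes)
    if global_zscore:
        sd = X.std(axis=0)
        keep = sd > 0
        X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
        y_sd = Y.std(axis=0)
        if np.any(y_sd == 0):
            raise ValueError("zero-variance target gene; global z-scoring is undefined")
        y_mu = Y.mean(axis=0)
        Y = (Y - y_mu) / y_sd

    predictions: dict[int, np.ndarray] = {}
    frames = []
    for i, p in enumerate(collection):
        p.validate_against(conditions.n_conditions)
        train = p.train_array
        test = p.test_array
        preds = np.empty((test.size, targets.n_genes))
        for g in range(targets.n_genes):
            preds[:, g] = fit_predict_partition(
                X[train], Y[train, g], X[test], spec, standardize=not global_zscore
            )
        if global_zscore:
            preds = preds * y_sd + y_mu
        predictions[i] = preds
        acc = partition_accuracy(p, targets, preds)
        acc = acc.rename_axis("gene_id").reset_index()
        acc.insert(0, "partition", i)
        frames.append(acc)
    per_partition = pd.concat(frames, ignore_index=True)

    pooled = None
    if collection.kind in ("rcv", "ccv"):
        pooled = pooled_cv_accuracy(collection, targets, predictions)
    eta = None
    if distances is not None:
        eta = pd.Series(
            [partition_distinctness(p, distances).mean for p in collection],
            name="distinctness_mean",
        )
    return EvaluationResult(
        method=spec.method,
        collection=collection,
        gene_ids=targets.gene_ids,
        predictions=predictions,
        per_partition=per_partition,
        pooled_pcc=pooled,
        distinctness_mean=eta,
    )


def evaluate_heldout(
    conditions: ConditionMatrix,
    targets: TargetMatrix,
    heldout_conditions: ConditionMatrix,
    heldout_targets: TargetMatrix,
    spec: RegressionSpec,
) -> pd.DataFrame:
    """Train on all given conditions, predict a held-out context; per-gene PCC and RMSD.

    Mirrors testing a model on samples from a biological context absent from
    every training fold.
    """
    heldout_targets.check_aligned(heldout_conditions)
    if conditions.feature_ids != heldout_conditions.feature_ids:
        raise ValueError("held-out conditions must share the training feature set")
    n_test = heldout_conditions.n_conditions
    preds = np.empty((n_test, targets.n_genes))
    for g in range(targets.n_genes):
        preds[:, g] = fit_predict_partition(
            conditions.values, targets.values[:, g], heldout_conditions.values, spec
        )
    truth = heldout_targets.values
    rmsd = np.sqrt(np.mean((preds - truth) ** 2, axis=0))
    pcc = np.array(
        [_pearson(preds[:, g], truth[:, g]) for g in range(targets.n_genes)]
    )
    return pd.DataFrame({"pcc": pcc, "rmsd": rmsd}, index=list(targets.gene_ids))


def compare_methods(
    results_a: EvaluationResult, results_b: EvaluationResult
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-partition distributions of per-gene RMSD differences (method A minus B).

    Returns the long table of differences and a per-partition quartile summary.
    Both results must come from identical partitions and genes.
    """
    if results_a.gene_ids != results_b.gene_ids:
        raise ValueError("results cover different gene sets")
    ca, cb = results_a.collection, results_b.collection
    if len(ca) != len(cb) or any(
        pa.test_indices != pb.test_indices for pa, pb in zip(ca, cb)
    ):
        raise ValueError("results were computed on different partitions")
    a = results_a.partition_metric("rmsd")
    b = results_b.partition_metric("rmsd")
    diff = a - b
    long = diff.stack().rename("rmsd_diff").reset_index()
    summary = pd.DataFrame(
        {
            "q1": diff.quantile(0.25, axis=1),
            "median": diff.median(axis=1),
            "q3": diff.quantile(0.75, axis=1),
        }
    )
    summary.index.name = "partition"
    return long, summary


def distinctness_accuracy_correlation(
    per_partition_distinctness: Sequence[float],
    per_partition_accuracy: pd.DataFrame,
) -> pd.Series:
    """Per-gene Spearman rank correlation between partition distinctness and accuracy.

    ``per_partition_accuracy`` is a partitions-by-genes table (e.g. the PCC
    pivot of an :class:`EvaluationResult`). Ties are handled by average ranks;
    constant accuracy across partitions yields a missing value with a warning.
    """
    eta = np.asarray(per_partition_distinctness, dtype=float)
    if eta.size < 3:
        raise ValueError("need at least 3 partitions for a rank correlation")
    if len(per_partition_accuracy) != eta.size:
        raise ValueError("distinctness and accuracy tables are not aligned")
    out = {}
    n_missing = 0
    for gene in per_partition_accuracy.columns:
        acc = per_partition_accuracy[gene].to_numpy(dtype=float)
        ok = np.isfinite(acc)
        if ok.sum() < 3 or np.ptp(acc[ok]) == 0 or np.ptp(eta[ok]) == 0:
            out[gene] = float("nan")
            n_missing += 1
            continue
        rho = stats.spearmanr(eta[ok], acc[ok]).statistic
        out[gene] = float(rho)
    if n_missing:
        warnings.warn(
            f"{n_missing} gene(s) with constant accuracy; correlation recorded as missing"
        )
    return pd.Series(out, name="spearman_rho")
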