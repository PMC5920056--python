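"""Synthetic clustered expression data with context-specific regulation.

Emulates the statistical structure of a multi-context transcriptomic compendium:
conditions fall into well-separated clusters in TF-expression space (distinct
biological contexts), target genes are sparse linear functions of the TFs whose
coefficients are perturbed per cluster (context-specific regulation), and a
fraction of conditions may be near-duplicate replicates.  Held-out clusters
share each gene's base regulatory program but carry fresh context perturbations,
so held-out accuracy measures cross-context generalization.

Cluster geometry is Gaussian and isotropic: the distinctness score and the
cross-validation comparisons depend only on the geometry, and Gaussians make
the generator's properties easy to reason about and test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datatypes import ConditionMatrix, TargetMatrix

__all__ = [
    "SyntheticConfig",
    "TrueCoefficients",
    "generate_conditions",
    "generate_targets",
    "generate_heldout",
]

# rng stream tags so the three generators draw independent substreams of one seed
_STREAM_CONDITIONS = 101
_STREAM_TARGETS = 202
_STREAM_HELDOUT = 303


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the generator.

    ``cluster_separation`` is the expected centroid spacing in units of the
    within-cluster standard deviation; ``context_shift_sd`` the standard
    deviation of the per-cluster perturbation added to each gene's nonzero
    regulatory coefficients; ``replicate_fraction`` the fraction of conditions
    duplicated with tiny jitter (0.01 x within_sd).
    """

    n_clusters: int = 6
    samples_per_cluster: int = 30
    n_features: int = 50
    cluster_separation: float = 8.0
    within_sd: float = 1.0
    replicate_fraction: float = 0.0
    n_genes: int = 20
    regulators_per_gene: int = 5
    context_shift_sd: float = 0.5
    noise_sd: float = 0.5
    heldout_clusters: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_clusters", "samples_per_cluster", "n_features", "n_genes",
                     "regulators_per_gene", "heldout_clusters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("cluster_separation", "within_sd", "context_shift_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.replicate_fraction < 1:
            raise ValueError("replicate_fraction must lie in [0, 1)")
        if self.regulators_per_gene > self.n_features:
            raise ValueError("regulators_per_gene cannot exceed n_features")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


def _centroid_scale(config: SyntheticConfig) -> float:
    # centroids ~ N(0, tau^2 I): expected pairwise centroid distance is
    # tau * sqrt(2 d), so tau = separation * within_sd / sqrt(2 d)
    return config.cluster_separation * config.within_sd / math.sqrt(2 * config.n_features)


def generate_conditions(config: SyntheticConfig) -> tuple[ConditionMatrix, np.ndarray]:
    """Draw clustered condition feature vectors; returns the matrix and cluster labels.

    Samples are centroid + isotropic Gaussian noise; a ``replicate_fraction``
    of them is duplicated with jitter 0.01 x within_sd, emulating biological
    replicates of the same condition.
    """
    n_base = config.n_clusters * config.samples_per_cluster
    if n_base < 4:
        raise ValueError("need at least 4 conditions (n_clusters x samples_per_cluster)")
    rng = np.random.default_rng([config.seed, _STREAM_CONDITIONS])
    centroids = rng.normal(0.0, _centroid_scale(config), (config.n_clusters, config.n_features))
    labels = np.repeat(np.arange(config.n_clusters), config.samples_per_cluster)
    X = centroids[labels] + rng.normal(0.0, config.within_sd, (n_base, config.n_features))
    ids = [f"s{i:04d}" for i in range(n_base)]

    n_rep = int(round(config.replicate_fraction * n_base))
    if n_rep:
        rep_of = rng.choice(n_base, size=n_rep, replace=False)
        jitter = rng.normal(0.0, 0.01 * config.within_sd, (n_rep, config.n_features))
        X = np.vstack([X, X[rep_of] + jitter])
        labels = np.concatenate([labels, labels[rep_of]])
        ids += [f"s{i:04d}_rep" for i in rep_of]

    matrix = ConditionMatrix(
        values=X,
        condition_ids=tuple(ids),
        feature_ids=tuple(f"tf{j:03d}" for j in range(config.n_features)),
        context_labels=tuple(f"ctx{c}" for c in labels),
    )
    return matrix, labels


@dataclass(frozen=True)
class TrueCoefficients:
    """Ground-truth regulatory programs for parameter-recovery tests.

    ``base`` is the genes-by-features coefficient matrix (sparse rows);
    ``support`` marks each gene's regulators; ``per_cluster`` maps a cluster
    label to the full perturbed coefficient matrix used in that context.
    """

    base: np.ndarray
    support: np.ndarray
    per_cluster: dict[int, np.ndarray]


def generate_targets(
    conditions: ConditionMatrix,
    cluster_labels: np.ndarray,
    config: SyntheticConfig,
) -> tuple[TargetMatrix, TrueCoefficients]:
    """Sparse linear targets with per-cluster coefficient perturbations and noise.

    For each gene a base coefficient vector with ``regulators_per_gene``
    standard-normal nonzeros is drawn; each cluster uses base + N(0,
    context_shift_sd) on the nonzero entries, and targets are the cluster's
    linear map of the features plus N(0, noise_sd) noise.
    """
    labels = np.asarray(cluster_labels)
    if labels.shape[0] != conditions.n_conditions:
        raise ValueError("cluster labels are not aligned with the conditions")
    rng = np.random.default_rng([config.seed, _STREAM_TARGETS])
    G, F = config.n_genes, conditions.n_features
    if config.regulators_per_gene > F:
        raise ValueError("regulators_per_gene cannot exceed the number of features")

    support = np.zeros((G, F), dtype=bool)
    base = np.zeros((G, F))
    for g in range(G):
        regs = rng.choice(F, size=config.regulators_per_gene, replace=False)
        support[g, regs] = True
        base[g, regs] = rng.normal(0.0, 1.0, config.regulators_per_gene)

    per_cluster: dict[int, np.ndarray] = {}
    Y = np.empty((conditions.n_conditions, G))
    for c in sorted(set(int(x) for x in labels)):
        coeffs = base.copy()
        coeffs[support] += rng.normal(0.0, config.context_shift_sd, int(support.sum()))
        per_cluster[c] = coeffs
        rows = np.flatnonzero(labels == c)
        Y[rows] = conditions.values[rows] @ coeffs.T + rng.normal(
            0.0, config.noise_sd, (rows.size, G)
        )
    targets = TargetMatrix(
        values=Y,
        condition_ids=conditions.condition_ids,
        gene_ids=tuple(f"g{j:03d}" for j in range(G)),
    )
    return targets, TrueCoefficients(base=base, support=support, per_cluster=per_cluster)


def generate_heldout(
    config: SyntheticConfig, coefficients: TrueCoefficients
) -> tuple[ConditionMatrix, TargetMatrix]:
    """Fresh clusters from unseen contexts sharing each gene's base regulators.

    New centroids and new per-cluster coefficient perturbations are drawn, so
    accuracy on these conditions reflects generalization to contexts absent
    from training.
    """
    rng = np.random.default_rng([config.seed, _STREAM_HELDOUT])
    H, F = config.heldout_clusters, config.n_features
    if coefficients.base.shape[1] != F:
        raise ValueError("coefficients were generated for a different feature count")
    centroids = rng.normal(0.0, _centroid_scale(config), (H, F))
    labels = np.repeat(np.arange(H), config.samples_per_cluster)
    n = labels.size
    X = centroids[labels] + rng.normal(0.0, config.within_sd, (n, F))
    G = coefficients.base.shape[0]
    Y = np.empty((n, G))
    for c in range(H):
        coeffs = coefficients.base.copy()
        coeffs[coefficients.support] += rng.normal(
            0.0, config.context_shift_sd, int(coefficients.support.sum())
        )
        rows = np.flatnonzero(labels == c)
        Y[rows] = X[rows] @ coeffs.T + rng.normal(0.0, config.noise_sd, (rows.size, G))
    conditions = ConditionMatrix(
        values=X,
        condition_ids=tuple(f"h{i:04d}" for i in range(n)),
        feature_ids=tuple(f"tf{j:03d}" for j in range(F)),
        context_labels=tuple(f"heldout{c}" for c in labels),
    )
    targets = TargetMatrix(
        values=Y,
        condition_ids=conditions.condition_ids,
        gene_ids=tuple(f"g{j:03d}" for j in range(G)),
    )
    return conditions, targets
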