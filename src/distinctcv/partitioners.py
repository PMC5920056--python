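"""Cross-validation partition generators.

Three strategies with increasing control over train/test distinctness:

* :func:`random_kfold` — uniformly random, mutually exclusive, exhaustive folds
  (RCV, the standard approach);
* :func:`clustered_kfold` — k-means clusters of conditions used directly as
  folds (CCV), forcing test conditions away from training conditions;
* :func:`sacv_generate` — simulated annealing over the space of fixed-size
  test sets, maximizing the partition's mean distinctness, from whose accepted
  trajectory a spectrum of partitions with gradually increasing distinctness
  is sampled (SACV).

The annealer uses the partition's *mean* per-test-sample distinctness as its
objective (the collection-level score divides by |C| and does not apply to a
single non-exhaustive partition), proposes uniform single-swap moves between
the test and training sets, and accepts with the Metropolis criterion:
improving moves always, worsening moves with probability exp(delta/T).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .datatypes import (
    ConditionMatrix,
    PairwiseDistances,
    Partition,
    PartitionCollection,
)

__all__ = [
    "SAConfig",
    "random_kfold",
    "clustered_kfold",
    "sacv_generate",
    "metropolis_accept",
]


def _complement(test: np.ndarray, n: int) -> frozenset[int]:
    mask = np.ones(n, dtype=bool)
    mask[test] = False
    return frozenset(int(i) for i in np.flatnonzero(mask))


def random_kfold(n_conditions: int, k: int, seed: int) -> PartitionCollection:
    """Uniformly random exhaustive K-fold split; fold sizes differ by at most 1."""
    if k < 2:
        raise ValueError(f"k must be at least 2, got {k}")
    if k > n_conditions:
        raise ValueError(f"k = {k} exceeds the number of conditions ({n_conditions})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_conditions)
    folds = np.array_split(perm, k)
    partitions = tuple(
        Partition(
            test_indices=frozenset(int(i) for i in fold),
            train_indices=_complement(fold, n_conditions),
        )
        for fold in folds
    )
    return PartitionCollection(partitions=partitions, kind="rcv", n_conditions=n_conditions)


def clustered_kfold(
    conditions: ConditionMatrix, k: int, seed: int, max_retries: int = 10
) -> PartitionCollection:
    """K-means clusters of the condition feature vectors used as CV folds.

    One k-means run per collection (++-style initialization, up to 300
    iterations, relative tolerance 1e-4), seeded for reproducibility. Fold
    sizes may be unequal. A run yielding an empty cluster is re-initialized up
    to ``max_retries`` times before erroring.
    """
    n = conditions.n_conditions
    if k < 2:
        raise ValueError(f"k must be at least 2, got {k}")
    if k >= n:
        raise ValueError(f"k = {k} must be smaller than the number of conditions ({n})")
    sub_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=max_retries)
    labels = None
    for attempt in range(max_retries):
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=1,
            max_iter=300,
            tol=1e-4,
            random_state=int(sub_seeds[attempt]),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            candidate = km.fit_predict(conditions.values)
        if len(np.unique(candidate)) == k:
            labels = candidate
            break
    if labels is None:
        raise RuntimeError(
            f"k-means produced an empty cluster in {max_retries} consecutive runs "
            f"(k = {k}, n = {n}); the data may have fewer than k distinct points"
        )
    partitions = tuple(
        Partition(
            test_indices=frozenset(int(i) for i in np.flatnonzero(labels == c)),
            train_indices=frozenset(int(i) for i in np.flatnonzero(labels != c)),
        )
        for c in range(k)
    )
    return PartitionCollection(partitions=partitions, kind="ccv", n_conditions=n)


@dataclass(frozen=True)
class SAConfig:
    """Simulated-annealing schedule for distinctness-controlled partitions.

    Defaults are sized for compendium-scale data: initial temperature 1, 500
    iterations per temperature level, cooling factor 0.98, stop at 1e-14,
    discard the first 50000 accepted partitions, then sample 30 partitions
    uniformly from the remainder. Scale the schedule down for small datasets
    (see docs/methods.md).
    """

    test_size: int
    t_initial: float = 1.0
    iters_per_temperature: int = 500
    cooling_factor: float = 0.98
    t_min: float = 1e-14
    burn_in: int = 50000
    n_select: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.test_size < 1:
            raise ValueError("test_size must be positive")
        if not 0 < self.cooling_factor < 1:
            raise ValueError("cooling_factor must lie in (0, 1)")
        if not self.t_min < self.t_initial:
            raise ValueError("t_min must be below t_initial")
        if self.t_min <= 0:
            raise ValueError("t_min must be positive")
        if self.iters_per_temperature < 1:
            raise ValueError("iters_per_temperature must be positive")
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")
        if self.n_select < 1:
            raise ValueError("n_select must be positive")


def metropolis_accept(delta: float, temperature: float, unif: float) -> bool:
    """Metropolis rule: accept improvements always, worsenings with exp(delta/T)."""
    if delta >= 0:
        return True
    if temperature <= 0:
        return False
    return unif < math.exp(delta / temperature)


def _mean_eta(s: np.ndarray, z: np.ndarray, n_train: int) -> float:
    """Mean distinctness from per-test inverse-distance sums and zero-distance counts."""
    eta = np.zeros(s.shape[0])
    ok = z == 0
    eta[ok] = n_train / s[ok]
    return float(eta.mean())


def sacv_generate(
    conditions: ConditionMatrix,
    distances: PairwiseDistances,
    config: SAConfig,
) -> tuple[PartitionCollection, pd.DataFrame]:
    """Anneal fixed-size test sets toward high mean distinctness and sample a spectrum.

    Starting from a uniformly random test set of ``config.test_size``
    conditions, each proposal swaps one uniformly chosen test condition with
    one uniformly chosen training condition; acceptance follows the Metropolis
    rule on the change in the partition's mean distinctness. Every accepted
    state is recorded; after discarding the first ``burn_in`` accepted states,
    ``n_select`` states are sampled uniformly without replacement from the
    remainder and returned ordered by acceptance step, so distinctness trends
    upward across the selection.

    Returns the selected collection (kind ``sacv``) and the acceptance trace —
    one row per accepted state with columns ``step`` (proposal index),
    ``temperature``, ``mean_eta`` and ``selected``.
    """
    n = distances.n
    if conditions.n_conditions != n:
        raise ValueError("conditions and distances disagree on the number of conditions")
    m = config.test_size
    if m >= n:
        raise ValueError(f"test_size = {m} must leave at least one training condition (n = {n})")

    rng = np.random.default_rng(config.seed)
    Dn = distances.normalized
    with np.errstate(divide="ignore"):
        W = np.where(Dn > 0, 1.0 / np.where(Dn > 0, Dn, 1.0), 0.0)
    Z = (Dn == 0.0)
    np.fill_diagonal(W, 0.0)
    np.fill_diagonal(Z, False)
    Zi = Z.astype(np.int64)

    S = rng.choice(n, size=m, replace=False)
    mask = np.ones(n, dtype=bool)
    mask[S] = False
    R = np.flatnonzero(mask)
    n_train = n - m

    s = W[np.ix_(S, R)].sum(axis=1)
    z = Zi[np.ix_(S, R)].sum(axis=1)
    current = _mean_eta(s, z, n_train)

    accepted_sets: list[np.ndarray] = []
    trace_step: list[int] = []
    trace_temp: list[float] = []
    trace_eta: list[float] = []

    temperature = config.t_initial
    step = 0
    while temperature > config.t_min:
        for _ in range(config.iters_per_temperature):
            step += 1
            ti = int(rng.integers(m))
            ri = int(rng.integers(n_train))
            t, r = int(S[ti]), int(R[ri])
            # incremental update: t leaves the test set for training, r the reverse
            s_new = s + W[S, t] - W[S, r]
            z_new = z + Zi[S, t] - Zi[S, r]
            s_new[ti] = W[r, R].sum() - W[r, r] + W[r, t]
            z_new[ti] = Zi[r, R].sum() - Zi[r, r] + Zi[r, t]
            proposed = _mean_eta(s_new, z_new, n_train)
            if metropolis_accept(proposed - current, temperature, float(rng.random())):
                S[ti] = r
                R[ri] = t
                s, z = s_new, z_new
                current = proposed
                accepted_sets.append(np.sort(S))
                trace_step.append(step)
                trace_temp.append(temperature)
                trace_eta.append(current)
                if len(accepted_sets) % 1000 == 0:
                    # refresh the incremental sums to cancel float drift
                    s = W[np.ix_(S, R)].sum(axis=1)
                    z = Zi[np.ix_(S, R)].sum(axis=1)
                    current = _mean_eta(s, z, n_train)
        temperature *= config.cooling_factor

    n_accepted = len(accepted_sets)
    if n_accepted <= config.burn_in + config.n_select:
        raise RuntimeError(
            f"only {n_accepted} accepted states for burn_in = {config.burn_in} and "
            f"n_select = {config.n_select}; lengthen the schedule (lower t_min, more "
            "iterations per temperature) or reduce the burn-in"
        )
    pool = n_accepted - config.burn_in
    picked = np.sort(rng.choice(pool, size=config.n_select, replace=False)) + config.burn_in

    partitions = tuple(
        Partition(
            test_indices=frozenset(int(i) for i in accepted_sets[i]),
            train_indices=_complement(accepted_sets[i], n),
        )
        for i in picked
    )
    collection = PartitionCollection(partitions=partitions, kind="sacv", n_conditions=n)
    trace = pd.DataFrame(
        {"step": trace_step, "temperature": trace_temp, "mean_eta": trace_eta}
    )
    trace["selected"] = False
    trace.loc[picked, "selected"] = True
    return collection, trace
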