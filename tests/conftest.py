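"""Shared fixtures: small random instances and the clustered study dataset."""

from __future__ import annotations

import numpy as np
import pytest

from distinctcv import (
    ConditionMatrix,
    SyntheticConfig,
    compute_pairwise_distances,
    generate_conditions,
    generate_targets,
)

#: root seed of the clustered study dataset used across the heavier tests
STUDY_SEED = 7


def make_conditions(n: int, d: int, seed: int) -> ConditionMatrix:
    """Small random condition matrix for oracle tests."""
    rng = np.random.default_rng(seed)
    return ConditionMatrix(
        values=rng.normal(size=(n, d)),
        condition_ids=tuple(f"c{i}" for i in range(n)),
        feature_ids=tuple(f"f{j}" for j in range(d)),
    )


@pytest.fixture(scope="session")
def study_config() -> SyntheticConfig:
    """Six well-separated clusters of 30 conditions, 50 TF features."""
    return SyntheticConfig(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_data(study_config):
    """Conditions, cluster labels, targets and ground-truth coefficients."""
    conditions, labels = generate_conditions(study_config)
    targets, coefficients = generate_targets(conditions, labels, study_config)
    return conditions, labels, targets, coefficients


@pytest.fixture(scope="session")
def study_distances(study_data):
    conditions = study_data[0]
    return compute_pairwise_distances(conditions)
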