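"""Shared fixtures: one well-separated planted dataset reused across the
consensus, score, survival, and acceptance tests (the expensive pieces —
consensus clustering and Boruta — run once per session)."""

import numpy as np
import pytest

from ubipattern import consensus, score
from ubipattern.synthetic import (
    SyntheticConfig,
    default_immune_sets,
    generate_expression,
)

PLANTED_SEED = 7


@pytest.fixture(scope="session")
def planted_config():
    return SyntheticConfig(
        n_samples=200,
        n_patterns=3,
        n_regulator_genes=300,
        n_noise_genes=100,
        pattern_separation=3.0,
        immune_sets=default_immune_sets(3),
        seed=PLANTED_SEED,
    )


@pytest.fixture(scope="session")
def planted(planted_config):
    return generate_expression(planted_config)


@pytest.fixture(scope="session")
def regulator_matrix(planted):
    mask = planted.gene_roles.isin(["positive-regulator", "negative-regulator"])
    return planted.expression.loc[mask.to_numpy()]


@pytest.fixture(scope="session")
def consensus_result(regulator_matrix):
    return consensus.consensus_cluster(
        regulator_matrix, [2, 3, 4, 5, 6], reps=100, subsample=0.8,
        seed=PLANTED_SEED,
    )


@pytest.fixture(scope="session")
def assignment(consensus_result):
    return consensus.assign_patterns(consensus_result, 3)


@pytest.fixture(scope="session")
def partition(regulator_matrix, assignment):
    return score.derive_partition(
        regulator_matrix, assignment, seed=PLANTED_SEED, n_trees=150,
    )


@pytest.fixture(scope="session")
def score_result(regulator_matrix, partition):
    return score.pc1_score(regulator_matrix, partition)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
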