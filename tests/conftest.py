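import numpy as np
import pytest

from napred import (AssociationMatrix, SimilarityMatrix, SyntheticSpec,
                    build_hetero_network, generate_dataset,
                    wang_disease_similarity)


@pytest.fixture(scope="session")
def toy_blocks():
    """Two drugs, one disease: the smallest assembled network."""
    R = SimilarityMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]), ["r1", "r2"])
    A = AssociationMatrix(np.array([[1.0], [0.0]]), ["r1", "r2"], ["d1"])
    D = SimilarityMatrix(np.array([[1.0]]), ["d1"])
    return R, A, D


@pytest.fixture(scope="session")
def toy_networks(toy_blocks):
    R, A, D = toy_blocks
    return [build_hetero_network(R, A, D, m) for m in (1, 2, 3)]


@pytest.fixture(scope="session")
def small_dataset():
    """A scaled-down generated dataset for integration tests."""
    spec = SyntheticSpec(n_drugs=20, n_diseases=15, n_features=(25, 30, 35),
                         density=0.12, seed=7)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_disease_sim(small_dataset):
    return wang_disease_similarity(
        small_dataset.dags,
        disease_ids=small_dataset.associations.disease_ids)


@pytest.fixture(scope="session")
def reference_dataset():
    """The reference study conditions: 60 drugs, 50 diseases, seed 42."""
    return generate_dataset(SyntheticSpec())
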