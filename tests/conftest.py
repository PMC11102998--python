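import numpy as np
import pytest

from mifam import WorldConfig, generate_world
from mifam.fusion_graph import build_fused_inputs
from mifam.training_evaluation import EntityInputs


@pytest.fixture(scope="session")
def small_world():
    """A compact, strongly clustered world for fast pipeline tests."""
    return generate_world(WorldConfig(
        n_drugs=40, n_targets=40, n_drug_clusters=4, n_target_clusters=4,
        view_dims=(24, 24, 24, 24), noise_sd=0.1, n_positive=120, seed=5,
    ))


@pytest.fixture(scope="session")
def small_world_inputs(small_world):
    drugs = EntityInputs(*build_fused_inputs(*small_world.drug_views, pca_dim=16))
    targets = EntityInputs(*build_fused_inputs(*small_world.target_views, pca_dim=16))
    return drugs, targets


def random_graph(rng: np.random.Generator, n: int, p: float = 0.5) -> np.ndarray:
    """Random symmetric 0/1 adjacency with self-loops."""
    A = (rng.random((n, n)) < p).astype(np.int8)
    A = np.maximum(A, A.T)
    np.fill_diagonal(A, 1)
    return A
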