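import numpy as np
import pytest

from pocketgnn import fixtures, nn, pipeline


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture(scope="session")
def pocket_scene():
    """One deterministic mid-size pocket scene with its ground truth."""
    return fixtures.make_pocket_scene(fixtures.SceneSpec(n_residues=20, seed=7))


@pytest.fixture(scope="session")
def small_model():
    """Small untrained model + a featurized graph for architecture tests."""
    scene, _ = fixtures.make_pocket_scene(fixtures.SceneSpec(n_residues=14, seed=3))
    graph, targets = pipeline.training_example(scene)
    config = nn.ModelConfig(hidden_dim=16, n_blocks=2, n_heads=2, att_dim=8, seed=11)
    params = nn.init_params(config)
    return scene, graph, targets, config, params
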