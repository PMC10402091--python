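"""Attention, block, forward, loss and training contracts of the network."""

import numpy as np
import pytest

from pocketgnn import fixtures, nn, pipeline
from pocketgnn.autodiff import Tensor
from pocketgnn.graph import FEATURE_SCHEMA, build_near_surface_graph, featurize, p2rank_reference_featurize
from pocketgnn.nn import (
    ModelConfig,
    _with_self_loops,
    forward,
    gat_layer,
    gatv2_attention,
    attention_block,
    init_params,
    load_checkpoint,
    loss,
    save_checkpoint,
    train,
)
from pocketgnn.types import InvalidInputError, ProteinGraph
from .conftest import random_rotation


def _random_graph(n, rng, n_feat=6):
    coords = rng.uniform(0, 12, size=(n, 3))
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(coords[i] - coords[j]) <= 5.0:
                edges += [(i, j), (j, i)]
    ei = np.array(edges, dtype=int).T if edges else np.zeros((2, 0), int)
    ef = np.zeros((ei.shape[1], 3))
    if ei.shape[1]:
        d = np.linalg.norm(coords[ei[0]] - coords[ei[1]], axis=1)
        ef[:, 0] = 1 / np.maximum(d, 0.1)
    return ProteinGraph(
        node_atom_index=np.arange(n),
        node_coords=coords,
        edge_index=ei,
        edge_features=ef,
        surface_mask=np.ones(n, bool),
        node_features=rng.normal(size=(n, n_feat)),
    )


# -------------------------------------------------------------- attention

def test_attention_normalizes_on_random_graphs():
    rng = np.random.default_rng(0)
    for _ in range(20):
        g = _random_graph(rng.integers(2, 15), rng)
        src, dst, ef = _with_self_loops(g)
        cfg = ModelConfig(in_dim=6, hidden_dim=6, n_blocks=1, n_heads=1, att_dim=4, seed=1)
        p = init_params(cfg)
        alpha = gatv2_attention(
            Tensor(g.node_features), src, dst, ef,
            p["blk0_head0_Watt"], p["blk0_head0_batt"], p["blk0_head0_a"], g.n_nodes,
        )
        sums = np.zeros(g.n_nodes)
        np.add.at(sums, dst, alpha.data.reshape(-1))
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)


def test_isolated_node_attention_is_one():
    rng = np.random.default_rng(1)
    g = _random_graph(1, rng)
    src, dst, ef = _with_self_loops(g)
    cfg = ModelConfig(in_dim=6, hidden_dim=6, n_blocks=1, n_heads=1, att_dim=4)
    p = init_params(cfg)
    alpha = gatv2_attention(
        Tensor(g.node_features), src, dst, ef,
        p["blk0_head0_Watt"], p["blk0_head0_batt"], p["blk0_head0_a"], 1,
    )
    assert alpha.data.reshape(-1)[0] == pytest.approx(1.0)


def test_symmetric_neighbors_get_equal_attention():
    # node 0 flanked by two chemically identical neighbours at equal distance
    g = _random_graph(3, np.random.default_rng(2))
    g.node_features = np.array([[1.0, 0], [0.5, 2.0], [0.5, 2.0]])
    g.edge_index = np.array([[1, 2, 0, 0], [0, 0, 1, 2]])
    g.edge_features = np.tile([0.4, 0.0, 0.0], (4, 1))
    src, dst, ef = _with_self_loops(g)
    cfg = ModelConfig(in_dim=2, hidden_dim=2, n_blocks=1, n_heads=1, att_dim=4, seed=3)
    p = init_params(cfg)
    alpha = gatv2_attention(
        Tensor(g.node_features), src, dst, ef,
        p["blk0_head0_Watt"], p["blk0_head0_batt"], p["blk0_head0_a"], 3,
    ).data.reshape(-1)
    into0 = {(s, d): a for s, d, a in zip(src, dst, alpha) if d == 0}
    assert into0[(1, 0)] == pytest.approx(into0[(2, 0)], abs=1e-12)


# -------------------------------------------------------------- gat layer

def test_uniform_attention_identity_gives_neighborhood_mean():
    rng = np.random.default_rng(4)
    g = _random_graph(6, rng)
    src, dst, _ = _with_self_loops(g)
    indeg = np.bincount(dst, minlength=6).astype(float)
    alpha = Tensor((1.0 / indeg[dst])[:, None])
    x = Tensor(g.node_features)
    sum_agg, _ = gat_layer(x, src, dst, alpha, None, 6)
    for i in range(6):
        nbrs = src[dst == i]
        np.testing.assert_allclose(
            sum_agg.data[i], g.node_features[nbrs].mean(axis=0), atol=1e-12
        )


def test_concentrated_attention_selects_neighbor():
    g = _random_graph(3, np.random.default_rng(5))
    g.edge_index = np.array([[1, 0], [0, 1]])
    g.edge_features = np.zeros((2, 3))
    src, dst, _ = _with_self_loops(g)
    alpha = np.zeros(len(src))
    alpha[(src == 1) & (dst == 0)] = 1.0          # node 0 looks only at node 1
    alpha[(src == dst)] = 1.0
    alpha[(src == 0) & (dst == 0)] = 0.0
    sum_agg, _ = gat_layer(Tensor(g.node_features), src, dst, Tensor(alpha[:, None]), None, 3)
    np.testing.assert_allclose(sum_agg.data[0], g.node_features[1], atol=1e-12)


def test_gat_layer_matches_brute_force_loop():
    rng = np.random.default_rng(6)
    g = _random_graph(10, rng)
    src, dst, ef = _with_self_loops(g)
    cfg = ModelConfig(in_dim=6, hidden_dim=6, n_blocks=1, n_heads=1, att_dim=4, seed=7)
    p = init_params(cfg)
    x = Tensor(g.node_features)
    alpha = gatv2_attention(
        x, src, dst, ef, p["blk0_head0_Watt"], p["blk0_head0_batt"],
        p["blk0_head0_a"], 10,
    )
    wv = p["blk0_head0_Wval"]
    sum_agg, mean_agg = gat_layer(x, src, dst, alpha, wv, 10)
    v = g.node_features @ wv.data
    for i in range(10):
        mask = dst == i
        expected = (alpha.data[mask] * v[src[mask]]).sum(axis=0)
        np.testing.assert_allclose(sum_agg.data[i], expected, atol=1e-10)
        np.testing.assert_allclose(mean_agg.data[i], expected / mask.sum(), atol=1e-10)


def test_sum_and_mean_aggregation_differ_by_neighbor_count():
    # path graph 0-1-2 with identical node states: sum equals the common
    # state (attention normalizes), mean divides by in-degree incl. self
    g = _random_graph(3, np.random.default_rng(7))
    g.node_features = np.tile([1.0, 2.0], (3, 1))
    g.edge_index = np.array([[0, 1, 1, 2], [1, 0, 2, 1]])
    g.edge_features = np.tile([0.25, 0, 0], (4, 1))
    src, dst, _ = _with_self_loops(g)
    indeg = np.bincount(dst, minlength=3).astype(float)
    alpha = Tensor((1.0 / indeg[dst])[:, None])
    sum_agg, mean_agg = gat_layer(Tensor(g.node_features), src, dst, alpha, None, 3)
    np.testing.assert_allclose(sum_agg.data, g.node_features, atol=1e-12)
    np.testing.assert_allclose(
        mean_agg.data, g.node_features / indeg[:, None], atol=1e-12
    )
    assert list(indeg) == [2.0, 3.0, 2.0]


def test_block_with_zero_mixing_is_pure_residual():
    rng = np.random.default_rng(8)
    g = _random_graph(5, rng, n_feat=8)
    cfg = ModelConfig(in_dim=8, hidden_dim=8, n_blocks=1, n_heads=2, att_dim=4, seed=9)
    p = init_params(cfg)
    p["blk0_Wmix"].data[:] = 0.0
    src, dst, ef = _with_self_loops(g)
    x = Tensor(g.node_features)
    out = attention_block(x, src, dst, ef, p, 0, cfg)
    expected = np.where(g.node_features > 0, g.node_features,
                        np.exp(g.node_features) - 1)
    np.testing.assert_allclose(out.data, expected, atol=1e-12)


# ----------------------------------------------------- forward invariances

def test_scores_bounded_for_random_inputs(small_model):
    _, graph, _, config, params = small_model
    res = forward(graph, params, config)
    assert np.all(res.node_scores >= 0) and np.all(res.node_scores <= 1)
    assert len(res.scored.scores) == graph.surface_mask.sum()


def test_forward_rotation_invariant(small_model):
    scene, graph, _, config, params = small_model
    rng = np.random.default_rng(10)
    base = forward(graph, params, config).node_scores
    moved = scene.transformed(random_rotation(rng), rng.uniform(-40, 40, 3))
    g2 = pipeline.prepare_graph(moved)
    np.testing.assert_allclose(
        forward(g2, params, config).node_scores, base, atol=1e-6
    )


def test_duplicated_disconnected_copy_scores_identically(small_model):
    _, graph, _, config, params = small_model
    n = graph.n_nodes
    shift = np.array([500.0, 0.0, 0.0])
    doubled = ProteinGraph(
        node_atom_index=np.concatenate([graph.node_atom_index,
                                        graph.node_atom_index + 10000]),
        node_coords=np.vstack([graph.node_coords, graph.node_coords + shift]),
        edge_index=np.concatenate([graph.edge_index, graph.edge_index + n], axis=1),
        edge_features=np.vstack([graph.edge_features, graph.edge_features]),
        surface_mask=np.concatenate([graph.surface_mask, graph.surface_mask]),
        node_features=np.vstack([graph.node_features, graph.node_features]),
    )
    scores = forward(doubled, params, config).node_scores
    np.testing.assert_allclose(scores[:n], scores[n:], atol=1e-9)
    np.testing.assert_allclose(
        scores[:n], forward(graph, params, config).node_scores, atol=1e-9
    )


def test_node_permutation_equivariance(small_model):
    _, graph, _, config, params = small_model
    rng = np.random.default_rng(11)
    perm = rng.permutation(graph.n_nodes)
    inv = np.argsort(perm)
    permuted = ProteinGraph(
        node_atom_index=graph.node_atom_index[perm],
        node_coords=graph.node_coords[perm],
        edge_index=inv[graph.edge_index],
        edge_features=graph.edge_features,
        surface_mask=graph.surface_mask[perm],
        node_features=graph.node_features[perm],
    )
    base = forward(graph, params, config).node_scores
    np.testing.assert_allclose(
        forward(permuted, params, config).node_scores, base[perm], atol=1e-9
    )


def test_zero_noise_training_input_is_clean(small_model):
    _, graph, _, config, params = small_model
    import dataclasses

    cfg = dataclasses.replace(config, noise_sigma=0.0)
    res_train = forward(graph, params, cfg, training=True,
                        rng=np.random.default_rng(0))
    res_eval = forward(graph, params, cfg)
    np.testing.assert_allclose(res_train.node_scores, res_eval.node_scores, atol=1e-12)
    assert res_train.clean_features is graph.node_features
    assert res_train.reconstruction is not None


# ------------------------------------------------- fixed-weight reduction

def test_gat_layer_with_frozen_weights_reduces_to_reference_featurizer():
    scene, _ = fixtures.make_pocket_scene(fixtures.SceneSpec(n_residues=12, seed=13))
    g = featurize(scene, build_near_surface_graph(scene, cutoff=6.0))
    src, dst, _ = _with_self_loops(g)
    d = np.linalg.norm(g.node_coords[src] - g.node_coords[dst], axis=1)
    w = 1.0 - d / 6.0
    denom = np.zeros(g.n_nodes)
    np.add.at(denom, dst, w)
    alpha = Tensor((w / denom[dst])[:, None])
    sum_agg, _ = gat_layer(Tensor(g.node_features), src, dst, alpha, None, g.n_nodes)
    reference = p2rank_reference_featurize(g.node_coords, scene, g, radius=6.0)
    np.testing.assert_allclose(sum_agg.data, reference, atol=1e-6)


# ------------------------------------------------------------------- loss

def _tiny_case():
    g = _random_graph(8, np.random.default_rng(14), n_feat=FEATURE_SCHEMA.n_features)
    cfg = ModelConfig(hidden_dim=8, n_blocks=1, n_heads=1, att_dim=4, seed=15)
    p = init_params(cfg)
    return g, cfg, p


def test_loss_zero_at_perfect_fit():
    from pocketgnn.labeling import AtomTargets

    g, cfg, p = _tiny_case()
    res = forward(g, p, cfg, training=True, rng=np.random.default_rng(0))
    targets = AtomTargets(atom_indices=g.node_atom_index, scores=res.node_scores)
    res.reconstruction = Tensor(res.clean_features)  # perfect denoiser
    assert loss(res, targets, g, cfg).data == pytest.approx(0.0, abs=1e-9)


def test_loss_additivity_in_denoise_weight():
    import dataclasses
    from pocketgnn.labeling import AtomTargets

    g, cfg, p = _tiny_case()
    res = forward(g, p, cfg, training=True, rng=np.random.default_rng(1))
    targets = AtomTargets(
        atom_indices=g.node_atom_index,
        scores=np.clip(res.node_scores + 0.1, 0, 1),
    )
    l0 = loss(res, targets, g, dataclasses.replace(cfg, denoise_loss_weight=0.0)).data
    l1 = loss(res, targets, g, dataclasses.replace(cfg, denoise_loss_weight=1.0)).data
    mse = ((res.reconstruction.data - res.clean_features) ** 2).mean()
    assert l1 == pytest.approx(l0 + mse, rel=1e-9)


def test_loss_closed_form_uniform_scores():
    """Uniform 0.5 scores vs 0.3 targets: per-node ln2 - H(0.3)."""
    from pocketgnn.labeling import AtomTargets

    g, cfg, p = _tiny_case()
    res = forward(g, p, cfg)
    res.logits = Tensor(np.zeros((g.n_nodes, 1)))  # scores exactly 0.5
    targets = AtomTargets(atom_indices=g.node_atom_index,
                          scores=np.full(g.n_nodes, 0.3))
    expected = np.log(2) - (-0.3 * np.log(0.3) - 0.7 * np.log(0.7))
    assert loss(res, targets, g, cfg).data == pytest.approx(expected, abs=1e-12)


# --------------------------------------------------------------- training

@pytest.fixture(scope="module")
def tiny_training():
    scenes = [fixtures.make_pocket_scene(fixtures.SceneSpec(n_residues=10, seed=40 + i))
              for i in range(2)]
    dataset = [pipeline.training_example(s) for s, _ in scenes]
    cfg = ModelConfig(hidden_dim=16, n_blocks=2, n_heads=2, att_dim=8,
                      lr=3e-3, seed=5)
    params, trace = train(dataset, cfg, epochs=120)
    return dataset, cfg, params, trace


def test_training_reduces_loss(tiny_training):
    _, _, _, trace = tiny_training
    assert trace[-1] < 0.5 * trace[0]


def test_training_deterministic(tiny_training):
    dataset, cfg, _, trace = tiny_training
    _, trace2 = train(dataset, cfg, epochs=5)
    _, trace3 = train(dataset, cfg, epochs=5)
    np.testing.assert_array_equal(trace2, trace3)


def test_checkpoint_roundtrip_bit_identical(tiny_training, tmp_path):
    dataset, cfg, params, _ = tiny_training
    path = tmp_path / "model.npz"
    save_checkpoint(path, params, cfg)
    params2, cfg2 = load_checkpoint(path)
    g = dataset[0][0]
    s1 = forward(g, params, cfg).node_scores
    s2 = forward(g, params2, cfg2).node_scores
    np.testing.assert_array_equal(s1, s2)


def test_checkpoint_schema_mismatch_refused(tiny_training, tmp_path):
    import json

    dataset, cfg, params, _ = tiny_training
    path = tmp_path / "model.npz"
    save_checkpoint(path, params, cfg)
    d = dict(np.load(path, allow_pickle=False))
    meta = json.loads(str(d["__meta__"]))
    meta["feature_schema"] = "something-else-v9"
    d["__meta__"] = np.array(json.dumps(meta))
    np.savez(tmp_path / "bad.npz", **d)
    with pytest.raises(InvalidInputError, match="schema"):
        load_checkpoint(tmp_path / "bad.npz")


def test_empty_dataset_rejected():
    with pytest.raises(InvalidInputError):
        train([], ModelConfig(hidden_dim=8, n_blocks=1, att_dim=4))


def test_denoising_head_beats_oversmoothing(tiny_training):
    """After training with the denoising regularizer the reconstruction
    error is far below the input feature variance: last-block states stay
    distinct enough to recover heterogeneous inputs."""
    dataset, cfg, params, _ = tiny_training
    g = dataset[0][0]
    res = forward(g, params, cfg, training=True, rng=np.random.default_rng(2))
    mse = ((res.reconstruction.data - res.clean_features) ** 2).mean()
    var = res.clean_features.var()
    assert mse < 0.25 * var
    last = res.reconstruction.data
    assert np.std(last, axis=0).max() > 1e-3
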