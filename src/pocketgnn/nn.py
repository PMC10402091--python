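"""Graph-attention network scoring surface atoms for ligand-binding likelihood.

Architecture: an MLP encoder lifts chemical node features to a hidden state;
a stack of attention blocks performs message passing; an MLP decoder reads a
jumping-knowledge concatenation of every block's output and squashes to a
per-atom score in [0,1]. Each block is a GATv2-style attention layer with
edge features, four heads whose summed *and* averaged messages are mixed by
a linear layer, instance normalization, a residual skip and an Elu — the
dual sum/mean aggregation lets the block weigh neighbourhood density
(sum) against composition (mean) per feature.

Attention (per head, over neighbours k of i including a self-loop):

    alpha_ij = softmax_j( a^T LeakyReLU( W_att [x_i || x_j || e_ij] ) )
    x'_i     = sum_j alpha_ij W_val x_j

Training uses the Noisy Nodes regularizer: Gaussian noise is added to the
continuous input channels and an auxiliary head must reconstruct the clean
features from the last block's states, which keeps deep representations
from oversmoothing. The score loss is the binary KL divergence between
predicted scores and the continuous distance-based targets (zero exactly at
a perfect fit); the reconstruction term is mean-squared error.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import Tensor, concat, gather_rows, segment_softmax, segment_sum
from .graph import FEATURE_SCHEMA
from .labeling import AtomTargets
from .types import InvalidInputError, ProteinGraph

__all__ = [
    "ModelConfig",
    "ScoredAtoms",
    "init_params",
    "gatv2_attention",
    "gat_layer",
    "attention_block",
    "forward",
    "loss",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]

SELF_EDGE_FEATURE = np.array([1.0, 0.0, 0.0])  # inverse-distance sentinel, no bond


@dataclass
class ModelConfig:
    in_dim: int = FEATURE_SCHEMA.n_features
    hidden_dim: int = 64
    n_blocks: int = 4
    n_heads: int = 4
    att_dim: int = 16            # hidden width of the attention MLP
    edge_dim: int = 3
    noise_sigma: float = 0.02
    denoise_loss_weight: float = 0.1
    dropout: float = 0.0
    leaky_slope: float = 0.2
    lr: float = 1e-3
    jk_include_encoder: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_heads < 1 or self.noise_sigma < 0:
            raise InvalidInputError("n_heads >= 1 and noise_sigma >= 0 required")
        if min(self.in_dim, self.hidden_dim, self.n_blocks, self.att_dim) <= 0:
            raise InvalidInputError("dimensions must be positive")

    @property
    def head_dim(self) -> int:
        return max(1, self.hidden_dim // self.n_heads)

    @property
    def jk_dim(self) -> int:
        return self.hidden_dim * (self.n_blocks + (1 if self.jk_include_encoder else 0))


@dataclass
class ScoredAtoms:
    """Binding likelihood in [0,1] for each surface atom."""

    atom_indices: np.ndarray   # protein-atom indices (surface atoms)
    scores: np.ndarray         # aligned, values in [0,1]


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> Tensor:
    lim = np.sqrt(6.0 / (n_in + n_out))
    return Tensor(rng.uniform(-lim, lim, size=(n_in, n_out)), requires_grad=True)


def _zeros(*shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def init_params(config: ModelConfig, rng: np.random.Generator | None = None) -> dict:
    """Glorot-initialized parameter dictionary, deterministic per seed."""
    rng = rng or np.random.default_rng(config.seed)
    h, f = config.hidden_dim, config.in_dim
    p: dict[str, Tensor] = {
        "enc_W1": _glorot(rng, f, h), "enc_b1": _zeros(h),
        "enc_W2": _glorot(rng, h, h), "enc_b2": _zeros(h),
    }
    att_in = 2 * h + config.edge_dim
    for b in range(config.n_blocks):
        for k in range(config.n_heads):
            p[f"blk{b}_head{k}_Watt"] = _glorot(rng, att_in, config.att_dim)
            p[f"blk{b}_head{k}_batt"] = _zeros(config.att_dim)
            p[f"blk{b}_head{k}_a"] = _glorot(rng, config.att_dim, 1)
            p[f"blk{b}_head{k}_Wval"] = _glorot(rng, h, config.head_dim)
        mix_in = 2 * config.n_heads * config.head_dim
        p[f"blk{b}_Wmix"] = _glorot(rng, mix_in, h)
        p[f"blk{b}_bmix"] = _zeros(h)
        p[f"blk{b}_gamma"] = Tensor(np.ones(h), requires_grad=True)
        p[f"blk{b}_beta"] = _zeros(h)
    p.update(
        dec_W1=_glorot(rng, config.jk_dim, h), dec_b1=_zeros(h),
        dec_W2=_glorot(rng, h, 1), dec_b2=_zeros(1),
        den_W1=_glorot(rng, h, h), den_b1=_zeros(h),
        den_W2=_glorot(rng, h, f), den_b2=_zeros(f),
    )
    return p


def _with_self_loops(g: ProteinGraph):
    n = g.n_nodes
    loops = np.arange(n)
    src = np.concatenate([g.edge_index[0], loops])
    dst = np.concatenate([g.edge_index[1], loops])
    ef = np.concatenate([g.edge_features, np.tile(SELF_EDGE_FEATURE, (n, 1))], axis=0)
    return src, dst, ef


def gatv2_attention(
    x: Tensor,
    src: np.ndarray,
    dst: np.ndarray,
    edge_features: np.ndarray,
    Watt: Tensor,
    batt: Tensor,
    a: Tensor,
    n_nodes: int,
    leaky_slope: float = 0.2,
) -> Tensor:
    """Attention coefficients alpha (one per directed edge incl. self-loops).

    For each receiving node the coefficients over its in-edges sum to 1.
    """
    z = concat([gather_rows(x, dst), gather_rows(x, src), Tensor(edge_features)], axis=1)
    scores = (z @ Watt + batt).leaky_relu(leaky_slope) @ a  # (E,1)
    return segment_softmax(scores, dst, n_nodes)


def gat_layer(
    x: Tensor,
    src: np.ndarray,
    dst: np.ndarray,
    alpha: Tensor,
    Wval: Tensor | None,
    n_nodes: int,
):
    """One attention-weighted message pass.

    Returns (sum_agg, mean_agg): the attention-weighted sum of transformed
    neighbour states per node, and the same divided by the in-degree
    (self-loop included). ``Wval=None`` means identity value transform.
    """
    v = x if Wval is None else x @ Wval
    messages = alpha * gather_rows(v, src)
    sum_agg = segment_sum(messages, dst, n_nodes)
    counts = np.bincount(dst, minlength=n_nodes).astype(float)
    counts[counts == 0] = 1.0
    mean_agg = sum_agg * Tensor((1.0 / counts)[:, None])
    return sum_agg, mean_agg


def _instance_norm(t: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = t.mean(axis=0, keepdims=True)
    centered = t - mu
    var = centered.square().mean(axis=0, keepdims=True)
    return centered / (var + eps).sqrt() * gamma + beta


def attention_block(
    x: Tensor,
    src: np.ndarray,
    dst: np.ndarray,
    edge_features: np.ndarray,
    params: dict,
    block: int,
    config: ModelConfig,
) -> Tensor:
    """Multi-head, dual-aggregation attention block with residual skip.

    out = Elu( x + InstanceNorm( Linear([sum_agg_heads || mean_agg_heads]) ) )
    """
    n = x.shape[0]
    sums, means = [], []
    for k in range(config.n_heads):
        alpha = gatv2_attention(
            x, src, dst, edge_features,
            params[f"blk{block}_head{k}_Watt"],
            params[f"blk{block}_head{k}_batt"],
            params[f"blk{block}_head{k}_a"],
            n, config.leaky_slope,
        )
        s, m = gat_layer(x, src, dst, alpha, params[f"blk{block}_head{k}_Wval"], n)
        sums.append(s)
        means.append(m)
    mixed = concat(sums + means, axis=1) @ params[f"blk{block}_Wmix"] + params[f"blk{block}_bmix"]
    normed = _instance_norm(mixed, params[f"blk{block}_gamma"], params[f"blk{block}_beta"])
    return (x + normed).elu()


@dataclass
class ForwardResult:
    scored: ScoredAtoms
    node_scores: np.ndarray          # (n_nodes,) all graph nodes
    logits: Tensor                   # (n_nodes, 1)
    reconstruction: Tensor | None    # (n_nodes, in_dim) in training mode
    clean_features: np.ndarray


def _dropout(t: Tensor, rate: float, rng) -> Tensor:
    if rate <= 0 or rng is None:
        return t
    mask = (rng.random(t.shape) >= rate) / (1.0 - rate)
    return t * Tensor(mask)


def forward(
    graph: ProteinGraph,
    params: dict,
    config: ModelConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> ForwardResult:
    """Score every node; report surface nodes as :class:`ScoredAtoms`.

    In training mode Gaussian noise (sigma = ``config.noise_sigma``) is
    added to the continuous input channels and the denoising head
    reconstructs the clean features from the last block's states.
    """
    if graph.node_features is None:
        raise InvalidInputError("graph is not featurized")
    if graph.node_features.shape[1] != config.in_dim:
        raise InvalidInputError(
            f"feature dim {graph.node_features.shape[1]} != config.in_dim {config.in_dim}"
        )
    clean = graph.node_features
    xin = clean
    if training and config.noise_sigma > 0:
        rng = rng or np.random.default_rng(config.seed)
        noise = np.zeros_like(clean)
        cmask = FEATURE_SCHEMA.continuous_mask()
        noise[:, cmask] = rng.normal(0.0, config.noise_sigma, size=(len(clean), cmask.sum()))
        xin = clean + noise
    src, dst, ef = _with_self_loops(graph)

    x = Tensor(xin)
    h = (x @ params["enc_W1"] + params["enc_b1"]).elu()
    h = _dropout(h, config.dropout if training else 0.0, rng)
    h = (h @ params["enc_W2"] + params["enc_b2"]).elu()
    encoded = h

    block_outs = []
    for b in range(config.n_blocks):
        h = attention_block(h, src, dst, ef, params, b, config)
        block_outs.append(h)

    # jumping knowledge: the decoder reads every block's output concatenated
    # (optionally the encoder output too)
    jk_list = ([encoded] if config.jk_include_encoder else []) + block_outs
    jk = concat(jk_list, axis=1)
    d = (jk @ params["dec_W1"] + params["dec_b1"]).elu()
    d = _dropout(d, config.dropout if training else 0.0, rng)
    logits = d @ params["dec_W2"] + params["dec_b2"]
    node_scores = (0.5 * (1.0 + np.tanh(0.5 * logits.data))).reshape(-1)

    recon = None
    if training:
        r = (block_outs[-1] @ params["den_W1"] + params["den_b1"]).elu()
        recon = r @ params["den_W2"] + params["den_b2"]

    scored = ScoredAtoms(
        atom_indices=graph.node_atom_index[graph.surface_mask],
        scores=node_scores[graph.surface_mask],
    )
    return ForwardResult(
        scored=scored,
        node_scores=node_scores,
        logits=logits,
        reconstruction=recon,
        clean_features=clean,
    )


def _binary_entropy(t: np.ndarray) -> np.ndarray:
    """H(t) = -t ln t - (1-t) ln(1-t), with 0 ln 0 = 0."""
    h = np.zeros_like(t)
    for v, lv in ((t, t), (1 - t, 1 - t)):
        mask = v > 0
        h[mask] -= v[mask] * np.log(lv[mask])
    return h


def loss(
    result: ForwardResult,
    targets: AtomTargets,
    graph: ProteinGraph,
    config: ModelConfig,
) -> Tensor:
    """Binary KL between scores and soft targets + weighted reconstruction MSE.

    The score term is cross-entropy minus the target entropy, so it is
    non-negative and exactly zero when scores equal the targets; its
    gradient matches plain binary cross-entropy. The reconstruction term is
    the mean squared error of the denoising head over all nodes.
    """
    surf_nodes = np.flatnonzero(graph.surface_mask)
    target_by_atom = dict(zip(targets.atom_indices.tolist(), targets.scores))
    try:
        t = np.array(
            [target_by_atom[int(graph.node_atom_index[i])] for i in surf_nodes]
        )
    except KeyError as exc:
        raise InvalidInputError(f"target missing for surface atom {exc}") from exc
    z = result.logits[graph.surface_mask]  # (n_surf, 1)
    t_col = t[:, None]
    bce = z.softplus() - z * Tensor(t_col)
    kl = bce.mean() - float(_binary_entropy(t_col).mean())
    total = kl
    if result.reconstruction is not None and config.denoise_loss_weight > 0:
        err = result.reconstruction - Tensor(result.clean_features)
        total = total + config.denoise_loss_weight * err.square().mean()
    return total


class Adam:
    """Plain Adam over a parameter dictionary."""

    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def train(
    dataset: list[tuple[ProteinGraph, AtomTargets]],
    config: ModelConfig,
    epochs: int = 300,
    params: dict | None = None,
    callback=None,
) -> tuple[dict, list[float]]:
    """Full-batch-per-graph Adam training; deterministic given config.seed.

    Returns the trained parameters and the per-epoch mean loss trace.
    Aborts with a diagnostic on NaN loss.
    """
    if not dataset:
        raise InvalidInputError("empty training dataset")
    rng = np.random.default_rng(config.seed)
    params = params if params is not None else init_params(config, rng)
    opt = Adam(params, lr=config.lr)
    trace: list[float] = []
    order = np.arange(len(dataset))
    for epoch in range(epochs):
        rng.shuffle(order)
        epoch_losses = []
        for gi in order:
            graph, targets = dataset[gi]
            opt.zero_grad()
            result = forward(graph, params, config, training=True, rng=rng)
            lv = loss(result, targets, graph, config)
            if not np.isfinite(lv.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, graph {gi}: {lv.data}"
                )
            lv.backward()
            opt.step()
            epoch_losses.append(float(lv.data))
        trace.append(float(np.mean(epoch_losses)))
        if callback is not None:
            callback(epoch, trace[-1])
    return params, trace


def save_checkpoint(path, params: dict, config: ModelConfig) -> None:
    """Checkpoint = parameters + config + feature-schema version (npz)."""
    meta = json.dumps(
        {"config": asdict(config), "feature_schema": FEATURE_SCHEMA.version}
    )
    np.savez(path, __meta__=np.array(meta), **{k: p.data for k, p in params.items()})


def load_checkpoint(path) -> tuple[dict, ModelConfig]:
    """Load a checkpoint; refuses to load across feature-schema versions."""
    d = np.load(path, allow_pickle=False)
    meta = json.loads(str(d["__meta__"]))
    if meta["feature_schema"] != FEATURE_SCHEMA.version:
        raise InvalidInputError(
            f"checkpoint schema {meta['feature_schema']!r} does not match "
            f"current {FEATURE_SCHEMA.version!r}"
        )
    config = ModelConfig(**meta["config"])
    params = {
        k: Tensor(d[k], requires_grad=True) for k in d.files if k != "__meta__"
    }
    return params, config
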