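"""Message-passing encoder-decoder over backbone neighbor graphs.

The encoder runs node updates (edge-conditioned messages summed over
neighbors, residual + layer norm, position-wise feed-forward) and, when
enabled, edge updates of the same shape.  The decoder is order-agnostic
autoregressive: for each position it consumes the token embeddings of
neighbors already decoded under the chosen permutation (zeroed otherwise, so
only the encoder-derived stream remains), which makes every position's
logits a function of structure plus previously decoded identities only.

Parameter accounting is exact and closed-form per block; see
``count_parameters``.
"""

from __future__ import annotations

import dataclasses
import io
import json
import zipfile
from typing import Sequence

import numpy as np

from . import nn
from .alphabet import VOCAB_SIZE
from .errors import ConfigurationError
from .features import FeaturizerConfig, NeighborGraph

__all__ = [
    "ModelConfig",
    "ModelParams",
    "GraphBatch",
    "param_inventory",
    "count_parameters",
    "init_params",
    "encode",
    "decode_logits",
    "attend_from_ranks",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_SCHEMA_VERSION = 1


@dataclasses.dataclass
class ModelConfig:
    """Architecture hyperparameters (3+3 layers, 128 hidden by default)."""

    n_encoder_layers: int = 3
    n_decoder_layers: int = 3
    hidden_dim: int = 128
    ffn_multiplier: int = 4
    vocab: int = VOCAB_SIZE
    dropout: float = 0.1
    edge_updates: bool = True
    featurizer: FeaturizerConfig = dataclasses.field(default_factory=FeaturizerConfig)

    def __post_init__(self):
        if min(self.n_encoder_layers, self.n_decoder_layers,
               self.hidden_dim, self.ffn_multiplier) < 1:
            raise ValueError("layer counts, hidden_dim, ffn_multiplier must be >= 1")
        if self.vocab < 2:
            raise ValueError("vocab must be >= 2")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["featurizer"] = FeaturizerConfig(**d.get("featurizer", {}))
        return cls(**d)


def _mlp3_shapes(prefix: str, d_in: int, h: int) -> list[tuple[str, tuple[int, ...]]]:
    """Three-layer message transform: d_in -> h -> h -> h, biased."""
    return [
        (f"{prefix}.W1", (d_in, h)), (f"{prefix}.b1", (h,)),
        (f"{prefix}.W2", (h, h)), (f"{prefix}.b2", (h,)),
        (f"{prefix}.W3", (h, h)), (f"{prefix}.b3", (h,)),
    ]


def _norm_shapes(prefix: str, h: int) -> list[tuple[str, tuple[int, ...]]]:
    return [(f"{prefix}.gain", (h,)), (f"{prefix}.offset", (h,))]


def param_inventory(config: ModelConfig) -> list[tuple[str, tuple[int, ...]]]:
    """Ordered (name, shape) inventory of every weight block."""
    h = config.hidden_dim
    f = config.ffn_multiplier
    inv: list[tuple[str, tuple[int, ...]]] = []
    # bias-free projection of raw edge features, then layer norm
    inv.append(("edge_proj.W", (config.featurizer.edge_width, h)))
    inv += _norm_shapes("edge_proj.norm", h)
    inv.append(("token_emb.W", (config.vocab, h)))
    for layer in range(config.n_encoder_layers):
        p = f"enc{layer}"
        inv += _mlp3_shapes(f"{p}.msg", 3 * h, h)
        inv += _norm_shapes(f"{p}.norm1", h)
        inv += [(f"{p}.ffn.W1", (h, f * h)), (f"{p}.ffn.b1", (f * h,)),
                (f"{p}.ffn.W2", (f * h, h)), (f"{p}.ffn.b2", (h,))]
        inv += _norm_shapes(f"{p}.norm2", h)
        if config.edge_updates:
            inv += _mlp3_shapes(f"{p}.edge", 3 * h, h)
            inv += _norm_shapes(f"{p}.edge_norm", h)
    for layer in range(config.n_decoder_layers):
        p = f"dec{layer}"
        inv += _mlp3_shapes(f"{p}.msg", 3 * h, h)
        inv += _norm_shapes(f"{p}.norm1", h)
        inv += [(f"{p}.ffn.W1", (h, f * h)), (f"{p}.ffn.b1", (f * h,)),
                (f"{p}.ffn.W2", (f * h, h)), (f"{p}.ffn.b2", (h,))]
        inv += _norm_shapes(f"{p}.norm2", h)
    inv.append(("out_proj.W", (h, config.vocab)))
    inv.append(("out_proj.b", (config.vocab,)))
    return inv


def count_parameters(config: ModelConfig) -> int:
    """Exact scalar count, written as a closed form per block.

    Per-layer costs at hidden h, feed-forward multiplier f:
      message MLP  (3h+1)h + 2(h+1)h
      edge MLP     (3h+1)h + 2(h+1)h          (encoder only, when enabled)
      feed-forward (h+1)fh + (fh+1)h
      layer norm   2h each
    plus the bias-free edge input projection (edge_width x h with norm 2h),
    token embedding (vocab x h) and output projection ((h+1) x vocab).
    """
    h = config.hidden_dim
    f = config.ffn_multiplier
    msg = (3 * h + 1) * h + 2 * (h + 1) * h
    ffn = (h + 1) * f * h + (f * h + 1) * h
    node_layer = msg + 2 * h + ffn + 2 * h
    edge_layer = msg + 2 * h
    total = config.featurizer.edge_width * h + 2 * h  # edge projection + norm
    total += config.vocab * h  # token embedding
    total += config.n_encoder_layers * node_layer
    if config.edge_updates:
        total += config.n_encoder_layers * edge_layer
    total += config.n_decoder_layers * node_layer
    total += h * config.vocab + config.vocab  # output projection
    return total


class ModelParams:
    """Named weight tensors plus their exact scalar count."""

    def __init__(self, tensors: dict[str, nn.Tensor]):
        self.tensors = tensors

    def __getitem__(self, name: str) -> nn.Tensor:
        return self.tensors[name]

    @property
    def total_count(self) -> int:
        return sum(int(t.data.size) for t in self.tensors.values())

    def copy(self) -> "ModelParams":
        return ModelParams({k: nn.parameter(v.data.copy()) for k, v in self.tensors.items()})

    def zero_grad(self) -> None:
        for t in self.tensors.values():
            t.grad = None


def init_params(config: ModelConfig, seed: int) -> ModelParams:
    """Fan-in-scaled Gaussian weights; norm gains 1, offsets and biases 0."""
    rng = np.random.default_rng(seed)
    tensors: dict[str, nn.Tensor] = {}
    for name, shape in param_inventory(config):
        if name.endswith(".gain"):
            data = np.ones(shape)
        elif name.endswith((".offset", ".b", ".b1", ".b2", ".b3")):
            data = np.zeros(shape)
        else:
            fan_in = shape[0]
            data = rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape)
        tensors[name] = nn.parameter(data)
    return ModelParams(tensors)


@dataclasses.dataclass
class GraphBatch:
    """Stack of equally shaped NeighborGraphs for batched forward passes."""

    edge_features: np.ndarray  # (B, N, K, W)
    neighbor_index: np.ndarray  # (B, N, K)
    edge_mask: np.ndarray  # (B, N, K)
    node_mask: np.ndarray  # (B, N)

    @classmethod
    def from_graphs(cls, graphs: Sequence[NeighborGraph]) -> "GraphBatch":
        shapes = {g.edge_features.shape for g in graphs}
        if len(shapes) != 1:
            raise ConfigurationError("graphs in a batch must share (N, K, W) shape")
        return cls(
            edge_features=np.stack([g.edge_features for g in graphs]),
            neighbor_index=np.stack([g.neighbor_index for g in graphs]),
            edge_mask=np.stack([g.edge_mask for g in graphs]),
            node_mask=np.stack([g.node_mask for g in graphs]),
        )

    @classmethod
    def from_graph(cls, graph: NeighborGraph) -> "GraphBatch":
        return cls.from_graphs([graph])

    @property
    def shape(self):
        return self.edge_features.shape[:3]


def _mlp3(params: ModelParams, prefix: str, x: nn.Tensor) -> nn.Tensor:
    y = nn.relu(nn.affine(x, params[f"{prefix}.W1"], params[f"{prefix}.b1"]))
    y = nn.relu(nn.affine(y, params[f"{prefix}.W2"], params[f"{prefix}.b2"]))
    return nn.affine(y, params[f"{prefix}.W3"], params[f"{prefix}.b3"])


def _node_block(params, prefix, h_v, msg_in, edge_mask, dropout_p, rng):
    """Shared node update: masked message mean, residual+norm, FFN, residual+norm.

    Messages are averaged over valid neighbors (not summed): neighbor counts
    vary between structures once k clamps to the structure size, and a raw
    sum would make message magnitude depend on length.
    """
    m = _mlp3(params, f"{prefix}.msg", msg_in)
    m = nn.mul(m, nn.Tensor(edge_mask[..., None]))
    count = np.maximum(edge_mask.sum(axis=2, keepdims=True), 1.0)  # (B, N, 1)
    msg = nn.mul(nn.reduce_sum(m, axis=2), nn.Tensor(1.0 / count))
    if rng is not None:
        msg = nn.dropout(msg, dropout_p, rng)
    h_v = nn.layer_norm(nn.add(h_v, msg),
                        params[f"{prefix}.norm1.gain"], params[f"{prefix}.norm1.offset"])
    ff = nn.relu(nn.affine(h_v, params[f"{prefix}.ffn.W1"], params[f"{prefix}.ffn.b1"]))
    ff = nn.affine(ff, params[f"{prefix}.ffn.W2"], params[f"{prefix}.ffn.b2"])
    if rng is not None:
        ff = nn.dropout(ff, dropout_p, rng)
    return nn.layer_norm(nn.add(h_v, ff),
                         params[f"{prefix}.norm2.gain"], params[f"{prefix}.norm2.offset"])


def encode(batch: GraphBatch, params: ModelParams, config: ModelConfig,
           train: bool = False, rng: np.random.Generator | None = None):
    """Run the encoder; returns (node embeddings, edge embeddings) tensors.

    Deterministic in evaluation mode (train=False).
    """
    B, N, K = batch.shape
    if batch.edge_features.shape[-1] != config.featurizer.edge_width:
        raise ConfigurationError(
            f"edge feature width {batch.edge_features.shape[-1]} does not match "
            f"config ({config.featurizer.edge_width})")
    drop_rng = rng if (train and config.dropout > 0) else None
    h_e = nn.layer_norm(nn.matmul(nn.Tensor(batch.edge_features), params["edge_proj.W"]),
                        params["edge_proj.norm.gain"], params["edge_proj.norm.offset"])
    h_v = nn.Tensor(np.zeros((B, N, config.hidden_dim)))
    for layer in range(config.n_encoder_layers):
        p = f"enc{layer}"
        h_i = nn.expand_neighbors(h_v, K)
        h_j = nn.gather_nodes(h_v, batch.neighbor_index)
        msg_in = nn.concat([h_i, h_j, h_e], axis=-1)
        h_v = _node_block(params, p, h_v, msg_in, batch.edge_mask, config.dropout, drop_rng)
        if config.edge_updates:
            h_i2 = nn.expand_neighbors(h_v, K)
            h_j2 = nn.gather_nodes(h_v, batch.neighbor_index)
            em = _mlp3(params, f"{p}.edge", nn.concat([h_i2, h_j2, h_e], axis=-1))
            if drop_rng is not None:
                em = nn.dropout(em, config.dropout, drop_rng)
            h_e = nn.layer_norm(nn.add(h_e, em),
                                params[f"{p}.edge_norm.gain"], params[f"{p}.edge_norm.offset"])
    return h_v, h_e


def decode_logits(h_v: nn.Tensor, h_e: nn.Tensor, batch: GraphBatch,
                  tokens: np.ndarray, attend: np.ndarray,
                  params: ModelParams, config: ModelConfig,
                  train: bool = False, rng: np.random.Generator | None = None) -> nn.Tensor:
    """Decoder forward pass under an autoregressive attendance mask.

    tokens: (B, N) integer sequence (entries at not-yet-decoded positions are
    ignored).  attend: (B, N, K) 0/1; attend[b, i, k] = 1 iff neighbor k of i
    was decoded before i.  Returns logits (B, N, vocab).
    """
    B, N, K = batch.shape
    if tokens.shape != (B, N):
        raise ConfigurationError("token array shape does not match the batch")
    if tokens.min() < 0 or tokens.max() >= config.vocab:
        raise ConfigurationError("token out of vocabulary range")
    drop_rng = rng if (train and config.dropout > 0) else None
    att = nn.Tensor(attend[..., None] * batch.edge_mask[..., None])
    att_not = nn.Tensor((1.0 - attend[..., None]) * batch.edge_mask[..., None])
    s = nn.embedding(params["token_emb.W"], tokens)  # (B, N, h)
    s_j = nn.gather_nodes(s, batch.neighbor_index)  # (B, N, K, h)
    tok_ctx = nn.mul(s_j, att)  # token embeddings of already-decoded neighbors
    h_enc_j = nn.gather_nodes(h_v, batch.neighbor_index)
    enc_ctx = nn.mul(h_enc_j, att_not)  # encoder-only stream for the rest
    for layer in range(config.n_decoder_layers):
        h_i = nn.expand_neighbors(h_v, K)
        # attended neighbors contribute token embedding + current decoder
        # state (all their context precedes this position, so no leakage);
        # unattended neighbors fall back to the encoder-only stream
        h_dec_j = nn.gather_nodes(h_v, batch.neighbor_index)
        ctx = nn.add(nn.add(tok_ctx, nn.mul(h_dec_j, att)), enc_ctx)
        msg_in = nn.concat([h_i, h_e, ctx], axis=-1)
        h_v = _node_block(params, f"dec{layer}", h_v, msg_in, batch.edge_mask,
                          config.dropout, drop_rng)
    return nn.affine(h_v, params["out_proj.W"], params["out_proj.b"])


def attend_from_ranks(ranks: np.ndarray, neighbor_index: np.ndarray) -> np.ndarray:
    """attend[b, i, k] = 1 iff rank of neighbor k is strictly before rank of i.

    ranks: (B, N) decoding ranks (tied slot members share a rank);
    neighbor_index: (B, N, K).
    """
    b_idx = np.arange(ranks.shape[0])[:, None, None]
    rank_j = ranks[b_idx, neighbor_index]
    return (rank_j < ranks[:, :, None]).astype(float)


def save_checkpoint(params: ModelParams, config: ModelConfig, path) -> None:
    """Single-archive checkpoint: JSON config + named weight arrays."""
    buf = io.BytesIO()
    np.savez(buf, **{k: v.data for k, v in params.tensors.items()})
    with zipfile.ZipFile(str(path), "w") as zf:
        zf.writestr("config.json", json.dumps(
            {"schema_version": CHECKPOINT_SCHEMA_VERSION, "model": config.to_dict()}))
        zf.writestr("weights.npz", buf.getvalue())


def load_checkpoint(path) -> tuple[ModelParams, ModelConfig]:
    with zipfile.ZipFile(str(path)) as zf:
        meta = json.loads(zf.read("config.json"))
        if meta.get("schema_version") != CHECKPOINT_SCHEMA_VERSION:
            raise ConfigurationError("unsupported checkpoint schema version")
        config = ModelConfig.from_dict(meta["model"])
        with zf.open("weights.npz") as fh:
            arrays = np.load(io.BytesIO(fh.read()))
            tensors = {k: nn.parameter(arrays[k]) for k in arrays.files}
    params = ModelParams(tensors)
    expected = dict(param_inventory(config))
    if set(expected) != set(params.tensors) or any(
            params.tensors[k].data.shape != tuple(expected[k]) for k in expected):
        raise ConfigurationError("checkpoint weights do not match its config")
    return params, config
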