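"""Backbone graph featurisation.

A structure becomes a k-nearest-neighbor residue graph (neighbors by Ca-Ca
distance, jointly across chains).  Each directed edge carries the 25
interatomic distances between the (N, Ca, C, O, virtual-Cb) atoms of the two
residues, each expanded in Gaussian radial basis functions, plus a relative
positional encoding clipped to ±32 within a chain (a dedicated class marks
inter-chain pairs) and a same/different-chain bit.  All node-level geometry
is carried by self-edges; node inputs to the network are zeros, which makes
the features rigid-motion invariant by construction.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .backbone import BackboneStructure, compute_virtual_cb
from .errors import EmptyStructureError, UndefinedMetricError

__all__ = [
    "FeaturizerConfig",
    "NeighborGraph",
    "knn_graph",
    "rbf_encode",
    "edge_features",
    "positional_encoding",
    "featurize",
    "add_backbone_noise",
    "burial_metric",
]

N_ATOM_TYPES = 5  # N, Ca, C, O, virtual Cb
N_ATOM_PAIRS = N_ATOM_TYPES * N_ATOM_TYPES  # 25 ordered pairs


@dataclasses.dataclass
class FeaturizerConfig:
    """Graph construction parameters.

    k_neighbors: neighbors per residue (clamped to the structure size).
    n_rbf / rbf_min / rbf_max: Gaussian radial basis expansion of distances;
    centers evenly spaced on [rbf_min, rbf_max] Å, width = center spacing.
    cap: relative-position clip (±cap within a chain).
    noise_std: Gaussian coordinate noise in Å (training augmentation).
    """

    k_neighbors: int = 48
    n_rbf: int = 16
    rbf_min: float = 2.0
    rbf_max: float = 22.0
    cap: int = 32
    noise_std: float = 0.0
    include_self: bool = True

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.n_rbf < 2:
            raise ValueError("n_rbf must be >= 2")
        if not self.rbf_min < self.rbf_max:
            raise ValueError("rbf_min must be < rbf_max")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")

    @property
    def n_position_classes(self) -> int:
        # 2*cap+1 same-chain offsets plus one inter-chain class
        return 2 * self.cap + 2

    @property
    def edge_width(self) -> int:
        # 25 RBF-expanded distances + positional one-hot + same-chain bit
        return N_ATOM_PAIRS * self.n_rbf + self.n_position_classes + 1


@dataclasses.dataclass
class NeighborGraph:
    """k-NN residue graph with per-edge features.

    neighbor_index[i] lists i's neighbors by increasing Ca-Ca distance
    (ties broken by lower node index); edge_mask flags usable slots.
    """

    n_nodes: int
    neighbor_index: np.ndarray  # (N, K) int
    edge_features: np.ndarray  # (N, K, W) float
    edge_mask: np.ndarray  # (N, K) float 0/1
    node_mask: np.ndarray  # (N,) float 0/1
    config: FeaturizerConfig


def _atom_stack(structure: BackboneStructure) -> tuple[np.ndarray, np.ndarray]:
    """(N, 5, 3) coordinates and (N, 5) validity for N/Ca/C/O/Cb."""
    atoms = np.concatenate([structure.coords, structure.cb[:, None, :]], axis=1)
    valid = np.concatenate(
        [structure.atom_mask, structure.residue_mask[:, None]], axis=1
    ) & structure.residue_mask[:, None]
    return atoms, valid


def knn_graph(structure: BackboneStructure, config: FeaturizerConfig):
    """Neighbor index table by Ca-Ca distance across all chains jointly.

    Returns (neighbor_index, edge_mask) of width min(k, n_nodes).  Masked
    residues never appear as neighbors and get no valid slots themselves.
    """
    n = structure.n_residues
    valid = structure.residue_mask.astype(bool)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise EmptyStructureError("no valid residues for graph construction")
    ca = structure.coords[:, 1, :]
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    d[:, ~valid] = np.inf
    if not config.include_self:
        np.fill_diagonal(d, np.inf)
    k = min(config.k_neighbors, n)
    order = np.argsort(d, axis=1, kind="stable")[:, :k]  # stable: ties -> lower index
    sorted_d = np.take_along_axis(d, order, axis=1)
    edge_mask = np.isfinite(sorted_d) & valid[:, None]
    neighbor_index = np.where(edge_mask, order, np.arange(n)[:, None])
    return neighbor_index, edge_mask.astype(float)


def rbf_encode(d, config: FeaturizerConfig) -> np.ndarray:
    """Gaussian radial basis expansion of distances (last axis appended)."""
    d = np.asarray(d, dtype=float)
    mu = np.linspace(config.rbf_min, config.rbf_max, config.n_rbf)
    sigma = (config.rbf_max - config.rbf_min) / (config.n_rbf - 1)
    return np.exp(-(((d[..., None] - mu) / sigma) ** 2))


def positional_encoding(pos_i: int, pos_j: int, chain_i, chain_j,
                        config: FeaturizerConfig) -> np.ndarray:
    """One-hot relative-position encoding plus the same-chain bit."""
    vec = np.zeros(config.n_position_classes + 1)
    if chain_i == chain_j:
        off = int(np.clip(pos_j - pos_i, -config.cap, config.cap))
        vec[off + config.cap] = 1.0
        vec[-1] = 1.0
    else:
        vec[2 * config.cap + 1] = 1.0
    return vec


def _pair_distance_block(structure, idx_i, idx_j, config):
    """RBF-expanded 25 atom-pair distances for edges (i, j); invalid pairs zeroed."""
    atoms, avalid = _atom_stack(structure)
    ai, aj = atoms[idx_i], atoms[idx_j]  # (..., 5, 3)
    diff = ai[..., :, None, :] - aj[..., None, :, :]  # (..., 5, 5, 3)
    dist = np.linalg.norm(diff, axis=-1)
    rbf = rbf_encode(dist, config)  # (..., 5, 5, n_rbf)
    pair_ok = avalid[idx_i][..., :, None] & avalid[idx_j][..., None, :]
    rbf *= pair_ok[..., None]
    return rbf.reshape(rbf.shape[:-3] + (N_ATOM_PAIRS * config.n_rbf,))


def edge_features(structure: BackboneStructure, i: int, j: int,
                  config: FeaturizerConfig) -> np.ndarray:
    """Feature vector of the directed edge i -> j."""
    if not (structure.residue_mask[i] and structure.residue_mask[j]):
        raise ValueError("edge endpoints must be valid residues")
    dists = _pair_distance_block(structure, np.array(i), np.array(j), config)
    pos = positional_encoding(
        int(structure.chain_pos[i]), int(structure.chain_pos[j]),
        int(structure.chain_index[i]), int(structure.chain_index[j]), config)
    return np.concatenate([dists, pos])


def featurize(structure: BackboneStructure, config: FeaturizerConfig) -> NeighborGraph:
    """Full graph featurisation of a structure (no noise; see add_backbone_noise)."""
    neighbor_index, edge_mask = knn_graph(structure, config)
    n, k = neighbor_index.shape
    src = np.repeat(np.arange(n)[:, None], k, axis=1)
    dist_block = _pair_distance_block(structure, src, neighbor_index, config)

    off = structure.chain_pos[neighbor_index] - structure.chain_pos[:, None]
    same_chain = structure.chain_index[neighbor_index] == structure.chain_index[:, None]
    cls = np.where(
        same_chain,
        np.clip(off, -config.cap, config.cap) + config.cap,
        2 * config.cap + 1,
    )
    pos_onehot = np.zeros((n, k, config.n_position_classes))
    np.put_along_axis(pos_onehot, cls[..., None], 1.0, axis=-1)
    feats = np.concatenate(
        [dist_block, pos_onehot, same_chain[..., None].astype(float)], axis=-1)
    feats *= edge_mask[..., None]
    return NeighborGraph(
        n_nodes=n,
        neighbor_index=neighbor_index,
        edge_features=feats,
        edge_mask=edge_mask,
        node_mask=structure.residue_mask.astype(float),
        config=config,
    )


def add_backbone_noise(structure: BackboneStructure, std: float, seed: int) -> BackboneStructure:
    """Independent Gaussian perturbation of every stored N/Ca/C/O coordinate.

    The virtual Cb is recomputed from the noised triad.  Deterministic given
    the seed; std=0 returns an identical copy.
    """
    if std < 0:
        raise ValueError("noise std must be >= 0")
    out = structure.copy()
    if std > 0:
        rng = np.random.default_rng(seed)
        out.coords = out.coords + rng.normal(0.0, std, size=out.coords.shape)
        out.cb = compute_virtual_cb(out.coords, out.residue_mask)
    return out


def burial_metric(structure: BackboneStructure, n_neighbors: int = 8) -> np.ndarray:
    """Mean virtual-Cb distance to the 8 closest other residues, per residue.

    Lower values indicate more buried positions.  Invalid residues get NaN.
    """
    valid = structure.residue_mask.astype(bool)
    if int(valid.sum()) < 2:
        raise UndefinedMetricError("burial requires at least 2 valid residues")
    cb = structure.cb
    d = np.linalg.norm(cb[:, None, :] - cb[None, :, :], axis=-1)
    d[:, ~valid] = np.inf
    np.fill_diagonal(d, np.inf)
    m = min(n_neighbors, int(valid.sum()) - 1)
    nearest = np.sort(d, axis=1)[:, :m]
    out = nearest.mean(axis=1)
    out[~valid] = np.nan
    return out
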