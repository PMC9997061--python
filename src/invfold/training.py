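"""Order-agnostic autoregressive training with backbone-noise augmentation.

Each visit of a structure applies fresh Gaussian coordinate noise, draws one
random decoding order (an unbiased estimate of the order-averaged loss) and
teacher-forces the native sequence; the loss is the mean categorical cross
entropy per valid residue.  Data are split by precomputed sequence cluster
labels so that no cluster spans two partitions.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import nn
from .alphabet import seq_to_tokens
from .backbone import BackboneStructure, read_backbone
from .errors import TrainingDivergedError
from .features import add_backbone_noise, featurize
from .model import (GraphBatch, ModelConfig, ModelParams, attend_from_ranks,
                    count_parameters, decode_logits, encode, init_params,
                    save_checkpoint)
from .seeds import substream, substream_seed

__all__ = [
    "TrainConfig",
    "DatasetSplit",
    "Record",
    "training_loss",
    "train",
    "cluster_split",
    "load_dataset",
]


@dataclasses.dataclass
class TrainConfig:
    """Optimisation settings.

    noise_std is the coordinate-noise augmentation in Å (0.02 by default,
    matching the featurizer's training regime); label smoothing is off.
    """

    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    lr_decay: float = 1.0  # multiplicative decay per epoch (1.0 = constant)
    seed: int = 0
    noise_std: float = 0.02
    gradient_clip: float = 1.0
    checkpoint_every: int = 0
    dropout: bool = True
    label_smoothing: float = 0.0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.label_smoothing != 0.0:
            raise ValueError("label smoothing is not supported (off by design)")


@dataclasses.dataclass
class Record:
    """One (structure, sequence) training example."""

    record_id: str
    structure: BackboneStructure
    tokens: np.ndarray


@dataclasses.dataclass
class DatasetSplit:
    """Cluster-aware partitioning; no cluster spans two partitions."""

    records: list[Record]
    cluster_ids: list[str]
    partitions: list[str]  # per record: train / validation / test

    def subset(self, partition: str) -> list[Record]:
        return [r for r, p in zip(self.records, self.partitions) if p == partition]


def _forward_group(params, config, structures, token_rows, noise_std, seed,
                   train_mode, drop_rng):
    """Batched teacher-forced forward pass for equal-length structures."""
    graphs = []
    ranks_rows = []
    for i, s in enumerate(structures):
        noised = add_backbone_noise(s, noise_std, substream_seed(seed, "noise", i)) \
            if noise_std > 0 else s
        graphs.append(featurize(noised, config.featurizer))
        perm = substream(seed, "order", i).permutation(s.n_residues)
        ranks = np.empty(s.n_residues, dtype=np.int64)
        ranks[perm] = np.arange(s.n_residues)
        ranks_rows.append(ranks)
    batch = GraphBatch.from_graphs(graphs)
    tokens = np.stack(token_rows)
    attend = attend_from_ranks(np.stack(ranks_rows), batch.neighbor_index)
    h_v, h_e = encode(batch, params, config, train=train_mode, rng=drop_rng)
    logits = decode_logits(h_v, h_e, batch, tokens, attend, params, config,
                           train=train_mode, rng=drop_rng)
    weights = batch.node_mask
    loss = nn.masked_cross_entropy(logits, tokens, weights)
    return loss, float(weights.sum())


def training_loss(params: ModelParams, config: ModelConfig,
                  batch: Sequence[tuple[BackboneStructure, np.ndarray | str]],
                  noise_std: float, seed: int,
                  train_mode: bool = False,
                  dropout_rng: np.random.Generator | None = None) -> nn.Tensor:
    """Mean per-residue cross entropy over a batch of (structure, sequence).

    Fresh noise and one random decoding order per structure, both derived
    from `seed`.  Returns a scalar graph tensor; call .backward() on it for
    gradients, .item() for the value.
    """
    if not batch:
        raise ValueError("training batch must be non-empty")
    prepared = []
    for i, (s, seq) in enumerate(batch):
        tokens = seq_to_tokens(seq) if isinstance(seq, str) else np.asarray(seq)
        if tokens.shape[0] != s.n_residues:
            raise ValueError("sequence length does not match structure")
        prepared.append((s, tokens, i))
    # group by length so each group runs as one stacked forward pass
    groups: dict[int, list] = {}
    for s, tokens, i in prepared:
        groups.setdefault(s.n_residues, []).append((s, tokens, i))
    total_w = 0.0
    weighted = []
    for n, members in sorted(groups.items()):
        loss, w = _forward_group(
            params, config,
            [m[0] for m in members], [m[1] for m in members],
            noise_std, substream_seed(seed, "group", n), train_mode, dropout_rng)
        weighted.append((loss, w))
        total_w += w
    out = None
    for loss, w in weighted:
        term = nn.mul(loss, w / total_w)
        out = term if out is None else nn.add(out, term)
    return out


def validation_perplexity(params, config, records: Sequence[Record], seed: int) -> float:
    """Noise-free teacher-forced perplexity over a record list."""
    loss = training_loss(params, config,
                         [(r.structure, r.tokens) for r in records],
                         noise_std=0.0, seed=seed, train_mode=False)
    return float(np.exp(loss.item()))


def train(config: ModelConfig, train_cfg: TrainConfig, split: DatasetSplit,
          out_dir=None) -> tuple[ModelParams, list[dict]]:
    """Seeded training loop; retains the best-validation-perplexity weights.

    History records one entry per epoch (train loss, validation perplexity,
    computed without noise).  Raises TrainingDivergedError on a non-finite
    loss, naming the epoch.
    """
    train_records = split.subset("train")
    if not train_records:
        raise ValueError("empty train partition")
    val_records = split.subset("validation")
    params = init_params(config, substream_seed(train_cfg.seed, "init"))
    opt = nn.Adam(params.tensors, lr=train_cfg.learning_rate)
    history: list[dict] = []
    best = params.copy()
    best_val = np.inf
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for epoch in range(train_cfg.epochs):
        opt.lr = train_cfg.learning_rate * train_cfg.lr_decay ** epoch
        rng = substream(train_cfg.seed, "shuffle", epoch)
        order = rng.permutation(len(train_records))
        # bucket by length so each fixed-size batch runs as one stacked
        # forward pass; batch order is itself shuffled
        order = order[np.argsort([train_records[i].structure.n_residues
                                  for i in order], kind="stable")]
        starts = np.arange(0, len(order), train_cfg.batch_size)
        starts = starts[rng.permutation(len(starts))]
        epoch_losses = []
        for b_start in starts:
            idx = order[b_start:b_start + train_cfg.batch_size]
            minibatch = [(train_records[i].structure, train_records[i].tokens)
                         for i in idx]
            drop_rng = substream(train_cfg.seed, "dropout", epoch, b_start) \
                if train_cfg.dropout else None
            params.zero_grad()
            loss = training_loss(params, config, minibatch, train_cfg.noise_std,
                                 substream_seed(train_cfg.seed, "visit", epoch, b_start),
                                 train_mode=train_cfg.dropout, dropout_rng=drop_rng)
            value = loss.item()
            if not np.isfinite(value):
                raise TrainingDivergedError(epoch)
            loss.backward()
            opt.step(grad_clip=train_cfg.gradient_clip)
            epoch_losses.append(value)
        entry = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}
        if val_records:
            vp = validation_perplexity(params, config, val_records,
                                       substream_seed(train_cfg.seed, "val"))
            entry["val_perplexity"] = vp
            if vp < best_val:
                best_val = vp
                best = params.copy()
        else:
            best = params.copy()
        history.append(entry)
        if out_dir is not None:
            with open(out_dir / "train_log.jsonl", "a") as fh:
                fh.write(json.dumps(entry) + "\n")
            if train_cfg.checkpoint_every and (epoch + 1) % train_cfg.checkpoint_every == 0:
                save_checkpoint(params, config, out_dir / f"epoch_{epoch:04d}.ckpt")
    if out_dir is not None:
        save_checkpoint(best, config, out_dir / "best.ckpt")
    return best, history


def cluster_split(records: Sequence[Record], cluster_ids: Sequence[str],
                  fractions: tuple[float, float, float], seed: int) -> DatasetSplit:
    """Assign whole clusters to train/validation/test until fractions are met."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if len(records) != len(cluster_ids):
        raise ValueError("one cluster id per record is required")
    clusters = sorted(set(cluster_ids))
    if len(clusters) < 3:
        raise ValueError("need at least as many clusters as partitions")
    rng = np.random.default_rng(seed)
    shuffled = [clusters[i] for i in rng.permutation(len(clusters))]
    counts = {c: sum(1 for cid in cluster_ids if cid == c) for c in clusters}
    n = len(records)
    targets = [fractions[0] * n, (fractions[0] + fractions[1]) * n]
    assignment: dict[str, str] = {}
    seen = 0
    for c in shuffled:
        if seen < targets[0]:
            assignment[c] = "train"
        elif seen < targets[1]:
            assignment[c] = "validation"
        else:
            assignment[c] = "test"
        seen += counts[c]
    partitions = [assignment[c] for c in cluster_ids]
    return DatasetSplit(records=list(records), cluster_ids=list(cluster_ids),
                        partitions=partitions)


def load_dataset(directory) -> tuple[list[Record], list[str]]:
    """Read the on-disk layout: PDB files + sequences.fasta + clusters.tsv."""
    directory = Path(directory)
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(directory / "sequences.fasta"), "fasta")}
    clusters = pd.read_csv(directory / "clusters.tsv", sep="\t",
                           names=["record_id", "cluster_id"], dtype=str)
    cluster_of = dict(zip(clusters.record_id, clusters.cluster_id))
    records, cluster_ids = [], []
    for rid in sorted(seqs):
        structure = read_backbone(directory / f"{rid}.pdb", "pdb")
        records.append(Record(record_id=rid, structure=structure,
                              tokens=seq_to_tokens(seqs[rid])))
        cluster_ids.append(cluster_of[rid])
    return records, cluster_ids
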