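"""Desk-scale benchmark protocols shared by the test suite and scripts.

Two end-to-end studies are defined on the synthetic geometric-code task:

* ``learnability_benchmark`` — train the reference small model (hidden 64,
  2 encoder + 2 decoder layers) on 300 structures and measure greedy design
  recovery on 50 structures from held-out clusters (one interior length per
  structural family, so the test families are unseen (kind, length) combos).

* ``noise_robustness_benchmark`` — train matched models with and without
  Gaussian backbone-noise augmentation and compare design recovery on clean
  versus 0.1 Å-perturbed test backbones (reference letters always come from
  the clean coordinates).

Problem sizes are fixed desk-scale choices (minutes on one CPU); see
docs/methods.md for the rationale behind each setting.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from .design import DesignConstraints, sample_sequence
from .features import FeaturizerConfig, add_backbone_noise
from .model import ModelConfig
from .alphabet import tokens_to_seq
from .seeds import substream, substream_seed
from .training import DatasetSplit, TrainConfig, load_dataset, train
from .synthetic import make_dataset

__all__ = ["build_benchmark_dataset", "learnability_benchmark",
           "noise_robustness_benchmark"]

# one interior length per family is held out (with every record of its
# cluster); the families at the remaining lengths form the training pool
HELDOUT_CLUSTERS = (
    "helix_L14",
    "strand_L16",
    "two_helix_hairpin_L19",
    "bundle_L20",
    "cyclic_assembly_L10",
)

REFERENCE_MODEL = dict(n_encoder_layers=2, n_decoder_layers=2, hidden_dim=64,
                       dropout=0.0)


def _greedy_recovery(params, config, structure, reference: str, seed: int) -> float:
    res = sample_sequence(params, config, structure,
                          DesignConstraints(seed=seed), reference=reference,
                          greedy=True)
    return float(res.samples[0].recovery)


def _stratified_split(records, cluster_ids, n_train: int, n_val: int, seed: int):
    test = [r for r, c in zip(records, cluster_ids) if c in HELDOUT_CLUSTERS]
    rest = [r for r, c in zip(records, cluster_ids) if c not in HELDOUT_CLUSTERS]
    order = substream(seed, "bench_split").permutation(len(rest))
    rest = [rest[i] for i in order]
    split = DatasetSplit(
        records=rest[:n_train] + rest[n_train:n_train + n_val],
        cluster_ids=["pool"] * min(len(rest), n_train + n_val),
        partitions=["train"] * min(n_train, len(rest))
        + ["validation"] * max(0, min(n_val, len(rest) - n_train)),
    )
    return split, test


def build_benchmark_dataset(data_seed: int, n_structures: int = 500):
    """Generate and load the benchmark dataset (the study's fixed input).

    Seed replicates of the learnability benchmark share one dataset and vary
    only the training / decoding randomness.
    """
    with tempfile.TemporaryDirectory() as tmp:
        make_dataset(n_structures, Path(tmp), seed=data_seed)
        return load_dataset(Path(tmp))


def learnability_benchmark(seed: int, n_train: int = 300,
                           n_test: int = 50, epochs: int = 20,
                           dataset=None) -> dict:
    """Train the reference model and measure held-out-cluster design recovery.

    Returns the median and per-family recoveries plus the best validation
    perplexity.  Deterministic given `seed` (and the dataset, which defaults
    to the one built from this seed's substream).
    """
    if dataset is None:
        dataset = build_benchmark_dataset(substream_seed(seed, "bench_data"))
    records, cluster_ids = dataset
    split, test_records = _stratified_split(records, cluster_ids, n_train, 32, seed)
    test_records = test_records[:n_test]
    config = ModelConfig(**REFERENCE_MODEL,
                         featurizer=FeaturizerConfig(k_neighbors=24))
    tc = TrainConfig(epochs=epochs, batch_size=25, learning_rate=2.5e-3,
                     lr_decay=0.95, seed=substream_seed(seed, "bench_train"),
                     noise_std=0.02, dropout=False)
    params, history = train(config, tc, split)
    per_kind: dict[str, list[float]] = {}
    values = []
    for r in test_records:
        v = _greedy_recovery(params, config, r.structure,
                             tokens_to_seq(r.tokens), seed)
        values.append(v)
        kind = r.record_id.split("_", 1)[1].rsplit("_L", 1)[0]
        per_kind.setdefault(kind, []).append(v)
    return {
        "median_recovery": float(np.median(values)),
        "mean_recovery": float(np.mean(values)),
        "n_test": len(values),
        "per_kind_median": {k: float(np.median(v)) for k, v in sorted(per_kind.items())},
        "best_val_perplexity": float(min(h["val_perplexity"] for h in history)),
        "params": params,
        "config": config,
    }


NOISE_BENCH_MIX = (
    ("helix", 0.4, (11, 12, 13, 14)),
    ("strand", 0.3, (11, 12, 13, 14)),
    ("two_helix_hairpin", 0.3, (15, 16, 17, 18)),
)


def noise_robustness_benchmark(seed: int, train_noise_std: float,
                               n_structures: int = 170, n_train: int = 125,
                               n_test: int = 30, epochs: int = 18,
                               test_perturbation: float = 0.1) -> dict:
    """Train one small model and score recovery on clean and perturbed backbones.

    The same held-out structures are evaluated twice: as generated, and with
    0.1 Å Gaussian noise added to every backbone atom (reference letters stay
    those of the clean structure).
    """
    with tempfile.TemporaryDirectory() as tmp:
        make_dataset(n_structures, Path(tmp), seed=substream_seed(seed, "noise_data"),
                     mix=NOISE_BENCH_MIX)
        records, cluster_ids = load_dataset(Path(tmp))
    order = substream(seed, "noise_split").permutation(len(records))
    records = [records[i] for i in order]
    test_records = records[:n_test]
    train_records = records[n_test:n_test + n_train]
    val_records = records[n_test + n_train:n_test + n_train + 12]
    split = DatasetSplit(
        records=train_records + val_records,
        cluster_ids=["pool"] * (len(train_records) + len(val_records)),
        partitions=["train"] * len(train_records) + ["validation"] * len(val_records),
    )
    config = ModelConfig(n_encoder_layers=2, n_decoder_layers=2, hidden_dim=48,
                         dropout=0.0, featurizer=FeaturizerConfig(k_neighbors=18))
    tc = TrainConfig(epochs=epochs, batch_size=25, learning_rate=2.5e-3,
                     lr_decay=0.95, seed=substream_seed(seed, "noise_train"),
                     noise_std=train_noise_std, dropout=False)
    params, _history = train(config, tc, split)
    clean, perturbed = [], []
    for i, r in enumerate(test_records):
        ref = tokens_to_seq(r.tokens)
        clean.append(_greedy_recovery(params, config, r.structure, ref, seed))
        noisy = add_backbone_noise(r.structure, test_perturbation,
                                   substream_seed(seed, "test_noise", i))
        perturbed.append(_greedy_recovery(params, config, noisy, ref, seed))
    return {
        "train_noise_std": train_noise_std,
        "clean_median_recovery": float(np.median(clean)),
        "perturbed_median_recovery": float(np.median(perturbed)),
        "n_test": len(test_records),
    }
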