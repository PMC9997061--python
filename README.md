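# invfold

Fixed-backbone protein sequence design ("inverse folding") with a
message-passing encoder–decoder over k-nearest-neighbor backbone graphs —
for structural bioinformaticians and protein designers who want a small,
fully inspectable, CPU-only implementation of this model family, complete
with constraint-aware sampling (fixed, tied, symmetric and multi-state
positions), teacher-forced scoring, noise-augmented training, and a
synthetic-backbone benchmark that exercises everything end to end with no
external data.

## The model

Given backbone atoms N, Cα, C, O per residue (one or more chains), each
residue becomes a graph node; its k nearest neighbors by Cα–Cα distance
(jointly across chains) define directed edges. An edge (i, j) carries the
25 distances between the five reference atoms (N, Cα, C, O and an
idealised virtual Cβ placed from the N/Cα/C triad) expanded in 16 Gaussian
radial basis functions, plus a relative-position encoding capped at ±32
within a chain and a same/different-chain flag. Node inputs are zeros, so
the features — and therefore every logit — are invariant under rigid
motion of the input by construction.

An encoder (default 3 layers, hidden width 128) alternates edge-conditioned
node updates with edge updates. The decoder (3 layers) is order-agnostic
autoregressive: for a decoding permutation π,

  p(s | X) = ∏ₜ p(s_{π(t)} | X, s_{π(<t)})

with each position's logits depending only on structure and previously
decoded identities; training samples π uniformly per visit, so any order is
valid at inference. That flexibility is what enables fixed regions to be
decoded first as context, tied positions (symmetry-equivalent residues
within or between chains) to be decoded jointly from averaged logits, and
multi-state design via signed linear combinations of per-state logits.
Sequence quality is measured as sequence recovery (fraction of positions
matching a reference) and perplexity (exponentiated per-residue categorical
cross entropy; 21 = uniform guessing over the vocabulary, 1 = certainty).

The network, including gradients, runs on a small numpy reverse-mode
autodiff core (`invfold.nn`) verified against finite differences; nothing
here needs a GPU.

## Worked example

Generate synthetic backbones with a deterministic geometry→sequence code,
train a small model, then design and score sequences for a held-out
backbone:

```python
import tempfile
from pathlib import Path
import invfold as iv
from invfold.training import TrainConfig, cluster_split, load_dataset, train

# 1. generate a small synthetic dataset (PDB + FASTA + cluster TSV)
data = Path(tempfile.mkdtemp()) / "data"
iv.make_dataset(120, data, seed=0)
records, clusters = load_dataset(data)
split = cluster_split(records, clusters, (0.8, 0.1, 0.1), seed=0)

# 2. train a small model for a couple of minutes on one CPU
config = iv.ModelConfig(n_encoder_layers=2, n_decoder_layers=2, hidden_dim=48,
                        dropout=0.0, featurizer=iv.FeaturizerConfig(k_neighbors=18))
params, history = train(config, TrainConfig(epochs=12, batch_size=25, seed=0,
                                            learning_rate=2.5e-3, lr_decay=0.95,
                                            noise_std=0.02, dropout=False), split)
print(f"validation perplexity: {history[-1]['val_perplexity']:.2f}")

# 3. design sequences for a held-out backbone and compare to its code
test = split.subset("test")[0]
native = iv.tokens_to_seq(test.tokens)
result = iv.sample_sequence(params, config, test.structure,
                            iv.DesignConstraints(temperature=0.1, n_samples=2, seed=1),
                            reference=native, greedy=True)
design = result.samples[0]
print(f"native: {native}")
print(f"design: {design.sequence}  recovery={design.recovery:.2f}")

# 4. teacher-forced score of the native sequence under 4 random orders
report = iv.score_sequence(params, config, test.structure, native, n_orders=4, seed=0)
print(f"native avg_log_prob={report.avg_log_prob:.3f}  perplexity={report.perplexity:.2f}")
```

This prints:

```
validation perplexity: 2.42
native: ENTTIIAIATEN
design: ETTAIIIIITNN  recovery=0.58
native avg_log_prob=-0.773  perplexity=2.17
```

The validation perplexity of 2.42 (versus 21 for uniform guessing) shows
the model has learned most of the geometric code from 96 training
structures; the designed sequence recovers 58 % of the held-out backbone's
code letters, and the native sequence scores a per-residue perplexity of
2.17 under the trained model. The benchmark protocols in
`invfold.benchmarks` run the same pipeline at larger desk scale (300
training structures, cluster-held-out test families).

Symmetric design works the same way — `tying_from_symmetry(structure,
"tie_chains")` ties position i across all chains of a homo-oligomer so
every sample carries identical subunit sequences, and `sample_multistate`
combines per-state logits with signed coefficients for positive–negative
multi-state design.

## Command line

A thin CLI wraps the library for shell use:

```
invfold synth  --n 300 --out data/ --seed 0
invfold train  --data data/ --config train.json --out ckpt/ --seed 0
invfold design --structure in.pdb --constraints c.json \
               --checkpoint ckpt/best.ckpt --out designs.fasta --seed 0
invfold score  --structure in.pdb --fasta seqs.fasta \
               --checkpoint ckpt/best.ckpt --out scores.tsv
invfold featurize --structure in.pdb --out edges.tsv
```

Constraints are JSON with author-numbered position keys, e.g.
`{"fixed": {"A12": "G"}, "tied": [[["A1", 1.0], ["B1", 1.0]]],
"omit": ["C"], "temperature": 0.1, "n_samples": 8, "seed": 0}`.
Every run writes a manifest next to its outputs, and all randomness flows
from the single `--seed`.

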