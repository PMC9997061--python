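# Methods

## The model

`invfold` performs fixed-backbone protein sequence design ("inverse
folding"): given backbone coordinates (N, Cα, C, O per residue, one or more
chains), predict an amino-acid sequence compatible with that geometry.

The backbone is converted into a k-nearest-neighbor residue graph.
Neighbors are selected by Cα–Cα distance jointly across all chains (ties
broken toward the lower residue index; self-edges included). Each directed
edge carries:

* the 25 interatomic distances between the (N, Cα, C, O, virtual Cβ) atoms
  of the two residues, each expanded in Gaussian radial basis functions
  (16 centers evenly spaced on 2–22 Å, width = center spacing);
* a relative-position one-hot clipped to ±32 within a chain, with a
  dedicated 66th class for inter-chain pairs, plus a same/different-chain
  bit.

The virtual Cβ is placed from the N/Cα/C triad by the ideal-tetrahedral
construction Cβ = Cα + w₁·(b×c) + w₂·b + w₃·c with b = Cα−N, c = C−Cα and
w = (−0.58273431, 0.56802827, −0.54067466); it is used for every residue
(including glycine) so featurisation never depends on the unknown sequence.
Node inputs are zeros — all geometry is carried by edges — which makes the
network rigid-motion invariant by construction.

The encoder runs `n_encoder_layers` rounds of message passing. A node
update concatenates (hᵢ, hⱼ, eᵢⱼ) per edge, passes it through a three-layer
MLP (ReLU activations), averages messages over valid neighbors, and applies
residual + layer norm followed by a position-wise feed-forward block
(expansion ×4) with residual + layer norm. Messages are *averaged*, not
summed: k clamps to the structure size on small inputs, and a sum would
make message magnitude depend on length. When `edge_updates` is on
(default), each layer also rewrites eᵢⱼ through an identically shaped MLP
with residual + layer norm.

The decoder is order-agnostic autoregressive. Under a decoding permutation,
the edge stream for position i carries, for each neighbor j: the token
embedding of j *plus j's current decoder state* if j precedes i in the
order, and j's encoder-only state otherwise. Because everything feeding
h_j's decoder state was itself decoded before j, position i's logits depend
exactly on structure plus previously decoded identities — the
autoregressive property holds bit-exactly, which the tests assert. A final
affine projection yields logits over the 21-letter vocabulary (20 amino
acids + X; X is consumed as context, never sampled).

Parameter accounting is closed-form per block (`count_parameters`). At
hidden width 128 the encoder edge-update blocks cost exactly
3·((3·128+1)·128 + 2·(128+1)·128 + 2·128) = 247,680 scalars and widening
the raw edge features by 384 dimensions costs exactly 384·128 = 49,152
through the bias-free input projection — matching the differences among the
published architecture-variant totals, which is how the otherwise unprinted
layer internals were pinned.

## Sampling, constraints and scoring

Decoding orders are uniformly random over "slots", with fixed positions
always decoded first (they contribute context but are never re-predicted)
and each tied group forming a single slot. At a tied slot, logits are
predicted at every member position, combined as Σcᵢ·logitsᵢ / Σ|cᵢ|
(reducing to the average for the symmetric case), omit-masked, divided by
temperature and softmaxed; one letter is drawn and written to all members.
The normalisation by Σ|cᵢ| keeps the logit scale stable when multi-state
design uses signed coefficients. An alternative "averaged probabilities"
mode (softmax first, then the coefficient-weighted average, renormalised)
is available as `tie_mode="probs"`. Multi-state design encodes each
backbone state independently and combines per-state logits with user
coefficients; states are matched by residue index and must have equal
lengths. Tied groups that mix fixed and free positions are rejected rather
than given ad-hoc semantics.

Temperature is applied as logits/T before the softmax, so T→0 recovers
greedy argmax (asserted). Each sample records, per position, the sampling
distribution actually drawn from and the raw (unit-temperature, unmasked)
log probability of the chosen letter; the mean of the latter is the
sample's average log probability, which is exactly what teacher-forced
re-scoring under the same single order reproduces.

Scoring teacher-forces a sequence under `n_orders` random decoding orders
(default 4; the count is recorded) and averages each position's log
probability of its true letter; perplexity = exp(−avg log prob). X
positions contribute context but are excluded from the averages. On a
3-residue chain, averaging over all six enumerated orders agrees with the
Monte-Carlo estimate within sampling error (asserted).

`DesignConstraints.refine_sweeps` optionally re-draws every free slot from
the fully conditioned distribution p(xᵢ | everything else) after the
initial pass — a trained quantity for an order-agnostic model (the
last-slot conditional). On the synthetic task it does not measurably change
recovery (the model's errors are systematic rather than context-starved),
so the default is 0.

## Training

Training minimises the order-agnostic autoregressive cross entropy: each
visit of a structure applies fresh Gaussian coordinate noise (σ = 0.02 Å by
default; the virtual Cβ is recomputed after noising), draws one random
decoding order (an unbiased one-sample estimate of the order-averaged
loss), teacher-forces the reference sequence and accumulates cross entropy
per valid residue. The optimiser is Adam with gradient-norm clipping at
1.0. The learning rate is fixed per epoch with an optional multiplicative
decay (`lr_decay`); the desk-scale benchmarks use 2.5·10⁻³ with decay 0.95,
which converged faster at these problem sizes than the flat 10⁻³ first
tried. Batches hold a fixed number of structures, bucketed by length so
each batch runs as one stacked forward pass. Validation perplexity is
computed without noise each epoch and the best-validation weights are
retained. Splits assign whole clusters to train/validation/test, so no
cluster spans two partitions; cluster labels arrive as a two-column TSV
(sequence clustering itself is external to this package).

All tensor math runs on a small reverse-mode autodiff core written for this
package (`invfold.nn`), in float64 throughout. Analytic gradients are
verified against central finite differences to 10⁻⁴ relative in the test
suite. Dropout is seed-reproducible in training mode; evaluation mode is
bit-deterministic. All randomness is routed through named substreams of a
single seed (dataset, initialisation, shuffling, noise, orders, draws), so
every experiment is exactly reproducible from one integer.

## Synthetic data and the geometric code

The synthetic generator emulates the *shape* of a structure-conditioned
sequence-design problem without any experimental data: parametric
backbones plus a deterministic, rigid-motion-invariant geometry→sequence
code that the model must learn.

Five structural families are generated from textbook α-helix Cα parameters
(radius 2.3 Å, rise 1.5 Å/residue, 100°/residue) and a twisted extended
chain (radius 0.9 Å, rise 3.4 Å, 140°/residue): single helices, extended
strands, two-helix hairpins, three-helix bundles, and C_n cyclic
assemblies. N, C and O are placed at fixed offsets in each residue's local
Cα frame; backbone bond lengths use ideal values (N–Cα 1.458 Å, Cα–C
1.525 Å, C=O 1.23 Å).

The code assigns each residue a letter from a fixed bijective 5×4 lookup:
its within-structure burial quantile (five rank bins of the mean virtual-Cβ
distance to the 8 closest residues — small = buried) × its local geometry
class (the Cα(i−1…i+2) pseudo-dihedral in four 90° sectors). Windows never
span a chain discontinuity (a Cα–Cα step above 5 Å, as at rigidly placed
segment junctions); termini and break-adjacent residues use the nearest
valid window. Burial dominates the code by construction, so
recovery-versus-burial analyses have a known ground-truth gradient.

Several generator choices exist specifically to make the code's labels
*stable* — a quantile bin is a rank statistic, and near-ties in burial make
labels chaotic functions of coordinates:

* chains carry a gentle *curl* whose curvature varies monotonically along
  the chain (arc-length parametrised, so Cα spacing is preserved). This
  breaks two degeneracies of regular secondary structure — identical
  interior environments and the i ↔ n−1−i mirror symmetry — and for
  strands is tight enough that the chain makes tertiary contacts (a
  straight extended chain has near-constant burial). Curl angles, not
  radii, are drawn per structure, so different lengths are rescaled
  versions of one family;
* hairpin arms splay apart (monotone inter-arm distance) and bundle
  segments sit on graded radial shells, giving every residue a distinct
  burial regime; segment phases are shared within a structure so junction
  geometry stays regular;
* within-cluster diversity comes from these continuous shape parameters
  (feature-visible), while coordinate jitter is kept at 0.05 Å — heavy
  jitter would flip burial ranks near quantile boundaries without visibly
  changing the features, i.e. inject label noise;
* the strand twist (140°) centres its pseudo-dihedral mid-sector so curls
  never push windows across a class boundary.

Emitted datasets round coordinates to PDB precision *before* labelling, so
re-reading a file and recomputing the code reproduces the emitted sequence
exactly. Cluster ids are (kind, length); dense step-1 length menus give
held-out clusters close training neighbors.

What the generator does **not** emulate: real side-chain packing,
Ramachandran statistics, loop closure at segment junctions, evolutionary
sequence constraints, or experimental coordinate error beyond isotropic
jitter. Passing the synthetic benchmarks therefore demonstrates that the
pipeline can learn a geometry-determined sequence code end to end — not
that it reaches any particular accuracy on experimental structures.

## Benchmarks and their problem sizes

`invfold.benchmarks` fixes two desk-scale studies (minutes on one CPU):

* **Learnability**: a 440-structure dataset; one interior length per family
  held out with its whole cluster (helix L14, strand L16, hairpin L19,
  bundle L20, C2 L10); 300 training and 32 validation structures from the
  remaining clusters; the reference model (hidden 64, 2+2 layers, k = 24 —
  chosen so the graph covers whole structures, which global rank statistics
  require); 20 epochs; greedy single-sample design of 50 held-out
  structures. Seed replicates share the dataset and vary training and
  decoding randomness.
* **Noise robustness**: 125 training structures from the three single-chain
  families, a hidden-48 model, 18 epochs; matched runs with training noise
  0 and 0.02 Å are evaluated on 30 held-out structures, clean and with
  0.1 Å coordinate noise added (labels stay those of the clean
  coordinates).

## Known limitations

* Held-out-family recovery trails in-distribution recovery by a sizeable
  margin at these problem sizes. The dominant error mode is off-by-one
  burial-bin confusions: a quantile bin is a global rank statistic, and
  residues whose burial margin to a bin boundary is small are intrinsically
  hard for a smooth function approximator, while the bin *grid* itself
  shifts with structure length. Within-family (same kind and length,
  unseen shape parameters) the reference model is substantially more
  accurate than across families.
* At desk scale, 0.02 Å training noise behaves as a mild regulariser: it
  reliably helps on perturbed test backbones, but it does not show the
  clean-backbone penalty expected from large-scale training, where noise
  genuinely blurs information the model would otherwise exploit.
* The decoder propagates sequence context through decoder states of
  already-decoded neighbors only; no beam search, no per-position bias
  vectors, and no position-specific omit lists are provided.
* PDB/mmCIF reading keeps the highest-occupancy alternate location and
  skips waters, heteroatoms and non-protein polymers; biological-assembly
  expansion from symmetry operators is not performed.
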