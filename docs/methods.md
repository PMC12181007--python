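# Methods

## Problem

Given a table of drugs (identifier + SMILES) and a table of drug pairs with
binary labels, the package predicts the probability that two drugs interact.
The prediction is treated as binary classification `f : D × D → [0, 1]`
trained with binary cross-entropy. Each drug is embedded from three
complementary views before the pair is scored; both drugs of a pair pass
through the same shared-parameter encoders (a Siamese arrangement).

## The three encoding channels

**Sequence view.** SMILES strings are split into base symbols
(multi-character element symbols such as `Cl`/`Br`, bracket atoms as one
token, two-digit ring closures, single characters otherwise) and a
vocabulary of frequent consecutive subsequences is mined by greedily merging
the most frequent adjacent pair, byte-pair-encoding style (ties broken
lexicographically, merges never crossing the `.` fragment separator). Each
drug becomes a fixed-length sequence of substructure-token ids (default
length k = 50; longer sequences truncated, shorter padded with PAD = 0),
processed by a 2-layer pre-norm Transformer with 8 heads. The output width
(75) is not divisible by the 8 heads, so attention runs at internal width
80 = 8 × 10 and a final linear layer projects 80 → 75. The embedding
`f_seq` is the masked mean over non-PAD token states. Learned positional
embeddings are used; PAD positions are excluded from attention and pooling,
so the output is invariant to the amount of trailing padding.

**Graph view.** The heavy-atom molecular graph (hydrogens implicit; the
bonded-hydrogen count is an atom feature) carries nine integer codes per
atom — atomic-number class (elements 1–100 + UNK), chirality tag, degree,
formal charge, H count, radical electrons, hybridization, aromatic flag,
ring flag — and three per bond (type, stereo, conjugation), each drawn from
a fixed versioned dictionary with a reserved UNK slot. A message-passing
attention network runs K = 2 layers: per-edge message candidates are linear
in the neighbour state and bond embedding; an additive scorer
(concat → tanh → scalar) assigns attention over each neighbourhood; the
softmax-weighted message (25-dim) and the current state feed a GRU cell
shared by all atoms. Atoms without neighbours receive the zero message. The
readout is self-attention graph pooling: per-atom scores from `gnn(h^K, h^0)`
are softmax-normalised across the atoms of the molecule and weight
`fnn(h^K, h^0)`. The softmax is applied per output dimension (matching the
Hadamard form of the weighting); a scalar-gate variant is available via
`graph_scalar_gate`. With K = 0 the readout sees only the initial atom
embeddings, which supports the message-passing-depth sensitivity harness
(`graph_mp_layers` configurable 1–6, default 2).

**Spatial-semantic view.** Per-atom inputs are the atom-feature embedding
plus in- and out-degree centrality embeddings (molecular graphs are
undirected, so both equal the degree; the two tables are kept separate,
mirroring the general directed form of the centrality encoding). Per-atom-pair attention
biases combine a spatial embedding of the shortest-path distance — computed
by BFS with deterministic lowest-neighbour-index tie-breaking, clipped at
20, with a dedicated bucket for the −1 sentinel assigned to atoms in
different connected components — and an edge encoding: the mean of learned
bond embeddings along one shortest path. The path chosen for the pair
(x, y) is the deterministic BFS path for min(x, y) → max(x, y) in both
directions, which makes the bias matrix exactly symmetric. Three pre-norm
attention blocks (8 heads, hidden 256) add this bias to the scaled-dot
logits. ProbSparse attention computes exact attention only for the
⌈c·ln n⌉ queries with the largest sparsity measurement (row max minus row
mean of the attention logits, c = 5); the remaining queries take the masked
mean of the value vectors. Molecules with fewer than 8 atoms always get
full attention. `f_semantic` is the masked mean over atom states projected
to width 75.

## Fusion and decoding

All three views are projected to a common width (75). Each view embedding f
receives a scalar logit `w = W2 · tanh(W1 f + b)` from a projection shared
across views and drugs; the coefficients (α_s, α_g, α_sem) are the softmax
of the enabled views' logits — nonnegative, summing to one — and the fused
drug embedding is the corresponding convex combination. A strictly
elementwise reading of these scores (elementwise product with a matrix
followed by a three-way softmax over vector-valued scores) is incoherent
for widths above one, so the standard matrix–vector form is used. When
channels are disabled (ablations) the softmax renormalises over the
remaining views; a single view passes through with α = 1.

Pairs are scored by three fully connected layers (150 → 256 → 64 → 1, ReLU
between, sigmoid output) on the concatenation [F_i ; F_j]. Concatenation is
order-sensitive; since interaction labels are unordered, a symmetrised mode
(`symmetric_pairs`) averages the pre-sigmoid logits of both orders.
Training minimises mean binary cross-entropy with predictions clamped to
[1e−7, 1 − 1e−7].

## Training protocol

Pairs are deduplicated as unordered pairs (prevents the same pair appearing
in two splits), optionally subsampled to `dataset_fraction` (the robustness
protocol retains 75 %, 50 % or 25 % of pairs before splitting), shuffled
with a seeded generator and split 8:1:1 at floor boundaries with the
remainder going to train. Optimisation uses Adam, learning rate 1e−4, batch
size 16, default 50 epochs, no early stopping; the checkpoint with the best
validation AUROC is retained (the validation split otherwise has no stated
role). Metrics are accuracy and F1 at threshold 0.5 and rank-based AUROC
(ties counted half); a single-class test set reports AUROC as missing
rather than zero. Experiments repeat `n_repeats = 5` times with consecutive
seeds and report per-run values plus the mean. The seven ablation variants
toggle channel subsets: full, no_seq, no_graph, no_semantic, seq_only,
graph_only, semantic_only.

## Numerical implementation

The model runs on a small reverse-mode automatic-differentiation core over
NumPy arrays written for this package (`ddifuse._tensor`, `ddifuse.nn`),
in float32. Masked softmax shifts logits by the detached row maximum
(exact gradients) and maps fully-masked rows to zeros, which implements the
zero-message convention for isolated atoms. Parameter initialisation is
Glorot-uniform for weight matrices and N(0, 0.02) for embeddings, driven by
an explicit seeded generator: two models built from the same seed are
bit-identical, and training is fully deterministic given the seed on a
fixed platform. Dropout (0.1) is active only in training mode.

## Synthetic benchmark

Because curated DDI pair sets are external downloads, the package
ships a generator for a self-contained toy benchmark: each drug is an alkyl
scaffold (3–8 carbons) with one or two functional-group motifs (carboxyl
`C(=O)O`, amine `N`, phenyl, chloro, hydroxyl) grafted as valence-legal
branches; every emitted SMILES round-trips through the parser. A pair is
labelled positive when one drug carries the carboxyl motif and the other
the amine motif (symmetric); negatives are sampled uniformly from
non-satisfying pairs to an exact 1:1 balance, mirroring the balanced
sampling used with the real datasets. Defaults: 200 drugs, 2000 pairs, no
label noise. The signal is pure substructure presence — detectable in
principle by all three channels — and a Bayes-optimal classifier reaches
AUROC 1.0 on the noiseless rule, so trained performance near 1.0 is the
expected ceiling. The generator does not attempt to mimic real
pharmaceutical chemistry: molecules are small, acyclic apart from the
phenyl motif, and the interaction rule is far simpler than real
pharmacology, so passing results demonstrate that the pipeline can extract
substructure signal end-to-end, not that it attains comparable accuracy on
curated pharmacological data.

On this benchmark the full model reaches test AUROC 1.0 within a few
epochs. One caveat observed consistently: the semantic channel alone
(hidden width 256, the largest encoder) drives *training* loss down faster
than the fused three-channel model, whose convex attention fusion mixes in
the slower sequence and graph views. On data where a single view carries
the whole signal, channel fusion is not expected to win on training loss;
its benefit is expected on held-out
metrics when the views carry complementary signal.

## Choices made where the design was open

- The frequent-subsequence miner is realised as BPE-style greedy merging
  (the cited algorithm is not specified); defaults max_merges = 3000,
  min_frequency = 2. On very small corpora this merges aggressively and can
  collapse short SMILES to one or two tokens.
- Sequence length k = 50, Transformer depth 2, masked-mean pooling,
  learned positional embeddings (all unstated).
- Graph channel: initial hidden size r = 75; additive neighbour attention;
  per-dimension readout softmax (notation-faithful default).
- Semantic channel: bias enters as a per-head additive attention-logit
  scalar; ProbSparse factor c = 5 with full-attention fallback below 8
  atoms; per-molecule (not per-pair) attention, consistent with the Siamese
  framing.
- Pair representation: concatenation by default, symmetrised mode optional.
- Decoder hidden sizes 256 → 64 → 1 with ReLU (unstated).
- Multi-fragment SMILES (salts) are kept as-is; cross-fragment atom pairs
  use the −1 spatial bucket.

## Known limitations

- Strict permutation invariance of the semantic view relies on shortest
  paths being either unique or tie-equivalent (equal mean bond features).
  This holds for the benchmark chemistry (single homogeneous aromatic
  rings); heterogeneous fused-ring systems could break exact invariance at
  float tolerance.
- CPU-only; the default problem sizes here (hundreds of drugs, thousands of
  pairs) train in minutes, but the implementation is not intended for
  full-scale curated datasets.
- Binary interaction labels only; no interaction-type classification.
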