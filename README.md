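# ddifuse

Multi-view prediction of drug–drug interactions (DDIs) from chemical
structure alone. Co-administering drugs can cause adverse interactions, and
screening candidate pairs computationally is far cheaper than discovering
interactions in the clinic. `ddifuse` is aimed at cheminformatics
practitioners who have a table of drugs (id + SMILES) and a table of
labelled drug pairs and want a structure-only interaction classifier with a
reproducible training protocol.

## Model

Each drug d is embedded from three complementary views, all produced by
shared-parameter (Siamese) encoders:

- **f_seq** — the SMILES string is decomposed into frequent consecutive
  subsequences (a BPE-style mined vocabulary of substructure tokens, e.g.
  `C(=O)O`) and encoded by a Transformer (8 heads); padded/truncated to
  k = 50 tokens, masked-mean pooled, output width 75.
- **f_graph** — a message-passing attention network on the 2D molecular
  graph: attention-weighted neighbour aggregation (25-dim messages), GRU
  node updates, K = 2 layers, then self-attention graph pooling
  `f_graph = Σ_v α_v ⊙ fnn(h_v^K, h_v^0)` with
  `α_v = softmax_v gnn(h_v^K, h_v^0)`; output width 75.
- **f_semantic** — atom-level spatial semantics: atom features plus degree
  centrality embeddings per atom, and per-atom-pair biases built from the
  shortest-path distance s(x, y) (sentinel −1 across fragments) and the
  mean bond embedding along the path, `E_(x,y) = (1/k) Σ_l P_l·W_edge +
  W_spat[s(x,y)]`, fed to 3 ProbSparse self-attention blocks (8 heads,
  hidden 256).

A shared attention module fuses the views per drug:
`w_view = W2·tanh(W1 f_view + b)`, `(α_s, α_g, α_sem) = softmax(w)`,
`F_d = α_s f_seq + α_g f_graph + α_sem f_semantic`. A pair (d_i, d_j) is
scored by a three-layer fully connected decoder with sigmoid output on
[F_i ; F_j], trained with binary cross-entropy (Adam, lr 1e−4, batch 16,
8:1:1 random splits, metrics ACC / F1 / AUROC averaged over 5 repeats).

The neural stack runs on a small NumPy reverse-mode autodiff core that
ships with the package; there is no GPU dependency. See
[docs/methods.md](docs/methods.md) for every modelling choice and the
numerical details.

## Worked example

The package ships a generator for a self-contained toy benchmark: valid
SMILES built from an alkyl scaffold with functional-group motifs, where a
pair interacts exactly when one drug carries a carboxyl group and the other
an amine (balanced negatives). End to end:

```bash
ddifuse simulate --outdir data --n-drugs 60 --n-pairs 300 --seed 7
ddifuse train --drugs data/drugs.csv --pairs data/pairs.csv \
              --outdir run --seed 7 --epochs 3
```

The first command writes `drugs.csv` (e.g. `D0001,CCC(C(=O)O)`),
`pairs.csv` and a metadata sidecar recording each drug's motifs and the
planted rule. The second trains the full three-channel model and prints the
held-out test metrics:

```
{
  "acc": 0.8333333333333334,
  "f1": 0.8484848484848485,
  "auroc": 0.96875,
  "split_sizes": [240, 30, 30]
}
```

so after three epochs on 240 training pairs the model already ranks
interacting pairs almost perfectly (AUROC 0.97 on the 30 test pairs;
training loss fell 0.712 → 0.497). More epochs drive test AUROC to 1.0 —
the Bayes ceiling for the noiseless rule. `run/` contains the checkpoint,
the resolved config, a manifest with input digests, and `report.json` with
the loss/validation history. Other subcommands: `build-vocab`, `evaluate`,
`predict` (CSV of pair probabilities), and `ablate`, which trains the seven
channel-toggle variants (full, no_seq, no_graph, no_semantic, seq_only,
graph_only, semantic_only) and writes a comparison table. `--fraction`
subsamples the pair table before splitting for robustness studies, and
`--channels seq,graph` selects channel subsets directly.

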