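"""Atom spatial-semantic encoder (third channel).

Per-atom inputs combine a learned embedding of the nine atom category codes
with in- and out-degree centrality embeddings (molecular graphs are
undirected, so both degrees equal the atom degree, but the two tables are
kept separate).  Per-atom-pair attention biases combine a spatial embedding
of the shortest-path distance (with a dedicated bucket for the -1 sentinel
of cross-component pairs) with an edge encoding: the mean of learned bond
embeddings along one deterministic shortest path between the two atoms.

The atom states are processed by a stack of ProbSparse self-attention
blocks: only the ceil(c ln n) queries with the highest sparsity measurement
(max minus mean of their attention-logit row) receive exact attention, the
rest take the mean of the value vectors.  For molecules with fewer than
``full_attn_below`` atoms the encoder falls back to full attention.  The
masked mean over atom states, projected to the fusion width, is f_semantic.

All parameters are shared between the two drugs of a pair (Siamese).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor
from .chem import ATOM_DICT_SIZES, BOND_ONEHOT_DIM, MolGraph, bond_onehot
from .errors import EmptyMolecule
from .graph_encoder import CategoricalEmbedding
from .nn import (
    Dropout,
    Embedding,
    FeedForward,
    LayerNorm,
    Linear,
    Module,
    MultiHeadAttention,
    masked_mean,
)

D_MAX_SPATIAL = 20   # shortest-path distances are clipped to this
MAX_DEGREE_EMB = 10  # degree clip for the centrality tables


def spatial_bucket(spd: np.ndarray) -> np.ndarray:
    """Map raw shortest-path distances to embedding buckets.

    Bucket 0 holds the -1 sentinel (different components); bucket d+1 holds
    distance d for d <= D_MAX_SPATIAL; everything farther shares the last
    bucket.
    """
    return np.where(spd < 0, 0, np.minimum(spd, D_MAX_SPATIAL + 1) + 1)


N_SPATIAL_BUCKETS = D_MAX_SPATIAL + 3


@dataclass
class SemanticArrays:
    """Static per-molecule inputs for the semantic channel."""

    atom_feats: np.ndarray   # (n, 9) int
    degree: np.ndarray       # (n,) int, clipped
    spd_bucket: np.ndarray   # (n, n) int
    path_onehot: np.ndarray  # (n, n, BOND_ONEHOT_DIM) mean bond one-hots


def semantic_arrays(g: MolGraph) -> SemanticArrays:
    if g.n_atoms == 0:
        raise EmptyMolecule("semantic featurisation of an empty molecule")
    n = g.n_atoms
    onehots = np.stack([bond_onehot(f) for _, _, f in g.bonds]) if g.bonds else None
    path_oh = np.zeros((n, n, BOND_ONEHOT_DIM))
    # use the x < y path for both directions: the bias matrix is then
    # exactly symmetric even when tie-breaking would pick different paths
    for (x, y), bond_ids in g.paths.items():
        if x < y:
            path_oh[x, y] = path_oh[y, x] = onehots[bond_ids].mean(axis=0)
    return SemanticArrays(
        atom_feats=g.atom_feats,
        degree=np.minimum(g.degrees(), MAX_DEGREE_EMB),
        spd_bucket=spatial_bucket(g.spd),
        path_onehot=path_oh,
    )


@dataclass
class SemanticBatch:
    atom_feats: np.ndarray   # (B, n, 9)
    degree: np.ndarray       # (B, n)
    spd_bucket: np.ndarray   # (B, n, n)
    path_onehot: np.ndarray  # (B, n, n, BOND_ONEHOT_DIM)
    mask: np.ndarray         # (B, n) bool
    n_atoms: np.ndarray      # (B,) true atom counts


def collate_semantic(mols: list[SemanticArrays]) -> SemanticBatch:
    b = len(mols)
    n_max = max(m.atom_feats.shape[0] for m in mols)
    atom_feats = np.zeros((b, n_max, 9), dtype=np.int64)
    degree = np.zeros((b, n_max), dtype=np.int64)
    spd_bucket = np.zeros((b, n_max, n_max), dtype=np.int64)
    path_oh = np.zeros((b, n_max, n_max, BOND_ONEHOT_DIM))
    mask = np.zeros((b, n_max), dtype=bool)
    n_atoms = np.zeros(b, dtype=np.int64)
    for i, m in enumerate(mols):
        n = m.atom_feats.shape[0]
        atom_feats[i, :n] = m.atom_feats
        degree[i, :n] = m.degree
        spd_bucket[i, :n, :n] = m.spd_bucket
        path_oh[i, :n, :n] = m.path_onehot
        mask[i, :n] = True
        n_atoms[i] = n
    return SemanticBatch(atom_feats, degree, spd_bucket, path_oh, mask, n_atoms)


class SemanticEncoder(Module):
    def __init__(
        self,
        rng: np.random.Generator,
        hidden: int = 256,
        n_heads: int = 8,
        n_blocks: int = 3,
        d_out: int = 75,
        sampling_factor: float = 5.0,
        full_attn_below: int = 8,
        dropout_p: float = 0.1,
    ):
        super().__init__()
        self.h = n_heads
        self.c = sampling_factor
        self.full_below = full_attn_below
        self.atom_emb = CategoricalEmbedding(rng, ATOM_DICT_SIZES, hidden)  # W_Siamese
        self.w_in = Embedding(rng, MAX_DEGREE_EMB + 1, hidden)
        self.w_out = Embedding(rng, MAX_DEGREE_EMB + 1, hidden)
        self.w_edge = Tensor(
            rng.normal(0.0, 0.02, size=(BOND_ONEHOT_DIM, n_heads)), requires_grad=True
        )
        self.w_spat = Embedding(rng, N_SPATIAL_BUCKETS, n_heads)
        drop = Dropout(dropout_p, rng)
        self.ln1 = [LayerNorm(hidden) for _ in range(n_blocks)]
        self.attn = [MultiHeadAttention(rng, hidden, n_heads) for _ in range(n_blocks)]
        self.ln2 = [LayerNorm(hidden) for _ in range(n_blocks)]
        self.ffn = [FeedForward(rng, hidden, hidden, drop) for _ in range(n_blocks)]
        self.dropout = drop
        self.ln_final = LayerNorm(hidden)
        self.proj = Linear(rng, hidden, d_out)

    def centrality_encode(self, atom_feats: np.ndarray, degree: np.ndarray) -> Tensor:
        """E_x = atom embedding + out-degree embedding + in-degree embedding."""
        return self.atom_emb(atom_feats) + self.w_out(degree) + self.w_in(degree)

    def edge_spatial_bias(self, spd_bucket: np.ndarray, path_onehot: np.ndarray) -> Tensor:
        """Per-pair, per-head additive attention bias (B, H, n, n)."""
        edge_term = Tensor(path_onehot) @ self.w_edge          # (B, n, n, H)
        spat_term = self.w_spat(spd_bucket)                    # (B, n, n, H)
        return (edge_term + spat_term).transpose(0, 3, 1, 2)

    def _budget(self, n_atoms: np.ndarray, n_max: int) -> np.ndarray:
        u = np.ceil(self.c * np.log(np.maximum(n_atoms, 1))).astype(np.int64)
        return np.where(n_atoms < self.full_below, n_max, np.minimum(u, n_max))

    def probsparse_encode(self, batch: SemanticBatch) -> Tensor:
        x = self.centrality_encode(batch.atom_feats, batch.degree)
        bias = self.edge_spatial_bias(batch.spd_bucket, batch.path_onehot)
        top_u = self._budget(batch.n_atoms, batch.mask.shape[1])
        for ln1, attn, ln2, ffn in zip(self.ln1, self.attn, self.ln2, self.ffn):
            x = x + self.dropout(attn(ln1(x), batch.mask, bias=bias, top_u=top_u))
            x = x + self.dropout(ffn(ln2(x)))
        x = self.ln_final(x)
        return self.proj(masked_mean(x, batch.mask, axis=1))

    __call__ = probsparse_encode
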