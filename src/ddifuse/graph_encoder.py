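"""Message-passing attention network over 2D molecular graphs.

Each atom starts from a learned embedding of its nine category codes.  At
every message-passing layer an attention scorer assigns a weight to each
neighbour (softmax over the neighbourhood); the attention-weighted sum of
per-edge message candidates is fed, together with the current hidden state,
to a GRU cell shared by all atoms.  After K layers a self-attention graph
pooling readout produces the graph-view embedding f_graph: per-atom scores
gnn(h^K, h^0) are softmax-normalised across the atoms of the molecule and
used to weight fnn(h^K, h^0).

The softmax in the readout is applied per output dimension by default (the
Hadamard form); a scalar-gate mode (one weight per atom) is available via
``scalar_gate=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, concat, masked_softmax
from .chem import ATOM_DICT_SIZES, BOND_DICT_SIZES, MolGraph
from .nn import GRUCell, Linear, Module


@dataclass
class GraphBatch:
    """Dense padded batch of molecular graphs."""

    atom_feats: np.ndarray   # (B, n, 9) int
    mask: np.ndarray         # (B, n) bool, True for real atoms
    adj: np.ndarray          # (B, n, n) bool
    bond_feats: np.ndarray   # (B, n, n, 3) int, zeros where no bond


def graph_arrays(g: MolGraph) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = g.n_atoms
    adj = np.zeros((n, n), dtype=bool)
    bond = np.zeros((n, n, 3), dtype=np.int64)
    for i, j, feat in g.bonds:
        adj[i, j] = adj[j, i] = True
        bond[i, j] = bond[j, i] = feat
    return g.atom_feats, adj, bond


def collate_graphs(graphs: list[MolGraph]) -> GraphBatch:
    n_max = max(g.n_atoms for g in graphs)
    b = len(graphs)
    atom_feats = np.zeros((b, n_max, 9), dtype=np.int64)
    mask = np.zeros((b, n_max), dtype=bool)
    adj = np.zeros((b, n_max, n_max), dtype=bool)
    bond = np.zeros((b, n_max, n_max, 3), dtype=np.int64)
    for i, g in enumerate(graphs):
        n = g.n_atoms
        af, ad, bf = graph_arrays(g)
        atom_feats[i, :n] = af
        mask[i, :n] = True
        adj[i, :n, :n] = ad
        bond[i, :n, :n] = bf
    return GraphBatch(atom_feats=atom_feats, mask=mask, adj=adj, bond_feats=bond)


class CategoricalEmbedding(Module):
    """Sum of per-slot embeddings for a tuple of category codes."""

    def __init__(self, rng, sizes: tuple[int, ...], d: int):
        super().__init__()
        self.offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        self.weight = Tensor(
            rng.normal(0.0, 0.02, size=(int(np.sum(sizes)), d)), requires_grad=True
        )

    def __call__(self, codes: np.ndarray) -> Tensor:
        idx = np.asarray(codes) + self.offsets  # (..., n_slots)
        return self.weight.take_rows(idx).sum(axis=-2)


class GraphEncoder(Module):
    def __init__(
        self,
        rng: np.random.Generator,
        hidden: int = 75,
        message_size: int = 25,
        n_layers: int = 2,
        d_out: int = 75,
        scalar_gate: bool = False,
    ):
        super().__init__()
        self.K = n_layers
        self.scalar_gate = scalar_gate
        self.atom_emb = CategoricalEmbedding(rng, ATOM_DICT_SIZES, hidden)
        self.bond_emb = CategoricalEmbedding(rng, BOND_DICT_SIZES, message_size)
        self.msg_net = Linear(rng, hidden + message_size, message_size)
        self.score1 = Linear(rng, 2 * hidden + message_size, 32)
        self.score2 = Linear(rng, 32, 1)
        self.gru = GRUCell(rng, message_size, hidden)
        self.fnn = Linear(rng, 2 * hidden, d_out)
        self.gnn = Linear(rng, 2 * hidden, 1 if scalar_gate else d_out)

    def _expand(self, h: Tensor, axis: int) -> Tensor:
        """(B, n, d) -> (B, n, n, d) constant-broadcast along ``axis`` (1 or 2)."""
        b, n, d = h.shape
        shape = (b, 1, n, d) if axis == 1 else (b, n, 1, d)
        tile = np.ones((1, n, 1, 1)) if axis == 1 else np.ones((1, 1, n, 1))
        return h.reshape(*shape) * Tensor(tile)

    def aggregate_messages(self, h: Tensor, edge_emb: Tensor, adj: np.ndarray) -> Tensor:
        """Attention-weighted neighbour aggregation (one layer of Eq-3 style).

        ``h``: (B, n, hidden); ``edge_emb``: (B, n, n, message); ``adj``:
        (B, n, n) bool.  Atoms with no neighbours receive the zero message.
        """
        hv = self._expand(h, axis=2)   # state of the receiving atom v
        hw = self._expand(h, axis=1)   # state of the neighbour w
        cand = self.msg_net(concat([hw, edge_emb], axis=-1))           # (B,n,n,msg)
        logits = self.score2(self.score1(concat([hv, hw, edge_emb], axis=-1)).tanh())
        alpha = masked_softmax(logits.reshape(*logits.shape[:3]), adj, axis=-1)
        return (cand * alpha.reshape(*alpha.shape, 1)).sum(axis=2)

    def update_nodes(self, h: Tensor, messages: Tensor) -> Tensor:
        return self.gru(messages, h)

    def readout_weights(self, h_final: Tensor, h0: Tensor, mask: np.ndarray) -> Tensor:
        """Importance scores alpha_v: softmax over the atoms of each molecule."""
        cat = concat([h_final, h0], axis=-1)
        return masked_softmax(self.gnn(cat), mask[..., None], axis=1)

    def readout(self, h_final: Tensor, h0: Tensor, mask: np.ndarray) -> Tensor:
        cat = concat([h_final, h0], axis=-1)
        weights = masked_softmax(self.gnn(cat), mask[..., None], axis=1)
        return (weights * self.fnn(cat)).sum(axis=1)

    def node_states(self, batch: GraphBatch) -> tuple[Tensor, Tensor]:
        """Run message passing; returns (h^K, h^0)."""
        h0 = self.atom_emb(batch.atom_feats)
        edge_emb = self.bond_emb(batch.bond_feats)
        h = h0
        for _ in range(self.K):
            m = self.aggregate_messages(h, edge_emb, batch.adj)
            h = self.update_nodes(h, m)
        return h, h0

    def __call__(self, batch: GraphBatch) -> Tensor:
        h, h0 = self.node_states(batch)
        return self.readout(h, h0, batch.mask)
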