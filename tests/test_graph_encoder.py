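"""Graph-channel encoder: attention aggregation, GRU update, pooling readout."""

import numpy as np
import pytest

from ddifuse._tensor import Tensor, concat
from ddifuse.chem import MolGraph, parse_drug
from ddifuse.graph_encoder import GraphEncoder, collate_graphs
from ddifuse.nn import GRUCell

from conftest import make_record


def _encoder(rng, **kw):
    defaults = dict(hidden=16, message_size=8, n_layers=2, d_out=10)
    defaults.update(kw)
    return GraphEncoder(rng, **defaults)


def _permute_molgraph(g: MolGraph, perm: np.ndarray) -> MolGraph:
    """Relabel atoms of a MolGraph by ``perm`` (new index of old atom i)."""
    inv = {int(old): int(new) for new, old in enumerate(perm)}
    n = g.n_atoms
    bonds = [(inv[i], inv[j], f) for i, j, f in g.bonds]
    neighbors = [[] for _ in range(n)]
    for i, j, _ in bonds:
        neighbors[i].append(j)
        neighbors[j].append(i)
    out = MolGraph(
        atom_feats=g.atom_feats[perm],
        bonds=bonds,
        neighbors=[sorted(nb) for nb in neighbors],
        spd=np.empty(0),
    )
    from ddifuse.chem import all_pairs_shortest_paths

    out.spd, out.paths = all_pairs_shortest_paths(out)
    return out


def test_single_neighbor_weight_is_one(rng):
    """Softmax over one neighbour: the message equals the lone candidate."""
    enc = _encoder(rng)
    batch = collate_graphs([parse_drug(make_record("CC"))])
    h = enc.atom_emb(batch.atom_feats)
    e = enc.bond_emb(batch.bond_feats)
    m = enc.aggregate_messages(h, e, batch.adj)
    # candidate for atom 0 from neighbour 1
    cand = enc.msg_net(concat([h[:, 1:2, :], e[:, 0:1, 1, :]], axis=-1))
    np.testing.assert_allclose(m.data[0, 0], cand.data[0, 0], atol=1e-6)


def test_isolated_atom_zero_message(rng):
    enc = _encoder(rng)
    batch = collate_graphs([parse_drug(make_record("[Na+].[Cl-]"))])
    h = enc.atom_emb(batch.atom_feats)
    m = enc.aggregate_messages(h, enc.bond_emb(batch.bond_feats), batch.adj)
    np.testing.assert_array_equal(m.data, 0.0)


def test_identical_neighbors_share_weight(rng):
    """Propane's central carbon: two identical neighbours get 0.5 each."""
    enc = _encoder(rng)
    batch = collate_graphs([parse_drug(make_record("CCC"))])
    h = enc.atom_emb(batch.atom_feats)
    e = enc.bond_emb(batch.bond_feats)
    m = enc.aggregate_messages(h, e, batch.adj)
    cand = enc.msg_net(concat([h[:, 0:1, :], e[:, 1:2, 0, :]], axis=-1))
    # 0.5 * cand(atom0) + 0.5 * cand(atom2) = cand (atoms 0 and 2 identical)
    np.testing.assert_allclose(m.data[0, 1], cand.data[0, 0], atol=1e-6)


def test_update_locality(rng):
    """Changing one atom's message leaves the other atoms' updates unchanged."""
    enc = _encoder(rng)
    h = Tensor(rng.normal(size=(1, 3, 16)))
    m1 = rng.normal(size=(1, 3, 8))
    m2 = m1.copy()
    m2[0, 0] += 1.0
    out1 = enc.update_nodes(h, Tensor(m1))
    out2 = enc.update_nodes(h, Tensor(m2))
    assert not np.allclose(out1.data[0, 0], out2.data[0, 0])
    np.testing.assert_array_equal(out1.data[0, 1:], out2.data[0, 1:])


def test_gru_matches_gate_equation_oracle(rng):
    """Independent three-gate GRU recurrence on a random 4-dim case."""
    cell = GRUCell(rng, 4, 4)
    x = rng.normal(size=(1, 4))
    h = rng.normal(size=(1, 4))
    out = cell(Tensor(x), Tensor(h))

    def sig(a):
        return 1.0 / (1.0 + np.exp(-a))

    wx, bx = cell.wx.weight.data, cell.wx.bias.data
    wh, bh = cell.wh.weight.data, cell.wh.bias.data
    gx, gh = x @ wx + bx, h @ wh + bh
    z = sig(gx[:, 0:4] + gh[:, 0:4])
    r = sig(gx[:, 4:8] + gh[:, 4:8])
    nctx = np.tanh(gx[:, 8:12] + r * gh[:, 8:12])
    expected = (1 - z) * nctx + z * h
    np.testing.assert_allclose(out.data, expected, atol=1e-6)


def test_zero_gru_zero_inputs_zero_output(rng):
    cell = GRUCell(rng, 4, 4)
    for p in cell.parameters():
        p.data = np.zeros_like(p.data)
    out = cell(Tensor(np.zeros((1, 4))), Tensor(np.zeros((1, 4))))
    np.testing.assert_array_equal(out.data, 0.0)


def test_single_atom_readout(rng):
    """Methane: softmax over one atom gives alpha=1, f = fnn(hK, h0)."""
    enc = _encoder(rng)
    batch = collate_graphs([parse_drug(make_record("C"))])
    h, h0 = enc.node_states(batch)
    f = enc.readout(h, h0, batch.mask)
    expected = enc.fnn(concat([h, h0], axis=-1))
    np.testing.assert_allclose(f.data[0], expected.data[0, 0], atol=1e-6)


def test_readout_weights_sum_to_one(rng, toy_graphs):
    enc = _encoder(rng)
    batch = collate_graphs(toy_graphs)
    h, h0 = enc.node_states(batch)
    w = enc.readout_weights(h, h0, batch.mask)
    sums = w.data.sum(axis=1)
    np.testing.assert_allclose(sums, 1.0, atol=1e-6)
    assert np.all(w.data >= 0.0)


def test_permutation_invariance(rng, toy_graphs):
    enc = _encoder(rng)
    for g in toy_graphs[:8]:
        perms = [np.random.default_rng(s).permutation(g.n_atoms) for s in range(10)]
        batch = collate_graphs([g] + [_permute_molgraph(g, p) for p in perms])
        out = enc(batch).data
        np.testing.assert_allclose(out, np.broadcast_to(out[0], out.shape), atol=1e-5)


def test_k0_depends_only_on_initial_embedding(rng, toy_graphs):
    enc = _encoder(rng, n_layers=0)
    batch = collate_graphs(toy_graphs[:4])
    h, h0 = enc.node_states(batch)
    np.testing.assert_array_equal(h.data, h0.data)
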