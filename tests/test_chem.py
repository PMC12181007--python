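"""Molecular graph construction, shortest paths and table I/O."""

import numpy as np
import pytest
from rdkit import Chem
from scipy.sparse.csgraph import floyd_warshall

from ddifuse.chem import (
    DrugRecord,
    MolGraph,
    all_pairs_shortest_paths,
    parse_drug,
    read_drug_table,
    read_pair_table,
    write_drug_table,
)
from ddifuse.errors import (
    DuplicateDrugId,
    EmptyMolecule,
    MissingColumn,
    NonBinaryLabel,
    UnknownDrugReference,
    UnparsableSmiles,
)

from conftest import make_record


def test_ethanol_linear_chain():
    g = parse_drug(make_record("CCO"))
    assert g.n_atoms == 3
    assert len(g.bonds) == 2
    assert g.spd[0, 2] == 2


def test_disconnected_salt_gets_sentinel():
    g = parse_drug(make_record("[Na+].[Cl-]"))
    assert g.n_atoms == 2
    assert len(g.bonds) == 0
    assert g.spd[0, 1] == -1
    assert (0, 1) not in g.paths


def test_benzene_flags_match_toolkit():
    g = parse_drug(make_record("c1ccccc1"))
    mol = Chem.MolFromSmiles("c1ccccc1")
    for i, atom in enumerate(mol.GetAtoms()):
        a = g.atom_feats[i]
        assert a[7] == int(atom.GetIsAromatic()) == 1
        assert a[8] == int(atom.IsInRing()) == 1
        assert a[2] == atom.GetDegree() == 2


def test_propane_shortest_path_bonds():
    g = parse_drug(make_record("CCC"))
    assert g.spd[0, 2] == 2
    assert g.paths[(0, 2)] == [0, 1]  # bond(0,1) then bond(1,2)
    assert g.spd[1, 1] == 0
    assert (1, 1) not in g.paths


def test_parse_errors(monkeypatch):
    with pytest.raises(UnparsableSmiles):
        parse_drug(make_record("not-a-smiles(("))
    with pytest.raises(UnparsableSmiles):
        parse_drug(make_record(""))
    # the toolkit never hands back a zero-atom parse for non-empty input, so
    # exercise the guard directly
    import ddifuse.chem as chem

    monkeypatch.setattr(chem.Chem, "MolFromSmiles", lambda s: Chem.RWMol())
    with pytest.raises(EmptyMolecule):
        parse_drug(make_record("CCO"))


def _random_molgraph(rng, n):
    """Random undirected graph dressed up as a MolGraph."""
    bonds = []
    neighbors = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.25:
                bonds.append((i, j, (1, 1, 0)))
                neighbors[i].append(j)
                neighbors[j].append(i)
    return MolGraph(
        atom_feats=np.zeros((n, 9), dtype=np.int64),
        bonds=bonds,
        neighbors=[sorted(nb) for nb in neighbors],
        spd=np.empty(0),
    )


def test_bfs_matches_floyd_warshall_oracle():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(1, 13))
        g = _random_molgraph(rng, n)
        spd, paths = all_pairs_shortest_paths(g)
        dense = np.full((n, n), np.inf)
        np.fill_diagonal(dense, 0.0)
        for i, j, _ in g.bonds:
            dense[i, j] = dense[j, i] = 1.0
        oracle = floyd_warshall(dense)
        expected = np.where(np.isinf(oracle), -1, oracle).astype(int)
        np.testing.assert_array_equal(spd, expected)
        # returned path lengths agree with the distances
        for (s, t), bond_ids in paths.items():
            assert len(bond_ids) == spd[s, t]


def test_spd_one_iff_bond(toy_graphs):
    for g in toy_graphs:
        bonded = set()
        for i, j, _ in g.bonds:
            bonded.add((i, j))
            bonded.add((j, i))
        n = g.n_atoms
        for i in range(n):
            for j in range(n):
                assert ((i, j) in bonded) == (g.spd[i, j] == 1)


def test_atom_permutation_equivariance(toy_drugs):
    """A renumbered SMILES of the same molecule gives an isomorphic graph."""
    for rec in toy_drugs[:10]:
        mol = Chem.MolFromSmiles(rec.smiles)
        perm = list(np.random.default_rng(3).permutation(mol.GetNumAtoms()))
        renumbered = Chem.MolToSmiles(
            Chem.RenumberAtoms(mol, [int(p) for p in perm]), canonical=False
        )
        assert Chem.MolToSmiles(Chem.MolFromSmiles(renumbered)) == Chem.MolToSmiles(mol)
        g1, g2 = parse_drug(rec), parse_drug(make_record(renumbered))
        assert g1.n_atoms == g2.n_atoms
        assert sorted(g1.degrees()) == sorted(g2.degrees())
        assert sorted(g1.spd.ravel()) == sorted(g2.spd.ravel())


def test_drug_table_roundtrip_and_errors(tmp_path):
    path = tmp_path / "drugs.csv"
    write_drug_table(path, [DrugRecord("a", "CCO"), DrugRecord("b", "CCN")])
    records = read_drug_table(path)
    assert [r.drug_id for r in records] == ["a", "b"]

    path.write_text("drug_id,smiles\na,CCO\na,CCN\n")
    with pytest.raises(DuplicateDrugId):
        read_drug_table(path)

    path.write_text("identifier,smiles\na,CCO\n")
    with pytest.raises(MissingColumn):
        read_drug_table(path)


def test_pair_table_errors(tmp_path):
    path = tmp_path / "pairs.csv"
    path.write_text("drug_id_1,drug_id_2,label\na,b,1\n")
    assert read_pair_table(path, known_ids=["a", "b"])[0].label == 1
    with pytest.raises(UnknownDrugReference):
        read_pair_table(path, known_ids=["a"])
    path.write_text("drug_id_1,drug_id_2,label\na,b,2\n")
    with pytest.raises(NonBinaryLabel):
        read_pair_table(path, known_ids=["a", "b"])
    path.write_text("drug_id_1,drug_id_2\na,b\n")
    with pytest.raises(MissingColumn):
        read_pair_table(path)
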