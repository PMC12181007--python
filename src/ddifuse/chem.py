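"""SMILES parsing, molecular-graph featurisation and dataset table I/O.

Molecules are heavy-atom graphs: hydrogens stay implicit and enter only
through the per-atom bonded-hydrogen count.  Each atom carries nine integer
category codes and each bond three, looked up in fixed dictionaries; values
outside a dictionary map to its reserved UNK slot.  The graph also stores an
all-pairs shortest-path-distance matrix (sentinel -1 for atoms in different
connected components) and, for every reachable ordered pair, one
deterministic shortest path as a list of bond indices.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .errors import (
    DuplicateDrugId,
    EmptyMolecule,
    MissingColumn,
    NonBinaryLabel,
    UnknownDrugReference,
    UnparsableSmiles,
)

RDLogger.DisableLog("rdApp.*")

# ---------------------------------------------------------------------------
# feature dictionaries (versioned: bump FEATURE_VERSION on any change)
# ---------------------------------------------------------------------------
FEATURE_VERSION = 1

MAX_ATOMIC_NUM = 100          # elements 1..100; anything else -> UNK
CHIRAL_TAGS = [
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
    Chem.ChiralType.CHI_OTHER,
]
MAX_DEGREE = 10
CHARGE_RANGE = list(range(-5, 6))
MAX_NUM_H = 8
MAX_RADICAL = 4
HYBRIDIZATIONS = [
    Chem.HybridizationType.S,
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
]
BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]
BOND_STEREO = [
    Chem.BondStereo.STEREONONE,
    Chem.BondStereo.STEREOANY,
    Chem.BondStereo.STEREOZ,
    Chem.BondStereo.STEREOE,
    Chem.BondStereo.STEREOCIS,
    Chem.BondStereo.STEREOTRANS,
]

# dictionary sizes (each +1 for the UNK / clip bucket where applicable)
ATOM_DICT_SIZES = (
    MAX_ATOMIC_NUM + 1,        # atomic number class (0 = UNK)
    len(CHIRAL_TAGS) + 1,
    MAX_DEGREE + 1,
    len(CHARGE_RANGE) + 1,
    MAX_NUM_H + 1,
    MAX_RADICAL + 1,
    len(HYBRIDIZATIONS) + 1,   # last slot = "other"
    2,                         # aromatic flag
    2,                         # in-ring flag
)
BOND_DICT_SIZES = (len(BOND_TYPES) + 1, len(BOND_STEREO) + 1, 2)
BOND_ONEHOT_DIM = sum(BOND_DICT_SIZES)


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    smiles: str


@dataclass(frozen=True)
class PairRecord:
    drug_id_1: str
    drug_id_2: str
    label: int


@dataclass
class MolGraph:
    """Annotated heavy-atom molecular graph."""

    atom_feats: np.ndarray                 # (n, 9) int codes
    bonds: list[tuple[int, int, tuple[int, int, int]]]
    neighbors: list[list[int]]             # sorted adjacency lists
    spd: np.ndarray                        # (n, n) shortest-path distances, -1 sentinel
    paths: dict[tuple[int, int], list[int]] = field(default_factory=dict)
    # paths maps an ordered reachable pair to the bond indices it traverses

    @property
    def n_atoms(self) -> int:
        return self.atom_feats.shape[0]

    def degrees(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors], dtype=np.int64)


def _encode_atom(atom: Chem.Atom) -> tuple[int, ...]:
    z = atom.GetAtomicNum()
    a1 = z if 1 <= z <= MAX_ATOMIC_NUM else 0
    tag = atom.GetChiralTag()
    a2 = CHIRAL_TAGS.index(tag) + 1 if tag in CHIRAL_TAGS else 0
    a3 = min(atom.GetDegree(), MAX_DEGREE)
    charge = atom.GetFormalCharge()
    a4 = CHARGE_RANGE.index(charge) + 1 if charge in CHARGE_RANGE else 0
    a5 = min(atom.GetTotalNumHs(), MAX_NUM_H)
    a6 = min(atom.GetNumRadicalElectrons(), MAX_RADICAL)
    hyb = atom.GetHybridization()
    a7 = HYBRIDIZATIONS.index(hyb) if hyb in HYBRIDIZATIONS else len(HYBRIDIZATIONS)
    a8 = int(atom.GetIsAromatic())
    a9 = int(atom.IsInRing())
    return (a1, a2, a3, a4, a5, a6, a7, a8, a9)


def _encode_bond(bond: Chem.Bond) -> tuple[int, int, int]:
    bt = bond.GetBondType()
    b1 = BOND_TYPES.index(bt) + 1 if bt in BOND_TYPES else 0
    st = bond.GetStereo()
    b2 = BOND_STEREO.index(st) + 1 if st in BOND_STEREO else 0
    b3 = int(bond.GetIsConjugated())
    return (b1, b2, b3)


def bond_onehot(feat: tuple[int, int, int]) -> np.ndarray:
    """Concatenated one-hot encoding of the three bond category codes."""
    v = np.zeros(BOND_ONEHOT_DIM)
    off = 0
    for code, size in zip(feat, BOND_DICT_SIZES):
        v[off + code] = 1.0
        off += size
    return v


def parse_drug(record: DrugRecord) -> MolGraph:
    """Parse a SMILES string into an annotated :class:`MolGraph`.

    Atom order follows RDKit's atom ordering for the input SMILES.  Raises
    :class:`UnparsableSmiles` on invalid grammar and :class:`EmptyMolecule`
    when the parse yields zero heavy atoms.
    """
    if not record.smiles:
        raise UnparsableSmiles(f"{record.drug_id}: empty SMILES")
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise UnparsableSmiles(f"{record.drug_id}: cannot parse {record.smiles!r}")
    n = mol.GetNumAtoms()
    if n == 0:
        raise EmptyMolecule(f"{record.drug_id}: zero atoms in {record.smiles!r}")
    atom_feats = np.array([_encode_atom(a) for a in mol.GetAtoms()], dtype=np.int64)
    bonds = []
    neighbors: list[list[int]] = [[] for _ in range(n)]
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bonds.append((i, j, _encode_bond(bond)))
        neighbors[i].append(j)
        neighbors[j].append(i)
    neighbors = [sorted(nb) for nb in neighbors]
    graph = MolGraph(atom_feats=atom_feats, bonds=bonds, neighbors=neighbors,
                     spd=np.empty(0))
    graph.spd, graph.paths = all_pairs_shortest_paths(graph)
    return graph


def all_pairs_shortest_paths(graph: MolGraph) -> tuple[np.ndarray, dict]:
    """BFS all-pairs shortest paths with deterministic tie-breaking.

    Neighbours are explored lowest-index-first, so the parent tree (hence the
    returned path for each ordered pair) is unique and reproducible.  Returns
    the (n, n) distance matrix (-1 for cross-component pairs) and a dict
    mapping each reachable ordered pair (s, t), s != t, to the list of bond
    indices along one shortest path from s to t.
    """
    n = graph.n_atoms
    bond_index = {}
    for idx, (i, j, _) in enumerate(graph.bonds):
        bond_index[(i, j)] = idx
        bond_index[(j, i)] = idx
    spd = -np.ones((n, n), dtype=np.int64)
    paths: dict[tuple[int, int], list[int]] = {}
    for s in range(n):
        spd[s, s] = 0
        parent = {s: -1}
        q = deque([s])
        while q:
            u = q.popleft()
            for w in graph.neighbors[u]:
                if w not in parent:
                    parent[w] = u
                    spd[s, w] = spd[s, u] + 1
                    q.append(w)
        for t in parent:
            if t == s:
                continue
            path = []
            node = t
            while parent[node] != -1:
                path.append(bond_index[(parent[node], node)])
                node = parent[node]
            paths[(s, t)] = path[::-1]
    return spd, paths


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------
def _read_table(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingColumn(f"{path}: missing column(s) {missing}")
    return df


def read_drug_table(path) -> list[DrugRecord]:
    df = _read_table(path, ["drug_id", "smiles"])
    seen = set()
    records = []
    for _, row in df.iterrows():
        did = str(row["drug_id"])
        if did in seen:
            raise DuplicateDrugId(f"{path}: duplicate drug_id {did!r}")
        seen.add(did)
        records.append(DrugRecord(drug_id=did, smiles=str(row["smiles"])))
    return records


def read_pair_table(path, known_ids=None) -> list[PairRecord]:
    df = _read_table(path, ["drug_id_1", "drug_id_2", "label"])
    known = set(known_ids) if known_ids is not None else None
    records = []
    for _, row in df.iterrows():
        d1, d2 = str(row["drug_id_1"]), str(row["drug_id_2"])
        if known is not None:
            for d in (d1, d2):
                if d not in known:
                    raise UnknownDrugReference(f"{path}: unknown drug id {d!r}")
        raw = str(row["label"]).strip()
        try:
            label = int(raw)
        except ValueError:
            raise NonBinaryLabel(f"{path}: label {raw!r} is not an integer") from None
        if label not in (0, 1):
            raise NonBinaryLabel(f"{path}: label {label} is not binary")
        records.append(PairRecord(drug_id_1=d1, drug_id_2=d2, label=label))
    return records


def write_drug_table(path, records: list[DrugRecord]) -> None:
    pd.DataFrame(
        {"drug_id": [r.drug_id for r in records], "smiles": [r.smiles for r in records]}
    ).to_csv(path, index=False)


def write_pair_table(path, records: list[PairRecord]) -> None:
    pd.DataFrame(
        {
            "drug_id_1": [r.drug_id_1 for r in records],
            "drug_id_2": [r.drug_id_2 for r in records],
            "label": [r.label for r in records],
        }
    ).to_csv(path, index=False)
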