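"""Molecule → attributed graph conversion.

Atoms are nodes and bonds are edges (stored once per direction).  The
feature scheme is versioned: node features are the concatenation of element
one-hot (+ unknown slot), heavy-atom degree one-hot 0-5 (clamped), formal
charge one-hot {-1, 0, +1}, aromaticity flag, in-ring flag, ring-size flags
3-9, hybridization one-hot {sp, sp2, sp3, other} and attached-H count
one-hot 0-4; edge features are bond-order one-hot {single, double, triple,
aromatic}, conjugation flag and in-ring flag.  Atom order follows RDKit's
canonical ranking, so two SMILES spellings of the same molecule produce
identical graphs.  Hydrogens are implicit throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

__all__ = ["FeatureScheme", "MolecularGraph", "featurize", "scheme_dims", "mol_from_smiles"]

_HYBRIDIZATIONS = (
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
)
_BOND_ORDERS = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)

_MAX_DEGREE = 5
_MAX_H = 4
_RING_SIZES = tuple(range(3, 10))


@dataclass(frozen=True)
class FeatureScheme:
    """Versioned description of the node/edge feature layout.

    The layout is a reconstruction kept behind this one interface so an
    alternative scheme can be swapped in without touching the model.
    """

    element_palette: tuple[str, ...] = ("C", "N", "O", "S")
    version: str = "v1"

    @property
    def node_dim(self) -> int:
        n_elem = len(self.element_palette) + 1  # + unknown slot
        return n_elem + (_MAX_DEGREE + 1) + 3 + 1 + 1 + len(_RING_SIZES) + 4 + (_MAX_H + 1)

    @property
    def edge_dim(self) -> int:
        return len(_BOND_ORDERS) + 2


def scheme_dims(scheme: FeatureScheme) -> tuple[int, int]:
    """(node feature width, edge feature width) — a pure function of the scheme."""
    if not scheme.element_palette:
        raise ValueError("empty element palette")
    return scheme.node_dim, scheme.edge_dim


@dataclass
class MolecularGraph:
    """One molecule as a directed attributed graph (both directions per bond)."""

    mol_id: str
    node_features: np.ndarray  # (N, F_n) of {0, 1}
    edge_index: np.ndarray     # (2, E) int, E = 2 * n_bonds
    edge_features: np.ndarray  # (E, F_e) of {0, 1}

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[1]


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


def _one_hot(index: int, width: int) -> np.ndarray:
    v = np.zeros(width)
    v[index] = 1.0
    return v


def _node_features(atom: Chem.Atom, ring_info, scheme: FeatureScheme) -> np.ndarray:
    palette = scheme.element_palette
    sym = atom.GetSymbol()
    if sym in palette:
        elem = _one_hot(palette.index(sym), len(palette) + 1)
    else:
        warnings.warn(f"element {sym} outside palette; using unknown slot", stacklevel=4)
        elem = _one_hot(len(palette), len(palette) + 1)
    degree = _one_hot(min(atom.GetDegree(), _MAX_DEGREE), _MAX_DEGREE + 1)
    charge = _one_hot(int(np.clip(atom.GetFormalCharge(), -1, 1)) + 1, 3)
    aromatic = np.array([float(atom.GetIsAromatic())])
    in_ring = np.array([float(atom.IsInRing())])
    ring_sizes = np.array(
        [float(ring_info.IsAtomInRingOfSize(atom.GetIdx(), s)) for s in _RING_SIZES]
    )
    hyb = atom.GetHybridization()
    hyb_idx = _HYBRIDIZATIONS.index(hyb) if hyb in _HYBRIDIZATIONS else 3
    hybrid = _one_hot(hyb_idx, 4)
    n_h = _one_hot(min(atom.GetTotalNumHs(), _MAX_H), _MAX_H + 1)
    return np.concatenate([elem, degree, charge, aromatic, in_ring, ring_sizes, hybrid, n_h])


def _edge_features(bond: Chem.Bond) -> np.ndarray:
    order = bond.GetBondType()
    idx = _BOND_ORDERS.index(order) if order in _BOND_ORDERS else 0
    return np.concatenate(
        [
            _one_hot(idx, len(_BOND_ORDERS)),
            np.array([float(bond.GetIsConjugated()), float(bond.IsInRing())]),
        ]
    )


def featurize(molecule: "Chem.Mol | str", scheme: FeatureScheme | None = None,
              mol_id: str = "") -> MolecularGraph:
    """Convert one molecule to its attributed graph.

    Node order follows canonical atom ranking (ties broken canonically), so
    the output is independent of the input SMILES atom ordering.
    """
    scheme = scheme or FeatureScheme()
    mol = mol_from_smiles(molecule) if isinstance(molecule, str) else molecule
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    order = np.argsort(ranks)  # order[r] = original index of rank r
    new_pos = {int(order[r]): r for r in range(mol.GetNumAtoms())}
    ring_info = mol.GetRingInfo()
    nodes = np.stack(
        [_node_features(mol.GetAtomWithIdx(int(order[r])), ring_info, scheme)
         for r in range(mol.GetNumAtoms())]
    ) if mol.GetNumAtoms() else np.zeros((0, scheme.node_dim))
    edges = []
    feats = []
    for bond in mol.GetBonds():
        i = new_pos[bond.GetBeginAtomIdx()]
        j = new_pos[bond.GetEndAtomIdx()]
        f = _edge_features(bond)
        edges.append((i, j))
        feats.append(f)
        edges.append((j, i))
        feats.append(f)
    if edges:
        edge_index = np.array(edges, dtype=np.int64).T
        edge_features = np.stack(feats)
        srt = np.lexsort((edge_index[1], edge_index[0]))
        edge_index = edge_index[:, srt]
        edge_features = edge_features[srt]
    else:
        edge_index = np.zeros((2, 0), dtype=np.int64)
        edge_features = np.zeros((0, scheme.edge_dim))
    return MolecularGraph(
        mol_id=mol_id,
        node_features=nodes,
        edge_index=edge_index,
        edge_features=edge_features,
    )
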