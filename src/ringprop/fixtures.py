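"""Generation and I/O of cyclic test molecules.

The generator assembles mono-, bi- and tricyclic molecules by template
assembly: ring skeletons (size 3-9, aromatic or aliphatic) are sampled,
heteroatom substitutions applied with valence checking, and rings joined by
one of four connection modes -- fused (share an edge), bridged (share two
non-adjacent atoms via a new bridge path), spiro (share one sp3 atom) or
linked (single bond, diaryl-like).  Candidate structures that fail RDKit
sanitization or fall outside the structural envelope (1-3 SSSR rings, ring
sizes 3-9, 3-24 heavy atoms) are rejected and re-sampled, and uniqueness is
enforced by canonical-SMILES equality, so every emitted record is a valid,
unique molecule.

Property tables travel as plain CSV with columns
``id,smiles,gap_eV,ip_eV,ea_eV,eox_V,ered_V``; empty property cells mark
unlabeled molecules.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

PROPERTY_COLUMNS = ("gap_eV", "ip_eV", "ea_eV", "eox_V", "ered_V")
DATASET_COLUMNS = ("id", "smiles") + PROPERTY_COLUMNS

CONNECTION_MODES = ("fused", "bridged", "spiro", "linked")

#: ring sizes allowed to be generated as aromatic templates. 3-, 4- and
#: 9-membered aromatics are excluded as anti-aromatic/unstable; 7- and
#: 8-membered neutral rings are not Hückel-aromatic, so the aromatic pool
#: is restricted to 5 and 6.
AROMATIC_SIZES = (5, 6)

#: ring-capable heteroatoms by valence class (divalent like O, trivalent
#: like N, tetravalent like C).
_DIVALENT = {"O", "S", "Se"}
_TRIVALENT = {"N", "P", "B"}
_TETRAVALENT = {"C", "Si"}
_MONOVALENT = {"F", "I"}  # substituent-only


class GenerationError(RuntimeError):
    """Raised when the assembler cannot satisfy the requested configuration."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One generated or loaded molecule."""

    mol_id: str
    smiles: str
    ring_count: int
    heavy_atom_count: int
    elements: tuple[str, ...]

    @classmethod
    def from_smiles(cls, mol_id: str, smiles: str) -> "MoleculeRecord":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES for id {mol_id!r}: {smiles!r}")
        canonical = Chem.MolToSmiles(mol)
        elements = tuple(sorted(a.GetSymbol() for a in mol.GetAtoms()))
        return cls(
            mol_id=mol_id,
            smiles=canonical,
            ring_count=count_rings_mol(mol),
            heavy_atom_count=mol.GetNumHeavyAtoms(),
            elements=elements,
        )


@dataclass
class GeneratorConfig:
    """Knobs of the template assembler.

    Defaults emulate the structural envelope of a large cyclic-molecule
    library: ring-count mixture weighted toward polycyclics (the mono/bi/
    tricyclic proportions of the 201k-molecule reference composition),
    ring sizes 3-9 and a compact C/N/O/S palette.  The extended palette
    (B, F, Si, P, Se, I) is opt-in.
    """

    n_molecules: int
    seed: int = 0
    ring_count_weights: tuple[float, float, float] = (0.076, 0.396, 0.528)
    ring_size_range: tuple[int, int] = (3, 9)
    element_palette: tuple[str, ...] = ("C", "N", "O", "S")
    connection_weights: tuple[float, float, float, float] = (0.35, 0.15, 0.15, 0.35)
    heteroatom_rate: float = 0.15
    saturation_rate: float = 0.4
    max_attempts_per_molecule: int = 400

    def validate(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        for name, w in (
            ("ring_count_weights", self.ring_count_weights),
            ("connection_weights", self.connection_weights),
        ):
            if any(p < 0 for p in w) or not math.isclose(sum(w), 1.0, abs_tol=1e-8):
                raise ValueError(f"{name} must be nonnegative and sum to 1")
        lo, hi = self.ring_size_range
        if not (3 <= lo <= hi <= 9):
            raise ValueError("ring_size_range must lie within [3, 9]")
        if "C" not in self.element_palette:
            raise ValueError("element_palette must contain C")
        unknown = set(self.element_palette) - (
            _DIVALENT | _TRIVALENT | _TETRAVALENT | _MONOVALENT
        )
        if unknown:
            raise ValueError(f"unsupported palette elements: {sorted(unknown)}")
        if not (0.0 <= self.heteroatom_rate <= 1.0 and 0.0 <= self.saturation_rate <= 1.0):
            raise ValueError("rates must be probabilities")


# ---------------------------------------------------------------------------
# ring counting
# ---------------------------------------------------------------------------

def count_rings_mol(mol: Chem.Mol) -> int:
    """SSSR ring count of a parsed molecule (= cycle rank for these inputs)."""
    return len(Chem.GetSSSR(mol))


def count_rings(smiles: str) -> int:
    """SSSR ring count of a SMILES string; raises on parse failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return count_rings_mol(mol)


# ---------------------------------------------------------------------------
# template assembly
# ---------------------------------------------------------------------------

def _ring_heteroatoms(cfg: GeneratorConfig, kind: str) -> list[str]:
    """Palette members usable at a given ring position kind."""
    if kind == "donor":  # 2pi lone-pair donor of an aromatic 5-ring
        pool = [e for e in ("N", "O", "S", "Se", "P") if e in cfg.element_palette]
    elif kind == "aromatic6":
        pool = [e for e in ("N", "P") if e in cfg.element_palette]
    else:  # aliphatic position
        pool = [e for e in ("N", "O", "S", "Si", "P", "Se", "B") if e in cfg.element_palette]
    return pool


@dataclass
class _RingSpec:
    size: int
    aromatic: bool
    elements: list[str]          # per ring position
    donor_position: int | None   # aromatic 5-ring lone-pair donor


#: relative frequency of ring sizes, mirroring the dominance of 5- and
#: 6-membered rings in real ring-system libraries.
_RING_SIZE_WEIGHTS = {3: 0.05, 4: 0.05, 5: 0.28, 6: 0.42, 7: 0.10, 8: 0.05, 9: 0.05}


def _sample_ring_spec(rng: np.random.Generator, cfg: GeneratorConfig) -> _RingSpec:
    lo, hi = cfg.ring_size_range
    sizes = list(range(lo, hi + 1))
    w = np.array([_RING_SIZE_WEIGHTS[s] for s in sizes])
    size = int(rng.choice(sizes, p=w / w.sum()))
    aromatic = size in AROMATIC_SIZES and rng.random() >= cfg.saturation_rate
    elements = ["C"] * size
    donor = None
    if aromatic and size == 5:
        pool = _ring_heteroatoms(cfg, "donor")
        if not pool:
            aromatic = False
        else:
            donor = 0
            elements[0] = str(rng.choice(pool))
            for i in range(1, size):
                if rng.random() < cfg.heteroatom_rate and "N" in cfg.element_palette:
                    if elements[i - 1] == "C":  # no adjacent heteroatom pairs
                        elements[i] = "N"
    elif aromatic:
        pool = _ring_heteroatoms(cfg, "aromatic6")
        n_sub = 0
        for i in range(size):
            if pool and n_sub < 3 and rng.random() < cfg.heteroatom_rate:
                if elements[i - 1] == "C":
                    elements[i] = str(rng.choice(pool))
                    n_sub += 1
    if not aromatic:
        pool = _ring_heteroatoms(cfg, "aliphatic")
        for i in range(size):
            if pool and rng.random() < cfg.heteroatom_rate:
                if elements[i - 1] == "C" and (i + 1 >= size or elements[(i + 1) % size] == "C"):
                    elements[i] = str(rng.choice(pool))
    return _RingSpec(size=size, aromatic=aromatic, elements=elements, donor_position=donor)


def _new_atom(em: Chem.RWMol, symbol: str, aromatic: bool, n_hs: int | None = None) -> int:
    atom = Chem.Atom(symbol)
    atom.SetIsAromatic(aromatic)
    if n_hs is not None:
        atom.SetNumExplicitHs(n_hs)
    return em.AddAtom(atom)


def _bond(em: Chem.RWMol, i: int, j: int, aromatic: bool) -> None:
    em.AddBond(i, j, Chem.BondType.AROMATIC if aromatic else Chem.BondType.SINGLE)
    if aromatic:
        em.GetBondBetweenAtoms(i, j).SetIsAromatic(True)


def _donor_h_count(symbol: str) -> int:
    # pyrrole-type N-H keeps one hydrogen; O/S/Se donors carry none
    return 1 if symbol in _TRIVALENT else 0


def _add_isolated_ring(em: Chem.RWMol, spec: _RingSpec) -> list[int]:
    idx = []
    for pos, sym in enumerate(spec.elements):
        hs = _donor_h_count(sym) if spec.aromatic and pos == spec.donor_position else None
        idx.append(_new_atom(em, sym, spec.aromatic, hs))
    for a in range(spec.size):
        _bond(em, idx[a], idx[(a + 1) % spec.size], spec.aromatic)
    return idx


def _free_valence(em: Chem.RWMol, i: int) -> int:
    atom = em.GetAtomWithIdx(i)
    sym = atom.GetSymbol()
    if sym in _DIVALENT:
        cap = 2
    elif sym in _TRIVALENT:
        cap = 3
    else:
        cap = 3 if atom.GetIsAromatic() else 4
    return cap - atom.GetDegree() - atom.GetNumExplicitHs()


def _try_fused(em, rng, rings, spec) -> list[int] | None:
    """Share one existing bond; append size-2 new atoms closing the ring."""
    if spec.size < 3:
        return None
    candidates = []
    for ring in rings:
        for a in range(len(ring)):
            i, j = ring[a], ring[(a + 1) % len(ring)]
            if em.GetBondBetweenAtoms(i, j) is None:
                continue  # stored connection lists may be open paths
            if _free_valence(em, i) >= 1 and _free_valence(em, j) >= 1:
                oki = em.GetAtomWithIdx(i).GetSymbol() in _TETRAVALENT
                okj = em.GetAtomWithIdx(j).GetSymbol() in _TETRAVALENT
                if oki and okj:
                    candidates.append((i, j))
    if not candidates:
        return None
    i, j = candidates[rng.integers(len(candidates))]
    if spec.aromatic:
        for t in (i, j):
            em.GetAtomWithIdx(t).SetIsAromatic(True)
        em.GetBondBetweenAtoms(i, j).SetBondType(Chem.BondType.AROMATIC)
        em.GetBondBetweenAtoms(i, j).SetIsAromatic(True)
    new_idx = []
    for pos in range(spec.size - 2):
        sym = spec.elements[pos]
        hs = _donor_h_count(sym) if spec.aromatic and spec.donor_position == 0 and pos == 0 and sym not in _TETRAVALENT else None
        new_idx.append(_new_atom(em, sym, spec.aromatic, hs))
    chain = [i] + new_idx + [j]
    for a in range(len(chain) - 1):
        if em.GetBondBetweenAtoms(chain[a], chain[a + 1]) is None:
            _bond(em, chain[a], chain[a + 1], spec.aromatic)
    return [i] + new_idx + [j]


def _try_spiro(em, rng, rings, spec) -> list[int] | None:
    """Share one sp3 carbon between an existing ring and a new aliphatic ring."""
    if spec.aromatic:
        return None
    candidates = [
        i
        for ring in rings
        for i in ring
        if not em.GetAtomWithIdx(i).GetIsAromatic()
        and em.GetAtomWithIdx(i).GetSymbol() in _TETRAVALENT
        and _free_valence(em, i) >= 2
    ]
    if not candidates:
        return None
    centre = int(candidates[rng.integers(len(candidates))])
    new_idx = [_new_atom(em, sym, False) for sym in spec.elements[: spec.size - 1]]
    chain = [centre] + new_idx + [centre]
    for a in range(len(chain) - 1):
        _bond(em, chain[a], chain[a + 1], False)
    return [centre] + new_idx


def _try_bridged(em, rng, rings, spec) -> list[int] | None:
    """Bridge two non-adjacent atoms of an existing aliphatic ring."""
    options = []
    for ring in rings:
        s = len(ring)
        if s < 4 or any(em.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            continue
        for a in range(s):
            for d in range(2, s - 1):
                b_len = max(1, spec.size - 3)  # bridge atoms drawn from new spec
                r1 = d + b_len + 1
                r2 = (s - d) + b_len + 1
                if r1 <= 9 and r2 <= 9 and min(r1, r2) >= 3:
                    i, j = ring[a], ring[(a + d) % s]
                    if (
                        em.GetAtomWithIdx(i).GetSymbol() in _TETRAVALENT
                        and em.GetAtomWithIdx(j).GetSymbol() in _TETRAVALENT
                        and _free_valence(em, i) >= 1
                        and _free_valence(em, j) >= 1
                    ):
                        options.append((i, j, b_len))
    if not options:
        return None
    i, j, b_len = options[rng.integers(len(options))]
    bridge = [_new_atom(em, "C", False) for _ in range(b_len)]
    chain = [i] + bridge + [j]
    for a in range(len(chain) - 1):
        _bond(em, chain[a], chain[a + 1], False)
    return [i] + bridge + [j]


def _try_linked(em, rng, rings, spec) -> list[int] | None:
    """Join a freshly built ring to the molecule through one single bond."""
    anchors = [
        i
        for ring in rings
        for i in ring
        if em.GetAtomWithIdx(i).GetSymbol() in _TETRAVALENT and _free_valence(em, i) >= 1
    ]
    if not anchors:
        return None
    anchor = int(anchors[rng.integers(len(anchors))])
    idx = _add_isolated_ring(em, spec)
    carbons = [i for i, sym in zip(idx, spec.elements) if sym in _TETRAVALENT]
    if not carbons:
        return None
    _bond(em, anchor, int(carbons[rng.integers(len(carbons))]), False)
    return idx


_CONNECTORS = {
    "fused": _try_fused,
    "bridged": _try_bridged,
    "spiro": _try_spiro,
    "linked": _try_linked,
}


def _assemble_one(rng: np.random.Generator, cfg: GeneratorConfig) -> str | None:
    """One assembly attempt; returns canonical SMILES or None on rejection."""
    n_rings = 1 + int(rng.choice(3, p=np.asarray(cfg.ring_count_weights)))
    em = Chem.RWMol()
    rings: list[list[int]] = [_add_isolated_ring(em, _sample_ring_spec(rng, cfg))]
    for _ in range(n_rings - 1):
        spec = _sample_ring_spec(rng, cfg)
        mode = CONNECTION_MODES[int(rng.choice(4, p=np.asarray(cfg.connection_weights)))]
        added = None
        for fallback in (mode, "fused", "linked"):
            added = _CONNECTORS[fallback](em, rng, rings, spec)
            if added is not None:
                break
        if added is None:
            return None
        rings.append(added)
    # optional monovalent substituents from the extended palette
    halogens = [e for e in cfg.element_palette if e in _MONOVALENT]
    if halogens:
        sites = [
            i
            for i in range(em.GetNumAtoms())
            if em.GetAtomWithIdx(i).GetSymbol() == "C" and _free_valence(em, i) >= 1
        ]
        for i in sites:
            if rng.random() < cfg.heteroatom_rate / 2:
                h = _new_atom(em, str(rng.choice(halogens)), False)
                _bond(em, i, h, False)
    mol = em.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    if not (3 <= mol.GetNumHeavyAtoms() <= 24):
        return None
    if count_rings_mol(mol) != n_rings:
        return None
    info = mol.GetRingInfo()
    if any(not (3 <= len(r) <= 9) for r in info.AtomRings()):
        return None
    smiles = Chem.MolToSmiles(mol)
    # canonical SMILES must re-parse and re-canonicalize to itself
    reparsed = Chem.MolFromSmiles(smiles)
    if reparsed is None or Chem.MolToSmiles(reparsed) != smiles:
        return None
    return smiles


def generate_molecules(config: GeneratorConfig) -> list[MoleculeRecord]:
    """Generate ``config.n_molecules`` unique valid cyclic molecules.

    Deterministic given ``config.seed``.  Raises :class:`GenerationError`
    when the attempt budget is exhausted before reaching the requested
    count (over-constrained configuration).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    seen: set[str] = set()
    records: list[MoleculeRecord] = []
    budget = config.max_attempts_per_molecule * config.n_molecules
    attempts = 0
    while len(records) < config.n_molecules:
        if attempts >= budget:
            raise GenerationError(
                f"exhausted {budget} assembly attempts after "
                f"{len(records)}/{config.n_molecules} unique molecules; "
                "the generator configuration is over-constrained"
            )
        attempts += 1
        smiles = _assemble_one(rng, config)
        if smiles is None or smiles in seen:
            continue
        seen.add(smiles)
        records.append(MoleculeRecord.from_smiles(f"mol{len(records):06d}", smiles))
    return records


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

def write_dataset(
    records: list[MoleculeRecord],
    properties: pd.DataFrame | None,
    path,
) -> None:
    """Write records (and an optional property table aligned by row) as CSV."""
    df = pd.DataFrame(
        {"id": [r.mol_id for r in records], "smiles": [r.smiles for r in records]}
    )
    for col in PROPERTY_COLUMNS:
        if properties is not None and col in properties.columns:
            df[col] = np.asarray(properties[col], dtype=float)
        else:
            df[col] = np.nan
    df.to_csv(path, index=False, na_rep="")


def read_dataset(path) -> tuple[list[MoleculeRecord], pd.DataFrame]:
    """Load a dataset CSV.

    Returns the molecule records (row order preserved) and a property table
    with one row per record; NaN marks missing labels.  Raises ``ValueError``
    naming offending rows for missing columns, duplicate ids or unparseable
    SMILES.
    """
    df = pd.read_csv(path, dtype={"id": str, "smiles": str}, float_precision="round_trip")
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset {path} is missing required columns: {missing}")
    dup = df["id"][df["id"].duplicated()].unique().tolist()
    if dup:
        rows = [int(i) + 2 for i in df.index[df["id"].isin(dup)]]  # 1-based + header
        raise ValueError(f"duplicate ids {dup} at file rows {rows}")
    records: list[MoleculeRecord] = []
    bad_rows: list[int] = []
    for i, (mol_id, smi) in enumerate(zip(df["id"], df["smiles"])):
        try:
            records.append(MoleculeRecord.from_smiles(mol_id, smi))
        except ValueError:
            bad_rows.append(i + 2)
    if bad_rows:
        raise ValueError(f"unparseable SMILES at file rows {bad_rows}")
    props = df[list(PROPERTY_COLUMNS)].astype(float).reset_index(drop=True)
    props.insert(0, "id", df["id"].to_numpy())
    return records, props


@dataclass
class DatasetSummary:
    ring_count_composition: dict[int, int]
    element_counts: dict[str, int]
    heavy_atom_histogram: dict[int, int]
    n_records: int = field(default=0)


def dataset_summary(records: list[MoleculeRecord]) -> DatasetSummary:
    """Composition statistics: ring-count mix, element and size histograms."""
    if not records:
        raise ValueError("dataset_summary requires a non-empty record list")
    ring = Counter(r.ring_count for r in records)
    elem: Counter = Counter()
    for r in records:
        elem.update(r.elements)
    heavy = Counter(r.heavy_atom_count for r in records)
    return DatasetSummary(
        ring_count_composition=dict(sorted(ring.items())),
        element_counts=dict(sorted(elem.items())),
        heavy_atom_histogram=dict(sorted(heavy.items())),
        n_records=len(records),
    )
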