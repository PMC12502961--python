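"""Hückel molecular-orbital label oracle.

Synthetic but physically structured labels for the five electronic targets.
The π system of a molecule (aromatic plus conjugated sp2/sp atoms) is
extracted and its tight-binding Hamiltonian solved:

    H_ii = alpha + h_X * beta        H_ij = k_XY * beta  (π-bonded pairs)

with Coulomb integral ``alpha`` and resonance integral ``beta`` (< 0) in eV,
and the standard Streitwieser heteroatom corrections h_X / k_XY.  Frontier
orbitals give the HOMO-LUMO gap, and the Koopmans approximation gives
IP = -eps_HOMO, EA = -eps_LUMO.  Saturated molecules with no π system fall
back to a documented group-contribution scheme around ``sigma_default_gap``.

Redox labels are planted linear maps of IP and EA,

    E_ox  = ox_slope  * IP + ox_intercept  + N(0, noise_sd)
    E_red = red_slope * EA + red_intercept + N(0, noise_sd)

so the population slope and R² of the IP-E_ox / EA-E_red correlations are
known in closed form and recoverable by the downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .fixtures import MoleculeRecord

__all__ = [
    "HuckelParams",
    "PiSystem",
    "PropertyVector",
    "default_huckel_params",
    "extract_pi_system",
    "huckel_solve",
    "frontier_gap",
    "oracle_properties",
]


@dataclass(frozen=True)
class PropertyVector:
    """The five targets: gap/IP/EA in eV, redox potentials in V."""

    gap: float
    ip: float
    ea: float
    eox: float
    ered: float

    def as_array(self) -> np.ndarray:
        return np.array([self.gap, self.ip, self.ea, self.eox, self.ered])


@dataclass
class HuckelParams:
    """Oracle constants.

    ``h_table``/``k_table`` are keyed by (element, n_pi_contributed):
    e.g. ``("N", 1)`` is a pyridine-type nitrogen (one π electron via a
    double bond) and ``("N", 2)`` a pyrrole-type lone-pair donor.  Bond
    factors ``k_table`` are keyed by unordered element pairs; missing
    heteroatom-heteroatom pairs fall back to the product of their
    carbon-pair factors.
    """

    alpha: float = -6.6
    beta: float = -2.7
    h_table: dict[tuple[str, int], float] = field(
        default_factory=lambda: {
            ("C", 1): 0.0,
            ("N", 1): 0.5,
            ("N", 2): 1.5,
            ("O", 1): 1.0,
            ("O", 2): 2.0,
            ("S", 2): 1.3,
            ("Se", 2): 1.4,
            ("P", 1): 0.2,
            ("P", 2): 0.8,
            ("B", 1): -1.0,
        }
    )
    k_table: dict[frozenset, float] = field(
        default_factory=lambda: {
            frozenset({"C"}): 1.0,
            frozenset({"C", "N"}): 0.8,
            frozenset({"C", "O"}): 0.8,
            frozenset({"C", "S"}): 0.7,
            frozenset({"C", "Se"}): 0.6,
            frozenset({"C", "P"}): 0.7,
            frozenset({"C", "B"}): 0.7,
        }
    )
    sigma_default_gap: float = 11.0
    #: group contributions for saturated (π-free) molecules, per heteroatom
    sigma_gap_shift: dict[str, float] = field(
        default_factory=lambda: {"N": -0.5, "O": -0.7, "S": -1.2, "P": -0.9, "Se": -1.3, "Si": -0.4, "B": -0.3, "F": -0.2, "I": -0.8}
    )
    sigma_ip_base: float = 10.9
    sigma_ip_shift: dict[str, float] = field(
        default_factory=lambda: {"N": -0.30, "O": -0.20, "S": -0.80, "P": -0.60, "Se": -0.90, "Si": -0.25, "B": -0.15, "F": 0.10, "I": -0.70}
    )
    sigma_ip_per_heavy_atom: float = -0.04
    ox_slope: float = 0.92
    ox_intercept: float = -4.9
    red_slope: float = -0.95
    red_intercept: float = 1.1
    noise_sd: float = 0.15

    def validate(self) -> None:
        if self.beta >= 0:
            raise ValueError("beta must be negative")
        if self.sigma_default_gap <= 0:
            raise ValueError("sigma_default_gap must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def k_factor(self, sym_a: str, sym_b: str) -> float:
        key = frozenset({sym_a, sym_b})
        if key in self.k_table:
            return self.k_table[key]
        # heteroatom-heteroatom fallback: product of the carbon-pair factors
        try:
            ka = self.k_table[frozenset({"C", sym_a})]
            kb = self.k_table[frozenset({"C", sym_b})]
        except KeyError as exc:
            raise KeyError(
                f"no resonance factor for bond {sym_a}-{sym_b}: {exc}"
            ) from exc
        return ka * kb


def default_huckel_params() -> HuckelParams:
    return HuckelParams()


@dataclass
class PiSystem:
    """A molecule's conjugated subsystem.

    ``coeff_matrix`` M is the dimensionless Hamiltonian: the full matrix is
    H = alpha * I + beta * M with M_ii = h_X and M_ij = k_XY.  Disconnected
    conjugated fragments simply make M block-diagonal; electrons are filled
    globally over the union spectrum.
    """

    atom_indices: list[int]
    coeff_matrix: np.ndarray
    n_pi_electrons: int


def _pi_electron_contribution(atom: Chem.Atom) -> int | None:
    """π electrons contributed by one conjugated atom, or None if it does
    not participate.

    sp2/sp atoms in a multiple bond or aromatic ring contribute 1 (their
    p-orbital electron); heteroatoms conjugating through a lone pair
    (pyrrole-type N, furan-type O, thiophene-type S) contribute 2.
    """
    sym = atom.GetSymbol()
    in_multiple = any(
        b.GetBondType() in (Chem.BondType.DOUBLE, Chem.BondType.TRIPLE)
        for b in atom.GetBonds()
    )
    if atom.GetIsAromatic():
        if sym == "C" or sym == "Si":
            return 1
        if sym == "B":
            return 1
        # aromatic heteroatom: lone-pair donor iff it has an H (pyrrole NH)
        # or only single/aromatic bonds with 2 neighbours and a lone pair
        if sym in ("N", "P"):
            if atom.GetTotalNumHs() > 0 or atom.GetDegree() == 3:
                return 2  # pyrrole-type
            return 1  # pyridine-type
        if sym in ("O", "S", "Se"):
            return 2  # furan/thiophene-type
        return 1
    if in_multiple:
        return 1
    return None


def extract_pi_system(mol: Chem.Mol, params: HuckelParams | None = None) -> PiSystem | None:
    """Induced conjugated subgraph with its dimensionless Hamiltonian.

    Returns None when no atom qualifies (fully saturated molecule).  A
    non-aromatic heteroatom bonded only by single bonds joins the system as
    a 2-electron donor when adjacent to a conjugated atom (amide/enamine
    style conjugation).
    """
    params = params or default_huckel_params()
    contrib: dict[int, int] = {}
    for atom in mol.GetAtoms():
        c = _pi_electron_contribution(atom)
        if c is not None:
            contrib[atom.GetIdx()] = c
    # second pass: saturated lone-pair donors adjacent to the π system
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        if i in contrib or atom.GetSymbol() not in ("N", "O", "S", "P", "Se"):
            continue
        if any(n.GetIdx() in contrib for n in atom.GetNeighbors()):
            contrib[i] = 2
    if not contrib:
        return None
    atom_indices = sorted(contrib)
    pos = {a: i for i, a in enumerate(atom_indices)}
    n = len(atom_indices)
    m = np.zeros((n, n))
    for a in atom_indices:
        atom = mol.GetAtomWithIdx(a)
        key = (atom.GetSymbol(), contrib[a])
        if key not in params.h_table:
            raise KeyError(
                f"no Coulomb correction h for element {key[0]} contributing "
                f"{key[1]} pi electron(s)"
            )
        m[pos[a], pos[a]] = params.h_table[key]
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if a in contrib and b in contrib:
            k = params.k_factor(
                mol.GetAtomWithIdx(a).GetSymbol(), mol.GetAtomWithIdx(b).GetSymbol()
            )
            m[pos[a], pos[b]] = m[pos[b], pos[a]] = k
    n_el = sum(contrib.values())
    if n_el % 2 != 0:
        raise ValueError(
            f"odd pi-electron count {n_el}: open-shell systems are outside "
            "the oracle's closed-shell model"
        )
    return PiSystem(atom_indices=atom_indices, coeff_matrix=m, n_pi_electrons=n_el)


def huckel_solve(pi: PiSystem, params: HuckelParams | None = None) -> np.ndarray:
    """Orbital energies alpha + beta * eig(M) in eV, ascending."""
    params = params or default_huckel_params()
    params.validate()
    mu = np.linalg.eigvalsh(pi.coeff_matrix)
    return np.sort(params.alpha + params.beta * mu)


def frontier_gap(energies: np.ndarray, n_pi_electrons: int) -> tuple[float, float, float]:
    """(eps_HOMO, eps_LUMO, gap) from an ascending orbital-energy list.

    Electrons doubly occupy the lowest orbitals; the gap is clamped at zero
    against eigensolver round-off on degenerate frontier levels.
    """
    if n_pi_electrons <= 0 or n_pi_electrons % 2 != 0:
        raise ValueError("n_pi_electrons must be a positive even integer")
    n_occ = n_pi_electrons // 2
    if n_occ > len(energies):
        raise ValueError("more electron pairs than orbitals")
    if n_occ == len(energies):
        raise ValueError("fully occupied pi system has no LUMO")
    homo = float(energies[n_occ - 1])
    lumo = float(energies[n_occ])
    return homo, lumo, max(lumo - homo, 0.0)


def _sigma_properties(mol: Chem.Mol, params: HuckelParams) -> tuple[float, float, float]:
    """Group-contribution gap/IP/EA for molecules with no π system."""
    counts: dict[str, int] = {}
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
    gap = params.sigma_default_gap + sum(
        params.sigma_gap_shift.get(sym, 0.0) * n for sym, n in counts.items()
    )
    gap = max(gap, 5.0)
    ip = (
        params.sigma_ip_base
        + sum(params.sigma_ip_shift.get(sym, 0.0) * n for sym, n in counts.items())
        + params.sigma_ip_per_heavy_atom * mol.GetNumHeavyAtoms()
    )
    ea = ip - gap
    return gap, ip, ea


def oracle_properties(
    molecule: "Chem.Mol | MoleculeRecord | str",
    params: HuckelParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> PropertyVector:
    """Label one molecule with the five synthetic targets.

    Deterministic given the rng seed.  π molecules use the Hückel frontier
    orbitals with Koopmans IP/EA; saturated molecules use the σ-framework
    group contributions; redox potentials are the planted linear maps plus
    Gaussian noise of sd ``params.noise_sd``.
    """
    params = params or default_huckel_params()
    params.validate()
    if isinstance(molecule, MoleculeRecord):
        molecule = molecule.smiles
    if isinstance(molecule, str):
        mol = Chem.MolFromSmiles(molecule)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {molecule!r}")
    else:
        mol = molecule
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pi = extract_pi_system(mol, params)
    if pi is not None:
        energies = huckel_solve(pi, params)
        homo, lumo, gap = frontier_gap(energies, pi.n_pi_electrons)
        ip, ea = -homo, -lumo
    else:
        gap, ip, ea = _sigma_properties(mol, params)
    eox = params.ox_slope * ip + params.ox_intercept + rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else params.ox_slope * ip + params.ox_intercept
    ered = params.red_slope * ea + params.red_intercept + rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else params.red_slope * ea + params.red_intercept
    return PropertyVector(gap=float(gap), ip=float(ip), ea=float(ea), eox=float(eox), ered=float(ered))


def label_records(
    records: list[MoleculeRecord],
    params: HuckelParams | None = None,
    seed: int | None = 0,
) -> "np.ndarray":
    """Label a record list; returns an (n, 5) array ordered gap/ip/ea/eox/ered."""
    params = params or default_huckel_params()
    rng = np.random.default_rng(seed)
    return np.array([oracle_properties(r, params, rng).as_array() for r in records])
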