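"""Embedding-space and chemical-space analysis.

PCA of pooled molecular embeddings (mean-centering + SVD, deterministic
sign convention), per-axis property gradients, exemplar selection, property
histograms, and a circular-fingerprint / Tanimoto novelty analysis for
high-error molecules.

The fingerprint is a documented reproducible construction: the initial atom
invariant is (element, heavy degree, formal charge, H count, in-ring flag);
for radius iterations 1..r each atom identifier is re-hashed together with
the sorted (bond-order, neighbour-identifier) tuples, and all identifiers of
all radii are folded modulo ``n_bits``.  Bit values are internally
consistent but intentionally not aligned with any external toolkit.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy import stats

from .featurize import mol_from_smiles

__all__ = [
    "PCAResult",
    "Fingerprint",
    "pca_fit",
    "property_gradient",
    "select_exemplars",
    "morgan_fingerprint",
    "tanimoto",
    "max_similarity_to_set",
    "property_histograms",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    mean: np.ndarray                     # (D,)
    components: np.ndarray               # (k, D), orthonormal rows
    explained_variance_ratio: np.ndarray  # (k,), non-increasing, sums <= 1
    coords: np.ndarray                   # (M, k)


def pca_fit(x: np.ndarray, k: int) -> PCAResult:
    """Principal components by mean-centering and SVD.

    The sign of each component is fixed so its largest-magnitude loading is
    positive, making projections deterministic across runs and platforms.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need an (M >= 2, D) embedding matrix")
    m, d = x.shape
    if not 1 <= k <= min(m, d):
        raise ValueError(f"k={k} out of range for a {m}x{d} matrix")
    mean = x.mean(axis=0)
    xc = x - mean
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    components = vt[:k]
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(components[np.arange(k), np.argmax(np.abs(components), axis=1)])
    flip[flip == 0] = 1.0
    components = components * flip[:, None]
    var = s**2 / (m - 1)
    total = xc.var(axis=0, ddof=1).sum()
    ratio = var[:k] / total if total > 0 else np.zeros(k)
    return PCAResult(
        mean=mean,
        components=components,
        explained_variance_ratio=ratio,
        coords=xc @ components.T,
    )


def property_gradient(coords: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Pearson correlation of each principal axis with a property.

    Quantifies the colour-gradient structure of property-over-PCA plots.
    """
    coords = np.asarray(coords, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if coords.shape[0] != values.shape[0]:
        raise ValueError("coords and values must be aligned")
    if np.ptp(values) == 0:
        raise ValueError("zero variance property")
    return np.array(
        [stats.pearsonr(coords[:, j], values).statistic for j in range(coords.shape[1])]
    )


def select_exemplars(mol_ids, values) -> tuple[str, str, str]:
    """(highest, lowest, closest-to-mean) molecule ids for one property.

    All ties break to the lexicographically smallest id, so the output is
    invariant to input ordering.
    """
    ids = list(mol_ids)
    vals = np.asarray(values, dtype=np.float64)
    if len(ids) == 0 or len(ids) != vals.size:
        raise ValueError("need aligned, non-empty ids and values")
    highest = min(zip(ids, vals), key=lambda t: (-t[1], t[0]))[0]
    lowest = min(zip(ids, vals), key=lambda t: (t[1], t[0]))[0]
    mean = vals.mean()
    closest = min(zip(ids, vals), key=lambda t: (abs(t[1] - mean), t[0]))[0]
    return highest, lowest, closest


# ---------------------------------------------------------------------------
# circular fingerprints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fingerprint:
    bits: frozenset[int]
    n_bits: int = 2048
    radius: int = 3


def _hash_tuple(items: tuple) -> int:
    """Stable 64-bit hash of an int tuple (independent of process salt)."""
    data = b",".join(str(i).encode() for i in items)
    return int.from_bytes(hashlib.blake2b(data, digest_size=8).digest(), "big")


_BOND_ORDER_CODE = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: 4,
}


def morgan_fingerprint(molecule: "Chem.Mol | str", radius: int = 3, n_bits: int = 2048) -> Fingerprint:
    """Binary circular fingerprint by iterative neighbourhood hashing."""
    if radius < 0 or n_bits < 1:
        raise ValueError("radius must be >= 0 and n_bits >= 1")
    mol = mol_from_smiles(molecule) if isinstance(molecule, str) else molecule
    ids = {
        a.GetIdx(): _hash_tuple(
            (
                a.GetAtomicNum(),
                a.GetDegree(),
                a.GetFormalCharge(),
                a.GetTotalNumHs(),
                int(a.IsInRing()),
            )
        )
        for a in mol.GetAtoms()
    }
    seen = set(ids.values())
    for _ in range(radius):
        nxt = {}
        for a in mol.GetAtoms():
            i = a.GetIdx()
            env = sorted(
                (_BOND_ORDER_CODE.get(b.GetBondType(), 0), ids[b.GetOtherAtomIdx(i)])
                for b in a.GetBonds()
            )
            nxt[i] = _hash_tuple((ids[i],) + tuple(v for pair in env for v in pair))
        ids = nxt
        seen.update(ids.values())
    return Fingerprint(bits=frozenset(h % n_bits for h in seen), n_bits=n_bits, radius=radius)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A∩B| / |A∪B|; defined as 1.0 when both bit sets are empty."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint lengths differ: {a.n_bits} vs {b.n_bits}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


def max_similarity_to_set(
    query_id: str,
    query_fp: Fingerprint,
    references: "list[tuple[str, Fingerprint]]",
) -> tuple[float, str | None]:
    """Maximum Tanimoto similarity of a query against a reference set,
    excluding any reference with the query's own id."""
    if not references:
        raise ValueError("empty reference set")
    best, best_id = -1.0, None
    for ref_id, fp in references:
        if ref_id == query_id:
            continue
        t = tanimoto(query_fp, fp)
        if t > best:
            best, best_id = t, ref_id
    return best, best_id


# ---------------------------------------------------------------------------
# property histograms
# ---------------------------------------------------------------------------

def property_histograms(properties: pd.DataFrame, bins: int = 40) -> dict[str, dict]:
    """Per-property histogram with observed min/max.

    NaN cells (unlabeled molecules) are excluded per property; counts sum to
    the number of labeled molecules.
    """
    out: dict[str, dict] = {}
    for col in properties.columns:
        if col == "id":
            continue
        vals = properties[col].to_numpy(dtype=np.float64)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        counts, edges = np.histogram(vals, bins=bins)
        out[col] = dict(
            counts=counts,
            bin_edges=edges,
            min=float(vals.min()),
            max=float(vals.max()),
            n=int(vals.size),
        )
    if not out:
        raise ValueError("no labeled molecules in the property table")
    return out
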