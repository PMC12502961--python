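# Methods

`ringprop` is a desk-scale framework for predicting five electronic
properties of cyclic organic molecules — the HOMO–LUMO gap, vertical
ionization potential (IP), vertical electron affinity (EA), and the
one-electron oxidation/reduction potentials E_ox and E_red — from 2D
molecular graphs. This note records the models, the synthetic study
conditions, and the design choices that were genuinely open.

## Synthetic molecule generator

The generator (`ringprop.fixtures`) assembles mono-, bi- and tricyclic
molecules by template assembly rather than rejection sampling of whole
graphs: ring skeletons (size 3–9, aromatic or aliphatic) are drawn, joined
by a sampled connection mode — fused (shared edge), bridged (two
non-adjacent atoms joined through a new bridge path), spiro (one shared sp3
atom), or linked (single bond, the diaryl-like case) — and heteroatoms are
substituted with valence checking. Candidates that fail RDKit sanitization
or leave the structural envelope (SSSR ring count 1–3, ring sizes 3–9,
3–24 heavy atoms, palette elements only) are rejected and re-drawn;
uniqueness is enforced by canonical-SMILES equality. Generation is fully
deterministic given the seed.

Defaults and their rationale:

- **Ring-count weights (0.076, 0.396, 0.528)** — the mono/bi/tricyclic
  proportions of the large reference library of cyclic molecules the
  generator emulates. Note that for large requests the *realized*
  composition drifts toward polycyclics, because the space of small unique
  monocyclic templates saturates and duplicates are discarded.
- **Ring-size weighting** — sizes 5 and 6 dominate (0.28/0.42), mirroring
  real ring-system libraries; 3, 4 and 7–9 are rarer.
- **Aromatic pool restricted to 5- and 6-membered rings.** 3-, 4- and
  9-membered aromatics are excluded as anti-aromatic/unstable; 7- and
  8-membered *neutral* rings are not Hückel-aromatic (the aromatic tropylium
  and cyclooctatetraene dianion are charged species outside scope), so those
  sizes are generated aliphatic only.
- **Palette** — C/N/O/S by default, keeping the Hückel parameter table
  small and canonical; B, F, Si, P, Se, I are opt-in (F/I only as exocyclic
  substituents, being monovalent).
- **heteroatom_rate 0.15, saturation_rate 0.4** — produce roughly one
  heteroatom per ring system and an even split of π-active vs. saturated
  molecules, which is what the downstream learning tasks need (both label
  regimes well represented).

What the generator does *not* emulate: acyclic substituents and functional
groups (carbonyls, nitriles, sulfonyls), charged species, stereochemistry,
macrocycles, and the synthetic-accessibility profile of vendor catalogs.
Tests passing on these fixtures therefore validate the machinery —
featurization, attention layers, training dynamics, analyses — not
DFT-level chemistry on real screening libraries.

## Hückel label oracle

Labels come from a tight-binding π-electron model
(`ringprop.huckel`). The conjugated subsystem (aromatic atoms, atoms in
multiple bonds, and saturated N/O/S lone-pair donors adjacent to it) gets
the Hamiltonian H = αI + βM with M_ii = h_X and M_ij = k_XY for π-bonded
pairs; disconnected conjugated fragments make M block-diagonal and
electrons fill the union spectrum globally. Frontier orbitals give
gap = ε_LUMO − ε_HOMO and the Koopmans values IP = −ε_HOMO, EA = −ε_LUMO.

- **α = −6.6 eV, β = −2.7 eV** so benzene's Koopmans IP is the realistic
  9.3 eV and its gap 5.4 eV, keeping synthetic ranges comparable to
  published DFT-level distributions of cyclic molecules.
- **Heteroatom corrections** are the standard Streitwieser set:
  h_N(pyridine) = 0.5, h_N(pyrrole) = 1.5, h_O(carbonyl) = 1.0,
  h_O(furan) = 2.0, h_S(thiophene) = 1.3; k_C–N = 0.8, k_C–O = 0.8,
  k_C–S = 0.7. Heteroatom–heteroatom bond factors fall back to the product
  of the carbon-pair factors.
- **Saturated molecules** (no π system) use a documented group-contribution
  scheme: gap = 11.0 eV plus per-heteroatom shifts (N −0.5, O −0.7, S −1.2,
  floor 5 eV); IP = 10.9 eV plus per-heteroatom shifts and −0.04 eV per
  heavy atom; EA = IP − gap. The 11 eV σ-gap is the magnitude expected for
  saturated hydrocarbon frameworks.
- **Planted redox structure**: E_ox = 0.92·IP − 4.9 V and
  E_red = −0.95·EA + 1.1 V plus Gaussian noise of sd 0.15 V. The linear form
  mirrors the empirical near-linearity between orbital energies and redox
  potentials; the coefficients make the population R² of the IP–E_ox pair
  exceed 0.9 at the generator's IP variance (analytically
  R² = s²·Var(IP)/(s²·Var(IP)+σ²)), so correlation-recovery analyses have a
  known ground truth. Degenerate frontier levels are handled by the
  ascending-index convention; the gap is clamped at zero against
  eigensolver round-off.

The oracle is 2D-topological by design: no conformers, no solvation, no
claim that its magnitudes match DFT beyond qualitative range overlap.

## Graph featurization

Atoms are nodes, bonds are edges (both directions stored, identical
features). Node features: element one-hot with an unknown slot, heavy
degree one-hot 0–5 (clamped, covering hypervalent S/P), formal charge
one-hot {−1,0,+1}, aromaticity and in-ring flags, ring-size flags 3–9,
hybridization one-hot {sp, sp2, sp3, other}, attached-H count one-hot 0–4.
Edge features: bond-order one-hot {single, double, triple, aromatic},
conjugation flag, in-ring flag. The exact published feature tables for this
class of model are not fixed by the architecture, so the scheme is a
conventional reconstruction, versioned (`FeatureScheme.version`) behind one
interface so an alternative layout can be swapped in. Node order follows
RDKit's canonical ranking, making the graph independent of the input SMILES
spelling. Hydrogens are implicit; self-loops are *not* stored — they are
added inside the attention layer, keeping stored graphs purely chemical.

## Edge-aware graph attention network

Three message-passing layers; in each, the attention score of edge j→i is

    s_ij = LeakyReLU_0.2( a·[W h_i ‖ W h_j ‖ W_e e_ij] ),

i.e. the standard graph-attention score minimally extended with a
transformed bond feature. A per-receiver softmax over incoming edges plus a
self-loop (zero edge features) yields weights α_ij, and the update is
h′_i = ELU(Σ_j α_ij W h_j). Heads (4 by default, hidden width 128) are
concatenated in the hidden layers and averaged in the last one — the
conventional choice for final attention layers. Global mean pooling gives
the molecular embedding; three fully connected layers (128→64→5, ELU
between) emit the five property predictions. Softmax uses max-subtraction;
initialization is seeded uniform Glorot.

The network is written directly in NumPy on flat parameter vectors with
hand-derived backward passes; segment reductions over edges are compiled
into sparse incidence-matrix products. Compute precision follows the
parameter dtype: float32 for training, float64 for gradient checks (central
differences, relative error < 1e-4) and for the dense-reference
equivalence tests (a deliberately naive N×N-masked implementation kept in
the test suite).

## Training protocol

Multi-task mean squared error over the five z-scored targets (per-property
standardization on training statistics only; metrics always reported in
original units), equal task weights — the simplest defensible choice.
Optimizer: Adam, lr 1e-3, batch 64, up to 60 epochs with early stopping
(patience 15) on validation loss; the best-validation-epoch parameters are
returned. These sizes are desk-scale defaults: on a few thousand molecules
the model is converged well past the R² levels the analyses need, and every
run is a pure function of (data, config, seeds). Splits are exact-size
random disjoint subsets; learning curves use nested training subsets with
fixed validation/test sets and identical seeds per size.

## Redox computation

With per-molecule state energies in eV, the thermodynamic cycle reduces to
E_ox = [G_aq(+1) − G_aq(0)]/n − E_ref and
E_red = [G_aq(0) − G_aq(−1)]/n − E_ref with n = 1 and E_ref = 4.28 V (the
absolute potential of the standard hydrogen electrode); division by the
Faraday constant is then the identity map eV → V per electron, which
eliminates molar-unit bugs. Under this sign convention a more stable anion
gives a higher (less negative) E_red — i.e. larger E_red means stronger
electron acceptance. (The opposite reading, "more negative E_red = more
reducible", appears occasionally in the literature; this package uses the
standard convention throughout.) Vertical IP/EA are plain gas-phase energy
differences at the neutral geometry; hartree input converts at
27.211386 eV/hartree. Two substitution identities — E_ox = IP − E_ref and
E_red = EA − E_ref when aqueous differences equal gas-phase ones — pin the
signs and are enforced programmatically.

## Embedding-space analysis

PCA is mean-centering + SVD with a deterministic sign convention (largest
absolute loading positive). Property gradients over the projection are
per-axis Pearson correlations; exemplars (highest / lowest /
closest-to-mean per property) break all ties toward the smallest molecule
id, making selection order-independent.

The novelty analysis uses an in-package binary circular fingerprint:
initial atom invariant (element, degree, formal charge, H count, in-ring
flag), three iterations of sorted (bond-order, neighbour-id) re-hashing
with a stable 64-bit hash, all identifiers folded modulo 2048 bits, compared
by Tanimoto similarity (defined as 1 for two empty sets). Binary bits and
2048 width are the common default choice. The construction is documented
and reproducible but intentionally claims only internal consistency — bit
values will not match any external toolkit, although similarity *orderings*
track RDKit's Morgan fingerprints closely (checked in the tests).

## Known limitations

- Labels are Hückel/group-contribution synthetic values; absolute
  accuracies do not transfer to DFT-labeled data.
- Under the oracle, monocyclic molecules carry intrinsically
  lower-complexity labels (one ring term, few heteroatoms), so
  ring-stratified error profiles can differ qualitatively from those of
  DFT-labeled datasets even under training-set skew.
- The generator's duplicate rejection skews realized ring-count
  composition toward polycyclics at large n.
- Single-CPU NumPy training is practical to ~10⁴ molecules; beyond that an
  autodiff/GPU backend would be the right tool.
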