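"""PCA, exemplar selection, circular fingerprints, histograms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem
from rdkit.Chem import AllChem, DataStructs
from sklearn.decomposition import PCA as SKPCA

from ringprop import (
    Fingerprint,
    max_similarity_to_set,
    morgan_fingerprint,
    pca_fit,
    property_gradient,
    property_histograms,
    select_exemplars,
    tanimoto,
)
import pandas as pd


class TestPCA:
    def test_collinear_points_are_rank_one(self, rng):
        t = rng.normal(size=30)
        x = np.outer(t, [1.0, -2.0, 0.5]) + [3, 1, -2]
        res = pca_fit(x, 1)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_full_rank_ratios_sum_to_one(self, rng):
        x = rng.normal(size=(40, 6))
        res = pca_fit(x, 6)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-10)
        assert (np.diff(res.explained_variance_ratio) <= 1e-12).all()

    def test_components_orthonormal(self, rng):
        res = pca_fit(rng.normal(size=(50, 8)), 5)
        np.testing.assert_allclose(res.components @ res.components.T, np.eye(5), atol=1e-8)

    def test_matches_covariance_eigendecomposition_oracle(self, rng):
        """Eigenvalues and |projections| agree with an independent dense
        eigendecomposition of the covariance matrix (up to 100×20)."""
        for m, d, k in ((30, 8, 5), (100, 20, 10)):
            x = rng.normal(size=(m, d)) @ rng.normal(size=(d, d))
            res = pca_fit(x, k)
            cov = np.cov(x, rowvar=False)
            evals, evecs = np.linalg.eigh(cov)
            evals, evecs = evals[::-1], evecs[:, ::-1]
            np.testing.assert_allclose(
                res.explained_variance_ratio, evals[:k] / evals.sum(), atol=1e-8
            )
            ref_coords = (x - x.mean(axis=0)) @ evecs[:, :k]
            np.testing.assert_allclose(np.abs(res.coords), np.abs(ref_coords), atol=1e-7)

    def test_matches_sklearn_reconstruction(self, rng):
        x = rng.normal(size=(50, 8))
        res = pca_fit(x, 3)
        sk = SKPCA(n_components=3).fit(x)
        np.testing.assert_allclose(
            res.explained_variance_ratio, sk.explained_variance_ratio_, atol=1e-10
        )
        recon = res.mean + res.coords @ res.components
        sk_recon = sk.inverse_transform(sk.transform(x))
        np.testing.assert_allclose(recon, sk_recon, atol=1e-8)

    def test_sign_convention_is_deterministic(self, rng):
        x = rng.normal(size=(20, 5))
        res = pca_fit(x, 3)
        for comp in res.components:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_k_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_fit(rng.normal(size=(5, 3)), 4)


class TestPropertyGradient:
    def test_property_equal_to_axis_gives_unit_correlation(self, rng):
        coords = rng.normal(size=(40, 3))
        corr = property_gradient(coords, coords[:, 0])
        assert corr[0] == pytest.approx(1.0, abs=1e-12)
        corr = property_gradient(coords, -coords[:, 1])
        assert corr[1] == pytest.approx(-1.0, abs=1e-12)

    def test_independent_property_has_small_correlation(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(2000, 2))
        corr = property_gradient(coords, rng.normal(size=2000))
        assert np.abs(corr).max() < 0.08


class TestExemplars:
    def test_basic_ordering(self):
        hi, lo, mid = select_exemplars(["a", "b", "c"], [1.0, 2.0, 3.0])
        assert (hi, lo, mid) == ("c", "a", "b")

    def test_all_equal_ties_break_to_first_id(self):
        hi, lo, mid = select_exemplars(["z", "y", "x"], [2.0, 2.0, 2.0])
        assert (hi, lo, mid) == ("x", "x", "x")

    def test_equidistant_from_mean_ties_break_by_id(self):
        hi, lo, mid = select_exemplars(["a", "b"], [0.0, 10.0])
        assert mid == "a"

    def test_invariant_to_input_ordering(self, rng):
        ids = [f"m{i}" for i in range(20)]
        vals = rng.normal(size=20)
        ref = select_exemplars(ids, vals)
        perm = rng.permutation(20)
        assert select_exemplars([ids[i] for i in perm], vals[perm]) == ref


class TestFingerprints:
    def test_spelling_invariance(self):
        a = morgan_fingerprint("c1ccc2ccccc2c1")
        b = morgan_fingerprint("c1ccc2c(c1)cccc2")
        assert a == b

    def test_different_molecules_differ(self):
        assert morgan_fingerprint("c1ccccc1") != morgan_fingerprint("C1CCCCC1")

    def test_radius_zero_benzene_has_one_environment(self):
        fp = morgan_fingerprint("c1ccccc1", radius=0)
        assert len(fp.bits) == 1

    def test_similarity_ordering_tracks_rdkit_morgan(self, small_records):
        """Internal fingerprints need not match RDKit bit-for-bit, but the
        similarity ordering against a probe should broadly agree."""
        gen = AllChem.GetMorganGenerator(radius=3, fpSize=2048)
        probe = small_records[0]
        ours, rdk = [], []
        for rec in small_records[1:41]:
            ours.append(
                tanimoto(morgan_fingerprint(probe.smiles), morgan_fingerprint(rec.smiles))
            )
            rdk.append(
                DataStructs.TanimotoSimilarity(
                    gen.GetFingerprint(Chem.MolFromSmiles(probe.smiles)),
                    gen.GetFingerprint(Chem.MolFromSmiles(rec.smiles)),
                )
            )
        assert np.corrcoef(ours, rdk)[0, 1] > 0.7


class TestTanimoto:
    def test_self_similarity_is_one(self):
        fp = morgan_fingerprint("c1ccncc1")
        assert tanimoto(fp, fp) == 1.0

    def test_disjoint_sets_are_zero(self):
        a = Fingerprint(bits=frozenset({1, 2}), n_bits=16)
        b = Fingerprint(bits=frozenset({3, 4}), n_bits=16)
        assert tanimoto(a, b) == 0.0

    def test_set_arithmetic_example(self):
        a = Fingerprint(bits=frozenset({1, 2, 3}), n_bits=16)
        b = Fingerprint(bits=frozenset({2, 3, 4}), n_bits=16)
        assert tanimoto(a, b) == 0.5

    def test_both_empty_defined_as_one(self):
        e = Fingerprint(bits=frozenset(), n_bits=16)
        assert tanimoto(e, e) == 1.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="lengths"):
            tanimoto(Fingerprint(frozenset(), 16), Fingerprint(frozenset(), 32))

    @settings(derandomize=True, max_examples=60)
    @given(
        a=st.frozensets(st.integers(0, 63), max_size=40),
        b=st.frozensets(st.integers(0, 63), max_size=40),
    )
    def test_symmetric_bounded_and_identity_iff_equal(self, a, b):
        fa, fb = Fingerprint(a, 64), Fingerprint(b, 64)
        t = tanimoto(fa, fb)
        assert 0.0 <= t <= 1.0
        assert t == tanimoto(fb, fa)
        assert (t == 1.0) == (a == b)


class TestMaxSimilarity:
    def test_duplicate_structure_under_other_id_scores_one(self):
        refs = [("r1", morgan_fingerprint("c1ccccc1")), ("r2", morgan_fingerprint("C1CC1"))]
        best, best_id = max_similarity_to_set("q", morgan_fingerprint("c1ccccc1"), refs)
        assert best == 1.0 and best_id == "r1"

    def test_self_id_excluded(self):
        refs = [("q", morgan_fingerprint("c1ccccc1")), ("r", morgan_fingerprint("C1CC1"))]
        best, best_id = max_similarity_to_set("q", morgan_fingerprint("c1ccccc1"), refs)
        assert best_id == "r"
        assert best < 1.0


class TestHistograms:
    def test_single_molecule_mass_in_one_bin(self):
        df = pd.DataFrame({"id": ["a"], "gap_eV": [5.4]})
        h = property_histograms(df, bins=10)["gap_eV"]
        assert h["counts"].sum() == 1
        assert h["min"] == h["max"] == 5.4

    def test_counts_conserve_labeled_molecules(self, small_labels):
        df = pd.DataFrame(
            small_labels.copy(), columns=["gap_eV", "ip_eV", "ea_eV", "eox_V", "ered_V"]
        )
        df.loc[:9, "ip_eV"] = np.nan
        hists = property_histograms(df)
        assert hists["gap_eV"]["counts"].sum() == len(df)
        assert hists["ip_eV"]["counts"].sum() == len(df) - 10

    def test_extremes_are_exact(self, small_labels):
        df = pd.DataFrame({"gap_eV": small_labels[:, 0]})
        h = property_histograms(df)["gap_eV"]
        assert h["min"] == small_labels[:, 0].min()
        assert h["max"] == small_labels[:, 0].max()
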