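"""Lipid-protein integration: normalization, cosine geometry, clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from desilipid import cosine_distance_matrix, hierarchical_cluster, normalize_modalities
from desilipid.errors import ValidationError


def _frames(rng, n_pat=8, n_lip=5, n_prot=6):
    pats = [f"p{i}" for i in range(n_pat)]
    L = pd.DataFrame(rng.uniform(1, 10, (n_pat, n_lip)), index=pats,
                     columns=[f"l{i}" for i in range(n_lip)])
    P = pd.DataFrame(rng.uniform(0.1, 3, (n_pat, n_prot)), index=pats,
                     columns=[f"pr{i}" for i in range(n_prot)])
    return L, P


class TestNormalization:
    def test_lipid_rows_sum_to_one_and_protein_max_is_one(self, rng):
        L, P = _frames(rng)
        Ln, Pn = normalize_modalities(L, P)
        np.testing.assert_allclose(Ln.sum(axis=1), 1.0)
        np.testing.assert_allclose(Pn.max(axis=0), 1.0)

    def test_scaling_a_patient_row_is_invisible(self, rng):
        L, P = _frames(rng)
        L2 = L.copy()
        L2.iloc[3] *= 5.0
        Ln, _ = normalize_modalities(L, P)
        Ln2, _ = normalize_modalities(L2, P)
        np.testing.assert_allclose(Ln.iloc[3], Ln2.iloc[3])

    def test_zero_total_names_patient(self, rng):
        L, P = _frames(rng)
        L.iloc[2] = 0.0
        with pytest.raises(ValidationError, match="p2"):
            normalize_modalities(L, P)


class TestCosine:
    def test_zero_diagonal_symmetry_and_range(self, rng):
        L, P = _frames(rng)
        res = cosine_distance_matrix(L, P)
        D = res.distance_matrix
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0.0)
        assert np.all(D >= -1e-12) and np.all(D <= 2.0 + 1e-12)
        assert res.modality == ["lipid"] * 5 + ["protein"] * 6

    def test_scaled_vector_has_zero_distance(self):
        pats = list("abcd")
        L = pd.DataFrame({"u": [1, 2, 3, 4], "v": [3, 6, 9, 12]}, index=pats, dtype=float)
        P = pd.DataFrame({"w": [1, 1, 1, 1]}, index=pats, dtype=float)
        res = cosine_distance_matrix(L, P, normalize=False)
        assert res.distance_matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_indicators_have_distance_one(self):
        pats = list("abcd")
        L = pd.DataFrame({"u": [1, 0, 0, 0], "v": [0, 1, 0, 0]}, index=pats, dtype=float)
        P = pd.DataFrame({"w": [0, 0, 1, 0]}, index=pats, dtype=float)
        res = cosine_distance_matrix(L, P, normalize=False)
        assert res.distance_matrix[0, 1] == pytest.approx(1.0)
        assert res.distance_matrix[0, 2] == pytest.approx(1.0)

    def test_patient_order_invariance(self, rng):
        L, P = _frames(rng)
        res1 = cosine_distance_matrix(L, P)
        perm = rng.permutation(len(L))
        res2 = cosine_distance_matrix(L.iloc[perm], P.iloc[perm])
        np.testing.assert_allclose(res1.distance_matrix, res2.distance_matrix)

    def test_zero_norm_species_is_named(self, rng):
        L, P = _frames(rng)
        P["pr3"] = 0.0
        with pytest.raises(ValidationError, match="pr3"):
            cosine_distance_matrix(L, P, normalize=False)


class TestClustering:
    def test_identical_species_merge_first_at_zero(self):
        D = np.array([
            [0.0, 0.0, 0.9, 0.8],
            [0.0, 0.0, 0.9, 0.8],
            [0.9, 0.9, 0.0, 0.7],
            [0.8, 0.8, 0.7, 0.0],
        ])
        Z, _order, _nwk = hierarchical_cluster(D)
        assert set(Z[0, :2].astype(int)) == {0, 1}
        assert Z[0, 2] == pytest.approx(0.0)

    def test_single_species_tree(self):
        Z, order, nwk = hierarchical_cluster(np.zeros((1, 1)), ["only"])
        assert order == [0] and nwk == "only;"

    def test_two_tight_pairs_merge_first(self):
        """Brute-force checkable 4-point metric: {a,b} and {c,d} are tight."""
        D = np.full((4, 4), 1.0)
        np.fill_diagonal(D, 0.0)
        D[0, 1] = D[1, 0] = 0.1
        D[2, 3] = D[3, 2] = 0.2
        for linkage in ("average", "complete", "centroid"):
            Z, _o, _n = hierarchical_cluster(D, linkage=linkage)
            first_two = {frozenset(Z[0, :2].astype(int)), frozenset(Z[1, :2].astype(int))}
            assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    def test_monotone_merge_heights(self, rng):
        X = rng.normal(size=(10, 4))
        D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        for linkage in ("average", "complete"):
            Z, _o, _n = hierarchical_cluster(D, linkage=linkage)
            assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_newick_contains_all_leaves(self, rng):
        L, P = _frames(rng, n_lip=3, n_prot=3)
        res = cosine_distance_matrix(L, P)
        _Z, order, nwk = hierarchical_cluster(res.distance_matrix, res.species_names)
        assert nwk.endswith(";")
        for name in res.species_names:
            assert name in nwk
        assert sorted(order) == list(range(6))

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValidationError, match="symmetric"):
            hierarchical_cluster(D)


def test_linked_protein_is_most_similar_to_its_lipid():
    """A protein generated with correlation 0.9 to the lipid at m/z 699.50
    is closer to it in cosine similarity than any exchangeable protein is
    to any planted lipid.  Needs a cohort-sized patient set: with a
    handful of patients a null protein can reach such correlations by
    chance."""
    from desilipid import SyntheticConfig, generate_cohort, generate_protein_table
    from desilipid.pipeline import build_patient_matrix
    from tests.conftest import PLANTED_MZ

    cfg = SyntheticConfig(n_cancer=40, n_benign=24, image_shape=(8, 8),
                          n_background_peaks=15, n_proteins=40,
                          n_differential_proteins=12, seed=17)
    imgs, masks, metas = generate_cohort(cfg)
    matrix = build_patient_matrix(imgs, masks)
    lipid_df = pd.DataFrame(
        matrix.intensities, index=matrix.sample_ids,
        columns=[f"{mz:.4f}" for mz in matrix.consensus_mz],
    )
    prot = generate_protein_table(cfg, metas, lipid_profiles=lipid_df)
    lip_cols = [c for c in lipid_df.columns
                if any(abs(float(c) - p) < 0.01 for p in PLANTED_MZ)]
    # exchangeable, unlinked proteins as the uncorrelated comparison set
    null_prots = [f"protein_{j:03d}" for j in
                  range(cfg.n_differential_proteins + 1, cfg.n_proteins + 1)]
    res = cosine_distance_matrix(lipid_df[lip_cols], prot[["protein_001"] + null_prots],
                                 lipids=lip_cols, proteins=["protein_001"] + null_prots)
    names = res.species_names
    i = next(k for k, nm in enumerate(names) if abs(float(nm) - 699.5014) < 0.01)
    j = names.index("protein_001")
    linked = res.similarity_matrix[i, j]
    others = [
        res.similarity_matrix[a, b]
        for a, b in itertools.product(range(len(lip_cols)), range(len(lip_cols), len(names)))
        if names[b] != "protein_001"
    ]
    assert linked > max(others)
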