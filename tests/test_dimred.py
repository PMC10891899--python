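"""PCA / Folded PCA / WaLuMI: eigen oracles, MI identities, Ward linkage."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from hsvein import (
    FoldedPCA,
    Hypercube,
    SpectralPCA,
    WaLuMIBandSelector,
    mi_matrix,
    reduce_cube,
    walumi_select,
    ward_linkage,
)
from hsvein.dimred import cut_tree, fit_fpca, fit_pca, load_model, mi_to_distance, save_model

from oracles import exhaustive_ward as _exhaustive_ward, random_distance_matrix


class TestSpectralPCA:
    def test_constant_matrix_zero_variance(self):
        X = np.full((10, 4), 3.0)
        m = SpectralPCA().fit(X)
        assert np.allclose(m.eigenvalues_, 0.0)
        assert np.allclose(m.transform(X), 0.0)

    def test_hand_2x2_eigen_oracle(self):
        """Covariance of [[1,-1],[-1,1]] is [[2,-2],[-2,2]] with spectrum (4, 0)."""
        X = np.array([[1.0, -1.0], [-1.0, 1.0]])
        m = SpectralPCA().fit(X)
        assert np.allclose(m.eigenvalues_, [4.0, 0.0], atol=1e-12)

    def test_matches_svd_oracle(self, rng):
        X = rng.normal(size=(50, 8))
        m = SpectralPCA().fit(X)
        Xc = X - X.mean(axis=0)
        s = np.linalg.svd(Xc, compute_uv=False)
        assert np.allclose(m.eigenvalues_, s**2 / (50 - 1), atol=1e-9)
        # orthonormal components
        assert np.allclose(m.components_ @ m.components_.T, np.eye(8), atol=1e-9)

    def test_centering_means_project_to_zero(self, rng):
        X = rng.normal(size=(30, 5))
        m = SpectralPCA(n_components=3).fit(X)
        assert np.allclose(m.transform(np.tile(m.mean_, (4, 1))), 0.0, atol=1e-12)

    def test_full_rank_reconstruction(self, rng):
        X = rng.normal(size=(20, 6))
        m = SpectralPCA().fit(X)
        assert np.allclose(m.inverse_transform(m.transform(X)), X, atol=1e-8)

    def test_projection_variance_equals_eigenvalue(self, rng):
        X = rng.normal(size=(200, 6))
        m = SpectralPCA().fit(X)
        Y = m.transform(X)
        assert np.allclose(Y.var(axis=0, ddof=1), m.eigenvalues_, atol=1e-8)

    def test_trace_conservation(self, rng):
        X = rng.normal(size=(100, 12))
        m = SpectralPCA().fit(X)
        assert m.eigenvalues_.sum() == pytest.approx(X.var(axis=0, ddof=1).sum(), abs=1e-8)

    def test_k_out_of_range(self, rng):
        with pytest.raises(ValueError):
            SpectralPCA(n_components=9).fit(rng.normal(size=(10, 4)))

    def test_too_few_pixels(self):
        with pytest.raises(ValueError):
            SpectralPCA().fit(np.ones((1, 4)))


class TestFoldedPCA:
    def test_h1_reduces_to_pca(self, rng):
        X = rng.normal(size=(200, 32))
        p = SpectralPCA().fit(X)
        f = FoldedPCA(fold_height=1).fit(X)
        assert np.allclose(p.eigenvalues_, f.eigenvalues_, atol=1e-9)
        Yp, Yf = p.transform(X), f.transform(X)
        signs = np.sign(np.sum(Yp * Yf, axis=0))
        signs[signs == 0] = 1.0
        assert np.allclose(Yp, Yf * signs, atol=1e-8)

    def test_partial_covariance_matches_double_loop_oracle(self, rng):
        X = rng.normal(size=(10, 6))
        H, W = 2, 3
        m = FoldedPCA(fold_height=H, fold_width=W).fit(X)
        Xc = X - X.mean(axis=0)
        Cp = np.zeros((W, W))
        for i in range(10):
            A = Xc[i].reshape(H, W)
            Cp += A.T @ A
        Cp /= 10 * H - 1
        assert np.allclose(np.sort(np.linalg.eigvalsh(Cp))[::-1], m.eigenvalues_, atol=1e-12)

    def test_constant_matrix_zero_variance(self):
        m = FoldedPCA(fold_height=2, fold_width=3).fit(np.full((8, 6), 2.0))
        assert np.allclose(m.eigenvalues_, 0.0)

    def test_full_feature_count_preserves_norm(self, rng):
        """With k = H*W the flattening is orthogonal, so norms are conserved."""
        X = rng.normal(size=(20, 8))
        m = FoldedPCA(fold_height=2, fold_width=4).fit(X)
        Y = m.transform(X)
        A = m._fold(X - m.mean_)
        assert np.allclose(
            np.linalg.norm(Y, axis=1), np.linalg.norm(A.reshape(20, -1), axis=1), atol=1e-8
        )

    def test_eigenvector_major_truncation_index_arithmetic(self, rng):
        """The 151x3 fold at k=310 yields components 1-2 whole plus 8 rows of 3."""
        F = 462
        X = rng.normal(size=(40, F))
        m = FoldedPCA(n_components=310, fold_height=151, fold_width=3).fit(X)
        Y = m.transform(X)
        assert Y.shape == (40, 310)
        A = m._fold(X - m.mean_)  # (40, 151, 3)
        full = (A @ m.eigenvectors_).transpose(0, 2, 1).reshape(40, -1)
        assert np.array_equal(Y, full[:, :310])
        # feature 302 is the first value of the third component
        third = (A @ m.eigenvectors_[:, 2])[:, 0]
        assert np.allclose(Y[:, 302], third, atol=1e-12)

    def test_padding_when_fold_exceeds_bands(self, rng):
        X = rng.normal(size=(15, 5))
        m = FoldedPCA(fold_height=2, fold_width=3).fit(X)  # 6 > 5, zero-pad
        assert m.transform(X).shape == (15, 6)

    def test_truncation_warns(self, rng, caplog):
        import logging

        X = rng.normal(size=(15, 7))
        with caplog.at_level(logging.WARNING, logger="hsvein.dimred"):
            FoldedPCA(fold_height=2, fold_width=3).fit(X)  # 6 < 7
        assert any("dropped" in r.message for r in caplog.records)


class TestMutualInformation:
    def test_diagonal_is_entropy(self, rng):
        X = rng.normal(size=(300, 5))
        m = mi_matrix(X, bins=8)
        assert np.allclose(np.diag(m.mi), m.entropies, atol=1e-9)

    def test_symmetry_exact(self, rng):
        m = mi_matrix(rng.normal(size=(200, 6)), bins=8)
        assert np.array_equal(m.mi, m.mi.T)

    def test_duplicate_band_attains_entropy(self, rng):
        x = rng.normal(size=(500, 1))
        X = np.hstack([x, x.copy(), rng.normal(size=(500, 1))])
        m = mi_matrix(X, bins=8)
        assert m.mi[0, 1] == pytest.approx(m.entropies[0], abs=1e-9)

    def test_independent_bands_near_zero(self):
        rng = np.random.default_rng(99)
        X = rng.random((10_000, 2))
        m = mi_matrix(X, bins=8)
        assert m.mi[0, 1] < 0.05

    def test_mi_bounded_by_min_entropy(self, rng):
        m = mi_matrix(rng.normal(size=(300, 6)), bins=8)
        for i in range(6):
            for j in range(6):
                assert m.mi[i, j] <= min(m.entropies[i], m.entropies[j]) + 1e-9

    def test_constant_band_zero_everything(self, rng):
        X = np.hstack([np.full((100, 1), 2.0), rng.normal(size=(100, 2))])
        m = mi_matrix(X, bins=8)
        assert m.entropies[0] == 0.0
        assert np.allclose(m.mi[0, :], 0.0)


class TestWardLinkage:
    def test_two_leaves_base_case(self):
        tree = ward_linkage(np.array([[0.0, 3.0], [3.0, 0.0]]))
        (a, b, h, s) = tree.merges[0]
        assert (a, b, s) == (0, 1, 2) and h == pytest.approx(3.0)

    def test_three_leaf_first_merge(self):
        D = np.array([[0.0, 1.0, 10.0], [1.0, 0.0, 1.0], [10.0, 1.0, 0.0]])
        tree = ward_linkage(D)
        assert set(tree.merges[0][:2]) == {0, 1}  # tie (0,1) vs (1,2) -> lowest pair

    @pytest.mark.parametrize("n", [3, 4])
    def test_matches_exhaustive_enumeration(self, rng, n):
        for _ in range(10):
            D = random_distance_matrix(rng, n)
            ours = ward_linkage(D).merges
            oracle = _exhaustive_ward(D)
            for (a, b, h, s), (oa, ob, oh, osz) in zip(ours, oracle):
                assert {a, b} == {oa, ob} and s == osz
                assert h == pytest.approx(oh, abs=1e-10)

    def test_matches_scipy_on_random_instances(self, rng):
        for n in (5, 8, 12):
            D = random_distance_matrix(rng, n)
            ours = ward_linkage(D).to_scipy()
            ref = scipy_linkage(squareform(D, checks=False), method="ward")
            assert np.allclose(ours, ref, atol=1e-8)

    def test_heights_monotone(self, rng):
        for _ in range(20):
            D = random_distance_matrix(rng, 10)
            h = [m[2] for m in ward_linkage(D).merges]
            assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(h, h[1:]))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ward_linkage(np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric
        with pytest.raises(ValueError):
            ward_linkage(np.array([[0.0, -1.0], [-1.0, 0.0]]))  # negative


class TestWaLuMI:
    def test_k_equals_f_selects_everything(self, rng):
        X = rng.normal(size=(100, 5))
        sel = walumi_select(X, 5, bins=8)
        assert sel.indices == (0, 1, 2, 3, 4)

    def test_duplicate_pairs_one_per_cluster(self, rng):
        for _ in range(10):
            base = rng.normal(size=(400, 2))
            X = np.hstack([base[:, [0]], base[:, [0]], base[:, [1]], base[:, [1]]])
            sel = walumi_select(X, 2, bins=8)
            assert len(set(sel.indices) & {0, 1}) == 1
            assert len(set(sel.indices) & {2, 3}) == 1

    def test_distance_matrix_properties(self, rng):
        m = mi_matrix(rng.normal(size=(300, 6)), bins=8)
        D = mi_to_distance(m)
        assert np.array_equal(D, D.T)
        assert np.all((D >= 0) & (D <= 1))
        assert np.allclose(np.diag(D), 0.0)

    def test_selection_contract_at_scale(self, rng):
        X = rng.normal(size=(150, 60))
        sel = walumi_select(X, 40, bins=8)
        assert len(sel.indices) == 40
        assert all(a < b for a, b in zip(sel.indices, sel.indices[1:]))
        # one selected band per cluster
        labels = sel.cluster_assignments
        assert sorted(labels[list(sel.indices)]) == list(range(40))

    def test_cut_tree_sizes(self, rng):
        D = random_distance_matrix(rng, 9)
        tree = ward_linkage(D)
        for k in (1, 3, 9):
            labels = cut_tree(tree, k)
            assert len(np.unique(labels)) == k


class TestReduceCube:
    def test_band_subset_identity(self, rng):
        data = rng.random((4, 4, 3))
        cube = Hypercube(data)
        sel = WaLuMIBandSelector(n_bands=2, bins=4)
        sel.fit(data.reshape(-1, 3))
        sel.selected_bands_ = np.array([0, 2])  # force a known subset
        out = reduce_cube(cube, sel)
        assert np.array_equal(out.data, data[:, :, [0, 2]])

    def test_full_rank_pca_round_trip(self, rng):
        data = rng.random((5, 6, 4))
        cube = Hypercube(data)
        m = SpectralPCA().fit(data.reshape(-1, 4))
        red = reduce_cube(cube, m)
        back = m.inverse_transform(red.pixels()).reshape(5, 6, 4)
        assert np.allclose(back, data, atol=1e-6)

    def test_matches_per_pixel_loop_oracle(self, rng):
        data = rng.random((4, 4, 6))
        cube = Hypercube(data)
        m = SpectralPCA(n_components=3).fit(data.reshape(-1, 6))
        red = reduce_cube(cube, m)
        for r in range(4):
            for c in range(4):
                expect = m.transform(data[r, c][None, :])[0]
                assert np.allclose(red.data[r, c], expect, atol=1e-12)

    def test_band_count_mismatch_rejected(self, rng):
        m = SpectralPCA(n_components=2).fit(rng.random((10, 5)))
        with pytest.raises(ValueError):
            reduce_cube(Hypercube(rng.random((3, 3, 4))), m)


class TestModelPersistence:
    @pytest.mark.parametrize("factory", [
        lambda X: fit_pca(X, 3),
        lambda X: fit_fpca(X, 2, 3, 4),
        lambda X: WaLuMIBandSelector(n_bands=3, bins=8).fit(X),
    ])
    def test_round_trip_preserves_transform(self, rng, tmp_path, factory):
        X = rng.normal(size=(60, 6))
        model = factory(X)
        save_model(model, tmp_path / "m.json")
        loaded = load_model(tmp_path / "m.json")
        assert np.allclose(model.transform(X), loaded.transform(X), atol=1e-12)
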