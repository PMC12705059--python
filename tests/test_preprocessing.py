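import numpy as np
import pytest

from comorbmtl import (TaskCollection, TaskData, apply_pca, apply_standardizer,
                       fit_pca, fit_standardizer, reconstruct_signature)
from comorbmtl.mtl_core import CoefficientMatrix
from comorbmtl.preprocessing import signature_to_nifti, signature_to_table


class TestStandardizer:
    def test_training_set_becomes_zero_mean_unit_sd(self, rng):
        X = rng.standard_normal((40, 5)) * 3 + 1
        s = fit_standardizer(X)
        Z = apply_standardizer(s, X)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1, atol=1e-10)

    def test_holdout_row_at_training_mean_maps_to_zero(self, rng):
        X = rng.standard_normal((20, 3))
        s = fit_standardizer(X)
        row = apply_standardizer(s, X.mean(axis=0, keepdims=True))
        np.testing.assert_allclose(row, 0, atol=1e-12)

    def test_sample_sd_convention(self):
        s = fit_standardizer(np.array([[1.0], [3.0]]))
        out = apply_standardizer(s, np.array([[5.0]]))
        assert out[0, 0] == pytest.approx((5 - 2) / np.sqrt(2))

    def test_zero_variance_column_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            fit_standardizer(np.array([[1.0, 2.0], [1.0, 3.0]]))

    def test_no_leakage_transform_invariant_to_holdout_permutation(self, rng):
        train = rng.standard_normal((30, 4))
        hold = rng.standard_normal((10, 4))
        s = fit_standardizer(train)
        perm = rng.permutation(10)
        out_full = apply_standardizer(s, hold)
        out_perm = apply_standardizer(s, hold[perm])
        np.testing.assert_array_equal(out_full[perm], out_perm)


class TestPca:
    def test_rank_one_data_has_one_nonzero_variance(self, rng):
        u = rng.standard_normal((15, 1))
        v = rng.standard_normal((1, 6))
        pca = fit_pca(u @ v)
        assert pca.explained_variance[0] > 1e-10
        assert np.all(pca.explained_variance[1:] < 1e-20)

    def test_loadings_orthonormal_and_scores_uncorrelated(self, rng):
        X = rng.standard_normal((25, 6))
        pca = fit_pca(X)
        np.testing.assert_allclose(pca.loadings.T @ pca.loadings,
                                   np.eye(pca.k), atol=1e-8)
        scores = apply_pca(pca, X)
        cov = np.cov(scores, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8

    def test_first_loading_matches_eigendecomposition_oracle(self):
        X = np.array([[2.0, 0.0], [0.0, 1.0], [-2.0, -1.0]])
        pca = fit_pca(X)
        C = np.cov(X - X.mean(axis=0), rowvar=False)
        evals, evecs = np.linalg.eigh(C)
        lead = evecs[:, np.argmax(evals)]
        dot = abs(float(lead @ pca.loadings[:, 0]))
        assert dot == pytest.approx(1.0, abs=1e-10)

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.decomposition import PCA

        X = rng.standard_normal((30, 5))
        ours = fit_pca(X, k=4)
        ref = PCA(n_components=4).fit(X)
        # compare up to sign
        for j in range(4):
            dot = abs(float(ref.components_[j] @ ours.loadings[:, j]))
            assert dot == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(ours.explained_variance,
                                   ref.explained_variance_, rtol=1e-8)

    def test_full_rank_round_trip(self, rng):
        X = rng.standard_normal((12, 5))
        pca = fit_pca(X)
        scores = apply_pca(pca, X)
        back = scores @ pca.loadings.T + pca.component_means
        np.testing.assert_allclose(back, X, atol=1e-8)

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pca(rng.standard_normal((5, 3)), k=5)


class TestSignature:
    def make_pca(self, rng, p=8, n=20, k=4):
        X = rng.standard_normal((n, p))
        std = fit_standardizer(X)
        return std, fit_pca(apply_standardizer(std, X), k=k)

    def test_single_selected_pc_gives_perfectly_correlated_task_maps(self, rng):
        std, pca = self.make_pca(rng)
        W = np.zeros((4, 2))
        W[1] = [0.9, -0.4]  # exactly one PC selected
        sig = reconstruct_signature(CoefficientMatrix(W, 0.3), pca, std)
        r = np.corrcoef(sig.voxel_weights[:, 0], sig.voxel_weights[:, 1])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-12)

    def test_zero_model_gives_zero_signature(self, rng):
        std, pca = self.make_pca(rng)
        sig = reconstruct_signature(CoefficientMatrix(np.zeros((4, 2)), 0.3), pca, std)
        assert np.all(sig.voxel_weights == 0)

    def test_identity_loadings_return_weights_unchanged(self, rng):
        from comorbmtl.preprocessing import PcaTransform

        W = rng.standard_normal((3, 2))
        pca = PcaTransform(np.eye(3), np.zeros(3), 3, np.ones(3))
        sig = reconstruct_signature(CoefficientMatrix(W, 0.1), pca)
        np.testing.assert_array_equal(sig.voxel_weights, W)

    def test_reconstruction_linear_in_weights(self, rng):
        std, pca = self.make_pca(rng)
        W1, W2 = rng.standard_normal((2, 4, 2))
        s1 = reconstruct_signature(CoefficientMatrix(W1, 0.1), pca, std).voxel_weights
        s2 = reconstruct_signature(CoefficientMatrix(W2, 0.1), pca, std).voxel_weights
        s12 = reconstruct_signature(CoefficientMatrix(W1 + 2 * W2, 0.1), pca,
                                    std).voxel_weights
        np.testing.assert_allclose(s12, s1 + 2 * s2, atol=1e-12)

    def test_raw_space_divides_by_training_sd(self, rng):
        std, pca = self.make_pca(rng)
        W = rng.standard_normal((4, 2))
        s_std = reconstruct_signature(CoefficientMatrix(W, 0.1), pca, std,
                                      space="standardized").voxel_weights
        s_raw = reconstruct_signature(CoefficientMatrix(W, 0.1), pca, std,
                                      space="raw").voxel_weights
        np.testing.assert_allclose(s_raw, s_std / std.sds[:, None], atol=1e-12)

    def test_nifti_round_trip_with_synthetic_mask(self, rng):
        import nibabel as nib

        std, pca = self.make_pca(rng, p=8)
        W = rng.standard_normal((4, 2))
        sig = reconstruct_signature(CoefficientMatrix(W, 0.1), pca, std)
        mask_data = np.zeros((2, 2, 3))
        mask_data.reshape(-1)[[0, 2, 3, 5, 7, 8, 10, 11]] = 1
        mask = nib.Nifti1Image(mask_data, np.eye(4))
        img = signature_to_nifti(sig, mask, task=0)
        flat = np.asarray(img.dataobj).reshape(-1)
        np.testing.assert_allclose(flat[mask_data.reshape(-1) != 0],
                                   sig.voxel_weights[:, 0])
        assert np.all(flat[mask_data.reshape(-1) == 0] == 0)

    def test_table_export(self, rng):
        std, pca = self.make_pca(rng)
        sig = reconstruct_signature(
            CoefficientMatrix(rng.standard_normal((4, 2)), 0.1), pca, std,
            task_ids=("pain", "depression"))
        df = signature_to_table(sig, [f"v{i}" for i in range(8)])
        assert list(df.columns) == ["pain", "depression"]
        assert df.shape == (8, 2)

    def test_dimension_mismatch_rejected(self, rng):
        std, pca = self.make_pca(rng)
        with pytest.raises(ValueError):
            reconstruct_signature(CoefficientMatrix(np.zeros((7, 2)), 0.1), pca, std)
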