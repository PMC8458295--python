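"""Scale-retaining GPA, shape matrix, dual-trick PCA, synthesis, projection."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mandssm.model import (
    ShapeMatrix,
    build_shape_matrix,
    centroid_size,
    fit_pca,
    gpa_align,
    load_model,
    project_new_sample,
    save_model,
    synthesize,
)
from conftest import principal_angles_deg


def _random_shapes(rng, n, p):
    return [rng.normal(0, 10, (p, 3)) for _ in range(n)]


class TestGpa:
    def test_rigid_motions_aligned_and_sizes_preserved(self):
        rng = np.random.default_rng(0)
        shape = rng.normal(0, 10, (40, 3))
        copies = []
        for _ in range(6):
            rot = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
            t = rng.normal(0, 30, 3)
            copies.append(shape @ rot.T + t)
        aligned = gpa_align(copies)
        ref = np.asarray(aligned[0])
        for orig, a in zip(copies, aligned):
            assert np.linalg.norm(np.asarray(a) - ref, axis=1).max() < 1e-8
            assert abs(centroid_size(np.asarray(a)) / centroid_size(orig) - 1) < 1e-12

    def test_scale_retained(self):
        rng = np.random.default_rng(1)
        shape = rng.normal(0, 10, (30, 3))
        aligned = gpa_align([shape, 2.0 * shape])
        s1 = centroid_size(np.asarray(aligned[0]))
        s2 = centroid_size(np.asarray(aligned[1]))
        assert abs(s2 / s1 - 2.0) < 1e-12

    def test_objective_monotone(self):
        rng = np.random.default_rng(2)
        shapes = _random_shapes(rng, 8, 25)
        aligned = gpa_align(shapes)
        obj = np.asarray(aligned.objective)
        assert np.all(np.diff(obj) <= 1e-9 * np.maximum(obj[:-1], 1.0))

    def test_too_few_shapes_rejected(self):
        with pytest.raises(ValueError):
            gpa_align([np.zeros((5, 3))])


class TestShapeMatrix:
    def test_semilandmark_vector_length(self):
        pts = [np.zeros((5801, 3)), np.ones((5801, 3))]
        mat = build_shape_matrix(pts)
        assert mat.data.shape[0] == 17403

    def test_single_sample_column_roundtrip(self):
        rng = np.random.default_rng(3)
        p = rng.normal(size=(12, 3))
        mat = build_shape_matrix([p, p * 2])
        assert np.array_equal(mat.column_points(0), p)
        assert np.array_equal(mat.data[:, 0], p.reshape(-1))

    def test_mixed_point_counts_rejected(self):
        with pytest.raises(ValueError):
            build_shape_matrix([np.zeros((5, 3)), np.zeros((6, 3))])


class TestPca:
    @pytest.mark.parametrize("trial", range(5))
    def test_dual_matches_bruteforce_covariance(self, trial):
        rng = np.random.default_rng(100 + trial)
        p = int(rng.integers(4, 20))  # 3P <= 60
        n = int(rng.integers(5, 16))
        data = rng.normal(0, 3, (3 * p, n))
        mat = ShapeMatrix(data, [f"s{i}" for i in range(n)], np.full(n, np.nan))
        model = fit_pca(mat, k_max=n)

        cov = np.cov(data, ddof=1)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        k = model.n_modes
        assert np.allclose(model.eigenvalues, evals[:k], atol=1e-8)
        # modes diagonalize the covariance (eigenvector property)
        for j in range(k):
            v = model.modes[:, j]
            assert np.linalg.norm(cov @ v - model.eigenvalues[j] * v) < 1e-6
        # trace identity: total variance is preserved
        assert abs(model.eigenvalues.sum() - np.trace(cov)) / np.trace(cov) < 1e-8 or k < n - 1

    def test_weights_are_sd_units(self):
        rng = np.random.default_rng(7)
        data = rng.normal(0, 2, (30, 12))
        mat = ShapeMatrix(data, [f"s{i}" for i in range(12)], np.full(12, np.nan))
        model = fit_pca(mat)
        assert np.abs(model.weights.mean(axis=0)).max() < 1e-10
        assert np.abs(model.weights.std(axis=0, ddof=1) - 1.0).max() < 1e-6

    def test_identical_samples_give_zero_modes(self):
        col = np.arange(9.0)
        mat = ShapeMatrix(np.tile(col[:, None], (1, 4)), list("abcd"), np.full(4, np.nan))
        model = fit_pca(mat)
        assert model.n_modes == 0
        assert np.allclose(model.mean_shape, col)

    def test_modes_orthonormal(self):
        rng = np.random.default_rng(8)
        data = rng.normal(size=(60, 10))
        mat = ShapeMatrix(data, [f"s{i}" for i in range(10)], np.full(10, np.nan))
        model = fit_pca(mat)
        gram = model.modes.T @ model.modes
        assert np.abs(gram - np.eye(model.n_modes)).max() < 1e-10

    def test_deterministic_mode_signs(self):
        rng = np.random.default_rng(9)
        data = rng.normal(size=(30, 8))
        mat = ShapeMatrix(data, [f"s{i}" for i in range(8)], np.full(8, np.nan))
        m1 = fit_pca(mat)
        m2 = fit_pca(ShapeMatrix(data.copy(), mat.sample_ids, mat.ages))
        assert np.array_equal(m1.modes, m2.modes)

    def test_subspace_recovery_noise_free(self):
        from mandssm.synthetic import CohortSpec, generate_cohort

        meshes, truth = generate_cohort(
            CohortSpec(n_samples=40, n_points_base=500, noise_sd=0.0, seed=3)
        )
        mat = build_shape_matrix([np.asarray(m.vertices) for m in meshes])
        model = fit_pca(mat, k_max=5)
        ang = principal_angles_deg(model.modes[:, :3], truth.flattened_modes())
        assert np.all(np.radians(ang) < 1e-4)


class TestSynthesize:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(11)
        data = rng.normal(0, 2, (24, 9))
        mat = ShapeMatrix(data, [f"s{i}" for i in range(9)], np.full(9, np.nan))
        return fit_pca(mat), mat

    def test_zero_weights_is_mean(self, fitted):
        model, _ = fitted
        out = synthesize(model, np.zeros(model.n_modes))
        assert np.allclose(out, model.mean_shape)

    def test_plus_minus_three_sd_reflect_about_mean(self, fitted):
        model, _ = fitted
        w = np.zeros(model.n_modes)
        w[0] = 3.0
        hi = synthesize(model, w)
        lo = synthesize(model, -w)
        assert np.allclose(0.5 * (hi + lo), model.mean_shape, atol=1e-10)

    def test_training_sample_roundtrip(self, fitted):
        model, mat = fitted
        recon = synthesize(model, model.weights[2])
        assert np.abs(recon - mat.data[:, 2]).max() < 1e-8

    def test_overlong_weights_rejected(self, fitted):
        model, _ = fitted
        with pytest.raises(ValueError):
            synthesize(model, np.zeros(model.n_modes + 1))


class TestProjection:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(13)
        data = rng.normal(0, 2, (30, 10))
        mat = ShapeMatrix(data, [f"s{i}" for i in range(10)], np.full(10, np.nan))
        return fit_pca(mat), mat

    def test_mean_projects_to_zero(self, fitted):
        model, _ = fitted
        w, _, err = project_new_sample(model, model.mean_points())
        assert np.abs(w).max() < 1e-8
        assert err < 1e-8

    def test_training_sample_full_rank_reconstruction(self, fitted):
        # training columns are already in the model frame, so the span
        # property is tested without the rigid pre-alignment
        model, mat = fitted
        _, _, err = project_new_sample(model, mat.column_points(4), align=False)
        assert err < 1e-8

    def test_training_sample_reconstruction_after_gpa(self):
        # with a Procrustes-aligned cohort the default aligning projection
        # reproduces training samples as well (re-alignment is a no-op)
        rng = np.random.default_rng(21)
        shapes = [rng.normal(0, 5, (20, 3)) for _ in range(8)]
        aligned = gpa_align(shapes)
        mat = build_shape_matrix(list(aligned))
        model = fit_pca(mat)
        _, _, err = project_new_sample(model, mat.column_points(3))
        assert err < 1e-6

    def test_error_monotone_in_k(self, fitted):
        model, _ = fitted
        rng = np.random.default_rng(14)
        new = rng.normal(0, 2, (10, 3))
        errs = [project_new_sample(model, new, k=k, align=False)[2]
                for k in range(1, model.n_modes + 1)]
        # nested projections: the L2 residual can only shrink; the reported
        # mean of per-point norms follows it up to a small tolerance
        errs = np.asarray(errs)
        assert np.all(np.diff(errs) <= 2e-3 * errs[:-1])
        assert errs[-1] < errs[0]

    def test_excess_k_rejected(self, fitted):
        model, _ = fitted
        with pytest.raises(ValueError):
            project_new_sample(model, model.mean_points(), k=model.n_modes + 1)


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(15)
        data = rng.normal(size=(18, 6))
        mat = ShapeMatrix(data, [f"s{i}" for i in range(6)], np.arange(6.0))
        model = fit_pca(mat)
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        assert np.array_equal(back.modes, model.modes)
        assert np.array_equal(back.weights, model.weights)
        assert (tmp_path / "model.weights.csv").exists()
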