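"""Concentration features and the MICF trace eigenproblem."""

import numpy as np
import pytest
import scipy.linalg

from enosedrift import (
    DriftSimConfig,
    MICFModel,
    build_concentration_features,
    concentration_kernel,
    concentration_levels,
    fit_micf,
    micf_objective,
    project,
    simulate_enose,
    standardize_per_batch,
)
from enosedrift.kernels import KernelSpec, centering_matrix, gram, hsic_estimate


def random_orthonormal(rng, n, h):
    Q, _ = np.linalg.qr(rng.normal(0, 1, (n, h)))
    return Q


class TestConcentrationLevels:
    @pytest.mark.parametrize(
        "conc, raw",
        [(100.0, 4), (np.exp(3.0), 3), (10.0, 2), (999.0, 6)],
    )
    def test_raw_level_is_integer_part_of_log(self, conc, raw):
        coding = concentration_levels([conc, conc])
        assert coding.level_map == {raw: 1}

    def test_levels_remapped_contiguously(self):
        coding = concentration_levels([10.0, 100.0, 1000.0])
        # floor(ln c) = 2, 4, 6 -> contiguous 1, 2, 3
        assert coding.levels.tolist() == [1, 2, 3]
        assert coding.level_map == {2: 1, 4: 2, 6: 3}

    def test_rejects_nonpositive_concentration(self):
        with pytest.raises(ValueError):
            concentration_levels([10.0, -1.0])


class TestConcentrationFeatureMatrix:
    def test_one_hot_columns_and_zero_for_unlabeled(self):
        Y = build_concentration_features(
            [1, 2, 1], [True, True, True, False], 4, n_levels=2
        )
        assert np.array_equal(Y.Y, [[1, 0, 1, 0], [0, 1, 0, 0]])

    def test_all_unlabeled_gives_zero_matrix_and_kernel(self):
        Y = build_concentration_features([], [False] * 3, 3, n_levels=1)
        assert not Y.Y.any()
        assert not concentration_kernel(Y).any()

    def test_kernel_marks_same_level_pairs(self):
        Y = build_concentration_features(
            [1, 2, 1], [True, True, True, False], 4, n_levels=2
        )
        Ky = concentration_kernel(Y)
        assert Ky[0, 2] == 1  # same level
        assert Ky[0, 1] == 0  # different levels
        assert not Ky[:, 3].any()  # unlabeled column

    def test_kernel_matches_column_inner_product_loop(self, rng):
        mask = rng.random(6) < 0.7
        levels = rng.integers(1, 4, int(mask.sum()))
        Y = build_concentration_features(levels, mask, 6, n_levels=3)
        Ky = concentration_kernel(Y)
        for i in range(6):
            for j in range(6):
                assert Ky[i, j] == Y.Y[:, i] @ Y.Y[:, j]

    def test_level_coded_variant_uses_level_value(self):
        Y = build_concentration_features(
            [2], [True, False], 2, n_levels=2, level_coded=True
        )
        assert Y.Y[1, 0] == 2.0

    def test_rejects_out_of_range_level(self):
        with pytest.raises(ValueError):
            build_concentration_features([3], [True], 1, n_levels=2)


class TestFitMICF:
    def test_zero_ky_reduces_to_kernel_pca_subspace(self, rng):
        X = rng.normal(0, 1, (10, 5))
        Kx = gram(X)
        model = fit_micf(Kx, np.zeros((10, 10)), mu=1.0, h=2)
        H = centering_matrix(10)
        M = Kx @ H @ Kx
        _, U = np.linalg.eigh((M + M.T) / 2)
        top = U[:, ::-1][:, :2]
        assert scipy.linalg.subspace_angles(model.W, top).max() < 1e-6

    def test_orthonormal_columns_and_real_descending_eigenvalues(self, rng):
        X = rng.normal(0, 1, (8, 4))
        Ky = np.zeros((8, 8))
        Ky[:4, :4] = 1.0
        model = fit_micf(gram(X), Ky, mu=0.5, h=3)
        assert np.max(np.abs(model.W.T @ model.W - np.eye(3))) < 1e-8
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_eigen_solution_beats_random_orthonormal_search(self, rng):
        for _ in range(5):
            n, h = 6, 2
            X = rng.normal(0, 1, (n, 3))
            Kx = gram(X)
            mask = rng.random(n) < 0.7
            levels = rng.integers(1, 3, int(mask.sum()))
            Ky = concentration_kernel(
                build_concentration_features(levels, mask, n, n_levels=2)
            )
            mu = float(rng.uniform(0.1, 2.0))
            model = fit_micf(Kx, Ky, mu=mu, h=h)
            best = micf_objective(model.W, Kx, Ky, mu)
            for _ in range(200):
                W = random_orthonormal(rng, n, h)
                assert best >= micf_objective(W, Kx, Ky, mu) - 1e-9

    def test_objective_equals_sum_of_returned_eigenvalues(self, rng):
        X = rng.normal(0, 1, (7, 3))
        Kx = gram(X)
        Ky = np.zeros((7, 7))
        Ky[2:5, 2:5] = 1.0
        model = fit_micf(Kx, Ky, mu=1.3, h=2)
        assert micf_objective(model.W, Kx, Ky, 1.3) == pytest.approx(
            float(np.sum(model.eigenvalues)), abs=1e-8
        )

    def test_objective_matches_naive_product_evaluation(self, rng):
        n, h = 5, 2
        X = rng.normal(0, 1, (n, 3))
        Kx, Ky = gram(X), np.outer(np.ones(n), np.ones(n))
        W = random_orthonormal(rng, n, h)
        H = centering_matrix(n)
        naive = np.trace(
            -W.T @ Kx @ H @ Ky @ H @ Kx @ W + 0.7 * W.T @ Kx @ H @ Kx @ W
        )
        assert micf_objective(W, Kx, Ky, 0.7) == pytest.approx(naive, abs=1e-10)

    def test_objective_rejects_non_orthonormal_w(self, rng):
        Kx = gram(rng.normal(0, 1, (4, 2)))
        with pytest.raises(ValueError):
            micf_objective(np.ones((4, 2)), Kx, np.zeros((4, 4)), 1.0)

    def test_large_mu_limit_recovers_variance_subspace(self, rng):
        n = 10
        X = rng.normal(0, 1, (n, 5))
        Kx = gram(X)
        levels = rng.integers(1, 4, n)
        Ky = concentration_kernel(
            build_concentration_features(levels, [True] * n, n, n_levels=3)
        )
        model = fit_micf(Kx, Ky, mu=1e6, h=2)
        H = centering_matrix(n)
        M = Kx @ H @ Kx
        _, U = np.linalg.eigh((M + M.T) / 2)
        top = U[:, ::-1][:, :2]
        assert scipy.linalg.subspace_angles(model.W, top).max() < 1e-3

    def test_fit_is_bit_stable_across_runs(self, rng):
        X = rng.normal(0, 1, (9, 4))
        Kx = gram(X)
        Ky = np.zeros((9, 9))
        Ky[:3, :3] = 1.0
        a = fit_micf(Kx, Ky, mu=1.0, h=3)
        b = fit_micf(Kx.copy(), Ky.copy(), mu=1.0, h=3)
        assert np.array_equal(a.W, b.W)
        assert np.array_equal(a.eigenvalues, b.eigenvalues)

    @pytest.mark.parametrize("h", [0, 9])
    def test_rejects_out_of_range_h(self, rng, h):
        Kx = gram(rng.normal(0, 1, (5, 2)))
        with pytest.raises(ValueError):
            fit_micf(Kx, np.zeros((5, 5)), mu=1.0, h=h)

    def test_rejects_asymmetric_kernel(self, rng):
        Kx = rng.normal(0, 1, (5, 5))
        with pytest.raises(ValueError):
            fit_micf(Kx, np.zeros((5, 5)), mu=1.0, h=1)


class TestProject:
    def test_identity_transform_returns_kernel(self, rng):
        Kx = gram(rng.normal(0, 1, (4, 3)))
        model = MICFModel(W=np.eye(4), mu=1.0, h=4)
        assert np.array_equal(project(model, Kx), Kx)

    def test_duplicate_kernel_columns_project_identically(self, rng):
        Kx = gram(rng.normal(0, 1, (5, 3)))
        Kx[:, 3] = Kx[:, 1]
        model = MICFModel(W=random_orthonormal(rng, 5, 2), mu=1.0, h=2)
        Z = project(model, Kx)
        assert np.array_equal(Z[:, 3], Z[:, 1])

    def test_matches_naive_multiplication(self, rng):
        Kx = gram(rng.normal(0, 1, (6, 2)))
        W = random_orthonormal(rng, 6, 3)
        model = MICFModel(W=W, mu=1.0, h=3)
        assert np.allclose(project(model, Kx), W.T @ Kx, atol=1e-12)

    def test_rejects_dimension_mismatch(self, rng):
        model = MICFModel(W=np.eye(4), mu=1.0, h=4)
        with pytest.raises(ValueError):
            project(model, np.eye(5))


class TestHSICReduction:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mu_zero_fit_minimizes_hsic_against_random_subspaces(self, seed):
        data = simulate_enose(
            DriftSimConfig(seed=seed, n_batches=2, samples_per_cell=2)
        )
        data = standardize_per_batch(data)
        src = data.is_source
        coding = concentration_levels(data.concentrations[src])
        Y = build_concentration_features(
            coding.levels, src, data.n_samples, n_levels=coding.n_levels
        )
        Kx = gram(data.features)
        Ky = concentration_kernel(Y)
        h = 4
        model = fit_micf(Kx, Ky, mu=0.0, h=h)
        fitted = hsic_estimate(gram(project(model, Kx).T), Ky)
        rng = np.random.default_rng(1000 + seed)
        for _ in range(50):
            W = random_orthonormal(rng, Kx.shape[0], h)
            assert fitted <= hsic_estimate(gram((W.T @ Kx).T), Ky) + 1e-12


class TestSerialization:
    def test_model_json_round_trip(self, rng, tmp_path):
        X = rng.normal(0, 1, (6, 3))
        Kx = gram(X)
        model = fit_micf(
            Kx,
            np.zeros((6, 6)),
            mu=2.0,
            h=2,
            kernel_spec=KernelSpec("rbf", bandwidth=1.5),
            level_map={2: 1, 4: 2},
        )
        path = tmp_path / "model.json"
        model.to_json(path)
        back = MICFModel.from_json(path)
        assert np.allclose(back.W, model.W)
        assert back.mu == model.mu and back.h == model.h
        assert back.kernel_spec == model.kernel_spec
        assert back.level_map == model.level_map
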