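"""Patch layout, sparse coding, pooling, GentleBoost and cross-validation."""

import numpy as np
import pytest

from subshape.classify import (
    Dictionary,
    SubjectDataset,
    allocate_folds,
    confusion_metrics,
    cross_validate,
    extract_patch_features,
    generate_patches,
    gentleboost_train,
    max_pool,
    scc_learn,
    sparse_encode,
    subject_vector,
    unflatten_patch,
)


class TestPatches:
    def test_default_window_count(self):
        layout = generate_patches((100, 150))
        assert len(layout) == 1008

    def test_single_full_grid_window(self):
        layout = generate_patches((30, 30), n_patches=1, side=30,
                                  periodic_v=False, seed=0)
        assert layout.windows == [(0, 0, 30)]

    def test_seed_determinism(self):
        l1 = generate_patches((100, 150), side=25, seed=9)
        l2 = generate_patches((100, 150), side=25, seed=9)
        assert l1.windows == l2.windows

    def test_windows_fit_in_u(self):
        layout = generate_patches((40, 60), n_patches=500, side=20, seed=1)
        assert all(u0 + s <= 40 for u0, v0, s in layout.windows)

    def test_oversized_side_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            generate_patches((25, 60), side=30)


class TestPatchExtraction:
    def test_row_length_30x30x4(self, rng):
        grid = rng.normal(size=(100, 150, 4))
        layout = generate_patches((100, 150), n_patches=10, side=30, seed=0)
        mat = extract_patch_features(grid, layout)
        assert mat.shape == (10, 3600)

    def test_constant_field_identical_rows(self):
        grid = np.full((40, 60, 4), 2.5)
        layout = generate_patches((40, 60), n_patches=20, side=10, seed=1)
        mat = extract_patch_features(grid, layout)
        assert np.all(mat == 2.5)
        assert np.ptp(mat, axis=0).max() == 0.0

    def test_block_round_trip_with_wrap(self, rng):
        grid = rng.normal(size=(40, 60, 4))
        layout = generate_patches((40, 60), n_patches=50, side=12, seed=2)
        mat = extract_patch_features(grid, layout)
        for row, (u0, v0, side) in zip(mat, layout.windows):
            block = unflatten_patch(row, side, 4)
            vi = np.arange(v0, v0 + side) % 60
            assert np.array_equal(block, grid[u0:u0 + side][:, vi])

    def test_dims_mismatch_rejected(self, rng):
        layout = generate_patches((40, 60), n_patches=5, side=10)
        with pytest.raises(ValueError, match="match"):
            extract_patch_features(rng.normal(size=(30, 60, 4)), layout)


class TestSCC:
    def make_sparse_data(self, rng, m=64, k=32, P=600, sparsity=3):
        D0 = rng.standard_normal((m, k))
        D0 /= np.linalg.norm(D0, axis=0)
        Z0 = np.zeros((P, k))
        for i in range(P):
            idx = rng.choice(k, sparsity, replace=False)
            Z0[i, idx] = rng.normal(0, 1, sparsity)
        return Z0 @ D0.T, D0, Z0

    def test_recovers_sparse_generative_model(self, rng):
        X, D0, _ = self.make_sparse_data(rng)
        d = scc_learn(X, k=32, gamma=0.05, epochs=10, seed=1)
        # dictionary quality measured by debiased (small-gamma) codes
        codes = sparse_encode(X, d, gamma=0.01)
        rec = codes @ d.atoms.T
        rel = np.linalg.norm(X - rec) / np.linalg.norm(X)
        assert rel < 0.10

    def test_zero_epochs_returns_normalized_init(self, rng):
        X = rng.normal(size=(50, 20))
        d1 = scc_learn(X, k=8, gamma=0.1, epochs=0, seed=4)
        d2 = scc_learn(X, k=8, gamma=0.1, epochs=0, seed=4)
        assert np.array_equal(d1.atoms, d2.atoms)
        assert np.allclose(np.linalg.norm(d1.atoms, axis=0), 1.0, atol=1e-9)

    def test_holdout_objective_descends(self, rng):
        X, _, _ = self.make_sparse_data(rng)
        d = scc_learn(X, k=32, gamma=0.05, epochs=5, seed=2)
        trace = d.metadata["holdout_objective"]
        assert trace[-1] <= trace[0] + 1e-6

    def test_excessive_gamma_warns(self, rng):
        X = 0.001 * rng.normal(size=(40, 16))
        with pytest.warns(UserWarning, match="zeroed"):
            scc_learn(X, k=8, gamma=10.0, epochs=2, seed=0, init="random")

    def test_unit_norm_enforced_by_container(self, rng):
        with pytest.raises(ValueError, match="unit norm"):
            Dictionary(rng.normal(size=(10, 4)), 0.1, 0, 0)


class TestSparseEncode:
    def test_atom_recovery_identity(self, rng):
        D = rng.standard_normal((30, 10))
        D /= np.linalg.norm(D, axis=0)
        d = Dictionary(D, 1e-8, 0, 0)
        z = sparse_encode(D[:, 3][None, :], d)[0]
        expected = np.zeros(10)
        expected[3] = 1.0
        assert np.abs(z - expected).max() < 1e-4

    def test_lasso_null_threshold(self, rng):
        D = rng.standard_normal((30, 10))
        D /= np.linalg.norm(D, axis=0)
        x = rng.normal(size=30)
        gamma = np.abs(D.T @ x).max() * 1.001
        d = Dictionary(D, gamma, 0, 0)
        z = sparse_encode(x[None, :], d)
        assert np.all(z == 0.0)

    def test_objective_matches_proximal_gradient_oracle(self, rng):
        D = rng.standard_normal((40, 16))
        D /= np.linalg.norm(D, axis=0)
        x = rng.normal(size=40)
        gamma = 0.2
        d = Dictionary(D, gamma, 0, 0)
        z_cd = sparse_encode(x[None, :], d)[0]

        # independent ISTA solver
        L = np.linalg.norm(D, 2) ** 2
        z = np.zeros(16)
        for _ in range(50000):
            g = D.T @ (D @ z - x)
            z_new = z - g / L
            z_new = np.sign(z_new) * np.maximum(np.abs(z_new) - gamma / L, 0)
            if np.abs(z_new - z).max() < 1e-12:
                z = z_new
                break
            z = z_new

        def obj(zz):
            return 0.5 * np.sum((x - D @ zz) ** 2) + gamma * np.abs(zz).sum()

        assert abs(obj(z_cd) - obj(z)) <= 1e-5 * max(obj(z), 1e-12)


class TestPooling:
    def test_two_by_two(self):
        assert np.array_equal(max_pool(np.array([[1, 2], [3, 4]])), [[4]])

    def test_constant_matrix(self):
        out = max_pool(np.full((6, 8), 3.5))
        assert out.shape == (3, 4)
        assert np.all(out == 3.5)

    def test_matches_naive_loops_with_truncated_edges(self, rng):
        A = rng.normal(size=(7, 9))
        out = max_pool(A, 2, 2)

        expect = np.empty((4, 5))
        for i in range(4):
            for j in range(5):
                expect[i, j] = A[2 * i:2 * i + 2, 2 * j:2 * j + 2].max()
        assert np.array_equal(out, expect)

    def test_oversized_window_warns_identity(self, rng):
        A = rng.normal(size=(1, 1))
        with pytest.warns(UserWarning, match="window"):
            out = max_pool(A, 2, 2)
        assert np.array_equal(out, A)


class TestSubjectVector:
    def test_default_pooling_length(self, rng):
        codes = rng.normal(size=(1008, 256))
        vec = subject_vector(codes)
        assert vec.shape == (504 * 128,)

    def test_global_pool_length(self, rng):
        codes = rng.normal(size=(100, 64))
        assert subject_vector(codes, "global_max").shape == (64,)

    def test_one_hot_max_survives_pooling(self):
        codes = np.zeros((10, 8))
        codes[4, 5] = 7.0
        vec = subject_vector(codes)
        pooled = vec.reshape(5, 4)
        assert pooled[2, 2] == 7.0       # row 4//2, col 5//2


class TestGentleBoost:
    def test_separable_blobs_zero_training_error(self, rng):
        X = np.vstack([rng.normal(-3, 1, (50, 2)), rng.normal(3, 1, (50, 2))])
        y = np.r_[-np.ones(50), np.ones(50)]
        model = gentleboost_train(X, y, n_rounds=20, max_depth=2, seed=0)
        assert (model.predict(X) != y).mean() == 0.0

    def test_single_stump_matches_exhaustive_search(self, rng):
        X = rng.normal(size=(40, 1))
        y = np.where(X[:, 0] + 0.3 * rng.normal(size=40) > 0, 1.0, -1.0)
        model = gentleboost_train(X, y, n_rounds=1, max_depth=1, seed=0)
        f = model.trees[0].predict(X)

        # oracle: best weighted LS stump by brute-force threshold search
        best_sse = np.inf
        xs = np.sort(X[:, 0])
        for thr in (xs[:-1] + xs[1:]) / 2:
            left = X[:, 0] <= thr
            pred = np.where(left, y[left].mean(), y[~left].mean())
            sse = np.sum((y - pred) ** 2)
            if sse < best_sse:
                best_sse, best_pred = sse, pred
        assert np.sum((y - f) ** 2) == pytest.approx(best_sse, rel=1e-9)

    def test_weights_increase_on_misclassified(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.where(X[:, 0] > 0, 1.0, -1.0)
        y[:3] *= -1          # three deliberately mislabelled points
        model = gentleboost_train(X, y, n_rounds=1, max_depth=1, seed=0)
        f = model.trees[0].predict(X)
        w = np.exp(-y * f)
        mis = np.sign(f) != y
        if mis.any() and (~mis).any():
            assert w[mis].min() > w[~mis].max() - 1e-12

    def test_bad_labels_rejected(self, rng):
        with pytest.raises(ValueError):
            gentleboost_train(rng.normal(size=(10, 2)), np.arange(10), 5, 2)


class TestCrossValidation:
    def test_311_subjects_fold_sizes(self):
        folds = allocate_folds(311, 10, seed=0)
        sizes = sorted(np.bincount(folds))
        assert sizes == [31] * 9 + [32]

    def test_perfect_classifier_stub_all_metrics_one(self, rng):
        X = np.vstack([np.zeros((20, 3)), np.ones((20, 3))])
        y = np.r_[-np.ones(20), np.ones(20)]

        class Oracle:
            def predict(self, X):
                return np.where(X[:, 0] > 0.5, 1, -1)

        rep = cross_validate((X, y), k_folds=10, seed=1,
                             model_factory=lambda Xt, yt, s: Oracle())
        for m in ("ACC", "SEN", "SPE", "PPV", "NPV"):
            assert rep.means[m] == 1.0

    def test_confusion_metric_formulas(self):
        m = confusion_metrics(tn=50, fp=10, fn=5, tp=35)
        assert m["ACC"] == pytest.approx(85 / 100)
        assert m["SEN"] == pytest.approx(35 / 40)
        assert m["SPE"] == pytest.approx(50 / 60)
        assert m["PPV"] == pytest.approx(35 / 45)
        assert m["NPV"] == pytest.approx(50 / 55)

    def test_pipeline_determinism(self, rng):
        mats = rng.normal(size=(20, 30, 32))
        mats[10:] += 1.0
        y = np.r_[-np.ones(10), np.ones(10)]
        ds = SubjectDataset(mats, y, k=8, gamma=0.15, epochs=1, n_rounds=10)
        r1 = cross_validate(ds, k_folds=5, seed=3)
        r2 = cross_validate(ds, k_folds=5, seed=3)
        assert r1.means == r2.means
        assert np.array_equal(r1.fold_assignment, r2.fold_assignment)

    def test_single_class_fold_flagged_na(self, rng):
        X = rng.normal(size=(12, 3))
        y = np.r_[-np.ones(11), np.ones(1)]   # one positive only

        class AlwaysNeg:
            def predict(self, X):
                return -np.ones(len(X), dtype=int)

        with pytest.warns(UserWarning, match="undefined"):
            rep = cross_validate((X, y), k_folds=4, seed=0,
                                 model_factory=lambda *a: AlwaysNeg())
        assert np.isnan(rep.per_fold["SEN"]).sum() >= 2
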