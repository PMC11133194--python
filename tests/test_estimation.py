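"""ALS initialization, the four-step update cycle, and the multi-start fit."""

import warnings

import numpy as np
import pytest

import tucker3pcovr as tp
from tucker3pcovr.core import loss as eq_loss, unfold
from tucker3pcovr.estimation import (
    AlsState,
    _project_initial,
    _regression_step,
    als_step,
    init_perturbed,
    init_random,
    init_rational,
)


def _random_state(rng, I, J, K, L, ranks):
    B, _ = np.linalg.qr(rng.standard_normal((J, ranks.R2)))
    C, _ = np.linalg.qr(rng.standard_normal((K, ranks.R3)))
    W = rng.standard_normal((L, ranks.R1))
    X = rng.standard_normal((I, L))
    A = X @ W
    return (
        AlsState(
            W=W, A=A, B=B, C=C,
            G=rng.standard_normal(ranks.astuple()),
            P_X=rng.standard_normal((L, ranks.R1)),
        ),
        X,
        rng.standard_normal((I, J, K)),
    )


class TestRationalInit:
    def test_component_matrices_orthonormal(self, rng):
        ds, _ = tp.generate(8, 5, 4, 6, (2, 2, 2), seed=0)
        A0, B0, C0 = init_rational(ds.X, ds.Y, tp.Ranks(3, 2, 2))
        for M in (A0, B0, C0):
            np.testing.assert_allclose(M.T @ M, np.eye(M.shape[1]), atol=1e-10)

    def test_b_spans_top_singular_subspace_of_mode_b_unfolding(self):
        ds, _ = tp.generate(8, 5, 4, 6, (2, 2, 2), snr_x=5, snr_y=5, seed=4)
        _, B0, _ = init_rational(ds.X, ds.Y, tp.Ranks(2, 2, 2))
        U, _, _ = np.linalg.svd(unfold(ds.Y, "B"))
        overlap = np.linalg.svd(B0.T @ U[:, :2], compute_uv=False)
        np.testing.assert_allclose(overlap, 1.0, atol=1e-10)

    def test_rank1_noiseless_data_solved_after_one_regression(self):
        ds, _ = tp.generate(6, 4, 3, 5, (1, 1, 1), snr_x=np.inf, snr_y=np.inf, seed=2)
        Y_A = unfold(ds.Y, "A")
        A0, B0, C0 = init_rational(ds.X, ds.Y, tp.Ranks(1, 1, 1))
        state = _project_initial(A0, B0, C0, ds.X, Y_A, alpha=0.5)
        val = eq_loss(state.A, state.B, state.C, state.G, state.P_X, 0.5, ds.X, Y_A)
        assert val < 1e-10

    def test_rank_deficient_gram_padded_with_warning(self):
        ds, _ = tp.generate(6, 4, 2, 5, (1, 1, 1), snr_x=np.inf, snr_y=np.inf, seed=3)
        with pytest.warns(UserWarning, match="padding with an orthonormal"):
            _, B0, _ = init_rational(ds.X, ds.Y, tp.Ranks(2, 2, 2))
        np.testing.assert_allclose(B0.T @ B0, np.eye(2), atol=1e-10)

    def test_deterministic_signs(self):
        ds, _ = tp.generate(seed=5)
        out1 = init_rational(ds.X, ds.Y, tp.Ranks(2, 2, 2))
        out2 = init_rational(ds.X, ds.Y, tp.Ranks(2, 2, 2))
        for M1, M2 in zip(out1, out2):
            np.testing.assert_array_equal(M1, M2)
            assert all(M1[np.argmax(np.abs(M1[:, c])), c] > 0 for c in range(M1.shape[1]))


class TestRandomAndPerturbedInit:
    def test_seed_reproducibility_and_shapes(self):
        r = tp.Ranks(2, 2, 2)
        a1 = init_random((8, 5, 4), r, np.random.default_rng(9))
        a2 = init_random((8, 5, 4), r, np.random.default_rng(9))
        a3 = init_random((8, 5, 4), r, np.random.default_rng(10))
        for M1, M2 in zip(a1, a2):
            np.testing.assert_array_equal(M1, M2)
        assert any(not np.array_equal(M1, M3) for M1, M3 in zip(a1, a3))
        assert [M.shape for M in a1] == [(8, 2), (5, 2), (4, 2)]

    def test_random_b_c_orthonormal(self):
        _, B0, C0 = init_random((8, 5, 4), tp.Ranks(2, 2, 2), np.random.default_rng(0))
        np.testing.assert_allclose(B0.T @ B0, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(C0.T @ C0, np.eye(2), atol=1e-12)

    def test_zero_perturbation_reproduces_rational(self):
        ds, _ = tp.generate(seed=1)
        rational = init_rational(ds.X, ds.Y, tp.Ranks(2, 2, 2))
        out = init_perturbed(rational, 0.0, np.random.default_rng(0))
        for M1, M2 in zip(rational, out):
            np.testing.assert_array_equal(M1, M2)

    def test_perturbation_distance_grows_with_scale(self):
        ds, _ = tp.generate(seed=1)
        rational = init_rational(ds.X, ds.Y, tp.Ranks(2, 2, 2))
        dist = {}
        for scale in (0.05, 0.5):
            ds_ = [
                np.linalg.norm(
                    init_perturbed(rational, scale, np.random.default_rng(s))[0]
                    - rational[0]
                )
                for s in range(20)
            ]
            dist[scale] = np.mean(ds_)
        assert dist[0.5] > dist[0.05]

    def test_perturbed_b_c_stay_orthonormal(self):
        ds, _ = tp.generate(seed=1)
        rational = init_rational(ds.X, ds.Y, tp.Ranks(2, 2, 2))
        _, B0, C0 = init_perturbed(rational, 0.3, np.random.default_rng(2))
        np.testing.assert_allclose(B0.T @ B0, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(C0.T @ C0, np.eye(2), atol=1e-12)


class TestAlsStep:
    @pytest.mark.parametrize("trial", range(20))
    def test_full_cycle_never_increases_loss(self, trial):
        rng = np.random.default_rng(1000 + trial)
        ranks = tp.Ranks(*rng.choice([(1, 1, 1), (2, 2, 2), (2, 2, 1)]))
        state, X, Y = _random_state(rng, 7, 4, 3, 5, ranks)
        Y_A = unfold(Y, "A")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            before = eq_loss(state.A, state.B, state.C, state.G, state.P_X, 0.4, X, Y_A)
            new = als_step(state, X, Y, 0.4)
            after = eq_loss(new.A, new.B, new.C, new.G, new.P_X, 0.4, X, Y_A)
        assert after <= before + 1e-12

    def test_converged_state_is_a_fixed_point(self, noisy_fit):
        fit = noisy_fit["fit"]
        pre = noisy_fit["pre"]
        state = AlsState(W=fit.W_X, A=fit.A, B=fit.B, C=fit.C, G=fit.G, P_X=fit.P_X)
        new = als_step(state, pre.X, pre.Y, fit.alpha)
        after = eq_loss(new.A, new.B, new.C, new.G, new.P_X, fit.alpha, pre.X, fit.Y_A)
        assert fit.loss - after < 1e-7
        assert after <= fit.loss + 1e-12

    def test_alpha_one_w_step_ignores_criterion_block(self, rng):
        # with beta = 1 the Y columns of Q and S are zeroed, so two Y blocks
        # that differ must produce the same W update
        state, X, Y1 = _random_state(rng, 7, 4, 3, 5, tp.Ranks(2, 2, 2))
        Y2 = np.random.default_rng(77).standard_normal(Y1.shape)
        Y2 *= np.linalg.norm(Y1) / np.linalg.norm(Y2)  # same norm, same beta
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            W1 = als_step(state, X, Y1, 1.0).W
            W2 = als_step(state, X, Y2, 1.0).W
        np.testing.assert_allclose(W1, W2, atol=1e-10)


class TestFit:
    def test_noiseless_data_fitted_exactly_at_true_ranks(self):
        ds, _ = tp.generate(8, 7, 6, 10, (2, 2, 2), snr_x=np.inf, snr_y=np.inf, seed=0)
        pre, _ = tp.preprocess_dataset(ds)
        fit = tp.fit(pre, tp.FitConfig(alpha=0.5, ranks=tp.Ranks(2, 2, 2), n_starts=2, seed=0))
        assert fit.loss < 1e-10

    def test_loss_history_non_increasing_and_invariants(self, noisy_fit):
        fit = noisy_fit["fit"]
        assert np.all(np.diff(fit.loss_history) <= 1e-12)
        np.testing.assert_allclose(fit.A, noisy_fit["pre"].X @ fit.W_X, atol=1e-8)
        np.testing.assert_allclose(fit.B.T @ fit.B, np.eye(2), atol=1e-10)
        np.testing.assert_allclose(fit.C.T @ fit.C, np.eye(2), atol=1e-10)

    def test_same_seed_reproduces_fit(self):
        ds, _ = tp.generate(seed=6)
        pre, _ = tp.preprocess_dataset(ds)
        cfg = tp.FitConfig(alpha=0.3, ranks=tp.Ranks(2, 2, 2), n_starts=4, seed=8)
        f1, f2 = tp.fit(pre, cfg), tp.fit(pre, cfg)
        np.testing.assert_array_equal(f1.A, f2.A)
        np.testing.assert_array_equal(f1.G, f2.G)

    def test_pca_limit_at_alpha_one(self, congruence):
        from sklearn.decomposition import PCA

        ds, _ = tp.generate(10, 4, 3, 6, (2, 2, 2), snr_x=5, snr_y=5, seed=12)
        pre, _ = tp.preprocess_dataset(ds)
        fit = tp.fit(
            pre,
            tp.FitConfig(alpha=1.0, ranks=tp.Ranks(2, 2, 2), n_starts=1,
                         tol=1e-14, max_iter=2000, seed=0),
        )
        pca = PCA(n_components=2).fit(pre.X)
        scores = pre.X @ pca.components_.T
        q1, _ = np.linalg.qr(fit.A)
        q2, _ = np.linalg.qr(scores)
        cosines = np.linalg.svd(q1.T @ q2, compute_uv=False)
        assert cosines.min() > 1 - 1e-8

    def test_reduced_rank_regression_limit_at_alpha_zero(self):
        ds, _ = tp.generate(10, 4, 3, 6, (2, 4, 3), snr_x=5, snr_y=5, seed=13)
        pre, _ = tp.preprocess_dataset(ds)
        fit = tp.fit(
            pre,
            tp.FitConfig(alpha=0.0, ranks=tp.Ranks(2, 4, 3), n_starts=3,
                         tol=1e-14, max_iter=2000, seed=0),
        )
        # independent SVD oracle: RRR fitted values = rank-R1 SVD truncation
        # of the projection of Y_A onto the column space of X
        H = pre.X @ np.linalg.pinv(pre.X)
        U, s, Vt = np.linalg.svd(H @ pre.Y_A, full_matrices=False)
        expected = U[:, :2] * s[:2] @ Vt[:2]
        np.testing.assert_allclose(fit.fitted_y(), expected, atol=1e-8)

    def test_fitted_values_invariant_under_component_reflection(self, noisy_fit):
        fit = noisy_fit["fit"]
        flipped = fit.copy()
        flipped.B = fit.B * np.array([-1, 1])
        flipped.G = fit.G.copy()
        flipped.G[:, 0, :] *= -1
        np.testing.assert_allclose(flipped.fitted_y(), fit.fitted_y(), atol=1e-10)

    def test_degenerate_single_source_mode(self):
        ds, _ = tp.generate(8, 5, 1, 6, (2, 2, 1), snr_x=5, snr_y=5, seed=14)
        pre, _ = tp.preprocess_dataset(ds)
        fit = tp.fit(pre, tp.FitConfig(alpha=0.5, ranks=tp.Ranks(2, 2, 1), n_starts=2, seed=0))
        assert fit.C.shape == (1, 1)
        assert np.all(np.diff(fit.loss_history) <= 1e-12)

    def test_invalid_ranks_rejected(self):
        ds, _ = tp.generate(seed=0)
        pre, _ = tp.preprocess_dataset(ds)
        with pytest.raises(ValueError, match="R3"):
            tp.fit(pre, tp.FitConfig(alpha=0.5, ranks=tp.Ranks(4, 4, 7), n_starts=1))

    def test_recovery_at_high_snr(self, congruence):
        vals_b, vals_c = [], []
        for seed in range(10):
            ds, truth = tp.generate(8, 7, 6, 10, (2, 2, 2), snr_x=10, snr_y=10, seed=seed)
            pre, info = tp.preprocess_dataset(ds)
            fit = tp.fit(pre, tp.FitConfig(alpha=0.5, ranks=tp.Ranks(2, 2, 2), n_starts=3, seed=seed))
            vals_b.append(congruence(fit.B, truth.B / info.y_scale[:, None]))
            vals_c.append(congruence(fit.C, truth.C))
        assert np.mean(vals_b) > 0.99
        assert np.mean(vals_c) > 0.99
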