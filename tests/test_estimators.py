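"""Divisive (Poisson-ML) and subtractive (least-squares) estimation dynamics."""

import numpy as np
import pytest

from divnorm.basis import FeatureBasis, circular_basis, paired_basis
from divnorm.estimators import (
    EstimatorConfig,
    EstimatorState,
    absolute_errors,
    divisive_step,
    effective_weights,
    fractional_errors,
    ml_estimate,
    poisson_loglik,
    run_to_convergence,
    save_estimator_trace,
    stationarity_residual,
    subtractive_closed_form,
    subtractive_linear,
    subtractive_nnls,
    subtractive_step,
)
from conftest import grid_search_ml, random_basis, random_poisson_instance


class TestFractionalErrors:
    def test_zero_at_perfectly_predicted_input(self, rng):
        b = random_basis(rng, 6, 3)
        x = rng.uniform(0, 2, 3)
        err = fractional_errors(b, x, b.mean_input(x))
        assert np.all(err == 0.0)

    def test_doubled_input_gives_plus_one(self, rng):
        b = random_basis(rng, 6, 3)
        x = rng.uniform(0, 2, 3)
        assert np.allclose(fractional_errors(b, x, 2 * b.mean_input(x)), 1.0)

    def test_zero_input_gives_minus_one_floor(self, rng):
        b = random_basis(rng, 6, 3)
        x = rng.uniform(0, 2, 3)
        err = fractional_errors(b, x, np.zeros(6))
        assert np.all(err == -1.0)
        # and -1 is a hard floor for any nonnegative input
        s = rng.uniform(0, 100, 6)
        assert np.all(fractional_errors(b, x, s) >= -1.0)


class TestDivisiveDynamics:
    def test_fixed_point_is_unchanged_by_a_step(self, two_input_basis):
        s = np.array([100.0, 100.0])
        state = EstimatorState(np.array([2.475]))
        out = divisive_step(two_input_basis, state, s, EstimatorConfig())
        assert np.allclose(out.x_hat, state.x_hat)
        assert out.iter == 1

    def test_single_feature_converges_to_ml_value(self, two_input_basis):
        # w x + w0 must equal the observed mean input (100): x = 99/40
        st = run_to_convergence(two_input_basis, np.array([100.0, 100.0]),
                                EstimatorConfig(tol=1e-12))
        assert st.converged
        assert st.x_hat[0] == pytest.approx(2.475, abs=1e-6)

    def test_noiseless_input_recovers_generating_features(self, rng):
        # random bases can be ill-conditioned, where the first-order flow
        # closes the last distance slowly: accept 1e-2 in parameters but
        # demand near-optimal likelihood
        b = random_basis(rng, 10, 4)
        x_true = rng.uniform(0.3, 2.0, 4)
        s = b.mean_input(x_true)
        st = run_to_convergence(b, s, EstimatorConfig(tol=1e-12, max_iters=200_000))
        assert np.allclose(st.x_hat, x_true, atol=0.03)
        ll_true = poisson_loglik(b, x_true, s)
        assert poisson_loglik(b, st.x_hat, s) >= ll_true - 1e-6 * abs(ll_true)

    def test_all_inputs_below_background_pins_estimate_at_zero(self, rng):
        b = random_basis(rng, 6, 3, background=5.0)
        s = rng.uniform(0.0, 4.0, 6)  # below w0 everywhere: gradients negative
        st = run_to_convergence(b, s, EstimatorConfig())
        assert np.all(st.x_hat == 0.0)

    def test_starting_at_fixed_point_converges_immediately(self, two_input_basis):
        st = run_to_convergence(two_input_basis, np.array([100.0, 100.0]),
                                x0=np.array([2.475]))
        assert st.converged
        assert st.iter == 1

    def test_nonconvergence_is_flagged_not_raised(self, two_input_basis):
        st = run_to_convergence(two_input_basis, np.array([100.0, 100.0]),
                                EstimatorConfig(max_iters=3))
        assert not st.converged

    def test_loglik_nondecreasing_along_iterates(self, rng):
        # ascent property of the gradient flow at the default (small) rate
        for _ in range(10):
            b, _, s = random_poisson_instance(rng, 8, 3)
            st = run_to_convergence(b, s, EstimatorConfig(max_iters=20_000),
                                    record_loglik=True)
            ll = np.array(st.loglik_trace)
            assert np.all(np.diff(ll) >= -1e-7 * np.abs(ll[:-1]))

    def test_matches_brute_force_likelihood_search(self, rng):
        for _ in range(5):
            b, x_true, s = random_poisson_instance(rng, 8, 2)
            st = run_to_convergence(b, s, EstimatorConfig(tol=1e-11, max_iters=200_000))
            oracle = grid_search_ml(b, s, x_max=2 * x_true.max() + 1)
            scale = max(1.0, np.abs(oracle).max())
            assert np.abs(st.x_hat - oracle).max() / scale < 1e-3

    def test_scale_property_interior_fixed_point(self, rng):
        # with negligible background, scaling the input scales the estimate
        b = random_basis(rng, 8, 3, background=1e-6)
        x_true = rng.uniform(0.5, 2.0, 3)
        s = b.mean_input(x_true)
        x1 = ml_estimate(b, s, max_iters=50_000, tol=1e-13)
        x3 = ml_estimate(b, 3 * s, max_iters=50_000, tol=1e-13)
        assert np.allclose(x3, 3 * x1, rtol=1e-3, atol=1e-6)


class TestMultiplicativeSolver:
    def test_agrees_with_gradient_dynamics(self, rng):
        for _ in range(5):
            b, _, s = random_poisson_instance(rng, 8, 3)
            grad = run_to_convergence(b, s, EstimatorConfig(tol=1e-11,
                                                            max_iters=200_000)).x_hat
            mult = ml_estimate(b, s, max_iters=20_000, tol=1e-13)
            # both approach the same optimum; the slower gradient flow is
            # allowed a finite-iteration gap in parameters, but the
            # likelihoods must agree tightly
            assert np.abs(grad - mult).max() < 1e-2
            ll_g, ll_m = poisson_loglik(b, grad, s), poisson_loglik(b, mult, s)
            assert abs(ll_g - ll_m) <= 1e-6 * max(1.0, abs(ll_m))

    def test_batched_equals_loop(self, rng):
        b, _, _ = random_poisson_instance(rng, 6, 2)
        S = rng.poisson(20.0, size=(5, 6)).astype(float)
        batch = ml_estimate(b, S)
        rows = np.stack([ml_estimate(b, s) for s in S])
        assert np.allclose(batch, rows, atol=1e-8)

    def test_kkt_residual_small_at_solution(self, rng):
        b, _, s = random_poisson_instance(rng, 10, 3)
        x = ml_estimate(b, s, max_iters=50_000, tol=1e-14)
        assert stationarity_residual(b, x, s) < 1e-6


class TestSubtractive:
    def test_fixed_point_unchanged_by_a_step(self, rng):
        b = random_basis(rng, 6, 3)
        x = rng.uniform(0, 2, 3)
        s = b.mean_input(x)
        out = subtractive_step(b, EstimatorState(x), s, EstimatorConfig())
        assert np.allclose(out.x_hat, x)

    def test_unclamped_dynamics_match_closed_form_exactly(self, rng):
        for _ in range(5):
            b, _, s = random_poisson_instance(rng, 10, 3)
            cfg = EstimatorConfig(tol=1e-14, max_iters=100_000,
                                  clamp_nonnegative=False)
            st = run_to_convergence(b, s, cfg, mode="subtractive")
            cf = subtractive_closed_form(b, s, clamp=False)
            assert np.abs(st.x_hat - cf).max() < 1e-8

    def test_closed_form_recovers_noiseless_features(self, rng):
        b = random_basis(rng, 10, 4)
        x_true = rng.uniform(0.2, 2.0, 4)
        assert np.allclose(subtractive_closed_form(b, b.mean_input(x_true)),
                           x_true, atol=1e-9)

    def test_two_input_normal_equations_value(self, two_input_basis):
        x = subtractive_closed_form(two_input_basis, np.array([100.0, 100.0]))
        assert x[0] == pytest.approx(99.0 / 40.0)

    def test_orthogonal_columns_reduce_to_projections(self, rng):
        W = np.zeros((6, 3))
        W[0:2, 0] = [3.0, 4.0]
        W[2:4, 1] = [1.0, 2.0]
        W[4:6, 2] = [5.0, 1.0]
        b = FeatureBasis(W, 0.5)
        s = rng.uniform(0, 50, 6)
        expected = (s - 0.5) @ W / (W**2).sum(axis=0)
        got = subtractive_closed_form(b, s, clamp=False)
        assert np.allclose(got, expected)

    def test_singular_gram_matrix_suggests_ridge(self):
        b = paired_basis(4)  # even-sized paired basis is rank deficient
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            subtractive_closed_form(b, np.full(4, 10.0))
        # and the ridge option resolves it
        out = subtractive_closed_form(b, np.full(4, 10.0), ridge=1e-6)
        assert np.all(np.isfinite(out))

    def test_nnls_matches_clamped_dynamics_fixed_point(self, rng):
        # the projected-gradient fixed point solves the same NNLS program
        b, _, _ = random_poisson_instance(rng, 8, 3)
        s = rng.uniform(0, 10, 8)  # weak input: active clamping likely
        st = run_to_convergence(b, s, EstimatorConfig(tol=1e-13, max_iters=300_000),
                                mode="subtractive")
        assert np.allclose(st.x_hat, subtractive_nnls(b, s), atol=1e-5)

    def test_linear_readout_is_minimum_norm_on_singular_basis(self):
        b = paired_basis(6)
        x = subtractive_linear(b, b.mean_input(np.ones(6)))
        assert np.allclose(b.weights @ x, b.weights @ np.ones(6), atol=1e-9)


class TestLoglik:
    def test_gradient_matches_weighted_fractional_errors(self, rng):
        b, _, s = random_poisson_instance(rng, 7, 3)
        x = rng.uniform(0.2, 1.5, 3)
        analytic = fractional_errors(b, x, s) @ b.weights
        eps = 1e-6
        for i in range(3):
            dx = np.zeros(3)
            dx[i] = eps
            num = (poisson_loglik(b, x + dx, s) - poisson_loglik(b, x - dx, s)) / (2 * eps)
            assert num == pytest.approx(analytic[i], rel=1e-4, abs=1e-6)

    def test_maximal_at_the_ml_estimate(self, rng):
        b, _, s = random_poisson_instance(rng, 8, 2)
        x = ml_estimate(b, s, max_iters=20_000, tol=1e-13)
        ll = poisson_loglik(b, x, s)
        for _ in range(20):
            pert = np.clip(x + rng.normal(0, 0.05, size=2), 0, None)
            assert poisson_loglik(b, pert, s) <= ll + 1e-9

    def test_independent_of_x_when_weights_vanish(self):
        b = FeatureBasis(np.zeros((4, 2)), 3.0)
        s = np.array([1.0, 2.0, 0.0, 5.0])
        assert poisson_loglik(b, np.zeros(2), s) == pytest.approx(
            poisson_loglik(b, np.array([4.0, 7.0]), s))


class TestEffectiveWeights:
    def test_zero_response_gives_w_over_background(self, rng):
        b = random_basis(rng, 6, 3, background=2.0)
        assert np.allclose(effective_weights(b, np.zeros(3)), b.weights / 2.0)

    def test_bounded_by_w_over_background_and_monotone(self, rng):
        b = random_basis(rng, 6, 3, background=2.0)
        r = rng.uniform(0, 2, 3)
        w_eff = effective_weights(b, r)
        assert np.all(w_eff <= b.weights / 2.0 + 1e-12)
        # growing any response shrinks the rows it feeds
        r2 = r.copy()
        r2[0] += 1.0
        w_eff2 = effective_weights(b, r2)
        rows = b.weights[:, 0] > 0
        assert np.all(w_eff2[rows] <= w_eff[rows] + 1e-12)

    def test_doubling_response_halves_weights_when_background_negligible(self, rng):
        b = random_basis(rng, 6, 3, background=1e-9)
        r = rng.uniform(0.5, 2, 3)
        assert np.allclose(effective_weights(b, 2 * r), effective_weights(b, r) / 2,
                           rtol=1e-6)


class TestTraceExport:
    def test_trajectory_written_as_delimited_text(self, tmp_path, two_input_basis):
        st = run_to_convergence(two_input_basis, np.array([100.0, 100.0]),
                                EstimatorConfig(max_iters=50),
                                record_loglik=True, record_trajectory=True)
        path = str(tmp_path / "trace.tsv")
        save_estimator_trace(st, path)
        data = np.genfromtxt(path, delimiter="\t", names=True)
        assert len(data) == len(st.trajectory)
        assert data["x_hat_0"][-1] == pytest.approx(st.x_hat[0])

    def test_export_without_trajectory_raises(self, two_input_basis):
        st = run_to_convergence(two_input_basis, np.array([100.0, 100.0]),
                                EstimatorConfig(max_iters=5))
        with pytest.raises(ValueError, match="trajectory"):
            save_estimator_trace(st, "/tmp/nope.tsv")


class TestValidation:
    def test_dimension_mismatch_raises(self, rng):
        b = random_basis(rng, 6, 3)
        with pytest.raises(ValueError, match="input"):
            fractional_errors(b, np.zeros(3), np.zeros(5))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EstimatorConfig(eta=-1.0)
        with pytest.raises(ValueError):
            EstimatorConfig(max_iters=0)
        with pytest.raises(ValueError):
            EstimatorConfig(tol=0.0)

    def test_unknown_mode_raises(self, two_input_basis):
        with pytest.raises(ValueError):
            run_to_convergence(two_input_basis, np.array([1.0, 1.0]), mode="bayesian")
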