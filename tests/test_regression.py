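"""Closed-form ridge solution and the signal/noise variance split."""

import numpy as np
import pytest

from chd.kernels import KernelSpec, feature_map, kernel_matrix
from chd.regression import (
    fit,
    low_rank_fit,
    predict,
    resolve_gamma,
    signal_to_noise,
)


def random_spd_gram(rng, n):
    a = rng.standard_normal((n, n))
    return a @ a.T / n


class TestSignalToNoise:
    @pytest.mark.parametrize(
        "vs,vn,expected", [(1.0, 1.0, 0.5), (0.0, 0.0, 0.0), (2.0, 0.0, 1.0)]
    )
    def test_values(self, vs, vn, expected):
        assert signal_to_noise(vs, vn) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            signal_to_noise(-1.0, 1.0)


class TestFit:
    def test_identity_gram(self, rng):
        y = rng.standard_normal(8)
        res = fit(np.eye(8), y, gamma=1.0)
        np.testing.assert_allclose(res.coefficients, y / 2)
        assert res.v_signal == pytest.approx(y @ y / 4)
        assert res.v_noise == pytest.approx(y @ y / 4)
        assert res.ratio == pytest.approx(0.5)

    def test_zero_targets(self, rng):
        res = fit(random_spd_gram(rng, 6), np.zeros(6), gamma=0.5)
        np.testing.assert_allclose(res.coefficients, 0.0)
        assert res.v_signal == 0.0 and res.v_noise == 0.0 and res.ratio == 0.0

    def test_objective_minimality_against_perturbations(self, rng):
        """The closed form minimizes ||f||^2 + (1/g)||f(X)-Y||^2 over z."""
        gram = random_spd_gram(rng, 12)
        y = rng.standard_normal(12)
        gamma = 0.7

        def objective(z):
            return z @ gram @ z + (1 / gamma) * np.sum((gram @ z - y) ** 2)

        res = fit(gram, y, gamma)
        base = objective(res.coefficients)
        for _ in range(200):
            z = res.coefficients + rng.standard_normal(12) * rng.uniform(1e-3, 1.0)
            assert objective(z) >= base - 1e-9

    def test_conservation_identity(self, rng):
        """V_signal + V_noise = Y'z on random instances."""
        for n in (5, 20, 60):
            gram = random_spd_gram(rng, n)
            y = rng.standard_normal(n)
            res = fit(gram, y, gamma=rng.uniform(0.05, 2.0))
            total = y @ res.coefficients
            assert res.v_signal + res.v_noise == pytest.approx(total, rel=1e-8)
            assert 0.0 <= res.ratio <= 1.0

    def test_spectral_form_of_noise_ratio(self, rng):
        """Noise share equals the eigenbasis formula sum w_i*g/(l_i+g)."""
        gram = random_spd_gram(rng, 15)
        y = rng.standard_normal(15)
        gamma = 0.3
        res = fit(gram, y, gamma)
        lam, q = np.linalg.eigh(gram)
        c2 = (q.T @ y) ** 2
        weights = c2 / (lam + gamma)
        expected = np.sum(weights * gamma / (lam + gamma)) / np.sum(weights)
        assert 1.0 - res.ratio == pytest.approx(expected, rel=1e-8)

    def test_asymmetric_gram_rejected(self, rng):
        gram = random_spd_gram(rng, 5)
        gram[0, 1] += 1.0
        with pytest.raises(ValueError, match="symmetric"):
            fit(gram, np.ones(5), 1.0)

    def test_nonpositive_gamma_rejected(self, rng):
        with pytest.raises(ValueError, match="gamma"):
            fit(np.eye(3), np.ones(3), 0.0)

    def test_indefinite_gram_rejected(self):
        gram = np.diag([1.0, -5.0])
        with pytest.raises(ValueError, match="positive definite"):
            fit(gram, np.ones(2), 0.5)


class TestResolveGamma:
    def test_auto_is_mean_eigenvalue(self, rng):
        gram = random_spd_gram(rng, 10)
        assert resolve_gamma(gram, "auto") == pytest.approx(np.trace(gram) / 10)

    def test_scaled_auto(self, rng):
        gram = random_spd_gram(rng, 10)
        assert resolve_gamma(gram, "auto:0.1") == pytest.approx(
            0.1 * np.trace(gram) / 10
        )

    def test_numeric_passthrough(self):
        assert resolve_gamma(np.eye(3), 0.25) == 0.25

    def test_unknown_setting_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            resolve_gamma(np.eye(3), "median")


class TestPredict:
    def test_training_rows_residual_identity(self, rng):
        """Predictions on the training rows equal Y - gamma*z exactly."""
        rows = rng.standard_normal((20, 3))
        spec = KernelSpec("quadratic", ("a", "b", "c"))
        gram = kernel_matrix(rows, rows, spec)
        y = rng.standard_normal(20)
        res = fit(gram, y, 0.4, kernel=spec)
        np.testing.assert_allclose(
            predict(res, rows, rows), y - 0.4 * res.coefficients, atol=1e-9
        )

    def test_zero_coefficients_predict_zero(self, rng):
        rows = rng.standard_normal((10, 2))
        spec = KernelSpec("linear", ("a", "b"))
        res = fit(kernel_matrix(rows, rows, spec), np.zeros(10), 1.0, kernel=spec)
        np.testing.assert_allclose(predict(res, rows, rows), 0.0)

    def test_interpolation_limit_on_noiseless_linear_data(self, rng):
        """As gamma -> 0 the ridge fit interpolates exact linear targets."""
        rows = rng.standard_normal((10, 1))
        y = 2.0 * rows[:, 0] + 1.0
        spec = KernelSpec("linear", ("a",))
        gram = kernel_matrix(rows, rows, spec)
        res = fit(gram, y, 1e-12, kernel=spec)
        np.testing.assert_allclose(predict(res, rows, rows), y, atol=1e-6)

    def test_ridge_oracle_equivalence(self, rng):
        """Kernel path agrees with explicit-feature ridge regression."""
        rows = rng.standard_normal((30, 2))
        new = rng.standard_normal((8, 2))
        y = rng.standard_normal(30)
        gamma = 0.6
        spec = KernelSpec("linear", ("a", "b"))
        res = fit(kernel_matrix(rows, rows, spec), y, gamma, kernel=spec)
        phi = feature_map(rows, spec)
        w = np.linalg.solve(phi.T @ phi + gamma * np.eye(phi.shape[1]), phi.T @ y)
        np.testing.assert_allclose(
            predict(res, rows, new), feature_map(new, spec) @ w, atol=1e-8
        )

    def test_missing_kernel_spec_rejected(self, rng):
        res = fit(np.eye(4), np.ones(4), 1.0)
        with pytest.raises(ValueError, match="kernel"):
            predict(res, np.ones((4, 1)), np.ones((2, 1)))


class TestLowRankFit:
    def test_agreement_with_full_gram(self, rng):
        """p x p solve reproduces the N x N solve on a quadratic kernel."""
        rows = rng.standard_normal((50, 4))
        y = rng.standard_normal(50)
        spec = KernelSpec("quadratic", ("a", "b", "c", "d"))
        full = fit(kernel_matrix(rows, rows, spec), y, 0.3)
        low = low_rank_fit(feature_map(rows, spec), y, 0.3)
        assert low.v_signal == pytest.approx(full.v_signal, rel=1e-6)
        assert low.v_noise == pytest.approx(full.v_noise, rel=1e-6)
        assert low.ratio == pytest.approx(full.ratio, rel=1e-6)
        np.testing.assert_allclose(low.coefficients, full.coefficients, atol=1e-8)

    def test_zero_targets(self, rng):
        low = low_rank_fit(rng.standard_normal((12, 3)), np.zeros(12), 1.0)
        assert low.v_signal == 0.0 and low.v_noise == 0.0

    def test_three_point_linear_dataset_matches_full_path(self):
        rows = np.array([[-1.0], [0.0], [2.0]])
        y = np.array([0.5, -0.2, 1.0])
        spec = KernelSpec("linear", ("a",))
        full = fit(kernel_matrix(rows, rows, spec), y, 0.8)
        low = low_rank_fit(feature_map(rows, spec), y, 0.8)
        assert low.ratio == pytest.approx(full.ratio, rel=1e-10)


def test_noise_share_nondecreasing_in_gamma(rng):
    """On random SPD instances the noise share grows with gamma.

    Monotonicity holds when the target's spectral weights are not
    pathologically concentrated on near-null directions; random dense
    SPD Grams with generic targets are in that regime.
    """
    for _ in range(5):
        gram = random_spd_gram(rng, 12) + 0.5 * np.eye(12)
        y = rng.standard_normal(12)
        shares = [
            1.0 - fit(gram, y, g).ratio for g in (0.05, 0.2, 0.8, 3.0, 10.0)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(shares, shares[1:]))
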