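"""Closed-form linear circuit (LC-K) and the SD-shrinkage cubic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ornln.data import ActivityEnsemble, InputError
from ornln.linear import lc_solve, sd_transform, verify_saddle
from ornln.objective import objective, objective_gradients
from ornln.pca import uncentered_pca, variance_in_directions
from ornln.stats import sqrt_psd


class TestSDTransform:
    def test_hand_examples(self):
        # 1 * (1 + 1^2 * 1^2) = 2 and 5 * (1 + 0) = 5
        assert sd_transform(2.0, 1.0) == pytest.approx(1.0, abs=1e-12)
        assert sd_transform(5.0, 0.0) == 5.0

    def test_zero_input(self):
        assert sd_transform(0.0, 2.0) == 0.0

    def test_cube_root_asymptote(self):
        rho = 10.0
        sy = sd_transform(1000.0, rho)
        assert rho**2 * sy**2 >= 100.0
        assert sy == pytest.approx((1000.0 / rho**2) ** (1 / 3), rel=0.01)

    @given(
        st.floats(min_value=0.0, max_value=1e6),
        st.floats(min_value=0.0, max_value=100.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_residual_and_shrinkage(self, sx, rho):
        sy = sd_transform(sx, rho)
        assert sy * (1 + rho**2 * sy**2) == pytest.approx(sx, abs=1e-12 * max(1.0, sx))
        assert 0.0 <= sy <= sx + 1e-12

    def test_nonincreasing_in_rho(self):
        sx = 3.7
        vals = [sd_transform(sx, r) for r in np.linspace(0, 5, 40)]
        assert np.all(np.diff(vals) <= 1e-12)

    def test_array_input(self):
        out = sd_transform(np.array([0.0, 2.0, 5.0]), 1.0)
        assert out.shape == (3,)
        assert out[0] == 0.0 and out[1] == pytest.approx(1.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(InputError):
            sd_transform(-1.0, 1.0)
        with pytest.raises(InputError):
            sd_transform(1.0, -1.0)


class TestLCSolve:
    def test_rho_zero_is_identity_on_y(self, rng):
        ens = ActivityEnsemble(rng.standard_normal((4, 30)))
        params, resp, _ = lc_solve(ens, K=2, rho=0.0)
        assert np.allclose(resp.Y, ens.X)
        assert np.allclose(resp.Z, 0.0)
        assert np.allclose(params.W, 0.0)

    def test_weight_matrices_are_activity_covariances(self, rng):
        ens = ActivityEnsemble(rng.standard_normal((5, 40)))
        params, resp, _ = lc_solve(ens, K=3, rho=1.2)
        T = ens.T
        assert np.allclose(params.W, resp.Y @ resp.Z.T / T, atol=1e-12)
        assert np.allclose(params.M, resp.Z @ resp.Z.T / T, atol=1e-12)

    def test_m_equals_rho_times_sqrt_wtw(self, rng):
        ens = ActivityEnsemble(rng.standard_normal((6, 50)))
        rho = 0.8
        params, _, _ = lc_solve(ens, K=4, rho=rho)
        S = sqrt_psd(params.W.T @ params.W)
        assert np.allclose(params.M, rho * S, rtol=1e-8, atol=1e-12)

    def test_leading_sds_shrunk_trailing_passed_through(self, rng):
        ens = ActivityEnsemble(rng.standard_normal((5, 200)))
        K, rho = 2, 1.5
        params, resp, pca = lc_solve(ens, K, rho)
        vy = variance_in_directions(resp.Y, pca.directions)
        for i in range(K):
            assert np.sqrt(vy[i]) == pytest.approx(sd_transform(pca.sds[i], rho), rel=1e-8)
        assert np.allclose(vy[K:], pca.variances[K:], rtol=1e-8)

    def test_ln_sds_are_rho_times_output_sds(self, rng):
        ens = ActivityEnsemble(rng.standard_normal((4, 80)))
        rho = 2.0
        params, resp, pca = lc_solve(ens, 2, rho)
        sz = np.sqrt(np.mean(resp.Z**2, axis=1))
        sy = np.array([sd_transform(s, rho) for s in pca.sds[:2]])
        assert np.allclose(sz, rho * sy, rtol=1e-8)

    def test_solution_is_stationary(self, rng):
        ens = ActivityEnsemble(rng.standard_normal((4, 30)))
        _, resp, _ = lc_solve(ens, 2, 1.0)
        gY, gZ = objective_gradients(ens.X, resp.Y, resp.Z, 1.0)
        scale = ens.T * np.linalg.norm(ens.X)
        assert np.linalg.norm(gY) <= 1e-10 * scale
        assert np.linalg.norm(gZ) <= 1e-10 * scale

    def test_k_and_t_validation(self, rng):
        ens = ActivityEnsemble(rng.standard_normal((3, 10)))
        with pytest.raises(InputError):
            lc_solve(ens, 0, 1.0)
        with pytest.raises(InputError):
            lc_solve(ens, 4, 1.0)
        tiny = ActivityEnsemble(rng.standard_normal((3, 1)))
        with pytest.raises(InputError):
            lc_solve(tiny, 2, 1.0)


class TestVerifySaddle:
    def test_matches_closed_form_small_instance(self, rng):
        ens = ActivityEnsemble(rng.standard_normal((3, 20)))
        rep = verify_saddle(ens, K=1, rho=1.0, n_starts=3, seed=0, n_iter=3000)
        rel = abs(rep.best_objective - rep.closed_form_objective) / max(
            1.0, abs(rep.closed_form_objective)
        )
        assert rel <= 1e-6
        assert rep.y_distance <= 1e-5
        assert rep.diverged == 0

    def test_rho_zero_rejected(self, rng):
        ens = ActivityEnsemble(rng.standard_normal((3, 10)))
        with pytest.raises(InputError):
            verify_saddle(ens, 1, 0.0)


class TestObjective:
    def test_rho_zero_reduces_to_fidelity(self, rng):
        X = rng.standard_normal((3, 7))
        Y = rng.standard_normal((3, 7))
        Z = rng.standard_normal((2, 7))
        assert objective(X, Y, Z, 0.0) == pytest.approx(0.5 * 7 * np.sum((X - Y) ** 2))

    def test_simplified_form_identity(self, rng):
        X = rng.standard_normal((3, 9))
        Y = rng.standard_normal((3, 9))
        Z = rng.standard_normal((2, 9))
        rho = 1.3
        YtY, ZtZ = Y.T @ Y, Z.T @ Z
        simplified = (
            0.5 * 9 * np.sum((X - Y) ** 2)
            + 0.5 * np.trace(YtY @ ZtZ)
            - np.sum(ZtZ * ZtZ) / (4 * rho**2)
        )
        assert objective(X, Y, Z, rho) == pytest.approx(simplified, rel=1e-12)

    def test_gradients_match_finite_differences(self, rng):
        X = rng.standard_normal((2, 5))
        Y = rng.standard_normal((2, 5))
        Z = rng.standard_normal((2, 5))
        rho = 0.9
        gY, gZ = objective_gradients(X, Y, Z, rho)
        h = 1e-6
        for arr, g in ((Y, gY), (Z, gZ)):
            i, j = 1, 3
            arr[i, j] += h
            up = objective(X, Y, Z, rho)
            arr[i, j] -= 2 * h
            dn = objective(X, Y, Z, rho)
            arr[i, j] += h
            assert (up - dn) / (2 * h) == pytest.approx(g[i, j], rel=1e-4, abs=1e-4)
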