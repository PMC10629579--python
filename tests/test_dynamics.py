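"""Circuit dynamics: linear steady state, ODE integration, rectified iteration."""

import numpy as np
import pytest

from ornln.data import ActivityEnsemble, CircuitParams, InputError
from ornln.dynamics import (
    DynamicsConfig,
    ablate_lnln,
    integrate_linear_dynamics,
    iterate_nonneg_dynamics,
    jacobian_spectral_abscissa,
    respond_ensemble,
    steady_state_linear,
)
from ornln.linear import lc_solve


def _lc_params(rng, D=4, K=2, T=40, rho=1.0, nonneg_input=False):
    X = rng.standard_normal((D, T))
    if nonneg_input:
        X = np.abs(X)
    ens = ActivityEnsemble(X)
    params, resp, _ = lc_solve(ens, K, rho)
    return ens, params, resp


class TestSteadyStateLinear:
    def test_fixed_point_satisfies_circuit_equations(self, rng):
        _, params, _ = _lc_params(rng)
        x = rng.standard_normal(4)
        y, z = steady_state_linear(x, params)
        assert np.allclose(y, x - params.W @ z, atol=1e-12)
        assert np.allclose(params.M @ z, params.rho**2 * params.W.T @ y, atol=1e-10)

    def test_matches_lc_response_columns(self, rng):
        ens, params, resp = _lc_params(rng)
        for t in (0, 7, 23):
            y, z = steady_state_linear(ens.X[:, t], params)
            assert np.allclose(y, resp.Y[:, t], atol=1e-8)
            assert np.allclose(z, resp.Z[:, t], atol=1e-8)

    def test_singular_system_rejected(self):
        params = CircuitParams(W=np.zeros((2, 1)), M=np.zeros((1, 1)), rho=1.0)
        with pytest.raises(InputError):
            steady_state_linear(np.ones(2), params)


class TestODEIntegration:
    def test_endpoint_matches_closed_form(self, rng):
        _, params, _ = _lc_params(rng, rho=1.5)
        a = jacobian_spectral_abscissa(params)
        assert a < 0
        cfg = DynamicsConfig(tol=1e-10, t_max=max(200.0, 40.0 / abs(a)))
        x = rng.standard_normal(4)
        y_ref, z_ref = steady_state_linear(x, params)
        y, z, conv, resid, _ = integrate_linear_dynamics(x, params, cfg)
        assert conv
        assert np.max(np.abs(y - y_ref)) <= 1e-6
        assert np.max(np.abs(z - z_ref)) <= 1e-6

    def test_zero_input_decays_to_rest(self, rng):
        _, params, _ = _lc_params(rng)
        y, z, conv, _, _ = integrate_linear_dynamics(
            np.zeros(4), params, y0=rng.standard_normal(4), z0=rng.standard_normal(2)
        )
        assert conv
        assert np.max(np.abs(y)) <= 1e-6 and np.max(np.abs(z)) <= 1e-6

    def test_nonpositive_leak_rejected(self, rng):
        params = CircuitParams(W=np.ones((2, 1)), M=np.array([[0.0]]), rho=1.0)
        with pytest.raises(InputError):
            integrate_linear_dynamics(np.ones(2), params)


class TestNonnegIteration:
    def test_matches_linear_solve_when_interior_nonneg(self, rng):
        # nonnegative input keeps the top principal direction nonnegative
        # (Perron-Frobenius), so the LC-1 fixed point tends to be interior
        found = 0
        cfg = DynamicsConfig(auto_step=True, tol=1e-10, max_iter=100_000)
        for seed in range(20):
            r = np.random.default_rng(seed)
            _, params, _ = _lc_params(r, D=3, K=1, rho=1.0, nonneg_input=True)
            x = np.abs(r.standard_normal(3))
            y_ref, z_ref = steady_state_linear(x, params)
            if np.all(y_ref >= 0) and np.all(z_ref >= 0):
                found += 1
                y, z, ok, _ = iterate_nonneg_dynamics(x, params, cfg)
                assert ok
                assert np.max(np.abs(y - y_ref)) <= 1e-6
                assert np.max(np.abs(z - z_ref)) <= 1e-6
        assert found >= 3  # the scenario actually occurred

    def test_outputs_nonnegative_and_kkt(self, rng):
        _, params, _ = _lc_params(rng, D=3, K=2, rho=1.0, nonneg_input=True)
        x = np.abs(rng.standard_normal(3))
        cfg = DynamicsConfig(auto_step=True, tol=1e-8, max_iter=50_000)
        y, z, ok, resid = iterate_nonneg_dynamics(x, params, cfg)
        assert ok
        assert np.all(y >= 0) and np.all(z >= 0)
        dy = -y - params.W @ z + x
        dz = -params.M @ z + params.rho**2 * params.W.T @ y
        tol = 1e-8 * (1 + np.linalg.norm(x))
        assert np.all(np.abs(dy[y > 0]) <= tol) and np.all(dy[y == 0] <= tol)
        assert np.all(np.abs(dz[z > 0]) <= tol) and np.all(dz[z == 0] <= tol)

    def test_max_iter_exhaustion_reports_not_converged(self, rng):
        _, params, _ = _lc_params(rng, nonneg_input=True)
        cfg = DynamicsConfig(max_iter=3, tol=1e-12)
        _, _, ok, resid = iterate_nonneg_dynamics(np.ones(4), params, cfg)
        assert not ok and resid > 0


class TestAblation:
    def test_off_diagonal_removed_rest_untouched(self, rng):
        _, params, _ = _lc_params(rng, K=3)
        params = CircuitParams(
            W=params.W, M=params.M + 0.01 * (np.ones((3, 3)) - np.eye(3)), rho=params.rho
        )
        ab = ablate_lnln(params)
        assert np.allclose(ab.M, np.diag(np.diag(params.M)))
        assert np.allclose(ab.W, params.W) and ab.rho == params.rho
        # original untouched
        assert np.any(params.M[~np.eye(3, dtype=bool)] != 0)

    def test_ablation_changes_response(self, rng):
        ens, params, _ = _lc_params(rng, K=3)
        params = CircuitParams(
            W=params.W, M=params.M + 0.05 * (np.ones((3, 3)) - np.eye(3)), rho=params.rho
        )
        r_full = respond_ensemble(ens, params)
        r_abl = respond_ensemble(ens, ablate_lnln(params))
        assert not np.allclose(r_full.Y, r_abl.Y)


class TestRespondEnsemble:
    def test_rho_zero_identity(self, rng):
        ens = ActivityEnsemble(rng.standard_normal((3, 10)))
        params = CircuitParams(W=np.zeros((3, 2)), M=np.eye(2), rho=0.0)
        resp = respond_ensemble(ens, params)
        assert np.allclose(resp.Y, ens.X) and np.allclose(resp.Z, 0.0)

    def test_linear_batch_matches_per_sample(self, rng):
        ens, params, _ = _lc_params(rng)
        resp = respond_ensemble(ens, params)
        assert resp.all_converged
        for t in (0, 5):
            y, z = steady_state_linear(ens.X[:, t], params)
            assert np.allclose(resp.Y[:, t], y, atol=1e-10)
            assert np.allclose(resp.Z[:, t], z, atol=1e-10)

    def test_nonneg_batch_matches_per_sample(self, rng):
        ens, params, _ = _lc_params(rng, D=3, K=1, T=6, rho=1.0, nonneg_input=True)
        params = CircuitParams(W=params.W, M=params.M, rho=1.0, constraint="nonnegative")
        cfg = DynamicsConfig(auto_step=True, tol=1e-10, max_iter=50_000)
        resp = respond_ensemble(ens, params, cfg)
        assert resp.all_converged
        y, z, _, _ = iterate_nonneg_dynamics(ens.X[:, 2], params, cfg)
        assert np.allclose(resp.Y[:, 2], y, atol=1e-8)
        assert np.allclose(resp.Z[:, 2], z, atol=1e-8)
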