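"""Per-sample neural dynamics of the ORN-LN circuit.

For given synaptic parameters (W, M, rho), an input pattern x drives the
coupled dynamics

    tau_y dy/dtau = -y - W z + x
    tau_z dz/dtau = -M z + rho^2 W' y

whose unique fixed point (when M + rho^2 W'W is invertible) is

    z = rho^2 (M + rho^2 W'W)^{-1} W' x,   y = x - W z.

The nonnegative circuit runs the discrete projected iteration

    y <- [y + eps(tau) (-y - W z + x)]_+
    z <- [z + eps(tau) (-M z + rho^2 W' y)]_+

until the boundary-aware fixed-point conditions hold: positive coordinates
have (near-)zero update drive, zero coordinates have non-positive drive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .data import ActivityEnsemble, CircuitParams, CircuitResponse, InputError

__all__ = [
    "DynamicsConfig",
    "steady_state_linear",
    "integrate_linear_dynamics",
    "iterate_nonneg_dynamics",
    "ablate_lnln",
    "respond_ensemble",
    "jacobian_spectral_abscissa",
]

logger = logging.getLogger(__name__)


def _default_schedule(eps0: float = 0.2, tau0: float = 100.0) -> Callable[[int], float]:
    def schedule(tau: int) -> float:
        return eps0 / (1.0 + tau / tau0)

    return schedule


@dataclass
class DynamicsConfig:
    """Numerical settings for the circuit dynamics solvers.

    ``step_size_schedule`` maps the discrete iteration index to a step in
    (0, 1]; the default is the decaying schedule eps0/(1 + tau/tau0) with
    eps0 = 0.2, tau0 = 100.  ``tol`` is the max-norm threshold on the update
    drive (boundary-aware in nonnegative mode).
    """

    tau_y: float = 1.0
    tau_z: float = 1.0
    step_size_schedule: Callable[[int], float] = field(default_factory=_default_schedule)
    max_iter: int = 50_000
    t_max: float = 200.0
    tol: float = 1e-8
    # derive a stable constant step from the drive Jacobian spectrum instead
    # of the decaying schedule (used by the batch NNC solver for speed)
    auto_step: bool = False

    def __post_init__(self) -> None:
        if self.tol <= 0 or self.tau_y <= 0 or self.tau_z <= 0:
            raise InputError("tol and time constants must be positive")


def _system_matrix(params: CircuitParams) -> np.ndarray:
    return params.M + params.rho**2 * (params.W.T @ params.W)


def steady_state_linear(
    x: np.ndarray, params: CircuitParams
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form fixed point of the linear dynamics for one input pattern."""
    x = np.asarray(x, float).ravel()
    W, rho = params.W, params.rho
    A = _system_matrix(params)
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise InputError(
            f"M + rho^2 W'W is singular or ill-conditioned (cond={cond:.3g})"
        )
    logger.debug("steady_state_linear: cond(M + rho^2 W'W) = %.3g", cond)
    z = rho**2 * np.linalg.solve(A, W.T @ x)
    y = x - W @ z
    return y, z


def jacobian_spectral_abscissa(params: CircuitParams, config: DynamicsConfig | None = None) -> float:
    """Largest real part of the linear dynamics Jacobian eigenvalues.

    Negative means the fixed point is exponentially stable.  Stability for
    arbitrary (W, M) is not guaranteed in general; callers can use this to
    flag marginal cases."""
    cfg = config or DynamicsConfig()
    D, K = params.D, params.K
    W, M, rho = params.W, params.M, params.rho
    J = np.zeros((D + K, D + K))
    J[:D, :D] = -np.eye(D) / cfg.tau_y
    J[:D, D:] = -W / cfg.tau_y
    J[D:, :D] = rho**2 * W.T / cfg.tau_z
    J[D:, D:] = -M / cfg.tau_z
    return float(np.max(np.linalg.eigvals(J).real))


def integrate_linear_dynamics(
    x: np.ndarray,
    params: CircuitParams,
    config: DynamicsConfig | None = None,
    y0: np.ndarray | None = None,
    z0: np.ndarray | None = None,
    n_eval: int = 0,
):
    """Numerically integrate the linear ODE from rest (or a given state).

    Returns ``(y, z, converged, residual, trajectory)`` where the residual is
    the max-norm of the update drive at the endpoint and ``trajectory`` is the
    solve_ivp result (with ``n_eval`` evaluation points if requested).
    """
    cfg = config or DynamicsConfig()
    params.require_positive_leaks()
    x = np.asarray(x, float).ravel()
    D, K = params.D, params.K
    W, M, rho = params.W, params.M, params.rho
    y0 = np.zeros(D) if y0 is None else np.asarray(y0, float).ravel()
    z0 = np.zeros(K) if z0 is None else np.asarray(z0, float).ravel()

    def rhs(_t, s):
        y, z = s[:D], s[D:]
        dy = (-y - W @ z + x) / cfg.tau_y
        dz = (-M @ z + rho**2 * W.T @ y) / cfg.tau_z
        return np.concatenate([dy, dz])

    t_eval = np.linspace(0.0, cfg.t_max, n_eval) if n_eval else None
    sol = solve_ivp(
        rhs,
        (0.0, cfg.t_max),
        np.concatenate([y0, z0]),
        method="RK45",
        rtol=min(cfg.tol, 1e-8),
        atol=min(cfg.tol, 1e-8) * 1e-2,
        t_eval=t_eval,
    )
    s = sol.y[:, -1]
    y, z = s[:D], s[D:]
    drive = np.concatenate([-y - W @ z + x, -M @ z + rho**2 * W.T @ y])
    residual = float(np.max(np.abs(drive)))
    converged = residual <= cfg.tol * (1.0 + float(np.linalg.norm(x)))
    if not converged:
        logger.info("linear ODE endpoint not converged (residual %.3g)", residual)
    return y, z, converged, residual, sol


def _nonneg_drives(Y, Z, X, W, M, rho):
    dY = -Y - W @ Z + X
    dZ = -M @ Z + rho**2 * (W.T @ Y)
    return dY, dZ


def _boundary_residuals(Y, Z, dY, dZ):
    """Per-sample max-norm of the KKT violation: positive coordinates must
    have zero drive, zero coordinates non-positive drive."""
    vY = np.where(Y > 0, np.abs(dY), np.maximum(dY, 0.0))
    vZ = np.where(Z > 0, np.abs(dZ), np.maximum(dZ, 0.0))
    return np.maximum(vY.max(axis=0), vZ.max(axis=0))


def _iterate_nonneg_matrix(
    X: np.ndarray,
    params: CircuitParams,
    config: DynamicsConfig,
    Y0: np.ndarray | None = None,
    Z0: np.ndarray | None = None,
):
    """Projected iteration on all samples (columns) at once."""
    params.require_positive_leaks()
    W, M, rho = params.W, params.M, params.rho
    D, T = X.shape
    K = params.K
    Y = np.zeros((D, T)) if Y0 is None else np.array(Y0, float)
    Z = np.zeros((K, T)) if Z0 is None else np.array(Z0, float)
    xnorm = 1.0 + np.linalg.norm(X, axis=0)
    resid = np.full(T, np.inf)
    active = np.ones(T, dtype=bool)
    eps_const = None
    if config.auto_step:
        # drive Jacobian A = [[I, W], [-rho^2 W', M]]; explicit Euler is
        # stable for eps < 2 Re(lam)/|lam|^2 over the eigenvalues of A
        A = np.zeros((D + K, D + K))
        A[:D, :D] = np.eye(D)
        A[:D, D:] = W
        A[D:, :D] = -rho**2 * W.T
        A[D:, D:] = M
        lam = np.linalg.eigvals(A)
        if np.all(lam.real > 0):
            eps_const = float(min(1.0, 0.9 * np.min(2.0 * lam.real / np.abs(lam) ** 2)))
    for tau in range(config.max_iter):
        eps = eps_const if eps_const is not None else config.step_size_schedule(tau)
        dY, dZ = _nonneg_drives(Y[:, active], Z[:, active], X[:, active], W, M, rho)
        Y[:, active] = np.maximum(Y[:, active] + eps * dY, 0.0)
        Z[:, active] = np.maximum(Z[:, active] + eps * dZ, 0.0)
        if tau % 25 == 24 or tau == config.max_iter - 1:
            dY, dZ = _nonneg_drives(Y, Z, X, W, M, rho)
            resid = _boundary_residuals(Y, Z, dY, dZ)
            active = resid > config.tol * xnorm
            if not active.any():
                break
    dY, dZ = _nonneg_drives(Y, Z, X, W, M, rho)
    resid = _boundary_residuals(Y, Z, dY, dZ)
    converged = resid <= config.tol * xnorm
    return Y, Z, converged, resid


def iterate_nonneg_dynamics(
    x: np.ndarray,
    params: CircuitParams,
    config: DynamicsConfig | None = None,
    y0: np.ndarray | None = None,
    z0: np.ndarray | None = None,
):
    """Rectified projected-gradient dynamics for one input pattern.

    Returns ``(y, z, converged, residual)``; ``converged`` is False (never an
    exception) if ``max_iter`` is exhausted.
    """
    cfg = config or DynamicsConfig()
    x = np.asarray(x, float).ravel()
    Y0 = None if y0 is None else np.asarray(y0, float).reshape(-1, 1)
    Z0 = None if z0 is None else np.asarray(z0, float).reshape(-1, 1)
    Y, Z, conv, resid = _iterate_nonneg_matrix(x[:, None], params, cfg, Y0, Z0)
    return Y[:, 0], Z[:, 0], bool(conv[0]), float(resid[0])


def ablate_lnln(params: CircuitParams) -> CircuitParams:
    """Remove LN-LN connections by zeroing the off-diagonal entries of M;
    leaks (diagonal), W and rho are untouched."""
    return params.ablate_lnln()


def respond_ensemble(
    ensemble: ActivityEnsemble,
    params: CircuitParams,
    config: DynamicsConfig | None = None,
) -> CircuitResponse:
    """Run the circuit on every sample of an ensemble.

    Dispatches on ``params.constraint``: the linear path uses the closed-form
    steady state, the nonnegative path the projected iteration.  When rho = 0
    both modes return Y = X, Z = 0.
    """
    cfg = config or DynamicsConfig()
    X = ensemble.X
    T = X.shape[1]
    K = params.K
    if params.rho == 0:
        return CircuitResponse(Y=X.copy(), Z=np.zeros((K, T)))
    if params.constraint == "linear":
        W, rho = params.W, params.rho
        A = _system_matrix(params)
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > 1e12:
            raise InputError(
                f"M + rho^2 W'W is singular or ill-conditioned (cond={cond:.3g})"
            )
        Z = rho**2 * np.linalg.solve(A, W.T @ X)
        Y = X - W @ Z
        drive = np.abs(np.vstack([-Y - W @ Z + X, -params.M @ Z + rho**2 * W.T @ Y]))
        resid = drive.max(axis=0)
        conv = resid <= max(cfg.tol, 1e-10) * (1.0 + np.linalg.norm(X, axis=0))
        return CircuitResponse(Y=Y, Z=Z, converged=conv, residuals=resid)
    Y, Z, conv, resid = _iterate_nonneg_matrix(X, params, cfg)
    n_bad = int((~conv).sum())
    if n_bad:
        logger.info("%d/%d samples did not converge within max_iter", n_bad, T)
    else:
        logger.info("all %d samples converged", T)
    return CircuitResponse(Y=Y, Z=Z, converged=conv, residuals=resid)
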