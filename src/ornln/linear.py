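"""Closed-form solution of the unconstrained (linear) similarity-matching
circuit: the LC-K model.

In the linear circuit with K local neurons, the LN activity encodes the top-K
uncentered principal subspace of the input, and the soma-to-axon map is a
partial zero-phase (ZCA) whitening: the principal directions are preserved
while the leading K standard deviations sigma_X,i are shrunk to the unique
nonnegative root sigma_Y of

    sigma_Y (1 + rho^2 sigma_Y^2) = sigma_X,

the trailing D-K directions pass through unchanged, and the LN standard
deviations are rho * sigma_Y.  The synaptic matrices follow as W = Y Z'/T,
M = Z Z'/T, which makes M = rho * (W'W)^{1/2}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .data import ActivityEnsemble, CircuitParams, CircuitResponse, InputError
from .objective import objective
from .pca import UncenteredPCA, uncentered_pca

__all__ = ["sd_transform", "lc_solve", "verify_saddle", "SaddleReport"]


def _sd_transform_scalar(sigma_x: float, rho: float) -> float:
    if sigma_x == 0.0:
        return 0.0
    if rho == 0.0 or rho**2 * max(sigma_x, 1.0) ** 2 < 1e-30:
        # the cubic term rho^2 s^3 is below the residual tolerance; the root
        # is sigma_x to working precision (and 1/rho^2 would overflow)
        return float(sigma_x)
    # depressed cubic s^3 + p s + q = 0 with p = 1/rho^2, q = -sigma_x/rho^2;
    # p > 0 so there is a single real (and nonnegative) root.  Cardano first,
    # bisection fallback if cancellation spoils the residual.
    p = 1.0 / rho**2
    q = -sigma_x / rho**2
    disc = np.sqrt(q**2 / 4.0 + p**3 / 27.0)
    s = np.cbrt(-q / 2.0 + disc) + np.cbrt(-q / 2.0 - disc)
    # polish with Newton (f strictly increasing, f' >= 1)
    for _ in range(3):
        f = s * (1.0 + rho**2 * s**2) - sigma_x
        s -= f / (1.0 + 3.0 * rho**2 * s**2)
    resid = abs(s * (1.0 + rho**2 * s**2) - sigma_x)
    if not np.isfinite(s) or resid > 1e-12 * max(1.0, sigma_x):
        hi = max(sigma_x, (sigma_x / rho**2) ** (1.0 / 3.0)) + 1.0
        s = brentq(lambda t: t * (1.0 + rho**2 * t**2) - sigma_x, 0.0, hi, xtol=1e-15)
    return float(max(s, 0.0))


def sd_transform(sigma_x, rho: float):
    """Map input PCA standard deviations to output ones (leading directions).

    Solves sigma_Y (1 + rho^2 sigma_Y^2) = sigma_X for the unique nonnegative
    root.  When rho = 0 the output equals the input; for rho^2 sigma_Y^2 >> 1
    the root follows the cube-root asymptote sigma_Y ~ (sigma_X / rho^2)^(1/3).
    Accepts scalars or arrays.
    """
    if rho < 0:
        raise InputError("rho must be nonnegative")
    arr = np.asarray(sigma_x, dtype=float)
    if np.any(arr < 0):
        raise InputError("sigma_x must be nonnegative")
    out = np.array([_sd_transform_scalar(s, rho) for s in np.atleast_1d(arr)])
    return float(out[0]) if arr.ndim == 0 else out.reshape(arr.shape)


def lc_solve(
    ensemble: ActivityEnsemble, K: int, rho: float
) -> tuple[CircuitParams, CircuitResponse, UncenteredPCA]:
    """Closed-form LC-K fit: optimal (W, M, Y, Z) for the given ensemble.

    The LN rotation degree of freedom is fixed to the identity, so z_i aligns
    with the i-th principal direction of the input; Y is unaffected by this
    choice.  Directions with sigma_X,i = 0 pass through unchanged.

    Returns the circuit parameters, the circuit response, and the input's
    uncentered PCA.
    """
    X = ensemble.X
    D, T = X.shape
    if not (1 <= K <= D):
        raise InputError(f"K must satisfy 1 <= K <= D={D}, got {K}")
    if T < K:
        raise InputError(f"need T >= K samples, got T={T}, K={K}")
    pca = uncentered_pca(ensemble)
    U = pca.directions
    sx = pca.sds
    C = U.T @ X  # PCA coordinates of the input
    scale = np.ones(D)
    sy = sx.copy()
    for i in range(K):
        if sx[i] > 0:
            sy[i] = sd_transform(sx[i], rho)
            scale[i] = sy[i] / sx[i]
    C_scaled = C * scale[:, None]
    Y = U @ C_scaled
    Z = rho * C_scaled[:K, :]
    W = Y @ Z.T / T
    M = Z @ Z.T / T
    M = 0.5 * (M + M.T)
    params = CircuitParams(W=W, M=M, rho=rho, constraint="linear")
    response = CircuitResponse(Y=Y, Z=Z)
    return params, response, pca


@dataclass
class SaddleReport:
    """Outcome of the brute-force numerical check of the LC closed form."""

    best_objective: float
    closed_form_objective: float
    y_distance: float  # Frobenius distance of the numerical Y to closed-form Y
    objectives: list
    diverged: int
    n_starts: int


def verify_saddle(
    ensemble: ActivityEnsemble,
    K: int,
    rho: float,
    n_starts: int = 5,
    seed: int = 0,
    n_iter: int = 4000,
) -> SaddleReport:
    """Numerically optimize the saddle objective and compare to ``lc_solve``.

    For each random start, Z is updated by gradient ascent on the reduced
    objective phi(Z) = L(Y*(Z), Z), where the inner minimization over Y is
    solved exactly: Y*(Z) = T X (T I + Z'Z)^{-1}.  This is a test oracle for
    the closed form, not a user-facing solver; divergent starts are reported,
    never raised.
    """
    if rho <= 0:
        raise InputError("verify_saddle needs rho > 0")
    X = ensemble.X
    D, T = X.shape
    rng = np.random.default_rng(seed)
    _, resp, _ = lc_solve(ensemble, K, rho)
    obj_cf = objective(X, resp.Y, resp.Z, rho)
    best_obj, best_Y = -np.inf, None
    objectives, diverged = [], 0
    scale = np.linalg.norm(X) / np.sqrt(T) + 1e-12

    def inner_y(Z: np.ndarray) -> np.ndarray:
        # exact argmin over Y: Y = T X (T I_T + Z'Z)^{-1}, via the K x K
        # Woodbury form (I - Z'(T I_K + Z Z')^{-1} Z)
        G = T * np.eye(K) + Z @ Z.T
        return X - (X @ Z.T) @ np.linalg.solve(G, Z)

    for _ in range(n_starts):
        Z = rho * scale * rng.standard_normal((K, T)) * 0.5
        for _ in range(n_iter):
            Y = inner_y(Z)
            ZZt = Z @ Z.T
            YZt = Y @ Z.T
            gZ = YZt.T @ Y - (ZZt @ Z) / rho**2
            lam = (
                np.linalg.norm(Y @ Y.T, 2)
                + 3.0 * np.linalg.norm(ZZt, 2) / rho**2
            )
            Z = Z + (0.9 / max(lam, 1e-12)) * gZ
            if not np.all(np.isfinite(Z)):
                break
        if not np.all(np.isfinite(Z)):
            diverged += 1
            objectives.append(float("nan"))
            continue
        Y = inner_y(Z)
        val = objective(X, Y, Z, rho)
        objectives.append(val)
        if val > best_obj:
            best_obj, best_Y = val, Y
    y_dist = float("nan") if best_Y is None else float(np.linalg.norm(best_Y - resp.Y))
    return SaddleReport(
        best_objective=best_obj,
        closed_form_objective=obj_cf,
        y_distance=y_dist,
        objectives=objectives,
        diverged=diverged,
        n_starts=n_starts,
    )
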