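"""The similarity-matching min-max objective shared by the linear and
nonnegative circuits.

The circuit output (Y, Z) for input X solves

    min_Y max_Z  (T/2)|X - Y|_F^2 - (rho^2/4)|Y'Y - (1/rho^2) Z'Z|_F^2
                 + (rho^2/4)|Y'Y|_F^2

optionally subject to Y >= 0, Z >= 0.  The first term anchors axonal activity
to the somatic input; the similarity-matching terms couple sample-by-sample
inner products of Y and Z and are what the reciprocal ORN-LN and LN-LN
synapses implement.  Expanding the squares, the objective simplifies to

    (T/2)|X - Y|^2 + (1/2) tr(Y'Y Z'Z) - (1/(4 rho^2))|Z'Z|^2,

whose stationarity conditions are exactly the circuit fixed point
y = x - W z, M z = rho^2 W' y with W = Y Z'/T and M = Z Z'/T.
"""

from __future__ import annotations

import numpy as np

__all__ = ["objective", "objective_gradients"]


def objective(X: np.ndarray, Y: np.ndarray, Z: np.ndarray, rho: float) -> float:
    """Evaluate the similarity-matching saddle objective L(Y, Z)."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    Z = np.asarray(Z, float)
    T = X.shape[1]
    fro2 = lambda A: float(np.sum(A * A))
    YtY = Y.T @ Y
    ZtZ = Z.T @ Z
    if rho == 0:
        # the two rho^2/4 terms vanish identically
        return 0.5 * T * fro2(X - Y)
    return (
        0.5 * T * fro2(X - Y)
        - 0.25 * rho**2 * fro2(YtY - ZtZ / rho**2)
        + 0.25 * rho**2 * fro2(YtY)
    )


def objective_gradients(
    X: np.ndarray, Y: np.ndarray, Z: np.ndarray, rho: float
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of L with respect to Y (descent direction) and Z (ascent).

    Uses the simplified form: dL/dY = -T(X - Y) + Y Z'Z,
    dL/dZ = Z Y'Y - (1/rho^2) Z Z'Z.
    """
    T = X.shape[1]
    ZtZ = Z.T @ Z
    gY = -T * (X - Y) + Y @ ZtZ
    gZ = Z @ (Y.T @ Y) - (Z @ ZtZ) / rho**2
    return gY, gZ
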