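"""Offline solver for the nonnegative circuit (NNC-K).

With nonnegativity constraints on axonal (Y) and LN (Z) activity, the
similarity-matching problem has no closed form; the LN layer performs
symmetric nonnegative matrix factorization of the axonal activity, i.e. a
soft clustering where z encodes cluster memberships and the columns of W
point toward cluster locations.

The solver alternates (i) running the projected circuit dynamics per sample
to convergence for the current (W, M), and (ii) the batch weight assignment
W <- Y Z'/T, M <- Z Z'/T, from several random restarts.  The dynamics plus
Hebbian assignment is the circuit's own online algorithm run in batch; no
monotone-descent guarantee is claimed, and non-identical restart optima are
surfaced in the report, never averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import ActivityEnsemble, CircuitParams, CircuitResponse, InputError
from .dynamics import DynamicsConfig, _iterate_nonneg_matrix
from .objective import objective

__all__ = ["objective", "nnc_solve", "cluster_labels", "SolveReport"]

logger = logging.getLogger(__name__)

_LEAK_FLOOR = 1e-9  # keeps dynamics well-posed if an LN goes silent


@dataclass
class SolveReport:
    """Restart-level diagnostics of an NNC solve."""

    objectives: list
    converged: list
    epochs: list
    selected: int
    seed: int

    @property
    def objective_spread(self) -> float:
        vals = [v for v in self.objectives if np.isfinite(v)]
        return float(np.max(vals) - np.min(vals)) if vals else float("nan")


def nnc_solve(
    ensemble: ActivityEnsemble,
    K: int,
    rho: float,
    n_restarts: int = 10,
    max_epochs: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
    dyn_config: DynamicsConfig | None = None,
    damping: float = 0.5,
) -> tuple[CircuitParams, CircuitResponse, SolveReport]:
    """Fit the NNC-K to a nonnegative ensemble by alternating optimization.

    Each restart initializes W with rectified Gaussian entries scaled by
    1/sqrt(D) and M with the identity, then alternates dynamics and the
    damped batch weight assignment W <- W + damping (Y Z'/T - W) (likewise
    for M; the undamped replacement oscillates) until the relative
    fixed-point residual max(|Y Z'/T - W|/|W|, |Z Z'/T - M|/|M|) drops below
    ``tol``.  Because the objective is maximized over Z, the restart with
    the highest objective value at its fixed point is the one whose LN layer
    extracts the most structure; it is returned.  Duplicated W columns for K
    larger than the number of clusters are expected behavior, not an error.
    """
    X = ensemble.X
    if np.any(X < 0):
        raise InputError("NNC input must be nonnegative")
    if K < 1 or rho <= 0:
        raise InputError("need K >= 1 and rho > 0")
    D, T = X.shape
    cfg = dyn_config or DynamicsConfig(tol=1e-8, max_iter=20_000, auto_step=True)
    rng = np.random.default_rng(seed)
    scale = float(np.sqrt((X**2).mean()))

    best = None
    objectives, conv_flags, epoch_counts = [], [], []
    for r in range(n_restarts):
        W = np.maximum(rng.standard_normal((D, K)), 0.0) * scale / np.sqrt(D)
        M = np.eye(K) * max(scale**2, 1.0)
        Y = np.zeros((D, T))
        Z = np.zeros((K, T))
        converged = False
        epoch = 0
        for epoch in range(1, max_epochs + 1):
            params = CircuitParams(W=W, M=M, rho=rho, constraint="nonnegative")
            # warm-start dynamics from the previous epoch's activities
            Y, Z, _, _ = _iterate_nonneg_matrix(X, params, cfg, Y, Z)
            W_tgt = Y @ Z.T / T
            M_tgt = Z @ Z.T / T
            dW = np.linalg.norm(W_tgt - W) / max(np.linalg.norm(W), 1e-30)
            dM = np.linalg.norm(M_tgt - M) / max(np.linalg.norm(M), 1e-30)
            W = W + damping * (W_tgt - W)
            M = M + damping * (M_tgt - M)
            M = 0.5 * (M + M.T)
            np.fill_diagonal(M, np.maximum(np.diag(M), _LEAK_FLOOR))
            if max(dW, dM) <= tol:
                converged = True
                break
        val = objective(X, Y, Z, rho)
        objectives.append(float(val))
        conv_flags.append(converged)
        epoch_counts.append(epoch)
        logger.info(
            "restart %d: objective %.6g, %sconverged in %d epochs",
            r, val, "" if converged else "NOT ", epoch,
        )
        if best is None or val > best[0]:
            params = CircuitParams(W=W, M=M, rho=rho, constraint="nonnegative")
            Yf, Zf, cflags, resid = _iterate_nonneg_matrix(X, params, cfg)
            best = (val, params, CircuitResponse(Y=Yf, Z=Zf, converged=cflags, residuals=resid))

    selected = int(np.nanargmax(objectives))
    if not any(conv_flags):
        logger.warning("no NNC restart converged; returning best-effort result")
    report = SolveReport(
        objectives=objectives,
        converged=conv_flags,
        epochs=epoch_counts,
        selected=selected,
        seed=seed,
    )
    return best[1], best[2], report


def cluster_labels(Z: np.ndarray) -> np.ndarray:
    """Per-sample soft-cluster assignment: the argmax LN of each column.

    All-zero columns are labeled -1 (unassigned); ties go to the smallest
    LN index.
    """
    Z = np.asarray(Z, float)
    if np.any(Z < 0):
        raise InputError("Z must be nonnegative")
    labels = np.argmax(Z, axis=0).astype(int)
    labels[np.all(Z == 0, axis=0)] = -1
    return labels
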