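"""Online, unsupervised Hebbian learning of the circuit weights.

After each stimulus presentation the circuit is run to steady state (the
stimulus is assumed present long enough for the neural dynamics to converge),
then the synapses are updated with the local Hebbian/anti-Hebbian rules

    W <- W + eps1 (y z' - W)
    M <- M + eps2 (z z' - M),

which drive (W, M) toward the offline optimum W = E[y z'], M = E[z z'].
ORN->LN and LN->ORN updates are Hebbian in (y, z); LN-LN updates are Hebbian
in z and act as anti-Hebbian inhibition through the dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np

from .data import ActivityEnsemble, CircuitParams, InputError
from .dynamics import DynamicsConfig, iterate_nonneg_dynamics, steady_state_linear
from .objective import objective

__all__ = ["hebbian_update", "train_online", "TrainingConfig", "TrainingHistory"]

logger = logging.getLogger(__name__)

_LEAK_FLOOR = 1e-6


def hebbian_update(
    W: np.ndarray,
    M: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    eps1: float,
    eps2: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One Hebbian step on (W, M) from a converged activity pair (y, z).

    Symmetry of M is preserved because z z' is symmetric.
    """
    if not (0 < eps1 <= 1 and 0 < eps2 <= 1):
        raise InputError("learning rates must lie in (0, 1]")
    y = np.asarray(y, float).reshape(-1, 1)
    z = np.asarray(z, float).reshape(-1, 1)
    W_new = W + eps1 * (y @ z.T - W)
    M_new = M + eps2 * (z @ z.T - M)
    return W_new, M_new


def _default_rate(a: float = 0.05, b: float = 500.0) -> Callable[[int], float]:
    def rate(t: int) -> float:
        return a / (1.0 + t / b)

    return rate


@dataclass
class TrainingConfig:
    """Settings for online training; learning rates follow a/(1 + t/b)."""

    eps1: Callable[[int], float] = field(default_factory=_default_rate)
    eps2: Callable[[int], float] = field(default_factory=_default_rate)
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    max_retries: int = 2  # on dynamics non-convergence, retry with halved step
    record_every: int = 1  # epochs between history snapshots


@dataclass
class TrainingHistory:
    """Weight and objective trajectories recorded during training."""

    epochs: list = field(default_factory=list)
    W_snapshots: list = field(default_factory=list)
    M_snapshots: list = field(default_factory=list)
    objective: list = field(default_factory=list)
    skipped: int = 0


def train_online(
    data: ActivityEnsemble | Iterable[np.ndarray],
    K: int,
    rho: float,
    mode: str = "linear",
    config: TrainingConfig | None = None,
    n_epochs: int = 20,
    seed: int = 0,
    W0: np.ndarray | None = None,
    M0: np.ndarray | None = None,
) -> tuple[CircuitParams, TrainingHistory]:
    """Learn (W, M) by stimulus presentations with Hebbian updates.

    With an :class:`ActivityEnsemble`, each epoch is one seeded shuffled pass
    over the samples; a generic iterable of patterns is consumed once in
    arrival order (streaming mode).  The diagonal of M (LN leaks) is clamped
    at a small positive floor so the dynamics stay well posed early in
    training; W is left sign-unconstrained even in nonnegative mode, where it
    inherits nonnegativity from y, z >= 0.
    """
    if mode not in ("linear", "nonnegative"):
        raise InputError(f"unknown mode {mode!r}")
    cfg = config or TrainingConfig()
    rng = np.random.default_rng(seed)
    streaming = not isinstance(data, ActivityEnsemble)
    if streaming:
        stream = iter(data)
        first = np.asarray(next(stream), float).ravel()
        D = first.shape[0]
    else:
        X = data.X
        if mode == "nonnegative" and np.any(X < 0):
            raise InputError("nonnegative mode requires nonnegative input")
        D, T = X.shape
    scale = 1.0 if streaming else float(np.sqrt((X**2).mean()))
    W = (
        np.array(W0, float)
        if W0 is not None
        else np.maximum(rng.standard_normal((D, K)), 0.0) * scale / np.sqrt(D)
    )
    M = np.array(M0, float) if M0 is not None else np.eye(K) * max(scale**2, 1e-2)
    history = TrainingHistory()
    t = 0

    def present(x: np.ndarray) -> bool:
        nonlocal W, M, t
        params = CircuitParams(W=W, M=M, rho=rho, constraint=mode)
        if mode == "linear":
            y, z = steady_state_linear(x, params)
            ok = True
        else:
            dyn = cfg.dynamics
            ok = False
            for retry in range(cfg.max_retries + 1):
                y, z, ok, _ = iterate_nonneg_dynamics(x, params, dyn)
                if ok:
                    break
                if dyn.auto_step:
                    # the constant step already satisfies the stability bound;
                    # non-convergence means a slow mode, so retry longer
                    dyn = DynamicsConfig(
                        tau_y=dyn.tau_y,
                        tau_z=dyn.tau_z,
                        max_iter=4 * dyn.max_iter,
                        tol=dyn.tol,
                        auto_step=True,
                    )
                else:
                    e0 = dyn.step_size_schedule(0) / 2.0
                    dyn = DynamicsConfig(
                        tau_y=dyn.tau_y,
                        tau_z=dyn.tau_z,
                        step_size_schedule=_default_rate(e0, 100.0),
                        max_iter=dyn.max_iter,
                        tol=dyn.tol,
                    )
            if not ok:
                return False
        W, M = hebbian_update(W, M, y, z, cfg.eps1(t), cfg.eps2(t))
        M = 0.5 * (M + M.T)
        np.fill_diagonal(M, np.maximum(np.diag(M), _LEAK_FLOOR))
        t += 1
        return True

    if streaming:
        present(first)
        for x in stream:
            if not present(np.asarray(x, float).ravel()):
                history.skipped += 1
        history.epochs.append(0)
        history.W_snapshots.append(W.copy())
        history.M_snapshots.append(M.copy())
    else:
        for epoch in range(n_epochs):
            order = rng.permutation(T)
            for j in order:
                if not present(X[:, j]):
                    history.skipped += 1
                    logger.info("presentation skipped after retries (epoch %d)", epoch)
            if epoch % cfg.record_every == 0 or epoch == n_epochs - 1:
                history.epochs.append(epoch)
                history.W_snapshots.append(W.copy())
                history.M_snapshots.append(M.copy())
                try:
                    params = CircuitParams(W=W, M=M, rho=rho, constraint=mode)
                    from .dynamics import respond_ensemble

                    resp = respond_ensemble(data, params, cfg.dynamics)
                    history.objective.append(objective(X, resp.Y, resp.Z, rho))
                except InputError:
                    history.objective.append(float("nan"))
    params = CircuitParams(W=W, M=M, rho=rho, constraint=mode)
    return params, history
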