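"""Core domain containers for activity ensembles and circuit parameterizations.

The circuit transforms activity patterns of D olfactory receptor neuron (ORN)
somas, ``x(t)``, into activity patterns of the D ORN axons, ``y(t)``, and of K
inhibitory local neurons (LNs), ``z(t)``.  An :class:`ActivityEnsemble` holds
T such patterns as the columns of a D x T matrix; :class:`CircuitParams` holds
the synaptic parameterization (W, M, rho); :class:`CircuitResponse` holds the
converged circuit outputs with per-sample convergence diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ActivityEnsemble",
    "CircuitParams",
    "CircuitResponse",
    "InputError",
]


class InputError(ValueError):
    """Raised when user-supplied data violates a documented precondition."""


def _as_label_list(labels: Sequence | None, n: int, prefix: str) -> list[str]:
    if labels is None:
        return [f"{prefix}{i}" for i in range(n)]
    out = [str(l) if not isinstance(l, tuple) else l for l in labels]
    if len(out) != n:
        raise InputError(f"expected {n} {prefix!r} labels, got {len(out)}")
    return out


@dataclass
class ActivityEnsemble:
    """A labeled D x T matrix of activity patterns.

    Parameters
    ----------
    X : ndarray, shape (D, T)
        Activity matrix; rows are channels (ORNs), columns are samples
        (odor x dilution conditions).  Units are arbitrary activity units
        (e.g. dF/F0).
    channel_labels : sequence of str, optional
        Length-D channel names; auto-generated when omitted.
    sample_labels : sequence, optional
        Length-T sample names; plain strings or (odorant, dilution) tuples.
    nonneg : bool
        Declares the ensemble nonnegative; enforced at construction.
    """

    X: np.ndarray
    channel_labels: list = field(default=None)  # type: ignore[assignment]
    sample_labels: list = field(default=None)  # type: ignore[assignment]
    nonneg: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
            raise InputError(f"X must be a 2-D matrix with D,T >= 1, got shape {X.shape}")
        if not np.all(np.isfinite(X)):
            raise InputError("X contains non-finite entries")
        if self.nonneg and np.any(X < 0):
            raise InputError("ensemble declared nonnegative but X has negative entries")
        self.X = X
        self.channel_labels = _as_label_list(self.channel_labels, X.shape[0], "ch")
        self.sample_labels = _as_label_list(self.sample_labels, X.shape[1], "s")

    @property
    def D(self) -> int:
        return self.X.shape[0]

    @property
    def T(self) -> int:
        return self.X.shape[1]

    def with_matrix(self, X: np.ndarray, nonneg: bool | None = None) -> "ActivityEnsemble":
        """Return a new ensemble with the same labels but a different matrix."""
        return ActivityEnsemble(
            X,
            channel_labels=list(self.channel_labels),
            sample_labels=list(self.sample_labels),
            nonneg=self.nonneg if nonneg is None else nonneg,
            meta=dict(self.meta),
        )


_M_SYM_RTOL = 1e-10


@dataclass
class CircuitParams:
    """Synaptic parameterization (W, M, rho) of the ORN-LN circuit.

    The k-th column of W is proportional to the ORNs <-> LN_k connection
    weight vector: feedforward ORN->LN weights are rho^2 * W and feedback
    LN->ORN weights are W.  Off-diagonal entries of M are LN-LN inhibitory
    weights; the diagonal entries encode LN leaks.  ``rho`` sets the ratio of
    feedback-inhibition to feedforward-excitation strength.
    """

    W: np.ndarray
    M: np.ndarray
    rho: float
    constraint: str = "linear"  # "linear" | "nonnegative"

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        M = np.asarray(self.M, dtype=float)
        if W.ndim != 2:
            raise InputError("W must be a D x K matrix")
        D, K = W.shape
        if K < 1:
            raise InputError("K must be >= 1")
        if M.shape != (K, K):
            raise InputError(f"M must be {K}x{K} to match W, got {M.shape}")
        scale = max(np.max(np.abs(M)), 1.0)
        if np.max(np.abs(M - M.T)) > _M_SYM_RTOL * scale:
            raise InputError("M must be symmetric (within 1e-10 relative)")
        M = 0.5 * (M + M.T)
        if self.rho < 0:
            raise InputError("rho must be nonnegative")
        if self.constraint not in ("linear", "nonnegative"):
            raise InputError(f"unknown constraint mode {self.constraint!r}")
        self.W, self.M = W, M

    @property
    def D(self) -> int:
        return self.W.shape[0]

    @property
    def K(self) -> int:
        return self.W.shape[1]

    def require_positive_leaks(self) -> None:
        """Dynamics need strictly positive LN leaks (diag of M) to be well posed."""
        if np.any(np.diag(self.M) <= 0):
            raise InputError("diag(M) must be > 0 for circuit dynamics")

    def ablate_lnln(self) -> "CircuitParams":
        """Remove LN-LN connections: zero off-diagonal entries of M."""
        M = np.diag(np.diag(self.M)).copy()
        return replace(self, M=M)


@dataclass
class CircuitResponse:
    """Converged circuit outputs Y (ORN axons) and Z (LNs) for an ensemble."""

    Y: np.ndarray
    Z: np.ndarray
    converged: np.ndarray = None  # type: ignore[assignment]
    residuals: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        T = self.Y.shape[1]
        if self.Z.shape[1] != T:
            raise InputError("Y and Z must have the same number of samples")
        if self.converged is None:
            self.converged = np.ones(T, dtype=bool)
        else:
            self.converged = np.asarray(self.converged, dtype=bool)
        if self.residuals is None:
            self.residuals = np.zeros(T)
        else:
            self.residuals = np.asarray(self.residuals, dtype=float)
        if self.converged.shape != (T,) or self.residuals.shape != (T,):
            raise InputError("convergence metadata must have one entry per sample")

    @property
    def all_converged(self) -> bool:
        return bool(np.all(self.converged))
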