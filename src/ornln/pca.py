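"""Uncentered PCA and elementary representation metrics.

All principal-component analysis in this package is *uncentered*: the
eigendecomposition of the second-moment matrix X X^T / T, with no mean
subtraction.  Downstream neurons experience raw (uncentered) activity, so the
relevant variance structure is that of the second moment.  A centered variant
is deliberately not provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import ActivityEnsemble, InputError

__all__ = [
    "UncenteredPCA",
    "uncentered_pca",
    "cv_of_variances",
    "pattern_magnitudes",
    "channel_and_pattern_correlations",
    "variance_in_directions",
]


@dataclass
class UncenteredPCA:
    """Orthonormal directions and variances of the second-moment matrix.

    ``directions`` is D x D with columns u_i; ``variances`` are the
    eigenvalues sigma_i^2 of X X^T / T in nonincreasing order; ``sds`` are
    their square roots sigma_i.
    """

    directions: np.ndarray
    variances: np.ndarray

    @property
    def sds(self) -> np.ndarray:
        return np.sqrt(np.clip(self.variances, 0.0, None))

    @property
    def D(self) -> int:
        return self.directions.shape[0]


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    U = U.copy()
    for j in range(U.shape[1]):
        col = U[:, j]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            U[:, j] = -col
    return U


def _order_ties(U: np.ndarray, lam: np.ndarray, rtol: float = 1e-12) -> np.ndarray:
    """Within groups of (numerically) equal eigenvalues, order columns
    lexicographically descending by their entries, so degenerate spectra get a
    reproducible direction order (e.g. an isotropic 2-D cloud yields the
    identity basis in natural order)."""
    scale = max(lam[0], 1.0) if lam.size else 1.0
    order = np.arange(U.shape[1])
    i = 0
    while i < lam.size:
        j = i + 1
        while j < lam.size and abs(lam[j] - lam[i]) <= rtol * scale:
            j += 1
        if j - i > 1:
            block = order[i:j]
            keys = [tuple(-U[:, k]) for k in block]  # descending lexicographic
            block = [b for _, b in sorted(zip(keys, block))]
            order[i:j] = block
        i = j
    return U[:, order]


def uncentered_pca(ensemble: ActivityEnsemble | np.ndarray) -> UncenteredPCA:
    """Eigendecomposition of X X^T / T with deterministic tie and sign rules.

    Variances are sorted descending; within exact ties, columns are ordered
    lexicographically; each direction's sign is fixed so its largest-magnitude
    entry is positive.
    """
    X = ensemble.X if isinstance(ensemble, ActivityEnsemble) else np.asarray(ensemble, float)
    if not np.all(np.isfinite(X)):
        raise InputError("activity matrix contains non-finite entries")
    D, T = X.shape
    S = X @ X.T / T
    S = 0.5 * (S + S.T)
    lam, U = np.linalg.eigh(S)
    idx = np.argsort(-lam, kind="stable")
    lam, U = lam[idx], U[:, idx]
    lam = np.clip(lam, 0.0, None)
    U = _fix_signs(U)
    U = _order_ties(U, lam)
    return UncenteredPCA(directions=U, variances=lam)


def cv_of_variances(variances) -> float:
    """Coefficient of variation CV_sigma = SD[{sigma_i^2}] / mean[{sigma_i^2}].

    Zero means a perfectly white (variance-equalized) representation.  Uses
    the population standard deviation (divide by n).
    """
    v = np.asarray(variances, dtype=float)
    if np.any(v < 0):
        raise InputError("variances must be nonnegative")
    m = v.mean()
    if m == 0:
        raise InputError("CV undefined: all variances are zero")
    return float(v.std() / m)


def pattern_magnitudes(ensemble: ActivityEnsemble | np.ndarray) -> np.ndarray:
    """Euclidean norm of each activity pattern (column); a proxy for the
    total activity all channels produce in response to one stimulus."""
    X = ensemble.X if isinstance(ensemble, ActivityEnsemble) else np.asarray(ensemble, float)
    return np.linalg.norm(X, axis=0)


def _safe_corrcoef(A: np.ndarray, what: str) -> np.ndarray:
    """Pearson correlation between rows of A; constant rows give NaN entries
    (reported with a warning), never zeros."""
    sd = A.std(axis=1)
    if np.all(sd == 0):
        raise InputError(f"all {what} are constant; correlations undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(A)
    R = np.atleast_2d(R)
    if np.any(sd == 0):
        warnings.warn(
            f"{int((sd == 0).sum())} constant {what}: correlation entries set to NaN",
            RuntimeWarning,
            stacklevel=3,
        )
        bad = sd == 0
        R[bad, :] = np.nan
        R[:, bad] = np.nan
    np.fill_diagonal(R, 1.0)
    return R


def channel_and_pattern_correlations(
    ensemble: ActivityEnsemble | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation matrices between channels (rows) and between
    activity patterns (columns).

    Correlations are the classical centered Pearson coefficients even though
    PCA elsewhere is uncentered.  Constant channels/patterns yield NaN rows
    and columns with a warning.
    """
    X = ensemble.X if isinstance(ensemble, ActivityEnsemble) else np.asarray(ensemble, float)
    D, T = X.shape
    if D < 2 or T < 2:
        raise InputError("need D >= 2 and T >= 2 for correlation matrices")
    return _safe_corrcoef(X, "channels"), _safe_corrcoef(X.T, "patterns")


def variance_in_directions(
    ensemble: ActivityEnsemble | np.ndarray, directions: np.ndarray
) -> np.ndarray:
    """Mean squared projection of the samples onto each (orthonormal) direction.

    With the ensemble's own uncentered PCA directions this recovers the PCA
    variances; with another ensemble's directions it shows how variance is
    redistributed by a transformation.
    """
    X = ensemble.X if isinstance(ensemble, ActivityEnsemble) else np.asarray(ensemble, float)
    U = np.asarray(directions, dtype=float)
    if U.ndim == 1:
        U = U[:, None]
    G = U.T @ U
    if np.max(np.abs(G - np.eye(U.shape[1]))) > 1e-8:
        raise InputError("directions must be orthonormal (within 1e-8)")
    proj = U.T @ X
    return (proj**2).mean(axis=1)
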