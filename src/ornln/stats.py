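"""Connectivity-activity and connectivity-connectivity statistics.

Generic operations for comparing synaptic weight matrices with activity
ensembles and with each other: per-type averaging of connection vectors,
connectivity tuning curves, entry-shuffle permutation tests with
Benjamini-Hochberg FDR control, the M ~ (W'W)^{1/2} relation test, mean
rectified correlation, principal-angle subspace alignment, and hierarchical
column ordering.

Permutation p-values use the add-one estimator (1 + #{null >= observed}) /
(n_perm + 1), switching to exact enumeration over all D! entry permutations
whenever D! <= n_perm.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.linalg import subspace_angles
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .data import ActivityEnsemble, InputError

__all__ = [
    "PermutationTestResult",
    "type_average",
    "tuning_curve",
    "perm_test_correlations",
    "bh_fdr",
    "sqrt_psd",
    "mw_relation_test",
    "mean_rectified_correlation",
    "subspace_alignment",
    "hierarchical_order",
]

logger = logging.getLogger(__name__)


@dataclass
class PermutationTestResult:
    observed: np.ndarray
    pvalues: np.ndarray
    n_perm: int
    sidedness: str  # "one_sided_greater" | "two_sided"
    fdr_flags: np.ndarray
    fdr_q: float
    seed: int
    exact: bool = False


def type_average(W: np.ndarray, labels) -> tuple[np.ndarray, list]:
    """Column-wise mean of W per distinct label, in order of first appearance.

    This is the per-LN-type average of connection vectors: w_type =
    (1/n) sum of the w vectors of that type's LNs.
    """
    W = np.asarray(W, float)
    labels = list(labels)
    if len(labels) != W.shape[1]:
        raise InputError("one label per column required")
    seen: list = []
    for l in labels:
        if l not in seen:
            seen.append(l)
    cols = [W[:, [i for i, l in enumerate(labels) if l == t]].mean(axis=1) for t in seen]
    return np.column_stack(cols), seen


def _pearson_to_columns(w: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Pearson r between a vector and each column of A (constant columns -> nan)."""
    w = w - w.mean()
    sw = np.linalg.norm(w)
    Ac = A - A.mean(axis=0, keepdims=True)
    sa = np.linalg.norm(Ac, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (w @ Ac) / (sw * sa)
    return r


def tuning_curve(w: np.ndarray, ensemble: ActivityEnsemble) -> list:
    """Connectivity tuning curve: Pearson r of a connection vector against
    every activity pattern, sorted in decreasing order of r.

    Returns a list of (sample_label, r) pairs.
    """
    w = np.asarray(w, float).ravel()
    if w.size < 3:
        raise InputError("need D >= 3")
    if np.ptp(w) == 0:
        raise InputError("constant connection vector: correlation undefined")
    r = _pearson_to_columns(w, ensemble.X)
    order = np.argsort(-r, kind="stable")
    return [(ensemble.sample_labels[i], float(r[i])) for i in order]


def _null_correlations(w: np.ndarray, A: np.ndarray, n_perm: int, rng) -> tuple[np.ndarray, bool]:
    """Correlations of entry-permuted w against the columns of A.

    Exact enumeration over all D! permutations when feasible, otherwise
    ``n_perm`` Monte-Carlo permutations.  Returns (null matrix [n x m], exact).
    """
    D = w.size
    if math.factorial(D) <= n_perm:
        P = np.array(list(permutations(range(D))))
        exact = True
    else:
        P = rng.permuted(np.tile(np.arange(D), (n_perm, 1)), axis=1)
        exact = False
    Wp = w[P]  # (n, D)
    Wp = Wp - Wp.mean(axis=1, keepdims=True)
    sw = np.linalg.norm(Wp, axis=1, keepdims=True)
    Ac = A - A.mean(axis=0, keepdims=True)
    sa = np.linalg.norm(Ac, axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        null = (Wp @ Ac) / (sw * sa)
    return null, exact


def perm_test_correlations(
    w: np.ndarray,
    targets: np.ndarray,
    n_perm: int = 10_000,
    sidedness: str = "one_sided_greater",
    seed: int = 0,
    fdr_q: float = 0.05,
) -> PermutationTestResult:
    """Entry-shuffle permutation test of Pearson correlations.

    The null distribution permutes the entries of ``w`` (preserving its value
    multiset); the statistic is r (|r| when two-sided) against each target
    column.  Constant targets yield NaN p-values, reported per pair.
    """
    w = np.asarray(w, float).ravel()
    A = np.atleast_2d(np.asarray(targets, float))
    if A.shape[0] != w.size:
        A = A.T
    if w.size < 3:
        raise InputError("need D >= 3")
    if np.ptp(w) == 0:
        raise InputError("constant w: correlation undefined")
    if sidedness not in ("one_sided_greater", "two_sided"):
        raise InputError(f"unknown sidedness {sidedness!r}")
    rng = np.random.default_rng(seed)
    obs = _pearson_to_columns(w, A)
    null, exact = _null_correlations(w, A, n_perm, rng)
    if sidedness == "two_sided":
        stat_obs, stat_null = np.abs(obs), np.abs(null)
    else:
        stat_obs, stat_null = obs, null
    n = null.shape[0]
    count = (stat_null >= stat_obs[None, :]).sum(axis=0).astype(float)
    if exact:
        pvals = count / n
    else:
        pvals = (1.0 + count) / (n + 1.0)
    const = np.isnan(obs)
    if const.any():
        logger.warning("%d constant target(s): p-values set to NaN", int(const.sum()))
        pvals[const] = np.nan
    flags = bh_fdr(np.where(np.isnan(pvals), 1.0, pvals), fdr_q)
    flags[const] = False
    return PermutationTestResult(
        observed=obs,
        pvalues=pvals,
        n_perm=n,
        sidedness=sidedness,
        fdr_flags=flags,
        fdr_q=fdr_q,
        seed=seed,
        exact=exact,
    )


def bh_fdr(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level q."""
    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1)):
        raise InputError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def sqrt_psd(S: np.ndarray, clip_rtol: float = 1e-10) -> np.ndarray:
    """Unique symmetric PSD square root of a symmetric PSD matrix.

    Small negative eigenvalues (>= -clip_rtol * ||S||) are clipped to zero
    and logged; larger indefiniteness raises, it is never silently clipped.
    """
    S = np.asarray(S, float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise InputError("S must be square")
    if np.max(np.abs(S - S.T)) > 1e-10 * max(1.0, np.max(np.abs(S))):
        raise InputError("S must be symmetric")
    lam, V = np.linalg.eigh(0.5 * (S + S.T))
    norm = max(np.max(np.abs(lam)), 1e-300)
    if lam.min() < -clip_rtol * norm:
        raise InputError(f"S is substantially indefinite (min eigenvalue {lam.min():.3g})")
    if lam.min() < 0:
        logger.info("clipping %d small negative eigenvalue(s) to 0", int((lam < 0).sum()))
    lam = np.clip(lam, 0.0, None)
    return (V * np.sqrt(lam)) @ V.T


def _offdiag_pairs(A: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(A.shape[0], k=1)
    return A[iu]


def mw_relation_test(
    W: np.ndarray, M: np.ndarray, n_perm: int = 10_000, seed: int = 0
) -> tuple[float, float, PermutationTestResult]:
    """Test the relation M ~ (W'W)^{1/2} between LN-LN and ORN->LN weights.

    Statistic: Pearson r between the off-diagonal entries of M and of
    sqrt_psd(W'W), each unordered pair once (the diagonal of M encodes
    unobservable leaks and is excluded).  Null: permute the entries within
    each column of W independently (each LN keeps its total synapse count),
    recompute the statistic.  One-sided p-value, add-one estimator.
    """
    W = np.asarray(W, float)
    M = np.asarray(M, float)
    K = W.shape[1]
    if K < 2:
        raise InputError("need K >= 2 LNs")
    if M.shape != (K, K):
        raise InputError("M must be K x K")
    if np.max(np.abs(M - M.T)) > 1e-10 * max(1.0, np.max(np.abs(M))):
        raise InputError("M must be symmetric")
    rng = np.random.default_rng(seed)
    m_off = _offdiag_pairs(M)

    def stat(Wc: np.ndarray) -> float:
        s_off = _offdiag_pairs(sqrt_psd(Wc.T @ Wc))
        a = m_off - m_off.mean()
        b = s_off - s_off.mean()
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        if denom == 0:
            return float("nan")
        return float(a @ b / denom)

    r_obs = stat(W)
    null = np.empty(n_perm)
    for i in range(n_perm):
        Wp = np.column_stack([rng.permutation(W[:, k]) for k in range(K)])
        null[i] = stat(Wp)
    count = float(np.sum(null >= r_obs))
    p = (1.0 + count) / (n_perm + 1.0)
    res = PermutationTestResult(
        observed=np.array([r_obs]),
        pvalues=np.array([p]),
        n_perm=n_perm,
        sidedness="one_sided_greater",
        fdr_flags=np.array([p < 0.05]),
        fdr_q=0.05,
        seed=seed,
    )
    return r_obs, p, res


def mean_rectified_correlation(R: np.ndarray) -> float:
    """Mean of max(0, r) over the off-diagonal entries of a correlation
    matrix (the diagonal is excluded); summarizes LN-group similarity."""
    R = np.asarray(R, float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise InputError("R must be square")
    if np.max(np.abs(R - R.T)) > 1e-8 or np.max(np.abs(np.diag(R) - 1)) > 1e-8:
        raise InputError("R must be symmetric with unit diagonal")
    off = R[~np.eye(R.shape[0], dtype=bool)]
    return float(np.maximum(off, 0.0).mean())


def subspace_alignment(
    A: np.ndarray,
    B: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[np.ndarray, int, np.ndarray]:
    """Principal angles between span(A) and span(B) with a shuffle null.

    Per-dimension significance compares each observed angle against the
    angles obtained by independently permuting the entries within each column
    of A (the same shuffle family as the other tests); a dimension is
    significantly aligned when its angle is smaller than the null at level
    ``alpha``.  Returns (angles, number of significant dimensions, p-values).
    """
    A = np.atleast_2d(np.asarray(A, float))
    B = np.atleast_2d(np.asarray(B, float))
    for name, Mx in (("A", A), ("B", B)):
        if np.linalg.matrix_rank(Mx) < Mx.shape[1]:
            raise InputError(f"columns of {name} are linearly dependent")
    angles = subspace_angles(A, B)  # descending order
    angles = np.sort(angles)  # ascending: best-aligned first
    rng = np.random.default_rng(seed)
    q = angles.size
    null = np.empty((n_perm, q))
    for i in range(n_perm):
        Ap = np.column_stack([rng.permutation(A[:, k]) for k in range(A.shape[1])])
        null[i] = np.sort(subspace_angles(Ap, B))
    count = (null <= angles[None, :]).sum(axis=0).astype(float)
    pvals = (1.0 + count) / (n_perm + 1.0)
    n_sig = int(np.sum(pvals < alpha))
    return angles, n_sig, pvals


def hierarchical_order(V: np.ndarray, method: str = "average") -> np.ndarray:
    """Column ordering from agglomerative clustering on correlation distance.

    Distance is 1 - Pearson r between columns; linkage defaults to average.
    The leaf order is scipy's deterministic dendrogram traversal (ties broken
    by cluster index), so identical inputs give identical orderings.
    """
    V = np.asarray(V, float)
    if V.ndim != 2 or V.shape[1] < 2:
        raise InputError("need at least 2 columns")
    if np.any(V.std(axis=0) == 0):
        raise InputError("constant column: correlation distance undefined")
    d = pdist(V.T, metric="correlation")
    Zl = linkage(d, method=method)
    return np.asarray(leaves_list(Zl), dtype=int)
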