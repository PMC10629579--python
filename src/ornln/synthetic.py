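"""Seeded generators of synthetic activity ensembles and connectome-like
weight matrices.

Three generators emulate the inputs the circuit analyses need:

* :func:`make_two_cluster_2d` -- a 2-channel toy ensemble of two isotropic
  Gaussian odor clusters (100 points each at (1, 0.3) and (0.3, 1) with
  SD 0.17 by default), the canonical clustering demonstration input.
* :func:`make_odor_panel` -- a nonnegative 21-channel panel of 34 odorants at
  5 dilutions with low-dimensional cluster structure and saturating
  (Hill-type) concentration scaling, emulating a Ca2+ imaging odor-response
  ensemble.
* :func:`make_connectome_like` -- a (W, M) pair with LN-type group structure
  obeying M = c (W'W)^{1/2} plus noise, emulating synaptic-count matrices.

All generators are bit-reproducible given their parameters and seed; the full
parameter set and seed are recorded in the output metadata.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from .data import ActivityEnsemble, InputError
from .stats import sqrt_psd

__all__ = [
    "SyntheticSpec",
    "make_two_cluster_2d",
    "make_odor_panel",
    "make_connectome_like",
]

logger = logging.getLogger(__name__)


@dataclass
class SyntheticSpec:
    """Record of a generator call: name, parameters, seed."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def make_two_cluster_2d(
    n_per_cluster: int = 100,
    centers=((1.0, 0.3), (0.3, 1.0)),
    sd: float = 0.17,
    seed: int = 0,
    clip_nonneg: bool = False,
) -> ActivityEnsemble:
    """Two isotropic Gaussian clusters in a 2-channel activity space.

    ``sd`` is the per-axis standard deviation.  Negative draws are possible
    (the lower center coordinate sits ~1.8 SDs from the axis); pass
    ``clip_nonneg`` to rectify at zero for nonnegative-mode consumers (the
    clip is logged and recorded in the metadata).
    """
    if sd < 0:
        raise InputError("sd must be nonnegative")
    rng = np.random.default_rng(seed)
    centers = np.asarray(centers, float)
    n_clusters, D = centers.shape
    pts, labels, clusters = [], [], []
    for k, c in enumerate(centers):
        pts.append(c[:, None] + sd * rng.standard_normal((D, n_per_cluster)))
        labels += [f"c{k}:{i}" for i in range(n_per_cluster)]
        clusters += [k] * n_per_cluster
    X = np.concatenate(pts, axis=1)
    if clip_nonneg:
        n_clip = int((X < 0).sum())
        if n_clip:
            logger.info("clipping %d negative entries to 0", n_clip)
        X = np.maximum(X, 0.0)
    spec = SyntheticSpec(
        "two_cluster_2d",
        seed,
        {
            "n_per_cluster": n_per_cluster,
            "centers": centers.tolist(),
            "sd": sd,
            "clip_nonneg": clip_nonneg,
        },
    )
    return ActivityEnsemble(
        X,
        sample_labels=labels,
        nonneg=clip_nonneg,
        meta={"spec": spec.to_dict(), "cluster": np.array(clusters)},
    )


def make_odor_panel(
    D: int = 21,
    n_odors: int = 34,
    n_dilutions: int = 5,
    n_clusters: int = 4,
    seed: int = 0,
    sparsity: float = 0.25,
    within_cluster_jitter: float = 0.3,
    noise_sd: float = 0.05,
    hill_n: float = 0.5,
    hill_half: float = 1e-6,
    dilutions=None,
) -> ActivityEnsemble:
    """Nonnegative odor-response panel with cluster structure and
    concentration scaling.

    Each odor's tuning vector is a rectified jittered copy of one of
    ``n_clusters`` sparse nonnegative prototypes (active fraction
    ``sparsity``).  Responses scale with concentration through a saturating
    Hill gain c^n / (c^n + c50^n), so per-odor pattern magnitude is strictly
    increasing in concentration when ``noise_sd`` is 0, and responses at the
    highest dilution are weak and sparse.  Additive Gaussian noise is applied
    before rectification at zero.  Sample labels are (odor, dilution) pairs.
    """
    if n_clusters > n_odors:
        raise InputError("n_clusters must be <= n_odors")
    rng = np.random.default_rng(seed)
    dil = (
        np.logspace(-8, -4, n_dilutions)
        if dilutions is None
        else np.asarray(dilutions, float)
    )
    gain = dil**hill_n / (dil**hill_n + hill_half**hill_n)
    # sparse nonnegative prototypes, one dominant channel each so the lowest
    # concentration activates mostly a single channel per odor
    protos = np.zeros((D, n_clusters))
    for k in range(n_clusters):
        mask = rng.random(D) < sparsity
        mask[rng.integers(D)] = True
        protos[mask, k] = rng.gamma(2.0, 1.0, size=int(mask.sum()))
        protos[:, k] /= np.linalg.norm(protos[:, k])
    assign = rng.integers(n_clusters, size=n_odors)
    amps = rng.lognormal(mean=0.0, sigma=0.3, size=n_odors)
    cols, labels = [], []
    for o in range(n_odors):
        v = protos[:, assign[o]] + within_cluster_jitter * rng.standard_normal(D) * (
            protos[:, assign[o]] > 0
        )
        v = np.maximum(v, 0.0)
        v = v / max(np.linalg.norm(v), 1e-12) * amps[o]
        for j, g in enumerate(gain):
            signal = v * g
            noisy = signal + noise_sd * rng.standard_normal(D) if noise_sd > 0 else signal
            cols.append(np.maximum(noisy, 0.0))
            labels.append((f"odor{o}", f"1e{np.log10(dil[j]):+.0f}"))
    X = np.column_stack(cols)
    # order: odor-major, dilution-minor (34 blocks of 5)
    spec = SyntheticSpec(
        "odor_panel",
        seed,
        {
            "D": D,
            "n_odors": n_odors,
            "n_dilutions": n_dilutions,
            "n_clusters": n_clusters,
            "sparsity": sparsity,
            "within_cluster_jitter": within_cluster_jitter,
            "noise_sd": noise_sd,
            "hill_n": hill_n,
            "hill_half": hill_half,
            "dilutions": dil.tolist(),
        },
    )
    return ActivityEnsemble(
        X,
        channel_labels=[f"ORN{i}" for i in range(D)],
        sample_labels=labels,
        nonneg=True,
        meta={
            "spec": spec.to_dict(),
            "odor_cluster": assign,
            "dilutions": dil,
            "n_odors": n_odors,
            "n_dilutions": n_dilutions,
        },
    )


def make_connectome_like(
    D: int = 21,
    K: int = 8,
    rho: float = 1.0,
    type_multiplicities=(3, 2, 2, 1),
    within_type_jitter: float = 0.15,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list, SyntheticSpec]:
    """A connectome-like (W, M) pair with LN-type group structure.

    One nonnegative prototype connection vector per LN type; the columns of W
    are rectified jittered prototypes repeated per type multiplicity, and
    M = rho * (W'W)^{1/2} plus symmetric off-diagonal noise (noise scale
    ``noise_sd`` relative to the mean off-diagonal magnitude), with the
    diagonal kept at its noise-free positive value.
    """
    mult = tuple(int(m) for m in type_multiplicities)
    if sum(mult) != K:
        raise InputError(f"type multiplicities {mult} must sum to K={K}")
    rng = np.random.default_rng(seed)
    protos = []
    for _ in range(len(mult)):
        p = rng.gamma(2.0, 1.0, size=D) * (rng.random(D) < 0.5)
        if p.max() == 0:
            p[rng.integers(D)] = rng.gamma(2.0, 1.0)
        protos.append(p / np.linalg.norm(p))
    cols, labels = [], []
    for t, m in enumerate(mult):
        for _ in range(m):
            w = protos[t] + within_type_jitter * rng.standard_normal(D)
            cols.append(np.maximum(w, 0.0))
            labels.append(f"type{t}")
    W = np.column_stack(cols)
    S = rho * sqrt_psd(W.T @ W)
    M = S.copy()
    if noise_sd > 0:
        off_scale = np.abs(S[~np.eye(K, dtype=bool)]).mean()
        E = rng.standard_normal((K, K)) * noise_sd * off_scale
        E = 0.5 * (E + E.T)
        np.fill_diagonal(E, 0.0)
        M = S + E
    spec = SyntheticSpec(
        "connectome_like",
        seed,
        {
            "D": D,
            "K": K,
            "rho": rho,
            "type_multiplicities": list(mult),
            "within_type_jitter": within_type_jitter,
            "noise_sd": noise_sd,
        },
    )
    return W, M, labels, spec
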