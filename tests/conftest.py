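import numpy as np
import pytest

from ornln.data import ActivityEnsemble


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def spiked_ensemble(D=5, T=100, sds=(3.0, 2.0, 0.5, 0.3, 0.2), seed=0):
    """Random-orientation ensemble with a prescribed uncentered spectrum."""
    rng = np.random.default_rng(seed)
    U, _ = np.linalg.qr(rng.standard_normal((D, D)))
    sds = np.asarray(sds, float)[:D]
    X = U @ (sds[:, None] * rng.standard_normal((D, T)))
    return ActivityEnsemble(X)


@pytest.fixture
def spiked():
    return spiked_ensemble


def subspace_distance(A, B):
    """sin of the largest principal angle between span(A) and span(B)."""
    Qa, _ = np.linalg.qr(np.asarray(A, float))
    Qb, _ = np.linalg.qr(np.asarray(B, float))
    s = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
    return float(np.sqrt(max(0.0, 1.0 - min(s) ** 2)))
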