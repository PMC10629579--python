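"""Quantifying the soma-to-axon transformation: partial whitening,
normalization and decorrelation.

The circuit's effect on the activity ensemble is summarized by comparing the
input (somatic) and output (axonal) ensembles along four axes: the spread of
uncentered PCA variances (CV_sigma; lower output spread = partial ZCA
whitening), per-channel uncentered variances, activity pattern magnitudes
(stronger dampening of large patterns = divisive-normalization-like
equalization), and channel/pattern Pearson correlations (decorrelation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ActivityEnsemble, InputError
from .pca import (
    UncenteredPCA,
    channel_and_pattern_correlations,
    cv_of_variances,
    pattern_magnitudes,
    uncentered_pca,
    variance_in_directions,
)

__all__ = ["WhiteningReport", "whitening_report", "offdiag"]


def offdiag(R: np.ndarray) -> np.ndarray:
    """Off-diagonal entries of a square matrix, each unordered pair once."""
    R = np.asarray(R, float)
    iu = np.triu_indices(R.shape[0], k=1)
    return R[iu]


@dataclass
class WhiteningReport:
    pca_x: UncenteredPCA
    pca_y: UncenteredPCA
    var_x_in_x_dirs: np.ndarray  # equals pca_x.variances; kept for symmetry
    var_y_in_x_dirs: np.ndarray  # output variance along input PCA directions
    cv_x: float
    cv_y: float
    channel_var_x: np.ndarray  # uncentered second moment per channel
    channel_var_y: np.ndarray
    magnitudes_x: np.ndarray
    magnitudes_y: np.ndarray
    channel_corr_x: np.ndarray
    channel_corr_y: np.ndarray
    pattern_corr_x: np.ndarray
    pattern_corr_y: np.ndarray

    @property
    def cv_ratio(self) -> float:
        """CV_sigma(Y) / CV_sigma(X); < 1 means the output is whiter."""
        return self.cv_y / self.cv_x

    def mean_abs_offdiag(self, which: str = "channel") -> tuple[float, float]:
        """Mean |off-diagonal correlation| for (input, output)."""
        if which == "channel":
            rx, ry = self.channel_corr_x, self.channel_corr_y
        elif which == "pattern":
            rx, ry = self.pattern_corr_x, self.pattern_corr_y
        else:
            raise InputError("which must be 'channel' or 'pattern'")
        return (
            float(np.nanmean(np.abs(offdiag(rx)))),
            float(np.nanmean(np.abs(offdiag(ry)))),
        )

    def magnitude_reduction_rank_corr(self) -> float:
        """Spearman rank correlation between input pattern magnitude and the
        input-output magnitude reduction; positive = large patterns dampened
        more (the normalization trend)."""
        from scipy.stats import spearmanr

        red = self.magnitudes_x - self.magnitudes_y
        return float(spearmanr(self.magnitudes_x, red).statistic)

    def to_dict(self) -> dict:
        """JSON-serializable summary (matrices as nested lists)."""
        return {
            "cv_x": self.cv_x,
            "cv_y": self.cv_y,
            "cv_ratio": self.cv_ratio,
            "pca_variances_x": self.pca_x.variances.tolist(),
            "pca_variances_y": self.pca_y.variances.tolist(),
            "var_y_in_x_dirs": self.var_y_in_x_dirs.tolist(),
            "channel_var_x": self.channel_var_x.tolist(),
            "channel_var_y": self.channel_var_y.tolist(),
            "magnitudes_x": self.magnitudes_x.tolist(),
            "magnitudes_y": self.magnitudes_y.tolist(),
            "offdiag_channel_corr_x": offdiag(self.channel_corr_x).tolist(),
            "offdiag_channel_corr_y": offdiag(self.channel_corr_y).tolist(),
            "offdiag_pattern_corr_x": offdiag(self.pattern_corr_x).tolist(),
            "offdiag_pattern_corr_y": offdiag(self.pattern_corr_y).tolist(),
            "mean_abs_channel_corr": self.mean_abs_offdiag("channel"),
            "mean_abs_pattern_corr": self.mean_abs_offdiag("pattern"),
            "magnitude_reduction_rank_corr": self.magnitude_reduction_rank_corr(),
        }


def whitening_report(
    x_ens: ActivityEnsemble, y_ens: ActivityEnsemble, centered_channel_var: bool = False
) -> WhiteningReport:
    """Compare an input ensemble with its circuit output.

    Per-channel "variance" is by default the uncentered second moment
    (mean of squares per row), consistent with the uncentered convention used
    throughout; set ``centered_channel_var`` for the centered alternative.
    """
    if x_ens.X.shape != y_ens.X.shape:
        raise InputError("input and output ensembles must have matching shape")
    if x_ens.channel_labels != y_ens.channel_labels or x_ens.sample_labels != y_ens.sample_labels:
        raise InputError("input and output ensembles must have matching labels")
    X, Y = x_ens.X, y_ens.X
    pca_x = uncentered_pca(x_ens)
    pca_y = uncentered_pca(y_ens)
    chvar = (
        (lambda A: A.var(axis=1)) if centered_channel_var else (lambda A: (A**2).mean(axis=1))
    )
    cx, px = channel_and_pattern_correlations(x_ens)
    cy, py = channel_and_pattern_correlations(y_ens)
    return WhiteningReport(
        pca_x=pca_x,
        pca_y=pca_y,
        var_x_in_x_dirs=variance_in_directions(x_ens, pca_x.directions),
        var_y_in_x_dirs=variance_in_directions(y_ens, pca_x.directions),
        cv_x=cv_of_variances(pca_x.variances),
        cv_y=cv_of_variances(pca_y.variances),
        channel_var_x=chvar(X),
        channel_var_y=chvar(Y),
        magnitudes_x=pattern_magnitudes(x_ens),
        magnitudes_y=pattern_magnitudes(y_ens),
        channel_corr_x=cx,
        channel_corr_y=cy,
        pattern_corr_x=px,
        pattern_corr_y=py,
    )
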