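"""Model / Results front-end for the circuit fits.

Three model classes wrap the functional solvers, each built from an
:class:`~ornln.data.ActivityEnsemble` and returning a
:class:`CircuitFitResults` from ``fit()``:

* :class:`LinearCircuit` -- the closed-form LC-K fit.
* :class:`NonnegativeCircuit` -- the NNC-K fit by restarted alternating
  optimization.
* :class:`OnlineCircuit` -- Hebbian training in either mode.

The results object carries the fitted synaptic weights, the circuit response,
representation diagnostics, and a text ``summary()``; simulation
(``respond``) and plotting hang off it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .data import ActivityEnsemble, CircuitParams, CircuitResponse, InputError
from .dynamics import DynamicsConfig, respond_ensemble
from .nonneg import SolveReport, cluster_labels, nnc_solve
from .linear import lc_solve
from .objective import objective
from .online import TrainingConfig, TrainingHistory, train_online
from .pca import cv_of_variances, uncentered_pca
from .whitening import WhiteningReport, whitening_report

__all__ = ["LinearCircuit", "NonnegativeCircuit", "OnlineCircuit", "CircuitFitResults"]


@dataclass
class CircuitFitResults:
    """Fitted circuit parameters with diagnostics.

    Attributes
    ----------
    model : the model instance that produced the fit
    params : CircuitParams with the fitted (W, M, rho)
    response : CircuitResponse on the training ensemble
    report : solver-specific report (restart objectives, training history, ...)
    """

    model: object
    params: CircuitParams
    response: CircuitResponse
    report: object = None
    _whitening: Optional[WhiteningReport] = field(default=None, repr=False)

    # -- convenience accessors -------------------------------------------------
    @property
    def W(self) -> np.ndarray:
        return self.params.W

    @property
    def M(self) -> np.ndarray:
        return self.params.M

    @property
    def rho(self) -> float:
        return self.params.rho

    @property
    def Y(self) -> np.ndarray:
        return self.response.Y

    @property
    def Z(self) -> np.ndarray:
        return self.response.Z

    @property
    def objective_value(self) -> float:
        return objective(self.model.ensemble.X, self.Y, self.Z, self.rho)

    def output_ensemble(self) -> ActivityEnsemble:
        """The axonal activity Y as a labeled ensemble (labels of the input)."""
        ens = self.model.ensemble
        return ens.with_matrix(self.Y, nonneg=bool(np.all(self.Y >= 0)))

    def whitening(self) -> WhiteningReport:
        """Input-vs-output representation report (computed once, cached)."""
        if self._whitening is None:
            self._whitening = whitening_report(self.model.ensemble, self.output_ensemble())
        return self._whitening

    def lc_cluster_labels(self) -> np.ndarray:
        raise AttributeError("cluster labels are defined for nonnegative fits only")

    def respond(
        self, ensemble: ActivityEnsemble, config: DynamicsConfig | None = None
    ) -> CircuitResponse:
        """Run the fitted circuit on a new ensemble."""
        return respond_ensemble(ensemble, self.params, config)

    def summary(self) -> str:
        ens = self.model.ensemble
        wr = self.whitening()
        lines = [
            f"{type(self.model).__name__} fit",
            "=" * 40,
            f"channels (D):        {ens.D}",
            f"samples (T):         {ens.T}",
            f"local neurons (K):   {self.params.K}",
            f"rho:                 {self.rho:g}",
            f"constraint:          {self.params.constraint}",
            f"objective:           {self.objective_value:.6g}",
            f"converged samples:   {int(self.response.converged.sum())}/{ens.T}",
            f"CV_sigma input:      {wr.cv_x:.4f}",
            f"CV_sigma output:     {wr.cv_y:.4f}  (ratio {wr.cv_ratio:.4f})",
            f"mean|r| channels:    {wr.mean_abs_offdiag('channel')[0]:.4f} -> "
            f"{wr.mean_abs_offdiag('channel')[1]:.4f}",
            f"mean|r| patterns:    {wr.mean_abs_offdiag('pattern')[0]:.4f} -> "
            f"{wr.mean_abs_offdiag('pattern')[1]:.4f}",
        ]
        return "\n".join(lines)

    def params_frame(self) -> pd.DataFrame:
        """W as a labeled DataFrame (channels x LNs)."""
        ens = self.model.ensemble
        cols = [f"LN{k}" for k in range(self.params.K)]
        return pd.DataFrame(self.W, index=ens.channel_labels, columns=cols)

    def plot_variances(self, ax=None):
        """Bar plot of input vs output uncentered PCA variances."""
        import matplotlib.pyplot as plt

        wr = self.whitening()
        if ax is None:
            _, ax = plt.subplots()
        idx = np.arange(wr.pca_x.variances.size)
        ax.bar(idx - 0.2, wr.pca_x.variances, width=0.4, label="input (somas)")
        ax.bar(idx + 0.2, wr.pca_y.variances, width=0.4, label="output (axons)")
        ax.set_xlabel("uncentered PCA direction")
        ax.set_ylabel("variance")
        ax.legend()
        return ax


class _BaseCircuitModel:
    def __init__(self, ensemble: ActivityEnsemble, K: int, rho: float):
        if not isinstance(ensemble, ActivityEnsemble):
            ensemble = ActivityEnsemble(np.asarray(ensemble, float))
        self.ensemble = ensemble
        self.K = int(K)
        self.rho = float(rho)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, K: int, rho: float, **kw):
        """Build from a channels-x-samples DataFrame (index = channel labels)."""
        ens = ActivityEnsemble(
            df.to_numpy(float),
            channel_labels=[str(i) for i in df.index],
            sample_labels=[str(c) for c in df.columns],
        )
        return cls(ens, K=K, rho=rho, **kw)


class LinearCircuit(_BaseCircuitModel):
    """Closed-form linear circuit (LC-K): LNs extract the top-K uncentered
    principal subspace; axons carry a partially ZCA-whitened input."""

    def fit(self) -> CircuitFitResults:
        params, response, pca = lc_solve(self.ensemble, self.K, self.rho)
        res = CircuitFitResults(model=self, params=params, response=response, report=pca)
        return res


class NonnegativeCircuit(_BaseCircuitModel):
    """Nonnegative circuit (NNC-K): LNs softly cluster the input; fitted by
    restarted alternating dynamics + batch Hebbian assignment."""

    def fit(
        self,
        n_restarts: int = 10,
        max_epochs: int = 500,
        tol: float = 1e-6,
        seed: int = 0,
        dyn_config: DynamicsConfig | None = None,
    ) -> CircuitFitResults:
        params, response, report = nnc_solve(
            self.ensemble,
            self.K,
            self.rho,
            n_restarts=n_restarts,
            max_epochs=max_epochs,
            tol=tol,
            seed=seed,
            dyn_config=dyn_config,
        )
        res = CircuitFitResults(model=self, params=params, response=response, report=report)
        res.cluster_labels = lambda: cluster_labels(response.Z)  # type: ignore[attr-defined]
        return res


class OnlineCircuit(_BaseCircuitModel):
    """Circuit trained online by Hebbian plasticity after each stimulus."""

    def __init__(self, ensemble, K: int, rho: float, mode: str = "linear"):
        super().__init__(ensemble, K, rho)
        if mode not in ("linear", "nonnegative"):
            raise InputError(f"unknown mode {mode!r}")
        self.mode = mode

    def fit(
        self,
        n_epochs: int = 20,
        seed: int = 0,
        config: TrainingConfig | None = None,
    ) -> CircuitFitResults:
        params, history = train_online(
            self.ensemble,
            self.K,
            self.rho,
            mode=self.mode,
            config=config,
            n_epochs=n_epochs,
            seed=seed,
        )
        cfg = (config or TrainingConfig()).dynamics
        response = respond_ensemble(self.ensemble, params, cfg)
        return CircuitFitResults(model=self, params=params, response=response, report=history)
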