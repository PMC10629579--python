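# ornln — similarity-matching models of the larval ORN–LN olfactory circuit

`ornln` implements a normative model of the peripheral olfactory circuit of
the fruit-fly larva: D olfactory receptor neurons (ORNs) reciprocally coupled
to K inhibitory local neurons (LNs).  The model proposes that the circuit's
activity and synaptic weights jointly solve a single similarity-matching
optimization, from which both the neural dynamics and the Hebbian plasticity
rules follow.

## The model

Given an ensemble of T somatic ORN activity patterns `x(t)` (columns of a
D × T matrix X), the axonal outputs Y and LN activities Z solve the min–max
problem

```
min_Y max_Z  (T/2)‖X − Y‖²_F − (ρ²/4)‖YᵀY − (1/ρ²)ZᵀZ‖²_F + (ρ²/4)‖YᵀY‖²_F
```

optionally subject to Y ≥ 0, Z ≥ 0.  The stationarity conditions are exactly
a circuit fixed point,

```
y = x − W z        (ORN axons: input minus LN feedback inhibition)
M z = ρ² Wᵀ y      (LNs: feedforward drive through recurrent inhibition)
```

with weights `W = Y Zᵀ/T` and `M = Z Zᵀ/T`, i.e. the synapses are activity
correlations and can be learned online by local Hebbian updates.  ρ sets the
strength of feedback inhibition relative to feedforward excitation.

Two variants are provided:

* **Linear circuit (LC-K)** — closed form.  The LNs extract the top-K
  uncentered principal subspace; the soma-to-axon map is a *partial ZCA
  whitening*: principal directions are preserved while the leading K
  standard deviations σ_X are shrunk to the root of
  σ_Y (1 + ρ² σ_Y²) = σ_X.  The LN–LN weights obey M = ρ (WᵀW)^½ exactly.
* **Nonnegative circuit (NNC-K)** — numerical.  With rectified activities the
  LN layer performs a symmetric nonnegative matrix factorization: LNs softly
  cluster odors and the columns of W point toward odor-cluster directions.

Both can be trained online: run the neural dynamics to steady state for each
stimulus, then apply `W ← W + ε₁(y zᵀ − W)`, `M ← M + ε₂(z zᵀ − M)`.

## Quick start

```python
import numpy as np
from ornln import LinearCircuit, NonnegativeCircuit, make_two_cluster_2d

# linear circuit on anisotropic Gaussian data
rng = np.random.default_rng(0)
X = np.diag([3.0, 2.0, 0.5, 0.3, 0.2]) @ rng.standard_normal((5, 100))
res = LinearCircuit(X, K=2, rho=1.0).fit()
print(res.summary())
```

```
LinearCircuit fit
========================================
channels (D):        5
samples (T):         100
local neurons (K):   2
rho:                 1
constraint:          linear
objective:           26257.9
converged samples:   100/100
CV_sigma input:      1.3016
CV_sigma output:     0.9602  (ratio 0.7377)
mean|r| channels:    0.0567 -> 0.0372
mean|r| patterns:    0.6088 -> 0.5223
```

```python
# nonnegative circuit clusters a two-cluster ensemble
ens = make_two_cluster_2d(seed=0, clip_nonneg=True)
res = NonnegativeCircuit(ens, K=2, rho=1.0).fit(n_restarts=10, seed=0)
labels = res.cluster_labels()          # argmax-LN soft cluster per sample
W = res.W                              # columns point at the cluster means
```

The same workflows are available from the command line:

```bash
ornln simulate-data --generator two_cluster --seed 0 --output data.csv
ornln fit-lc --input data.csv --k 2 --rho 1.0 --output bundle/
ornln respond --input data.csv --params bundle/ --output-y Y.csv --output-z Z.csv
ornln whitening-report --x data.csv --y bundle/Y.csv --output report.json
```

Exit codes: 0 success, 2 input error, 3 non-convergence.

## What's in the package

| module | contents |
| --- | --- |
| `ornln.data` | `ActivityEnsemble`, `CircuitParams`, `CircuitResponse` containers |
| `ornln.pca` | uncentered PCA, CV of variances, magnitudes, correlations |
| `ornln.objective` | the similarity-matching objective and its gradients |
| `ornln.linear` | closed-form LC-K solver, SD-shrinkage cubic, saddle verifier |
| `ornln.dynamics` | linear ODE / closed-form steady state, rectified iteration, LN–LN ablation |
| `ornln.nonneg` | restarted alternating NNC-K solver, cluster readout |
| `ornln.online` | Hebbian updates and the online training loop |
| `ornln.whitening` | input-vs-output whitening / normalization / decorrelation report |
| `ornln.stats` | permutation tests, BH-FDR, M vs (WᵀW)^½ test, subspace alignment |
| `ornln.synthetic` | seeded generators: two-cluster toy, odor panel, connectome-like (W, M) |
| `ornln.model` | `LinearCircuit` / `NonnegativeCircuit` / `OnlineCircuit` model classes |
| `ornln.io`, `ornln.cli` | labeled CSV IO, parameter bundles, `ornln` command line |

See `docs/methods.md` for the mathematical conventions, parameter defaults
and numerical choices.

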