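# Methods

This document records the mathematical conventions, parameter defaults, and
numerical choices behind `ornln`.

## 1. Model and conventions

Activity ensembles are D × T matrices X: rows are channels (ORNs), columns
are samples (activity patterns, e.g. odor × dilution conditions).  All
second-order statistics are **uncentered** — PCA diagonalizes XXᵀ/T without
mean subtraction, and per-channel "variance" defaults to the mean of squares
per row — because the circuit operates on rectified, nonnegative-mean
activity where the origin is physically meaningful (no response).

The circuit output for input X is the saddle point of

L(Y, Z) = (T/2)‖X − Y‖²_F − (ρ²/4)‖YᵀY − (1/ρ²)ZᵀZ‖²_F + (ρ²/4)‖YᵀY‖²_F,

minimized over Y (ORN axons), maximized over Z (LNs), optionally with
Y, Z ≥ 0.  Expanding squares, L = (T/2)‖X−Y‖² + ½ tr(YᵀY ZᵀZ) −
(1/4ρ²)‖ZᵀZ‖²; setting gradients to zero yields the circuit fixed point
y = x − Wz, Mz = ρ²Wᵀy with W = YZᵀ/T, M = ZZᵀ/T.  At ρ = 0 the coupling
terms vanish identically and the output is Y = X, Z = 0.

### Linear circuit (closed form)

With no sign constraints the solution is a partial ZCA whitening.  Writing
the uncentered PCA of X as XXᵀ/T = U diag(σ²_X) Uᵀ:

* the leading K standard deviations are shrunk to the unique nonnegative
  root of σ_Y (1 + ρ² σ_Y²) = σ_X; trailing directions pass through;
* Z = ρ × (scaled top-K PCA coordinates).  The LN rotation is a gauge
  freedom; we fix it to the identity so LN i aligns with principal
  direction i.  Y is unaffected by this choice;
* consequently W has columns ρ σ²_{Y,k} u_k and M = ρ² diag(σ²_Y), giving
  the exact identity **M = ρ (WᵀW)^½**.

The cubic is solved by Cardano's formula plus three Newton polishing steps,
with a bracketing (`brentq`) fallback if cancellation spoils the residual,
and a closed-form `σ_Y = σ_X` shortcut when ρ²σ_X² < 1e-30 (the cubic term
is below the residual tolerance and 1/ρ² would overflow).  Residuals are
kept below 1e-12·max(1, σ_X).

`verify_saddle` is a test oracle, not a user-facing solver: it optimizes the
reduced objective φ(Z) = L(Y*(Z), Z) by gradient ascent, with the inner
minimization over Y solved **exactly** via the K × K Woodbury identity
Y*(Z) = X − (XZᵀ)(T·I + ZZᵀ)⁻¹Z.  The ascent step is 0.9/(‖YYᵀ‖₂ +
3‖ZZᵀ‖₂/ρ²), a local Lipschitz bound.  Exact inner minimization replaces
naive alternating gradient descent in Y because the saddle structure makes
the latter oscillate; the reduced problem is a plain maximization.

### Dynamics

For fixed (W, M, ρ) the linear dynamics are τ_y ẏ = −y − Wz + x,
τ_z ż = −Mz + ρ²Wᵀy, with unique fixed point z = ρ²(M + ρ²WᵀW)⁻¹Wᵀx
(systems with condition number above 1e12 are rejected as input errors).
The nonnegative circuit runs the projected iteration
y ← [y + ε(−y − Wz + x)]₊ (and likewise for z) until the boundary-aware
KKT conditions hold: positive coordinates have |drive| ≤ tol, zero
coordinates have drive ≤ tol (relative to 1 + ‖x‖).

Two step-size policies exist: the decaying schedule ε(τ) = ε₀/(1 + τ/τ₀)
(ε₀ = 0.2, τ₀ = 100), robust for single-sample use, and `auto_step`, a
constant step derived from the drive Jacobian A = [[I, W], [−ρ²Wᵀ, M]]:
ε = min(1, 0.9·min_λ 2 Re λ/|λ|²) over the eigenvalues λ of A, the explicit
Euler stability bound with a 10 % margin.  `auto_step` is the default inside
the batch NNC solver, where the decaying schedule is prohibitively slow.

Stability of the linear dynamics is not guaranteed for arbitrary (W, M);
`jacobian_spectral_abscissa` lets callers flag marginal systems.  Parameters
produced by the package's own solvers were always stable in our sweeps.

### Nonnegative solver

`nnc_solve` alternates (i) batch projected dynamics over all samples
(warm-started from the previous epoch) and (ii) the **damped** Hebbian batch
assignment W ← W + η(YZᵀ/T − W), M ← M + η(ZZᵀ/T − M) with η = 0.5.  The
undamped replacement W ← YZᵀ/T exhibits period-2 oscillations on clustered
data; damping by ½ removes them.  Convergence is declared on the *undamped*
relative fixed-point residual max(‖YZᵀ/T − W‖/‖W‖, ‖ZZᵀ/T − M‖/‖M‖) ≤ tol
(default 1e-6).  Diagonal entries of M (LN leaks) are floored at 1e-9 so a
temporarily silent LN cannot make the dynamics ill-posed.

Restarts (default 10) draw W from rectified Gaussians scaled by RMS(X)/√D.
The returned restart is the one with the **highest** objective value: the
objective is maximized over Z, so a higher attained value means the LN layer
extracted more similarity structure; degenerate restarts (dead or merged
LNs) sit at visibly lower values and all-zero restarts at 0.  Restart
objectives are reported, never averaged.  Duplicated W columns when K
exceeds the number of clusters are expected behavior.

### Online learning

Each presentation runs the dynamics to steady state (closed form in linear
mode; projected iteration with up to 2 halved-step retries in nonnegative
mode, skipping the sample if still unconverged), then applies
W ← W + ε₁(yzᵀ − W), M ← M + ε₂(zzᵀ − M).  Default rates ε(t) = a/(1 + t/b)
with a = 0.05, b = 500.  diag(M) is floored at 1e-6 during training.  Given
an ensemble, each epoch is one seeded shuffled pass; a generic iterable is
consumed once in arrival order (streaming).  Online runs can settle in
degenerate optima exactly like offline restarts; protocols that need the
non-degenerate solution should train from a few seeds and keep the run with
the highest objective — the same selection rule the offline solver applies
to its restarts.

## 2. Representation metrics

* `cv_of_variances`: population (ddof = 0) SD / mean of the uncentered PCA
  variances; 0 for white ensembles, decreasing = whiter.
* pattern magnitudes: column Euclidean norms; the normalization trend is the
  Spearman rank correlation between input magnitude and input−output
  magnitude reduction (positive = large patterns dampened more).
* correlations: centered Pearson, both between channels (rows) and between
  patterns (columns).  Constant vectors give NaN entries with a warning;
  an all-constant matrix is an input error.

## 3. Connectivity statistics

* Permutation tests shuffle the **entries** of a connection vector w
  (preserving its value multiset); p-values use the add-one estimator
  (1 + #{null ≥ obs})/(n + 1), switching to exact enumeration over all D!
  permutations whenever D! ≤ n_perm.  BH-FDR uses the standard step-up rule.
* `mw_relation_test` correlates off-diagonal entries of M with those of
  (WᵀW)^½ (diagonal excluded — leaks are not synapse counts), against a
  null that permutes entries within each W column (each LN keeps its synapse
  total).
* `sqrt_psd` uses an eigendecomposition, clipping eigenvalues down to
  −1e-10·‖S‖ to zero; anything more indefinite raises.
* `subspace_alignment` computes principal angles (SciPy) with the same
  within-column shuffle null; `hierarchical_order` uses average linkage on
  1 − r correlation distance with SciPy's deterministic leaf order.

## 4. Synthetic generators

All generators are bit-reproducible given parameters and seed, and embed
their full parameterization in the output metadata.

* `make_two_cluster_2d` — two isotropic Gaussian clusters, 100 points each
  at (1, 0.3) and (0.3, 1), per-axis SD 0.17.  The low coordinate sits
  ≈ 1.8 SDs from the axis, so ~4 % of draws are negative; nonnegative-mode
  consumers pass `clip_nonneg=True` (rectification at zero, logged and
  recorded in metadata).
* `make_odor_panel` — D = 21 channels × (34 odors × 5 dilutions) = 170
  patterns.  Odor tuning vectors are rectified jittered copies of 4 sparse
  nonnegative prototypes; responses scale with concentration through a
  saturating Hill gain c^n/(c^n + c50^n) (n = 0.5, c50 = 1e-6, dilutions
  10⁻⁸…10⁻⁴) — an invented stand-in for realistic dose–response structure,
  not a fit to any dataset.  Additive Gaussian noise precedes rectification.
* `make_connectome_like` — K = 8 LNs in 4 types with multiplicities
  (3, 2, 2, 1); W columns are rectified jittered type prototypes and
  M = ρ(WᵀW)^½ plus optional symmetric off-diagonal noise.  Counts follow
  the reference design: 170 patterns, C(21,2) = 210 channel pairs,
  C(68,2) = 2278 pattern pairs at the two highest dilutions, and
  8 LNs × 2 directions = 16 connection vectors.

Problem sizes in the test-suite sweeps (D ≤ 8, T ≤ 60, 20–50 instances) are
the package's own choices, balancing coverage against runtime.

## 5. Error handling and determinism

User-facing precondition violations raise `InputError` (a `ValueError`);
numerical non-convergence is reported through flags/reports, never as an
exception, except where a result would be meaningless (singular linear
systems).  Every stochastic routine takes an explicit seed and is
deterministic given it.  CLI commands print their fully resolved
configuration at INFO level; exit codes are 0 (success), 2 (input error),
3 (non-convergence).
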