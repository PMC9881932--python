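# Methods

## Model and estimation

Cases `X` (m×n1) and controls `Y` (m×n0) are modelled as a shared low-rank
term plus, in cases only, a weak case-specific term, plus isotropic Gaussian
noise (see README for the display).  Estimation proceeds in three steps:

1. **Shared directions.**  Sample-space CCA maximizes `aᵀXᵀYb` under
   `‖Xa‖ = ‖Yb‖ = 1`.  We solve the equivalent symmetric problem: with
   `S_XX = XᵀX`, `S_YY = YᵀY`, `S_XY = XᵀY`, the SVD of
   `(S_XX+εI)^{-1/2} S_XY (S_YY+εI)^{-1/2}` gives all min(n0, n1) canonical
   pairs at once with guaranteed real spectrum; this coincides with the
   iterative formulation that constrains each image `u_r = X a_r` to be
   orthogonal to its predecessors.  All pairs are computed once and cached;
   the dimension search below never recomputes the CCA.

2. **Effective shared dimension.**  Binary search over k ∈ {1, …,
   min(n0, n1)}.  At each candidate both matrices are residualized against
   their own top-k canonical images (`X` against orthonormalized `Xa_r`,
   `Y` against orthonormalized `Yb_r`), the top PC of the case residual is
   extracted, and its variance in each group is compared with nulls formed
   by permuting the PC's feature loadings.  Case-only significance and
   neither-significant both move the search down; both-significant moves it
   up unless the case/control variance ratio exceeds γ; control-only
   significance terminates the search (model assumption violated).  The
   selected k is the smallest candidate classified case-specific.  When the
   search bottoms out at k = 1 we additionally probe k = 0, so data with no
   shared structure at all select k = 0 and the case matrix passes through
   unchanged apart from centering.

3. **Case-specific components.**  `X̃ = X − U Uᵀ X` with U the
   orthonormalized top-k images; SVD of `X̃` yields loadings, sample scores
   and explained variances.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `gamma` | 10 | case/control variance-ratio threshold that upgrades a both-significant probe to case-specific; raising it removes more shared axes, lowering it risks under-correction |
| `n_permutations` | 100 | loading permutations per probe of the dimension search |
| `significance_level` | 0.05 | one-sided empirical-quantile level for probe significance |
| `standardization` | `center` | each matrix is centered by its own feature means, so case/control mean shifts (which are not subphenotypic structure) never enter the CCA; `zscore` additionally scales features and drops constant ones |
| `ridge_epsilon` | `1e-8·trace(S)/n` per side | regularizer for near-singular sample Gram matrices; 0 forbids regularization and errors on singularity |
| `y_residual_mode` | `own` | controls are residualized against their own canonical images (each matrix expresses the shared structure in its own sample coordinates); `cross` reuses the case-side basis |

The degenerate probe outcome `var_y = 0` is treated as an infinite variance
ratio (case-specific), which avoids division by zero and matches the
case-only semantics.  Empirical quantiles use the `higher` method — the
conservative choice for a permutation test.  All randomness descends from
one integer seed through `numpy` seed sequences, so `fit.json` is
bit-reproducible.

### Significance testing of discovered structure

Whether a fitted top component reflects genuinely case-specific variation
is judged by a label re-randomization test: the statistic is the variance of
the top component's case scores; null replicates re-partition the pooled
samples into pseudo-cases and pseudo-controls of the original sizes and
refit.  Re-partitioning destroys case-specific structure while preserving
all shared structure, which is exactly the null hypothesis.  Calibration
runs use 19 re-randomizations — the smallest count at which a level-0.05
one-sided permutation test is exact (rejection iff the observed statistic
beats every null draw).  The loading-permutation statistic of the dimension
search is available as an alternative but is not used for calibration: the
top PC of any finite-sample residual overfits the sample variance, so a
loading-permutation null is anti-conservative for this purpose.

### Randomized variant

Sample-space CCA requires m > max(n0, n1).  `fit_rpaca` covers the opposite
regime by drawing, per batch, equal-size case and control sample subsets
small enough that the subset pair is a valid problem, running the standard
residualization on each, and averaging the implied case-sample covariance
entries over the batches in which both samples co-occur.  The aggregated
covariance is eigendecomposed for scores.  k is selected independently per
batch (each batch is a self-contained problem).  Every case pair must
co-occur at least once; the coverage check fails otherwise with a hint to
increase the batch count.  With one batch containing all samples in the
m > n regime the procedure reduces exactly to the direct fit.  This batch
protocol is our reconstruction from a one-sentence description of the
approach; its aggregation details (mean over co-occurrences, per-batch k)
are package choices.

## Simulator

`simulate()` draws from the generative model directly.  Design choices:

* **Shared spectrum**: geometric decay from 10σ to σ across the k0 axes.
  The weakest shared axes sit at the noise scale and straddle typical
  subtype strengths, so the *effective* dimension to remove is genuinely
  smaller than k0 — a flat spectrum would make dimension selection trivial.
* **Signal strength**: the case-specific column norm is
  `signal_strength × median(shared spectrum)`, a dimensionless knob.  The
  experiment grid uses weak = 1.5, moderate = 2.5, strong = 4.  The weak
  level was placed at the detection margin of the generator (pilot runs of
  the generator alone): much below it every linear method sits at the
  correlation noise floor (≈ 1/√n1) and comparisons are uninformative;
  at 1.5 the methods have modest, clearly distinguishable power.
* **Sparsity**: the case-specific axis is supported on ⌈sparsity·m⌉ random
  features (grid: 0.01–1.0), then projected orthogonal to span(W0) so the
  orthogonality assumption holds structurally, and finally rescaled —
  sparsity concentrates the signal without changing its total size.
* **Subtype labels**: Bernoulli(prop), prop grid {0.5, 0.75, 0.9}; the
  case-specific score is the centered indicator.  A single-class draw is
  redrawn (a subtype split needs two groups).
* **Orthogonality violation**: `violation_rho` gives the first (strongest)
  shared factor of the cases a correlation ρ with the subtype indicator
  *and* shrinks the uniquely case-specific norm by √(1−ρ²): violation
  reallocates a fraction ρ² of the subtype's expression into the shared
  subspace.  At ρ → 1 the subtype lives entirely inside the shared
  structure and no contrastive method can recover it; score mixing alone
  would leave the unique axis fully informative and no method would lose
  power.  A side effect worth knowing: plain PCA *gains* power as ρ grows,
  because the contaminated dominant axis then carries subtype information —
  the contrastive methods degrade toward (and below) that baseline.
* **Scale presets**: the full grid (n1 = n0 = 1000, m = 2000, k0 = 400) and
  a 1/5-scale desk preset (n1 = n0 = 200, m = 400, k0 = 80) preserving the
  n/m and k0/n ratios.  All shipped experiments and the acceptance script
  use the desk preset with 20–100 replicates — identical code path,
  tractable on a single CPU.

### What the simulator does not emulate

Continuous Gaussian features only: no genotype discreteness, methylation
boundary effects, heteroskedastic noise, feature-feature correlation beyond
the low-rank terms, or missingness.  Passing simulation tests therefore
demonstrates correctness of the estimation machinery under the stated
model, not robustness to real-data artefacts.  Confounders affecting only
one group (e.g. site effects in a case-only site) are outside the model and
are known failure modes of the approach.

## Numerical conventions

* Variances use ddof = 1 throughout.
* Eigen/singular vectors fix the sign of their largest-magnitude entry
  positive, making fits deterministic and comparable across runs.
* The shared basis is an ordered (QR) orthonormalization of the canonical
  images, preserving the leading direction; under a ridge the raw images
  are only approximately orthogonal.
* Top principal axes are computed from the smaller-side Gram matrix.
* `suggest_alphas` reimplements the published contrast-strength selection
  heuristic (principal-angle affinities, spectral clustering, cluster
  medoids) from its description; representatives whose subspaces coincide
  numerically are collapsed.  Treat its output as indicative.

## Known limitations

* The orthogonality assumption is load-bearing; the violation sweep in the
  test suite quantifies the degradation.
* Dimension selection inherits permutation-test granularity: with 100
  permutations the probe level cannot resolve below 1/101.
* cPCA-∞ at weak signal operates near its power floor, so multiplicative
  collapse statements about it are not meaningful in that regime (its
  violation tests assert a significant drop instead).
* The rPACA aggregation is a reconstruction (above); its statistical
  efficiency relative to the original is unverified.
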