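# Methods

This note documents the statistical model behind `netrl`, the numerical
and design choices that were genuinely open, and what the simulation
evidence does and does not establish.

## Model and estimation

A directed gene regulatory network is read off the per-target linear
models y<sub>ℓ</sub> = Σ<sub>j≠ℓ</sub> x<sub>j</sub> β<sub>ℓj</sub> + ε:
a nonzero β<sub>ℓj</sub> is the edge j → ℓ.  Predictors are
standardized (mean 0, unit sample standard deviation, ddof = 1 — the
scale convention is immaterial to selection because penalty grids are
data-driven) and the response is centered; no intercept is fit.

The estimator is a three-stage bootstrap ensemble (stage-by-stage
summary in the README).  Design choices worth recording:

* **Candidate-set sizes.**  p₁\* = p₂\* = ⌈q/2⌉ of the q candidate
  regulators, configurable.  Half keeps candidate sets diverse (any
  pair of correlated regulators is separated in ~half the replicates)
  while leaving enough signal per fit.
* **Aggregation.**  Final weights are (1/Ω) Σ<sub>ω</sub>
  β̂<sup>(ω)</sup> with zeros counted for genes a replicate did not
  sample or did not select; the median over replicates is available as
  an option.  This follows the ensemble-average definition literally.
  Consequence: weights are shrunk by roughly the selection frequency
  m/Ω, which costs prediction accuracy (see *Limitations*) but is what
  the selection-count significance machinery is calibrated to.
* **Importance-weighted sampling** uses Gumbel-perturbed log-weights
  (Efraimidis–Spirakis keys), which reproduces successive
  without-replacement draws with probability ∝ C<sub>j</sub> exactly and
  vectorizes.  Zero-importance genes receive a floor of 10⁻⁶·max C so a
  draw of p₂\* genes is always feasible (floor 0 restores strictness).
* **Sign reference.**  The sign flip S in the Laplacian penalty uses the
  signs of the stage-1 averaged coefficients (zero treated as +1).  The
  literal penalty with sgn(β)β = |β| would be non-differentiable and
  self-referential; a fixed preliminary sign vector preserves the
  intent — smoothing magnitudes of negatively correlated neighbors —
  and keeps the problem a convex augmented-data lasso.
* **Sub-Laplacian.**  Stage 2 restricts the rows/columns of the
  full-universe normalized Laplacian to the candidate set; degrees are
  *not* recomputed on the subgraph, so a candidate's connectivity to
  unsampled genes still discounts its penalty.
* **Permutation null.**  Permutations reuse the observed run's bootstrap
  rows and candidate sets and permute only the response, so the null
  isolates the response–regulator association; σ̂² is re-estimated on
  each permuted response (it then approaches var(y), making null fits
  sparse — this contrast is what powers the test).
* **Hypergeometric calibration.**  With N = Ω·p₂\* candidate slots,
  K = Σ<sub>j</sub> m<sub>j</sub> total selections and n<sub>j</sub> the
  candidacy count of gene j, the p-value is the upper tail
  P(Hypergeom(N, K, n<sub>j</sub>) ≥ m<sub>j</sub>): the probability
  that a gene would be selected this often if selections were spread
  over candidate slots at random.
* **Seed policy.**  A master integer seed spawns independent streams
  for stage 1, the adjacency sweep, stage 2 and the permutations; in
  multi-target runs each target's seed is a CRC-32 hash of its gene
  identifier XOR the master seed, so results are independent of target
  order and byte-reproducible.
* **Graph variants.**  `beta` builds the adjacency from an all-target
  stage-1 sweep (every gene regressed on the rest — the expensive,
  default variant); `corr` uses the absolute correlation matrix as an
  external prior, in which case centralities also come from it
  (binarized at 0 the correlation graph is near-complete, so hubness ≈ 1
  and importance reduces to the statistical factor); `prior` accepts a
  user graph; `none` drops the graph entirely, which together with
  λ₂ ≡ 0 and a 1/n truncation of the averaged coefficients is exactly
  the classic random lasso and is what the benchmark's
  `random-lasso` method runs.

## BIC tuning and the noise variance

Hyperparameters minimize BIC = ‖y − ŷ‖²/(nσ̂²) + (log n / n)·df̂ with
df̂ = #{β̂<sub>j</sub> ≠ 0}, ties broken toward larger λ₁ then larger λ₂.
Within the pipeline the grid is 30 log-spaced λ₁ values from the
critical λ<sub>max</sub> down to 0.01·λ<sub>max</sub>, crossed with
λ₂ ∈ {0, 0.1, 1, 10}, re-selected inside every bootstrap replicate on
that replicate's data; the single-fit API defaults to a finer grid
(50 values to 0.001·λ<sub>max</sub>, λ₂ ∈ {0, 0.01, 0.1, 1, 10},
δ ∈ {0.1, …, 0.9}).

σ² is estimated once per dataset (and once per permuted response).  For
q < n it is the OLS residual variance RSS/(n − q).  For q ≥ n
residual-based plug-ins degenerate (a weakly penalized fit
interpolates, σ̂² → 0, and the BIC then always prefers the densest
model), so the package uses the cross-validated-lasso plug-in:
choose λ by 5-fold CV with the one-standard-error rule, then
σ̂² = RSS(λ)/(n − df̂) on the full data.  Under a pure-noise response
this approaches var(y); under strong signal it approaches the residual
noise scale.  Both the selection behavior of the baselines and the
power of the permutation test hinge on this estimator; it is
configurable (`sigma2` override, `ridge-gcv` alternative).

An emergent consequence of in-sample BIC with df̂ = support size: the
Laplacian weight λ₂ = 0 wins in the large majority of replicates (a
pure quadratic penalty cannot reduce in-sample RSS and gets no
degrees-of-freedom credit).  The network information therefore acts
mainly through the centrality-guided importance sampling, which is
where the selection gains over the plain random lasso appear.

## Numerical core

All ensemble fits run on a Gram-matrix coordinate-descent path kernel
(numba): for Gram G = XᵀX and correlations Xᵀy, the network penalty
folds into the Gram as G + 2λ₂·SLS, so one weighted elastic-net kernel
covers every penalty in the package.  Warm starts descend the λ₁ path;
convergence is declared when the largest coefficient update falls below
`cd_tol` (default 10⁻⁵ in the pipeline) relative to max(1, max|β|);
the path freezes early once the active set reaches n (the residual sum
of squares is then saturated and denser points cannot win the BIC).
Per-replicate Gram matrices and penalized Grams are precomputed once
and shared across all permutation replicates.  The public single-fit
functions (`fit_lasso`, `fit_elastic_net`, `fit_adaptive_lasso`,
`fit_network_lasso`) delegate to scikit-learn at tolerance 10⁻¹²; the
test suite ties the kernel to scikit-learn paths, closed forms, KKT
conditions and a bound-constrained quadratic-programming oracle.
Degenerate inputs: constant columns are rejected at standardization;
an all-zero correlation vector yields the null fit; isolated graph
nodes get zero Laplacian rows; betweenness on fewer than three nodes
is zero; disconnected pairs contribute zero to betweenness.

## The simulator and what passing tests show

The generator emulates a TF → target cascade: u TF expression levels
are i.i.d. N(0, 1); each of a TF's v = 10 children is
0.7·TF + N(0, 0.51), giving TF–child correlation 0.7 and unit child
variance; the target adds N(0, σ²) noise on top of a sparse
block-structured coefficient vector (TF blocks 5, −5, 3, −3, children
at the TF value over √10, or √5/√15 in the heavier-tailed scenarios;
scenarios 2 and 4 flip the first 30 % of each block's children; the
"large-support" situation repeats the 4-block pattern twice, putting
44 vs 88 true regulators on either side of the 48 training samples).
v = 10 and the block divisors follow the established
network-regularization benchmark convention; both are configurable.

This design has features real expression data lack: Gaussian margins,
homoscedastic noise, a block-diagonal correlation structure, and a
target that is not itself a column of the design.  Recovery rates
achieved here therefore bound expectations for RNA-seq applications
from above; what the passing tests *do* establish is internal
correctness (oracle agreement, calibrated type-I error of the
permutation criterion on pure noise) and that the implementation
reproduces the published operating points of the benchmark within
Monte Carlo tolerance.

Problem sizes in the shipped checks: the deterministic property suite
runs at q ≤ 8; the null calibration uses p = 20, n = 48, Ω = 50,
Π = 200 over 50 datasets; the Monte Carlo table checks run 20 datasets
for the fast baselines and 8 per setting for netRL (Ω = Π = 50) in the
test suite, and 50/20 datasets in `scripts/acceptance.py`.

## Limitations

* **Prediction accuracy of the aggregated weights.**  The zeros-counted
  ensemble mean biases weights toward zero by ≈ m/Ω.  In the benchmark
  netRL therefore recovers support better than the lasso but predicts
  held-out expression somewhat worse; users who need calibrated
  weights should refit the selected support or use the conditional
  (selected-replicates-only) average, neither of which this package
  does by default.
* **No global multiple-testing control.**  Significance is per edge
  within a target; a network-wide FDR layer is left to the user.
* **The beta adjacency sweep is O(p·Ω) penalized fits** and dominates
  runtime for large universes; the correlation variant is the cheap
  alternative.
* **Two-group analyses assume exchangeable samples within groups**; the
  balanced bootstrap equalizes information, it does not remove batch or
  covariate structure.
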