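# Methods

## Model

`slslogit` selects SNPs (or genes) associated with a binary case–control
phenotype by penalized logistic regression.  For genotypes
`X` (n samples × p SNPs, additive 0/1/2 coding, columns standardized so
that `n⁻¹‖X_m‖² = 1`) and disease status `y ∈ {0,1}ⁿ`, the model is the
intercept-free logistic regression `P(y=1|x) = logistic(x'β)`, and the
estimate minimizes

    Q(β) = −n⁻¹ Σᵢ [yᵢ log πᵢ + (1−yᵢ) log(1−πᵢ)]
           + Σₘ ρ(βₘ; λ₁, γ)
           + (λ₂/2) Σ_{m<k} |a_mk| (βₘ − sgn(a_mk) βₖ)²

* `ρ` is the **minimax concave penalty** (MCP): lasso-like shrinkage near
  zero, no shrinkage beyond `|β| = γλ₁`, which reduces the bias of the L1
  penalty on large effects.
* The quadratic term is a **signed Laplacian penalty** on an LD network:
  if two SNPs are strongly positively correlated the penalty pulls their
  coefficients together; if negatively correlated, toward opposite signs.
  This borrows strength across a correlated cluster instead of letting a
  sparsity penalty pick one arbitrary representative.

The λ₂/2 weight on the network quadratic is a bookkeeping convention: λ₂
is defined as the coefficient that appears in the closed-form coordinate
update (`u_m = z_m + λ₂ Σ_{k≠m} a_mk βₖ`, `t_m = 1/4 + λ₂ Σ_{k≠m}
|a_mk|`), and the objective above is the function of which that update is
the exact one-dimensional minimizer.  `laplacian_penalty()` itself
evaluates the plain quadratic sum, so callers passing λ₂/2 recover the
solver's objective exactly.

## The LD network

Edge weights use a signed power adjacency on the Pearson correlation
`r_mk` of the standardized design actually passed to the solver:

    a_mk = sgn(r_mk) · |r_mk|^α · I{|r_mk| > r_c}

* `α = 5` (default).  The power only rescales weights — it never changes
  the edge set — so it is deliberately not tuned.  The signed form
  `sgn(r)|r|^α` preserves the correlation sign for *any* α (a plain power
  `r^α` would do so only for odd integers).
* `r_c = tanh(c/√(n−3))` inverts the Fisher z-transform at a
  standard-normal threshold `c`; under zero true correlation
  `√(n−3)·arctanh(r)` is approximately N(0,1).  `c` defaults to 1.96 (the
  two-sided 5% quantile).  The threshold constant is a genuinely open
  choice — no canonical value exists for this construction — so results
  that depend on the edge density should be read as configuration-
  dependent; `c` is exposed in `NetworkConfig`.
* Ties `|r| = r_c` are excluded (strict inequality).

## Algorithm

Coordinate descent inside a bounded-weight IRLS majorization:

1. The logistic Hessian weights `πᵢ(1−πᵢ)` are replaced by their upper
   bound 1/4.  This gives a quadratic *upper bound* of the loss — so every
   sweep provably decreases Q — and makes the curvature `t_m` constant
   across iterations, avoiding per-iteration reweighting.  (The
   exactly-reweighted variant is not implemented; the fixed bound is the
   whole point of the design.)
2. At the start of each sweep the working residual `r = 4(y−π)` is
   refreshed from the current linear predictor.
3. Each coordinate is updated in closed form (two branches: soft
   threshold scaled by `t_m − 1/γ` inside the MCP region, unshrunken
   `u_m/t_m` beyond it).  `γ > 4` is required so that `t_m − 1/γ > 0`;
   the default is γ = 4.5 (a deliberately aggressive concavity — larger
   γ behaves more like the lasso).
4. Convergence: the L2 change of β over a *full* sweep below `tol`
   (default 1e-4).  Between full sweeps the solver iterates over the
   currently nonzero coordinates only (an active-set refinement, the
   same strategy glmnet/ncvreg use).  Every sweep — full or restricted —
   uses a fresh surrogate and decreases the same objective, so the fixed
   points are unchanged; convergence is only ever declared on a full
   sweep.  `max_iter` (default 1000) counts both kinds of sweep.
5. Initialization is β = 0; coordinates cycle in index order.

Because MCP makes Q non-convex, the iterate path (and occasionally the
attained local optimum) depends on the coordinate order and the sweep
schedule; selected supports are stable in practice, but coefficient-level
agreement between schedules is only to solver tolerance.  Fits at very
small λ₁ can descend a nearly flat valley of Q slower than the sweep
budget; they are returned with `converged=False` and are, in practice,
selection-equivalent to fully converged fits (tripling the budget changed
no TP/FP count in our checks).

Comparators are special cases of the same kernel: MCP (λ₂ = 0), LASSO
(λ₂ = 0 and the soft-threshold branch only, the γ→∞ limit), elastic net
(`u_m = z_m`, `t_m = 1/4 + λ₂`, i.e. L1 + ridge).

## Tuning

Two-dimensional grid search selected by misclassification
(`ŷ = I(π > 1/2)`; π = 1/2 predicts class 0) on an independent validation
set of the same size as the training set:

* λ₁: 20 geometric points from `λ_max` (the smallest λ₁ that zeroes every
  coordinate at β = 0, `max_m |n⁻¹X_m'(y − ½)|`) down to `0.01·λ_max`,
  warm-started downward within each λ₂ column.
* λ₂ ∈ {0, 0.01, 0.1, 1, 10} (also the ridge grid for the elastic net).
* Ties broken toward larger λ₁, then larger λ₂ (the sparser, smoother
  model); the winning pair is refit from zero.

## Synthetic data

The generator mimics an LD-clustered SNP panel derived from latent
expression values:

* p predictors in independent clusters of equal size (5 for p = 750, 10
  for p = 1500); within-cluster correlation either AR(1) (`ρ^|i−j|`) or
  compound-symmetric (`ρ`), marginals N(0,1).
* SNP mode cuts each column at its empirical quartiles into 0/1/2
  (upper quartile → 2; the orientation is arbitrary and immaterial after
  standardization, but fixed for reproducibility).  Level frequencies are
  (¼, ½, ¼), implied allele frequency ½.  Empirical — not theoretical
  ±0.6745 — quartiles are used.
* 10% of clusters (rounded up) carry effects; every coefficient in a
  chosen cluster is drawn Unif[0.25, 0.75]; all others are exactly 0.
  For p = 750 this gives 75 true positives, for p = 1500, 150.
* `y ~ Bernoulli(logistic(X_std β))` with no intercept, so prevalence is
  ≈ ½ — a balanced case-control framing.
* Train/validation/test draws share β and differ only in noise; all
  randomness derives from one master seed via `SeedSequence` spawning.

What this generator does **not** emulate: realistic LD decay along a
chromosome (blocks are independent and equicorrelated/AR), allele-
frequency spectra (every SNP has MAF ½), genotyping error, missingness,
covariates, or case-control ascertainment.  Passing benchmarks therefore
demonstrate correct behavior under idealized clustered correlation, not
performance on real GWAS panels.

## Benchmark conventions

* "Selected" = exactly nonzero coefficient.  The thresholding update
  produces exact zeros, so no epsilon cutoff is applied.
* TP/FP are counted against the generating support; replicate seeds are
  `master_seed + replicate`, so any replicate subset is reproducible.
* ROC curves are built in selection space along the λ₁ path at a fixed
  λ₂, averaged across replicates vertically (mean TPR on an FPR grid).
* Tuning is per replicate (each replicate gets its own validation draw).
* Reported tables use replicate counts of 100 by default; the acceptance
  script and test suite use 20 replicates for the (500, 750) scenarios
  and 5 for the p = 1500 scenarios, which keeps the Monte-Carlo error of
  the reported means small relative to the published replicate spread.

## Numerical choices

* Probabilities are computed with an overflow-safe logistic and clipped
  to [1e-10, 1−1e-10] before logarithms.
* Standardization uses the population scale (`n⁻¹‖X_m−x̄_m‖² = 1`),
  required for the unit-curvature coordinate update; coefficients are
  reported on the standardized scale.
* Missing genotypes are imputed to the column mean before
  standardization (a plumbing default, overridable by complete-case
  filtering upstream); multiallelic VCF sites are skipped with a logged
  count.
* MAF and Hardy–Weinberg filters exist as optional flags (defaults off)
  for real-data hygiene; the chi-square HWE test has 1 df on genotype
  counts.

## Known limitations

* No inference (p-values, CIs) on selected SNPs; selection only.
* No screening stage for ultra-high dimensions; the dense correlation
  matrix is O(p²) memory, fine for p in the thousands.
* The per-coordinate 1/4 weight bound trades per-sweep progress for
  guaranteed descent; on weakly-regularized, highly-correlated problems
  the solver can need hundreds of sweeps.
* An unpenalized intercept is available (`fit_intercept=True`) for
  unbalanced real data but is off by default to match the balanced
  simulation design.
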