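# slslogit

Network-constrained regularized logistic regression for selecting
disease-associated SNPs in case–control studies.

## The problem

In a case–control association study with p SNPs ≫ n subjects, penalized
logistic regression is the standard joint-analysis tool, but generic
sparsity penalties (LASSO, MCP) treat SNPs as exchangeable and ignore
linkage disequilibrium: when a cluster of SNPs is highly correlated, they
tend to pick one arbitrary representative and discard the rest.
`slslogit` implements a sparse Laplacian shrinkage penalty for the
logistic model that encodes LD as a signed correlation network, so that
correlated SNPs are selected (or dropped) coherently.

The estimate minimizes

    Q(β) = −n⁻¹ Σᵢ [yᵢ log πᵢ + (1−yᵢ) log(1−πᵢ)]        (logistic loss)
           + Σₘ ρ(βₘ; λ₁, γ)                              (MCP sparsity)
           + (λ₂/2) Σ_{m<k} |a_mk| (βₘ − sgn(a_mk) βₖ)²   (network smoothing)

where `ρ` is the minimax concave penalty and `a_mk = sgn(r_mk)|r_mk|^α ·
I{|r_mk| > r_c}` is a signed power adjacency built from pairwise Pearson
correlations, with a Fisher-transform cutoff `r_c = tanh(c/√(n−3))`.
Optimization is coordinate descent within an IRLS majorization using the
fixed weight bound 1/4, giving closed-form updates and guaranteed descent.
MCP, LASSO and elastic-net comparators are special cases of the same
solver.  See `docs/methods.md` for the full model and algorithm notes.

The package also ships the simulation generator (clustered AR/block
multivariate-normal "expression" values, quartile-dichotomized into 0/1/2
genotypes, sparse cluster-level effects) and a replicate benchmark
producing mean(sd) true/false-positive tables and selection-space ROC
curves for all four methods.

## Worked example

One simulated replicate of the base scenario — 500 subjects, 750 SNPs in
150 LD clusters of 5 with AR(ρ=0.9) within-cluster correlation, 15
clusters (75 SNPs) truly associated:

```python
from slslogit import (SimulationConfig, make_dataset, standardize_columns,
                      build_network, NetworkConfig, tune, selection_metrics)

cfg = SimulationConfig(n=500, p=750, cluster_size=5, structure="ar",
                       rho=0.9, data_type="snp", seed=42)
train, val = make_dataset(cfg)
X, mu, sd = standardize_columns(train.X)
X_val = (val.X - mu) / sd

net = build_network(X, NetworkConfig(alpha=5.0, c=1.96, n_obs=cfg.n))
print(f"network: {net.p} SNPs, {net.n_edges} edges, r_c = {net.r_c:.4f}")

result = tune(X, train.y, X_val, val.y, net=net, method="network")
lam1, lam2 = result.best_pair
m = selection_metrics(result.best_fit.beta, train.support_true)
print(f"best (lambda1, lambda2) = ({lam1:.4f}, {lam2:g}), "
      f"validation misclassification = {result.val_misclassification.min():.3f}")
print(f"selected {m.n_selected} SNPs: {m.tp} true positives, "
      f"{m.fp} false positives (of 75 truly associated)")
```

Output:

```
network: 750 SNPs, 16809 edges, r_c = 0.0877
best (lambda1, lambda2) = (0.0377, 10), validation misclassification = 0.058
selected 75 SNPs: 75 true positives, 0 false positives (of 75 truly associated)
```

The tuner searched a 20 × 5 grid of (λ₁, λ₂) by misclassification on the
independent validation set; it chose a strongly network-smoothed model
(λ₂ = 10) that recovers the full 75-SNP support with no false positives.
The MCP comparator on the same replicate (`method="mcp"`) typically finds
only one or two SNPs per correlated cluster.

A command-line interface exposes the same pipeline for files on disk
(`slslogit simulate / network / fit / tune / benchmark / evaluate`);
genotypes are read from TSV or VCF, networks are exchanged as edge-list
TSVs, and `benchmark` runs a YAML-configured scenario grid.

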