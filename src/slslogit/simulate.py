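"""Synthetic case-control data with clustered, correlated predictors.

The generator emulates a gene-expression-backed SNP design: predictors come
in independent clusters of equal size; within a cluster the latent
expression values are multivariate normal with either an AR(1) correlation
``rho^|i-j|`` or a compound-symmetric ("block") correlation ``rho``.
Expression columns are marginally standard normal.  SNP genotypes are
obtained by cutting each expression column at its empirical 1st and 3rd
quartiles into additive levels (0, 1, 2) for (aa, Aa, AA) — the upper
quartile maps to 2, a fixed orientation (after standardization the
orientation is immaterial for the fit).  This yields genotype frequencies
(1/4, 1/2, 1/4), an implied allele frequency of 1/2, and correlated SNPs
wherever the underlying expressions are correlated — a stylized stand-in
for linkage disequilibrium.

A randomly chosen 10% of clusters carry effects: every coefficient in a
chosen cluster is drawn Unif[0.25, 0.75], all others are exactly zero.
The binary response follows the intercept-free logistic model
``P(y=1|x) = logistic(x' beta)`` on the standardized design, so prevalence
is ~1/2, matching a balanced case-control framing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .solver import standardize_columns, _sigmoid_np

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_expression",
    "dichotomize_to_snps",
    "assign_effects",
    "simulate_response",
    "make_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation scenario.

    Defaults give the base scenario: n = 500 samples, p = 750 predictors
    in clusters of 5 (hence 150 clusters), AR(1) within-cluster
    correlation, 10% effect clusters with Unif[0.25, 0.75] coefficients,
    SNP (dichotomized) predictors.
    """

    n: int = 500
    p: int = 750
    cluster_size: int = 5
    structure: Literal["ar", "block"] = "ar"
    rho: float = 0.5
    effect_cluster_fraction: float = 0.10
    effect_bounds: tuple[float, float] = (0.25, 0.75)
    data_type: Literal["snp", "expression"] = "snp"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p % self.cluster_size != 0:
            raise ValueError(
                f"p = {self.p} must be divisible by cluster_size = "
                f"{self.cluster_size}")
        if not 0 <= self.rho < 1:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if not 0 <= self.effect_cluster_fraction <= 1:
            raise ValueError("effect_cluster_fraction must be in (0, 1]")
        lo, hi = self.effect_bounds
        if lo > hi:
            raise ValueError("effect_bounds must satisfy low <= high")
        if self.structure not in ("ar", "block"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.data_type not in ("snp", "expression"):
            raise ValueError(f"unknown data_type {self.data_type!r}")
        if self.n < 4:
            raise ValueError("n must be at least 4 (quartile cuts)")

    @property
    def n_clusters(self) -> int:
        return self.p // self.cluster_size


@dataclass
class SimulatedDataset:
    """Design matrix + response + ground truth for one data role."""

    X: np.ndarray
    y: np.ndarray
    beta_true: np.ndarray
    support_true: np.ndarray
    role: str = "train"

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def _cluster_correlation(size: int, rho: float, structure: str) -> np.ndarray:
    if structure == "ar":
        idx = np.arange(size)
        return rho ** np.abs(idx[:, None] - idx[None, :])
    C = np.full((size, size), rho)
    np.fill_diagonal(C, 1.0)
    return C


def simulate_expression(config: SimulationConfig,
                        rng: np.random.Generator | None = None,
                        n: int | None = None) -> np.ndarray:
    """n x p matrix of clustered MVN expression values.

    Clusters are mutually independent; within-cluster correlation is
    AR(1) or compound-symmetric at ``config.rho``; marginals are N(0, 1).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n if n is None else n
    k = config.cluster_size
    C = _cluster_correlation(k, config.rho, config.structure)
    # rho >= 0 keeps both structures positive definite for any cluster size
    L = np.linalg.cholesky(C)
    Z = rng.standard_normal((n, config.n_clusters, k))
    X = Z @ L.T
    return X.reshape(n, config.p)


def dichotomize_to_snps(expr: np.ndarray) -> np.ndarray:
    """Cut each column at its empirical quartiles into levels 0/1/2.

    x <= Q1 -> 0 (aa), Q1 < x <= Q3 -> 1 (Aa), x > Q3 -> 2 (AA); level
    frequencies are ~(1/4, 1/2, 1/4) per column.
    """
    expr = np.asarray(expr, dtype=np.float64)
    if expr.shape[0] < 4:
        raise ValueError("need at least 4 observations for quartile cuts")
    q1 = np.quantile(expr, 0.25, axis=0)
    q3 = np.quantile(expr, 0.75, axis=0)
    return ((expr > q1).astype(np.int8) + (expr > q3).astype(np.int8))


def assign_effects(config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """True coefficients: whole clusters on or off.

    ``ceil(fraction * n_clusters)`` clusters are chosen uniformly without
    replacement; their coefficients are iid Unif(low, high), all others 0.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_eff = int(np.ceil(config.effect_cluster_fraction * config.n_clusters))
    chosen = rng.choice(config.n_clusters, size=n_eff, replace=False)
    beta = np.zeros(config.p)
    lo, hi = config.effect_bounds
    for c in chosen:
        sl = slice(c * config.cluster_size, (c + 1) * config.cluster_size)
        beta[sl] = rng.uniform(lo, hi, size=config.cluster_size)
    return beta


def simulate_response(X: np.ndarray, beta_true: np.ndarray,
                      seed=None) -> np.ndarray:
    """Bernoulli response through the logistic link on the standardized X."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    X = np.asarray(X, dtype=np.float64)
    beta_true = np.asarray(beta_true, dtype=np.float64)
    if X.shape[1] != beta_true.size:
        raise ValueError("X and beta_true have incompatible shapes")
    Xs, _, _ = standardize_columns(X)
    pi = _sigmoid_np(Xs @ beta_true)
    return (rng.uniform(size=X.shape[0]) < pi).astype(np.int8)


def _one_role(config: SimulationConfig, beta: np.ndarray, role: str,
              rng: np.random.Generator) -> SimulatedDataset:
    expr = simulate_expression(config, rng)
    X = dichotomize_to_snps(expr) if config.data_type == "snp" else expr
    y = simulate_response(X, beta, rng)
    return SimulatedDataset(X=X, y=y, beta_true=beta,
                            support_true=np.flatnonzero(beta), role=role)


def make_dataset(config: SimulationConfig, with_test: bool = False
                 ) -> tuple[SimulatedDataset, ...]:
    """Train + validation (+ test) draws sharing one ground truth.

    All three roles use the same ``beta_true`` and cluster layout but
    independent expression/response draws; everything is a pure function
    of ``config`` (validation and test sets have size ``config.n``).
    """
    ss = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(4)]
    beta = assign_effects(config, rngs[0])
    roles = ["train", "validation"] + (["test"] if with_test else [])
    return tuple(_one_role(config, beta, role, rng)
                 for role, rng in zip(roles, rngs[1:]))
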