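"""Signed, weighted SNP–SNP adjacency networks from pairwise correlation.

Linkage disequilibrium induces correlation between genotype columns.  The
network used for the Laplacian penalty encodes that correlation with a
*power adjacency*: the edge weight between SNPs ``m`` and ``k`` is

    a_mk = sgn(r_mk) * |r_mk|**alpha * I{|r_mk| > r_c}

where ``r_mk`` is the Pearson correlation and ``r_c`` a cutoff derived from
the Fisher z-transform: under zero true correlation, ``sqrt(n-3) * z`` is
approximately standard normal, so a standard-normal threshold ``c``
translates into ``r_c = tanh(c / sqrt(n-3))``.  Raising a correlation to a
power ``alpha > 1`` keeps strong edges near full weight while downweighting
weak ones; the signed form preserves the sign of the correlation for any
``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "NetworkConfig",
    "AdjacencyNetwork",
    "pearson_matrix",
    "fisher_z",
    "correlation_cutoff",
    "build_adjacency",
    "build_network",
    "write_edge_list",
    "read_edge_list",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Parameters of the power-adjacency construction.

    Parameters
    ----------
    alpha
        Soft-threshold power applied to correlations.  Only rescales edge
        weights; the edge *set* is fixed by the cutoff.
    c
        Standard-normal threshold applied to ``sqrt(n-3) * fisher_z(r)``.
        The default 1.96 is the two-sided 5% normal quantile.
    n_obs
        Sample count behind the correlations; sets the cutoff scale.
    """

    alpha: float = 5.0
    c: float = 1.96
    n_obs: int = 500

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.c < 0:
            raise ValueError(f"c must be nonnegative, got {self.c}")
        if self.n_obs < 4:
            raise ValueError(
                f"n_obs must be >= 4 for the Fisher cutoff, got {self.n_obs}"
            )


@dataclass
class AdjacencyNetwork:
    """Sparse signed symmetric p x p SNP network.

    ``weights`` has zero diagonal, entries in [-1, 1], and the sparsity
    pattern {(m, k): |r_mk| > r_c, m != k}.
    """

    weights: sp.csr_array
    r_c: float
    config: NetworkConfig
    node_ids: list[str] | None = field(default=None)

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of undirected edges."""
        return self.weights.nnz // 2

    def abs_row_sums(self) -> np.ndarray:
        """sum_k |a_mk| per node, the network part of t_m."""
        return np.asarray(abs(self.weights).sum(axis=1)).ravel()


def pearson_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of the columns of ``X``.

    Raises
    ------
    ValueError
        If any column is constant (correlation undefined) or n < 2.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with at least 2 rows")
    sd = X.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant column(s) at indices {bad.tolist()}: "
                         "Pearson correlation is undefined")
    R = np.corrcoef(X, rowvar=False)
    # corrcoef can stray slightly outside [-1, 1] in floating point
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    return R


def fisher_z(r):
    """Fisher z-transform, 0.5*log((1+r)/(1-r)) = arctanh(r); |r| < 1."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(r) >= 1):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return out.item() if out.ndim == 0 else out


def correlation_cutoff(n_obs: int, c: float) -> float:
    """Correlation cutoff r_c = tanh(c / sqrt(n_obs - 3)).

    Inverts the Fisher transform at the standard-normal threshold ``c``:
    correlations whose ``sqrt(n-3) * z`` statistic exceeds ``c`` in absolute
    value pass the cutoff.  Monotone increasing in ``c``, decreasing in
    ``n_obs``.
    """
    if n_obs < 4:
        raise ValueError(f"n_obs must be >= 4, got {n_obs}")
    if c < 0:
        raise ValueError(f"c must be nonnegative, got {c}")
    return float(np.tanh(c / np.sqrt(n_obs - 3)))


def build_adjacency(R: np.ndarray, config: NetworkConfig) -> AdjacencyNetwork:
    """Threshold and power-transform a correlation matrix into a network.

    a_mk = sgn(r_mk)*|r_mk|**alpha when |r_mk| > r_c, else 0; the signed
    power keeps sign preservation for any alpha (the plain power r**alpha
    would only preserve sign for odd integer alpha).  Ties |r| == r_c are
    excluded (strict inequality).
    """
    R = np.asarray(R, dtype=np.float64)
    p = R.shape[0]
    if R.shape != (p, p) or not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("R must be a symmetric square matrix")
    r_c = correlation_cutoff(config.n_obs, config.c)
    A = np.where(np.abs(R) > r_c, np.sign(R) * np.abs(R) ** config.alpha, 0.0)
    np.fill_diagonal(A, 0.0)
    # exact symmetry regardless of floating-point asymmetries in R
    A = (A + A.T) / 2.0
    W = sp.csr_array(A)
    W.eliminate_zeros()
    return AdjacencyNetwork(weights=W, r_c=r_c, config=config)


def build_network(X: np.ndarray, config: NetworkConfig | None = None,
                  node_ids: list[str] | None = None) -> AdjacencyNetwork:
    """Correlation network straight from a design matrix (n x p)."""
    X = np.asarray(X, dtype=np.float64)
    if config is None:
        config = NetworkConfig(n_obs=X.shape[0])
    net = build_adjacency(pearson_matrix(X), config)
    net.node_ids = list(node_ids) if node_ids is not None else None
    return net


def write_edge_list(net: AdjacencyNetwork, path) -> None:
    """Write the network as a 3-column TSV (id_a, id_b, signed weight).

    One line per undirected edge (upper triangle).
    """
    coo = sp.triu(net.weights, k=1).tocoo()
    ids = net.node_ids or [f"snp{m}" for m in range(net.p)]
    df = pd.DataFrame({
        "snp_id_a": [ids[i] for i in coo.row],
        "snp_id_b": [ids[j] for j in coo.col],
        "weight": coo.data,
    })
    df.to_csv(path, sep="\t", index=False)


def read_edge_list(path, node_ids: list[str],
                   config: NetworkConfig | None = None,
                   r_c: float = 0.0) -> AdjacencyNetwork:
    """Read a 3-column TSV edge list back into an AdjacencyNetwork.

    ``node_ids`` fixes the node order (edge endpoints must be a subset).
    """
    df = pd.read_csv(path, sep="\t")
    expected = ["snp_id_a", "snp_id_b", "weight"]
    if list(df.columns) != expected:
        raise ValueError(f"edge list must have columns {expected}, "
                         f"got {list(df.columns)}")
    index = {s: i for i, s in enumerate(node_ids)}
    try:
        rows = df["snp_id_a"].map(index).to_numpy(dtype=np.int64)
        cols = df["snp_id_b"].map(index).to_numpy(dtype=np.int64)
    except (ValueError, TypeError) as exc:
        unknown = set(df["snp_id_a"]).union(df["snp_id_b"]) - set(node_ids)
        raise ValueError(f"edge list references unknown SNP ids: "
                         f"{sorted(unknown)[:5]}") from exc
    w = df["weight"].to_numpy(dtype=np.float64)
    p = len(node_ids)
    W = sp.coo_array((np.r_[w, w], (np.r_[rows, cols], np.r_[cols, rows])),
                     shape=(p, p)).tocsr()
    if config is None:
        config = NetworkConfig(n_obs=max(4, p))
    return AdjacencyNetwork(weights=W, r_c=r_c, config=config,
                            node_ids=list(node_ids))
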