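"""Penalized logistic regression with MCP + signed network (Laplacian) penalty.

Model
-----
For a binary response ``y`` and standardized design ``X`` (columns centered,
``n^{-1}||X_m||^2 = 1``), the coefficients minimize

    Q(beta) = -(1/n) sum_i [y_i log pi_i + (1-y_i) log(1-pi_i)]
              + sum_m rho(beta_m; lambda1, gamma)
              + (lambda2/2) sum_{m<k} |a_mk| (beta_m - sgn(a_mk) beta_k)^2

with ``pi_i = logistic(x_i' beta)``, ``rho`` the minimax concave penalty
(MCP) and ``a_mk`` signed network weights (see :mod:`slslogit.netadj`).
The MCP term promotes sparsity without over-shrinking large effects; the
quadratic network term pulls coefficients of connected (correlated)
predictors toward sign-adjusted equality.  The ``lambda2/2`` weight on the
quadratic sum is the convention under which the closed-form coordinate
update below is its exact minimizer; ``lambda2`` is therefore defined by
the update equations, and :func:`laplacian_penalty` itself evaluates the
plain quadratic sum.

Algorithm
---------
Coordinate descent inside an IRLS majorization.  The logistic Hessian
weights ``pi(1-pi)`` are bounded by 1/4, so each sweep works on the
quadratic upper bound with fixed weight ``w = 1/4`` and working residual
``r = 4(y - pi)``, refreshed at the start of every sweep.  For coordinate
``m``:

    z_m = (1/4)(n^{-1} X_m' r + beta_m)
    u_m = z_m + lambda2 sum_{k != m} a_mk beta_k
    t_m = 1/4 + lambda2 sum_{k != m} |a_mk|

    beta_m <- S(u_m, lambda1) / (t_m - 1/gamma)   if |u_m| <= t_m gamma lambda1
              u_m / t_m                           otherwise

where ``S`` is soft thresholding.  With ``gamma > 4`` the one-dimensional
subproblem is strictly convex (``t_m - 1/gamma > 0``) and the penalized
objective is non-increasing sweep over sweep.  The comparators are special
cases: MCP is ``lambda2 = 0``; LASSO additionally replaces the two-branch
MCP update by plain soft thresholding (the ``gamma -> inf`` limit); the
elastic net uses ``u_m = z_m`` and ``t_m = 1/4 + lambda2`` (L1 + ridge).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from numba import njit

from .netadj import AdjacencyNetwork

__all__ = [
    "PenaltySpec",
    "SolverState",
    "FitResult",
    "TuningResult",
    "mcp",
    "laplacian_penalty",
    "objective",
    "soft_threshold",
    "working_quantities",
    "coordinate_update",
    "fit",
    "fit_comparator",
    "tune",
    "standardize_columns",
    "lambda_max",
    "lambda1_grid",
    "predict_proba",
    "DEFAULT_LAMBDA2_GRID",
]

#: Fixed IRLS majorization weight: pi(1-pi) <= 1/4 for the logistic link.
W_BOUND = 0.25

#: Default network-penalty / ridge grid used by :func:`tune`.
DEFAULT_LAMBDA2_GRID = (0.0, 0.01, 0.1, 1.0, 10.0)

_MODE_MCP = 0   # MCP (+ optional network) update, Eq-(5) two branches
_MODE_SOFT = 1  # pure soft-threshold update (LASSO; gamma -> inf limit)
_MODE_ENET = 2  # elastic net: u = z, t = 1/4 + lambda2


@dataclass(frozen=True)
class PenaltySpec:
    """Tuning parameters: MCP level, network level, MCP concavity.

    ``gamma`` must exceed ``1/w = 4`` so every coordinate subproblem stays
    convex under the 1/4 majorization weight; 4.5 is the default used
    throughout the simulations (small gamma keeps concavity strong).
    """

    lambda1: float
    lambda2: float = 0.0
    gamma: float = 4.5

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1 and lambda2 must be nonnegative")
        if not self.gamma > 1.0 / W_BOUND:
            raise ValueError(
                f"gamma must be > {1.0 / W_BOUND} for a convex coordinate "
                f"subproblem under the 1/4 weight bound; got {self.gamma}. "
                "Use a larger gamma.")


@dataclass
class SolverState:
    """Per-iteration IRLS quantities (reference bookkeeping).

    ``residual`` is ``W^{-1}(y - pi) = 4(y - pi)`` and ``working_response``
    is ``eta + residual``, both refreshed at the start of each sweep.
    """

    beta: np.ndarray
    eta: np.ndarray
    pi: np.ndarray
    working_response: np.ndarray
    residual: np.ndarray
    weight: float = W_BOUND
    iteration: int = 0

    @classmethod
    def initialize(cls, X: np.ndarray, y: np.ndarray,
                   beta: np.ndarray | None = None) -> "SolverState":
        """State at beta (default 0), with working quantities refreshed."""
        n, p = X.shape
        if beta is None:
            beta = np.zeros(p)
        eta = X @ beta
        state = cls(beta=np.asarray(beta, dtype=np.float64), eta=eta,
                    pi=np.full(n, 0.5), working_response=eta.copy(),
                    residual=np.zeros(n))
        return working_quantities(state, X, y)


@dataclass
class FitResult:
    """A fitted coefficient vector with convergence metadata."""

    beta: np.ndarray
    intercept: float
    converged: bool
    n_iterations: int
    objective: float
    objective_path: np.ndarray
    spec: PenaltySpec
    method: str = "network"

    @property
    def support(self) -> np.ndarray:
        """Indices of exactly-nonzero coefficients (0-based)."""
        return np.flatnonzero(self.beta)


@dataclass
class TuningResult:
    """Grid-search record: one validation misclassification per pair."""

    grid: list[tuple[float, float]]
    val_misclassification: np.ndarray
    best_pair: tuple[float, float]
    best_fit: FitResult
    fits: list[FitResult] = field(default_factory=list, repr=False)


# ---------------------------------------------------------------------------
# penalties and objective
# ---------------------------------------------------------------------------

def soft_threshold(u, lam):
    """S(u, lam) = sgn(u) (|u| - lam)_+ ."""
    if lam < 0:
        raise ValueError("threshold must be nonnegative")
    u = np.asarray(u, dtype=np.float64)
    out = np.sign(u) * np.maximum(np.abs(u) - lam, 0.0)
    return out.item() if out.ndim == 0 else out


def mcp(t, spec: PenaltySpec):
    """MCP value rho(t; lambda1, gamma).

    Equals ``lambda1|t| - t^2/(2 gamma)`` up to the kink ``|t| = gamma
    lambda1`` and the constant ``gamma lambda1^2 / 2`` beyond it — i.e. the
    integral of the linearly decaying threshold ``lambda1 (1 - x/(gamma
    lambda1))_+``.
    """
    t = np.asarray(t, dtype=np.float64)
    a = np.abs(t)
    lam, g = spec.lambda1, spec.gamma
    inside = lam * a - t * t / (2.0 * g)
    sat = 0.5 * g * lam * lam
    out = np.where(a <= g * lam, inside, sat)
    return out.item() if out.ndim == 0 else out


def laplacian_penalty(beta: np.ndarray, net: AdjacencyNetwork,
                      lambda2: float) -> float:
    """Signed network quadratic: lambda2 sum_{m<k} |a_mk| (b_m - sgn(a_mk) b_k)^2.

    Zero exactly when every connected pair satisfies
    ``beta_m = sgn(a_mk) beta_k``.
    """
    beta = np.asarray(beta, dtype=np.float64)
    if net.weights.shape[0] != beta.size:
        raise ValueError(
            f"network has {net.weights.shape[0]} nodes but beta has "
            f"{beta.size} entries")
    coo = sp.triu(net.weights, k=1).tocoo()
    if coo.nnz == 0:
        return 0.0
    diff = beta[coo.row] - np.sign(coo.data) * beta[coo.col]
    return float(lambda2 * np.sum(np.abs(coo.data) * diff * diff))


def objective(beta: np.ndarray, X: np.ndarray, y: np.ndarray,
              net: AdjacencyNetwork | None, spec: PenaltySpec,
              intercept: float = 0.0) -> float:
    """Penalized objective Q(beta) the solver decreases.

    Negative mean Bernoulli log-likelihood plus the MCP sum plus the
    network quadratic at weight ``lambda2/2`` (the update-equation
    convention, see the module docstring).
    """
    y = _check_binary(y)
    eta = X @ beta + intercept
    pi = np.clip(_sigmoid_np(eta), 1e-10, 1.0 - 1e-10)
    loss = -np.mean(y * np.log(pi) + (1.0 - y) * np.log(1.0 - pi))
    pen = float(np.sum(mcp(beta, spec)))
    if net is not None and spec.lambda2 > 0:
        pen += laplacian_penalty(beta, net, spec.lambda2 / 2.0)
    return float(loss + pen)


# ---------------------------------------------------------------------------
# reference (pure numpy) single steps — mirrored by the compiled kernel
# ---------------------------------------------------------------------------

def working_quantities(state: SolverState, X: np.ndarray,
                       y: np.ndarray) -> SolverState:
    """Refresh pi, the working response and the residual from current eta.

    With the fixed weight 1/4 the residual is ``4(y - pi)``.
    """
    y = _check_binary(y)
    pi = np.clip(_sigmoid_np(state.eta), 1e-10, 1.0 - 1e-10)
    residual = (1.0 / state.weight) * (y - pi)
    state.pi = pi
    state.residual = residual
    state.working_response = state.eta + residual
    return state


def coordinate_update(m: int, state: SolverState, X: np.ndarray,
                      net: AdjacencyNetwork | None, spec: PenaltySpec,
                      update: str = "mcp") -> float:
    """Closed-form update for coordinate ``m`` (reference implementation).

    ``update``: "mcp" (two-branch MCP), "soft" (plain soft threshold,
    LASSO / gamma->inf), or "enet" (u = z, t = 1/4 + lambda2).
    """
    n = X.shape[0]
    z = W_BOUND * (X[:, m] @ state.residual / n + state.beta[m])
    lam2 = spec.lambda2
    if update == "enet":
        u, t = z, W_BOUND + lam2
    else:
        if net is not None and lam2 > 0:
            row = net.weights[[m], :].toarray().ravel()
            u = z + lam2 * float(row @ state.beta)
            t = W_BOUND + lam2 * float(np.abs(row).sum())
        else:
            u, t = z, W_BOUND
    if update == "soft" or update == "enet":
        return float(soft_threshold(u, spec.lambda1) / t)
    denom = t - 1.0 / spec.gamma
    if denom <= 0:
        raise ValueError(
            f"t_m - 1/gamma = {denom:.4g} <= 0 at coordinate {m}; "
            "use a larger gamma (must exceed 4)")
    if abs(u) <= t * spec.gamma * spec.lambda1:
        return float(soft_threshold(u, spec.lambda1) / denom)
    return float(u / t)


# ---------------------------------------------------------------------------
# compiled coordinate-descent kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sigmoid(t):
    if t >= 0.0:
        return 1.0 / (1.0 + np.exp(-t))
    e = np.exp(t)
    return e / (1.0 + e)


@njit(cache=True)
def _soft(u, lam):
    if u > lam:
        return u - lam
    if u < -lam:
        return u + lam
    return 0.0


@njit(cache=True)
def _kernel_objective(eta, y, beta, b0, indptr, indices, aw,
                      lam1, lam2, gamma, mode):
    n = y.size
    p = beta.size
    loss = 0.0
    for i in range(n):
        e = eta[i]
        # log(1 + exp(eta)) - y*eta, numerically stable
        if e > 0.0:
            loss += e + np.log1p(np.exp(-e)) - y[i] * e
        else:
            loss += np.log1p(np.exp(e)) - y[i] * e
    loss /= n
    pen = 0.0
    if mode == _MODE_MCP:
        for m in range(p):
            a = abs(beta[m])
            if a <= gamma * lam1:
                pen += lam1 * a - beta[m] * beta[m] / (2.0 * gamma)
            else:
                pen += 0.5 * gamma * lam1 * lam1
    else:
        for m in range(p):
            pen += lam1 * abs(beta[m])
    if mode == _MODE_ENET:
        if lam2 > 0.0:
            ss = 0.0
            for m in range(p):
                ss += beta[m] * beta[m]
            pen += 0.5 * lam2 * ss
    elif lam2 > 0.0:
        # ordered-pair CSR sum counts each edge twice: weight lam2/4
        lap = 0.0
        for m in range(p):
            for idx in range(indptr[m], indptr[m + 1]):
                a = aw[idx]
                s = 1.0 if a > 0 else -1.0
                d = beta[m] - s * beta[indices[idx]]
                lap += abs(a) * d * d
        pen += 0.25 * lam2 * lap
    return loss + pen


@njit(cache=True)
def _update_coord(m, z, beta, indptr, indices, aw, sabs, lam1, lam2,
                  gamma, mode):
    """Closed-form coordinate minimizer given z_m; returns new beta_m."""
    if mode == _MODE_ENET:
        u = z
        t = 0.25 + lam2
    else:
        if lam2 > 0.0:
            s = 0.0
            for idx in range(indptr[m], indptr[m + 1]):
                s += aw[idx] * beta[indices[idx]]
            u = z + lam2 * s
            t = 0.25 + lam2 * sabs[m]
        else:
            u = z
            t = 0.25
    if mode == _MODE_MCP:
        if abs(u) <= t * gamma * lam1:
            return _soft(u, lam1) / (t - 1.0 / gamma)
        return u / t
    return _soft(u, lam1) / t


@njit(cache=True)
def _refresh_residual(y, eta, r, fit_intercept, b0_io):
    """New IRLS surrogate: r = 4(y - pi); unpenalized intercept step."""
    n = y.size
    for i in range(n):
        r[i] = 4.0 * (y[i] - _sigmoid(eta[i]))
    diff2 = 0.0
    if fit_intercept:
        delta = 0.0
        for i in range(n):
            delta += r[i]
        delta /= n
        if delta != 0.0:
            b0_io[0] += delta
            for i in range(n):
                r[i] -= delta
                eta[i] += delta
            diff2 = delta * delta
    return diff2


@njit(cache=True, fastmath=True)
def _active_sweep(XT, y, indptr, indices, aw, sabs, lam1, lam2, gamma,
                  mode, fit_intercept, beta, b0_io, eta, coords, r):
    """One cycle over the listed coordinates on a fresh IRLS surrogate.

    Direct per-coordinate gradients with an incrementally updated working
    residual — cheaper than the Gram path when few coordinates are listed.
    """
    n = y.size
    diff2 = _refresh_residual(y, eta, r, fit_intercept, b0_io)
    for mi in range(coords.size):
        m = coords[mi]
        xm = XT[m]
        dot = 0.0
        for i in range(n):
            dot += xm[i] * r[i]
        z = 0.25 * (dot / n + beta[m])
        nb = _update_coord(m, z, beta, indptr, indices, aw, sabs, lam1,
                           lam2, gamma, mode)
        delta = nb - beta[m]
        if delta != 0.0:
            beta[m] = nb
            for i in range(n):
                r[i] -= delta * xm[i]
                eta[i] += delta * xm[i]
            diff2 += delta * delta
    return diff2


@njit(cache=True)
def _cd_solve(XT, y, indptr, indices, aw, sabs, lam1, lam2, gamma,
              mode, fit_intercept, tol, max_iter, beta, b0_io, eta,
              active_set):
    """Coordinate descent; mutates beta, b0_io, eta in place.

    Full cyclic sweeps over all p coordinates; with ``active_set`` the
    solver additionally iterates over the currently nonzero coordinates
    between full sweeps (same surrogate refresh and same fixed points —
    convergence is only declared when a *full* sweep changes beta by less
    than ``tol`` in L2).  Returns (n_sweeps, converged, status,
    objective_path); status 1 flags non-finite values.
    """
    n = y.size
    p = XT.shape[0]
    obj_path = np.empty(max_iter)
    r = np.empty(n)
    all_coords = np.arange(p)
    n_done = 0
    converged = False
    while n_done < max_iter:
        diff2 = _active_sweep(XT, y, indptr, indices, aw, sabs, lam1,
                              lam2, gamma, mode, fit_intercept, beta,
                              b0_io, eta, all_coords, r)
        obj = _kernel_objective(eta, y, beta, b0_io[0], indptr, indices, aw,
                                lam1, lam2, gamma, mode)
        obj_path[n_done] = obj
        n_done += 1
        if not np.isfinite(obj):
            return n_done, False, 1, obj_path[:n_done]
        if np.sqrt(diff2) < tol:
            converged = True
            break
        if active_set:
            act = np.flatnonzero(beta)
            if act.size == 0 or act.size == p:
                continue
            while n_done < max_iter:
                d2 = _active_sweep(XT, y, indptr, indices, aw, sabs,
                                   lam1, lam2, gamma, mode, fit_intercept,
                                   beta, b0_io, eta, act, r)
                obj = _kernel_objective(eta, y, beta, b0_io[0], indptr,
                                        indices, aw, lam1, lam2, gamma, mode)
                obj_path[n_done] = obj
                n_done += 1
                if not np.isfinite(obj):
                    return n_done, False, 1, obj_path[:n_done]
                if np.sqrt(d2) < tol:
                    break
    return n_done, converged, 0, obj_path[:n_done]


# ---------------------------------------------------------------------------
# fitting front ends
# ---------------------------------------------------------------------------

def _fit_core(X, y, net, spec, *, mode, tol, max_iter, fit_intercept,
              beta0, intercept0, method_name,
              active_set=True) -> FitResult:
    X = np.asarray(X, dtype=np.float64)
    y = _check_binary(y)
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y have incompatible shapes")
    if net is not None and net.weights.shape[0] != p:
        raise ValueError(
            f"network has {net.weights.shape[0]} nodes, X has {p} columns")
    if net is not None and spec.lambda2 > 0 and mode != _MODE_ENET:
        W = net.weights
        indptr = W.indptr.astype(np.int64)
        indices = W.indices.astype(np.int64)
        aw = W.data.astype(np.float64)
        sabs = net.abs_row_sums()
    else:
        indptr = np.zeros(p + 1, dtype=np.int64)
        indices = np.empty(0, dtype=np.int64)
        aw = np.empty(0, dtype=np.float64)
        sabs = np.zeros(p)
    beta = (np.zeros(p) if beta0 is None
            else np.asarray(beta0, dtype=np.float64).copy())
    b0 = np.array([float(intercept0)])
    eta = X @ beta + b0[0]
    XT = np.ascontiguousarray(X.T)
    n_iter, converged, status, obj_path = _cd_solve(
        XT, y, indptr, indices, aw, sabs,
        float(spec.lambda1), float(spec.lambda2), float(spec.gamma),
        mode, fit_intercept, float(tol), int(max_iter), beta, b0, eta,
        bool(active_set))
    if status == 1:
        raise FloatingPointError(
            f"non-finite values encountered at sweep {n_iter}; "
            "check that X is standardized and y is binary")
    return FitResult(beta=beta, intercept=float(b0[0]),
                     converged=bool(converged), n_iterations=int(n_iter),
                     objective=float(obj_path[-1]),
                     objective_path=np.asarray(obj_path),
                     spec=spec, method=method_name)


def fit(X, y, net: AdjacencyNetwork | None, spec: PenaltySpec,
        tol: float = 1e-4, max_iter: int = 1000, *,
        fit_intercept: bool = False, beta0=None,
        intercept0: float = 0.0, active_set: bool = True) -> FitResult:
    """Fit the network-constrained MCP logistic regression.

    ``X`` must be standardized (columns centered, ``n^{-1}||X_m||^2 = 1``;
    see :func:`standardize_columns`).  ``net=None`` or ``lambda2=0`` gives
    the plain MCP fit.  No intercept is fitted by default — the model is
    ``eta = X beta`` — matching the balanced case-control design; an
    unpenalized intercept is available via ``fit_intercept=True``.
    """
    return _fit_core(X, y, net, spec, mode=_MODE_MCP, tol=tol,
                     max_iter=max_iter, fit_intercept=fit_intercept,
                     beta0=beta0, intercept0=intercept0,
                     active_set=active_set,
                     method_name="network" if (net is not None and
                                               spec.lambda2 > 0) else "mcp")


def fit_comparator(method: str, X, y, spec: PenaltySpec,
                   net: AdjacencyNetwork | None = None,
                   tol: float = 1e-4, max_iter: int = 1000, *,
                   fit_intercept: bool = False, beta0=None,
                   intercept0: float = 0.0,
                   active_set: bool = True) -> FitResult:
    """Comparator fits: ``mcp`` / ``lasso`` / ``enet``.

    ``mcp`` is the main solver with ``lambda2 = 0``; ``lasso`` disables the
    MCP branch (pure soft-threshold update, the gamma->inf limit); ``enet``
    uses the L1 + ridge update with ridge level ``lambda2``.
    """
    if method == "mcp":
        spec0 = PenaltySpec(spec.lambda1, 0.0, spec.gamma)
        res = _fit_core(X, y, None, spec0, mode=_MODE_MCP, tol=tol,
                        max_iter=max_iter, fit_intercept=fit_intercept,
                        beta0=beta0, intercept0=intercept0,
                        active_set=active_set,
                        method_name="mcp")
    elif method == "lasso":
        spec0 = PenaltySpec(spec.lambda1, 0.0, spec.gamma)
        res = _fit_core(X, y, None, spec0, mode=_MODE_SOFT, tol=tol,
                        max_iter=max_iter, fit_intercept=fit_intercept,
                        beta0=beta0, intercept0=intercept0,
                        active_set=active_set,
                        method_name="lasso")
    elif method == "enet":
        res = _fit_core(X, y, None, spec, mode=_MODE_ENET, tol=tol,
                        max_iter=max_iter, fit_intercept=fit_intercept,
                        beta0=beta0, intercept0=intercept0,
                        active_set=active_set,
                        method_name="enet")
    else:
        raise ValueError(
            f"unknown method {method!r}; expected 'mcp', 'lasso' or 'enet'")
    return res


# ---------------------------------------------------------------------------
# tuning
# ---------------------------------------------------------------------------

def lambda_max(X, y) -> float:
    """Smallest lambda1 for which beta = 0 is a fixed point (at beta = 0)."""
    X = np.asarray(X, dtype=np.float64)
    y = _check_binary(y)
    return float(np.max(np.abs(X.T @ (y - 0.5))) / X.shape[0])


def lambda1_grid(lam_max: float, n_points: int = 20,
                 min_ratio: float = 0.01) -> np.ndarray:
    """Geometric ladder from lambda_max down to min_ratio * lambda_max."""
    if lam_max <= 0:
        raise ValueError("lambda_max must be positive")
    return np.geomspace(lam_max, min_ratio * lam_max, n_points)


def predict_proba(X, beta, intercept: float = 0.0) -> np.ndarray:
    """P(y = 1) under the logistic model."""
    return _sigmoid_np(np.asarray(X) @ np.asarray(beta) + intercept)


def _misclassification(beta, intercept, X, y) -> float:
    yhat = (predict_proba(X, beta, intercept) > 0.5).astype(np.float64)
    return float(np.mean(yhat != y))


def tune(X_train, y_train, X_val, y_val,
         net: AdjacencyNetwork | None = None,
         lam1_grid=None, lam2_grid=None, gamma: float = 4.5,
         method: str = "network", tol: float = 1e-4, max_iter: int = 1000,
         warm_start: bool = True, fit_intercept: bool = False,
         keep_fits: bool = True) -> TuningResult:
    """Grid search over (lambda1, lambda2) by validation misclassification.

    Fits every pair — warm-started along decreasing lambda1 within each
    lambda2 — and selects the pair minimizing the misclassification of
    ``yhat = I(pi > 1/2)`` on the validation set.  Ties go to the larger
    lambda1, then the larger lambda2 (the sparser, smoother model).  The
    returned ``best_fit`` is refit cold at the selected pair.

    For ``method='lasso'`` the lambda2 grid collapses to {0}; for
    ``'enet'`` lambda2 is the ridge level; for ``'mcp'`` lambda2 is forced
    to 0 as well.
    """
    y_train = _check_binary(y_train)
    y_val = _check_binary(y_val)
    if len(np.unique(y_val)) < 2:
        warnings.warn("validation labels are all one class; "
                      "misclassification is still computed", stacklevel=2)
    if lam1_grid is None:
        lam1_grid = lambda1_grid(lambda_max(X_train, y_train))
    lam1_grid = np.sort(np.asarray(lam1_grid, dtype=np.float64))[::-1]
    if method in ("lasso", "mcp"):
        lam2_grid = np.array([0.0])
    elif lam2_grid is None:
        lam2_grid = np.asarray(DEFAULT_LAMBDA2_GRID)
    else:
        lam2_grid = np.asarray(lam2_grid, dtype=np.float64)
    if lam1_grid.size == 0 or lam2_grid.size == 0:
        raise ValueError("tuning grids must be nonempty")

    def _one_fit(l1, l2, beta0, b0):
        spec = PenaltySpec(float(l1), float(l2), gamma)
        if method == "network":
            return fit(X_train, y_train, net, spec, tol, max_iter,
                       fit_intercept=fit_intercept, beta0=beta0,
                       intercept0=b0)
        return fit_comparator(method, X_train, y_train, spec, net, tol,
                              max_iter, fit_intercept=fit_intercept,
                              beta0=beta0, intercept0=b0)

    grid: list[tuple[float, float]] = []
    errs: list[float] = []
    fits: list[FitResult] = []
    best = None  # (miscl, -lam1, -lam2, fit)
    for l2 in lam2_grid:
        beta0, b0 = None, 0.0
        for l1 in lam1_grid:
            res = _one_fit(l1, l2, beta0, b0)
            if warm_start:
                beta0, b0 = res.beta, res.intercept
            err = _misclassification(res.beta, res.intercept, X_val, y_val)
            grid.append((float(l1), float(l2)))
            errs.append(err)
            if keep_fits:
                fits.append(res)
            key = (err, -l1, -l2)
            if best is None or key < best[0]:
                best = (key, res)
    best_l1, best_l2 = -best[0][1], -best[0][2]
    best_fit = _one_fit(best_l1, best_l2, None, 0.0)
    return TuningResult(grid=grid,
                        val_misclassification=np.asarray(errs),
                        best_pair=(best_l1, best_l2),
                        best_fit=best_fit, fits=fits)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def standardize_columns(X):
    """Center columns and scale to n^{-1}||X_m||^2 = 1 (population sd).

    Returns (X_std, means, scales).  Raises on constant columns.
    """
    X = np.asarray(X, dtype=np.float64)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant column(s) at indices {bad.tolist()} "
                         "cannot be standardized")
    return (X - mu) / sd, mu, sd


def _sigmoid_np(t):
    t = np.asarray(t, dtype=np.float64)
    out = np.empty_like(t)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _check_binary(y) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64).ravel()
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("y must be binary in {0, 1}")
    return y
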