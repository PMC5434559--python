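"""Replicate-level variable-selection benchmark.

Per replicate: simulate an independent train/validation pair, build the
correlation network on the standardized training design, tune each method
over its (lambda1, lambda2) grid by validation misclassification, refit at
the selected pair, and count true/false positives of the selected support
against the generating truth.  Replicates are aggregated as mean(sd) per
method x scenario — the layout of the simulation tables.  "Selected" means
an exactly nonzero coefficient (the thresholding update produces exact
zeros; no epsilon cutoff).

Replicate seeds are ``master_seed + replicate index``, so any subset of
replicates is independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .netadj import NetworkConfig, build_network
from .simulate import SimulationConfig, make_dataset
from .solver import (FitResult, predict_proba, standardize_columns, tune,
                     _check_binary)

__all__ = [
    "SelectionMetrics",
    "BenchmarkTable",
    "selection_metrics",
    "misclassification_rate",
    "roc_points",
    "average_roc",
    "run_replicate",
    "roc_from_tuning",
    "run_benchmark",
    "METHODS",
]

logger = logging.getLogger(__name__)

#: Method labels in the order of the comparison tables.
METHODS = ("network", "mcp", "enet", "lasso")


@dataclass(frozen=True)
class SelectionMetrics:
    """TP/FP of one fitted support against the ground truth."""

    tp: int
    fp: int
    replicate_id: int = 0
    method: str = ""

    @property
    def n_selected(self) -> int:
        return self.tp + self.fp


@dataclass
class BenchmarkTable:
    """Tidy per-replicate records plus mean(sd) aggregates."""

    records: pd.DataFrame       # one row per replicate x method
    summary: pd.DataFrame       # mean/sd per scenario x method
    n_failed: int = 0
    roc: dict | None = None     # (scenario key, method) -> averaged curve

    def to_wide(self) -> pd.DataFrame:
        """Scenario rows x method columns with 'mean(sd)' cells."""
        s = self.summary.copy()
        for stat in ("tp", "fp"):
            s[stat] = (s[f"{stat}_mean"].map("{:.2f}".format) + "(" +
                       s[f"{stat}_sd"].map("{:.2f}".format) + ")")
        idx = ["structure", "rho", "data_type", "n", "p", "stat"]
        long = s.melt(id_vars=["structure", "rho", "data_type", "n", "p",
                               "method"],
                      value_vars=["tp", "fp"], var_name="stat")
        return long.pivot_table(index=idx, columns="method", values="value",
                                aggfunc="first")


def selection_metrics(beta_hat: np.ndarray, support_true,
                      replicate_id: int = 0,
                      method: str = "") -> SelectionMetrics:
    """Count exactly-nonzero coefficients inside/outside the true support."""
    beta_hat = np.asarray(beta_hat)
    support_true = np.asarray(support_true, dtype=np.int64)
    if support_true.size and support_true.max() >= beta_hat.size:
        raise ValueError("support_true indices exceed beta length")
    selected = np.flatnonzero(beta_hat)
    truth = set(support_true.tolist())
    tp = sum(1 for m in selected if m in truth)
    return SelectionMetrics(tp=tp, fp=selected.size - tp,
                            replicate_id=replicate_id, method=method)


def misclassification_rate(beta_hat: np.ndarray, X: np.ndarray,
                           y: np.ndarray, intercept: float = 0.0) -> float:
    """Mean of I(yhat != y) with yhat = I(pi > 1/2); pi = 1/2 predicts 0."""
    y = _check_binary(y)
    yhat = (predict_proba(X, beta_hat, intercept) > 0.5).astype(np.float64)
    return float(np.mean(yhat != y))


def roc_points(path_fits: list[FitResult], support_true,
               p: int | None = None) -> np.ndarray:
    """Selection-space ROC along a lambda1 path: (FPR, TPR) per fit.

    TPR = tp/|S|, FPR = fp/(p - |S|); points sorted by FPR with (0,0)
    prepended and (1,1) appended.
    """
    if not path_fits:
        raise ValueError("empty lambda1 path")
    support_true = np.asarray(support_true, dtype=np.int64)
    if p is None:
        p = path_fits[0].beta.size
    n_true = support_true.size
    n_null = p - n_true
    pts = [(0.0, 0.0)]
    for res in path_fits:
        m = selection_metrics(res.beta, support_true)
        pts.append((m.fp / n_null if n_null else 0.0,
                    m.tp / n_true if n_true else 0.0))
    pts.append((1.0, 1.0))
    arr = np.array(sorted(pts))
    return arr


def average_roc(per_replicate: list[np.ndarray],
                fpr_grid: np.ndarray | None = None) -> np.ndarray:
    """Vertically average ROC curves: mean TPR at a common FPR grid."""
    if fpr_grid is None:
        fpr_grid = np.linspace(0.0, 1.0, 101)
    tprs = [np.interp(fpr_grid, c[:, 0], c[:, 1]) for c in per_replicate]
    return np.column_stack([fpr_grid, np.mean(tprs, axis=0)])


def roc_from_tuning(tr, support_true) -> np.ndarray:
    """Selection-space ROC for one replicate: the lambda1 path at the
    tuned lambda2 (requires a TuningResult with kept fits)."""
    if not tr.fits:
        raise ValueError("tuning result has no kept fits; tune with "
                         "keep_fits=True")
    l2 = tr.best_pair[1]
    path = [f for f in tr.fits if f.spec.lambda2 == l2]
    path.sort(key=lambda f: -f.spec.lambda1)
    return roc_points(path, support_true)


def run_replicate(config: SimulationConfig, methods=METHODS,
                  net_config: NetworkConfig | None = None,
                  lam2_grid=None, gamma: float = 4.5,
                  n_lambda1: int = 20, tol: float = 1e-4,
                  max_iter: int = 1000, keep_tuning: bool = False):
    """Simulate one replicate and tune + evaluate every method on it.

    Returns a list of dict records (one per method), plus the TuningResult
    per method when ``keep_tuning``.
    """
    train, val = make_dataset(config)
    Xtr, mu, sd = standardize_columns(train.X)
    Xva = (val.X - mu) / sd
    if net_config is None:
        net_config = NetworkConfig(n_obs=config.n)
    net = build_network(Xtr, net_config) if "network" in methods else None
    records, tunings = [], {}
    for method in methods:
        tr = tune(Xtr, train.y, Xva, val.y, net=net, lam2_grid=lam2_grid,
                  gamma=gamma, method=method, tol=tol, max_iter=max_iter,
                  keep_fits=keep_tuning)
        m = selection_metrics(tr.best_fit.beta, train.support_true,
                              replicate_id=config.seed, method=method)
        records.append({
            "method": method, "tp": m.tp, "fp": m.fp,
            "n_selected": m.n_selected,
            "lambda1": tr.best_pair[0], "lambda2": tr.best_pair[1],
            "val_misclassification": float(tr.val_misclassification.min()),
            "converged": tr.best_fit.converged,
        })
        tunings[method] = tr if keep_tuning else None
    return records, tunings


def run_benchmark(scenarios, methods=METHODS, n_replicates: int = 100,
                  master_seed: int = 0,
                  net_config: NetworkConfig | None = None,
                  lam2_grid=None, gamma: float = 4.5,
                  tol: float = 1e-4, max_iter: int = 1000,
                  collect_roc: bool = False) -> BenchmarkTable:
    """Mean(sd) TP/FP per scenario x method over independent replicates.

    Fully deterministic given ``master_seed``; a replicate whose fit fails
    is logged and excluded from the aggregates.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if isinstance(scenarios, SimulationConfig):
        scenarios = [scenarios]
    rows = []
    roc_curves: dict = {}
    n_failed = 0
    for config in scenarios:
        for rep in range(n_replicates):
            rep_config = replace(config, seed=master_seed + rep)
            try:
                records, tunings = run_replicate(
                    rep_config, methods=methods, net_config=net_config,
                    lam2_grid=lam2_grid, gamma=gamma, tol=tol,
                    max_iter=max_iter, keep_tuning=collect_roc)
            except (FloatingPointError, np.linalg.LinAlgError) as exc:
                n_failed += 1
                logger.warning("replicate %d of scenario %s failed: %s",
                               rep, config, exc)
                continue
            for rec in records:
                rec.update(structure=config.structure, rho=config.rho,
                           data_type=config.data_type, n=config.n,
                           p=config.p, replicate=rep)
                rows.append(rec)
            if collect_roc:
                train_support = make_dataset(rep_config)[0].support_true
                for method, tr in tunings.items():
                    roc_curves.setdefault((id(config), method), []).append(
                        roc_from_tuning(tr, train_support))
    records_df = pd.DataFrame(rows)
    keys = ["structure", "rho", "data_type", "n", "p", "method"]
    grouped = records_df.groupby(keys, sort=False)
    summary = grouped.agg(
        tp_mean=("tp", "mean"), tp_sd=("tp", "std"),
        fp_mean=("fp", "mean"), fp_sd=("fp", "std"),
        n_replicates=("tp", "size")).reset_index()
    # a single replicate has no spread: report sd 0 by convention
    single = summary["n_replicates"] == 1
    if single.any():
        logger.warning("sd reported as 0 for scenarios with one replicate")
        summary.loc[single, ["tp_sd", "fp_sd"]] = 0.0
    if n_failed:
        logger.warning("%d replicate(s) failed and were excluded", n_failed)
    roc = None
    if collect_roc:
        roc = {}
        for (cid, method), curves in roc_curves.items():
            scen = next(c for c in scenarios if id(c) == cid)
            key = (scen.structure, scen.rho, scen.data_type, scen.n,
                   scen.p, method)
            roc[key] = average_roc(curves)
    return BenchmarkTable(records=records_df, summary=summary,
                          n_failed=n_failed, roc=roc)
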