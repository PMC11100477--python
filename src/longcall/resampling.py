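"""Bootstrap stability sweeps over observation counts, feature counts, and
balanced class subsamples.

Each iteration subsamples the feature table (without replacement), re-runs
affinity propagation and fuzzy c-means, and optionally a single-split SVM,
recording cluster counts, mean typicality, and classification accuracy.
Every iteration's random stream is reconstructible from
``(master seed, grid value, iteration)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler

from .hard_clustering import APConfig, affinity_propagation, similarity_matrix
from .soft_clustering import FCMConfig, fuzzy_cmeans, select_model
from .supervised import split_train_test, train_eval_svm

DEFAULT_N_GRID = tuple(range(100, 901, 100))
DEFAULT_P_GRID = (2, 4, 6, 8, 16, 32, 40)


def _cluster_stats(
    X: np.ndarray,
    ap_config: APConfig,
    c_grid,
    mu: float,
    seed: int,
) -> dict:
    Xs = StandardScaler().fit_transform(X)
    ap = affinity_propagation(similarity_matrix(Xs), ap_config)
    # fuzzy c-means cluster count: silhouette-selected c over the grid
    chosen, _ = select_model(Xs, c_grid=c_grid, mu_grid=(mu,), seed=seed,
                             n_restarts=2, stability=False)
    sol = fuzzy_cmeans(Xs, chosen)
    return {
        "n_clusters_ap": ap.n_clusters,
        "n_clusters_fcm": sol.n_effective_clusters,
        "mean_typicality": float(sol.typicality.mean()),
    }


def _one_iteration(
    table: pd.DataFrame,
    feature_cols: list[str],
    label_col: str | None,
    rng_key: list[int],
    ap_config: APConfig,
    c_grid,
    mu: float,
    run_svm: bool,
) -> dict:
    X = table[feature_cols].to_numpy(dtype=float)
    seed = int(np.random.default_rng(rng_key).integers(2**31))
    out = _cluster_stats(X, ap_config, c_grid, mu, seed)
    if run_svm and label_col is not None:
        sub = table[feature_cols + [label_col]]
        train, test = split_train_test(sub, 0.6, seed=seed)
        if train[label_col].nunique() >= 2:
            res = train_eval_svm(train, test, "linear", label_col, feature_cols)
            out["svm_accuracy"] = res.overall_accuracy
        else:
            out["svm_accuracy"] = float("nan")
    else:
        out["svm_accuracy"] = float("nan")
    return out


def bootstrap_observations(
    table: pd.DataFrame,
    feature_cols: list[str],
    label_col: str | None = None,
    n_grid=DEFAULT_N_GRID,
    iterations: int = 25,
    seed: int = 0,
    ap_config: APConfig | None = None,
    c_grid=range(2, 8),
    mu: float = 1.5,
    run_svm: bool = False,
) -> pd.DataFrame:
    """Re-run the unsupervised (and optional SVM) analyses on random
    observation subsets of sizes ``n_grid``, ``iterations`` times each.

    Returns one row per (grid value, iteration) with AP and FCM cluster
    counts, mean typicality, and SVM accuracy.
    """
    ap_config = ap_config or APConfig(q=0.0)
    n = len(table)
    rows = []
    for gv in n_grid:
        if gv > n:
            raise ValueError(f"grid value {gv} exceeds table size {n}")
        for it in range(iterations):
            rng = np.random.default_rng([seed, gv, it])
            idx = rng.choice(n, size=gv, replace=False)
            sub = table.iloc[idx]
            stats = _one_iteration(sub, feature_cols, label_col,
                                   [seed, gv, it, 1], ap_config, c_grid, mu,
                                   run_svm)
            rows.append({"grid_value": gv, "iteration": it, **stats})
    return pd.DataFrame(rows)


def bootstrap_features(
    table: pd.DataFrame,
    feature_cols: list[str],
    label_col: str | None = None,
    p_grid=DEFAULT_P_GRID,
    iterations: int = 25,
    seed: int = 0,
    ap_config: APConfig | None = None,
    c_grid=range(2, 8),
    mu: float = 1.5,
    run_svm: bool = False,
) -> pd.DataFrame:
    """As :func:`bootstrap_observations`, but subsampling feature columns."""
    ap_config = ap_config or APConfig(q=0.0)
    p = len(feature_cols)
    rows = []
    for gv in p_grid:
        if gv > p:
            raise ValueError(f"grid value {gv} exceeds feature count {p}")
        for it in range(iterations):
            rng = np.random.default_rng([seed, gv, it])
            cols = [feature_cols[i]
                    for i in rng.choice(p, size=gv, replace=False)]
            stats = _one_iteration(table, cols, label_col,
                                   [seed, gv, it, 1], ap_config, c_grid, mu,
                                   run_svm)
            rows.append({"grid_value": gv, "iteration": it, **stats})
    return pd.DataFrame(rows)


def balanced_subsample(
    table: pd.DataFrame,
    label_col: str = "true_class",
    per_class: int = 39,
    seed: int = 0,
) -> pd.DataFrame:
    """Exactly ``per_class`` rows per class, sampled without replacement.

    Guards against the majority-class bias of unbalanced data; the default
    of 39 per class corresponds to sizing every class to the smallest one.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for cls, grp in table.groupby(label_col, sort=True):
        if len(grp) < per_class:
            raise ValueError(
                f"class {cls!r} has only {len(grp)} rows (< {per_class})")
        idx = rng.choice(len(grp), size=per_class, replace=False)
        parts.append(grp.iloc[idx])
    return pd.concat(parts, ignore_index=True)
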