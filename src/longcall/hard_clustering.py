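"""Affinity propagation from the message-passing updates, with q-quantile
preference and silhouette evaluation.

Affinity propagation elects exemplars by exchanging responsibility and
availability messages over a similarity matrix (negative squared Euclidean
distance off-diagonal). The shared diagonal "preference" controls how many
exemplars emerge; it is set to the q-quantile of the off-diagonal
similarities, so q = 0 (the minimum) favors few clusters and q = 1 (the
maximum) many. The algorithm is deterministic: no random initialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


@dataclass
class APConfig:
    q: float = 0.5
    damping: float = 0.9
    max_iterations: int = 1000
    convergence_iterations: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"q must be in [0, 1] (got {self.q})")
        if not 0.5 <= self.damping < 1.0:
            raise ValueError(f"damping must be in [0.5, 1) (got {self.damping})")


@dataclass
class ClusterSolution:
    labels: np.ndarray          # cluster id per point = exemplar row index
    exemplars: np.ndarray       # sorted exemplar row indices
    n_clusters: int
    converged: bool = True
    silhouette_values: np.ndarray | None = None
    mean_silhouette: float | None = None
    net_similarity: float | None = None
    config: APConfig | None = None
    extras: dict = field(default_factory=dict)


def similarity_matrix(table) -> np.ndarray:
    """Negative squared Euclidean similarities; diagonal left at zero until
    a preference is applied."""
    X = np.asarray(table, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if not np.isfinite(X).all():
        bad = np.where(~np.isfinite(X).all(axis=1))[0]
        raise ValueError(f"non-finite features in rows {bad.tolist()}")
    S = -cdist(X, X, metric="sqeuclidean")
    np.fill_diagonal(S, 0.0)
    return S


def preference_from_quantile(S: np.ndarray, q: float) -> float:
    """q-quantile (linear interpolation) of the off-diagonal similarities."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be in [0, 1] (got {q})")
    n = S.shape[0]
    off = S[~np.eye(n, dtype=bool)]
    return float(np.quantile(off, q))


def affinity_propagation(S: np.ndarray, config: APConfig | None = None,
                         preference: float | None = None) -> ClusterSolution:
    """Run damped responsibility/availability updates to convergence.

    ``preference`` defaults to the ``config.q`` quantile of the
    off-diagonal similarities and is written onto the diagonal. Exemplars
    are the points k with ``r(k,k) + a(k,k) > 0`` once the exemplar set has
    been stable for ``convergence_iterations`` sweeps; every other point
    joins the exemplar with the highest similarity (ties toward the lowest
    exemplar index). Non-convergence returns the current solution flagged
    ``converged=False``.
    """
    config = config or APConfig()
    S = np.array(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if not np.isfinite(S).all():
        raise ValueError("S must be finite")
    n = S.shape[0]
    if n == 1:
        return ClusterSolution(labels=np.zeros(1, int), exemplars=np.array([0]),
                               n_clusters=1, config=config)
    if preference is None:
        preference = preference_from_quantile(S, config.q)
    np.fill_diagonal(S, preference)

    # tiny deterministic jitter removes degenerate ties (standard practice)
    jit = np.random.default_rng(0).uniform(0, 1, size=(n, n))
    scale = max(np.abs(S).max(), 1.0)
    S = S + 1e-12 * scale * jit

    R = np.zeros((n, n))
    A = np.zeros((n, n))
    lam = config.damping
    idx = np.arange(n)
    last_exemplars: frozenset | None = None
    stable = 0
    converged = False
    for _ in range(config.max_iterations):
        # responsibilities: r(i,k) = s(i,k) - max_{k'!=k} [a(i,k') + s(i,k')]
        AS = A + S
        first = np.argmax(AS, axis=1)
        max1 = AS[idx, first]
        AS_tmp = AS.copy()
        AS_tmp[idx, first] = -np.inf
        max2 = AS_tmp.max(axis=1)
        Rnew = S - max1[:, None]
        Rnew[idx, first] = S[idx, first] - max2
        R = lam * R + (1 - lam) * Rnew

        # availabilities: a(i,k) = min(0, r(k,k) + sum_{i'!=i,k} max(0, r(i',k)))
        Rp = np.maximum(R, 0.0)
        np.fill_diagonal(Rp, np.diag(R))
        col = Rp.sum(axis=0)
        Anew = np.minimum(0.0, col[None, :] - Rp)
        Anew[idx, idx] = col - np.diag(Rp)
        A = lam * A + (1 - lam) * Anew

        exemplars = frozenset(np.where(np.diag(R) + np.diag(A) > 0)[0].tolist())
        if exemplars and exemplars == last_exemplars:
            stable += 1
            if stable >= config.convergence_iterations:
                converged = True
                break
        else:
            stable = 0
        last_exemplars = exemplars

    ex = np.array(sorted(last_exemplars)) if last_exemplars else np.array(
        [int(np.argmax(np.diag(R) + np.diag(A)))])
    labels = ex[np.argmax(S[:, ex], axis=1)]
    labels[ex] = ex  # exemplars label themselves
    net = float(S[idx, labels].sum())
    return ClusterSolution(labels=labels, exemplars=ex, n_clusters=len(ex),
                           converged=converged, net_similarity=net, config=config)


def silhouette_coefficients(table, labels) -> tuple[np.ndarray, float]:
    """Per-point silhouettes s(i) = (b_i - a_i)/max(a_i, b_i).

    ``a_i`` is the mean distance to the other members of i's cluster,
    ``b_i`` the smallest mean distance to any other cluster. Members of
    singleton clusters get s = 0 by convention. Raises with fewer than two
    clusters.
    """
    X = np.asarray(table, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    D = cdist(X, X)
    s = np.zeros(len(labels))
    for i in range(len(labels)):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a_i = D[i, own].sum() / (n_own - 1)
        b_i = min(D[i, labels == c].mean() for c in uniq if c != labels[i])
        denom = max(a_i, b_i)
        s[i] = (b_i - a_i) / denom if denom > 0 else 0.0
    return s, float(s.mean())


def ap_q_sweep(table, q_grid=(0.0, 0.25, 0.5, 0.75, 1.0),
               config: APConfig | None = None) -> pd.DataFrame:
    """Affinity propagation over a preference-quantile grid.

    Returns one row per q with the cluster count and mean silhouette, the
    standard model-selection sweep for this method.
    """
    base = config or APConfig()
    S = similarity_matrix(table)
    rows = []
    for q in q_grid:
        cfg = APConfig(q=q, damping=base.damping,
                       max_iterations=base.max_iterations,
                       convergence_iterations=base.convergence_iterations)
        sol = affinity_propagation(S.copy(), cfg)
        if sol.n_clusters >= 2:
            _, mean_sil = silhouette_coefficients(table, sol.labels)
        else:
            mean_sil = float("nan")
        rows.append({"q": q, "n_clusters": sol.n_clusters,
                     "mean_silhouette": mean_sil, "converged": sol.converged})
    return pd.DataFrame(rows)
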