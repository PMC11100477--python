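"""Fuzzy c-means clustering with typicality coefficients and the
internal-validity / stability measures used for model selection.

The clusterer minimizes the Bezdek objective

    J = sum_i sum_k m_ik^mu * ||x_i - v_k||^2

by alternating closed-form membership and centroid updates. The fuzzifier
``mu`` (> 1) controls membership softness: as mu -> 1 memberships become
binary (hard k-means limit), and growing mu lets clusters overlap and
eventually merge. Each pulse's typicality coefficient is the gap between
its largest and second-largest membership: near 1 = prototypical for its
cluster, near 0 = graded/intermediate.

Model selection over a (c, mu) grid uses three internal-validity measures
(connectivity, silhouette width, Dunn index) and four stability measures
under single-feature deletion (APN, AD, ADM, FOM), the candidate winning
the majority of measures being chosen.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .hard_clustering import silhouette_coefficients

#: measures where smaller is better
_MINIMIZE = {"connectivity", "APN", "AD", "ADM", "FOM"}
_MAXIMIZE = {"dunn_index", "silhouette_width"}
VALIDITY_MEASURES = tuple(sorted(_MINIMIZE | _MAXIMIZE))


@dataclass
class FCMConfig:
    c: int = 2
    mu: float = 2.0
    tolerance: float = 1e-6
    max_iterations: int = 300
    n_restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ValueError(f"c must be >= 2 (got {self.c})")
        if not self.mu > 1.0:
            raise ValueError(f"fuzzifier mu must be > 1 (got {self.mu})")


@dataclass
class FuzzySolution:
    memberships: np.ndarray  # (n, c), rows sum to 1
    centroids: np.ndarray    # (c, p)
    objective: float
    hard_labels: np.ndarray
    typicality: np.ndarray
    config: FCMConfig
    objective_trace: list[float] = field(default_factory=list)
    degenerate: bool = False

    @property
    def n_effective_clusters(self) -> int:
        return len(np.unique(self.hard_labels))


def _fcm_memberships(D2: np.ndarray, mu: float) -> np.ndarray:
    """Closed-form membership update from squared distances (n, c)."""
    zero = D2 <= 1e-300
    any_zero = zero.any(axis=1)
    expo = 1.0 / (mu - 1.0)
    with np.errstate(divide="ignore", over="ignore"):
        inv = D2 ** -expo
    m = inv / inv.sum(axis=1, keepdims=True)
    if any_zero.any():  # point coincides with a centroid
        m[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
    return m


def fuzzy_cmeans(table, config: FCMConfig | None = None) -> FuzzySolution:
    """Fuzzy c-means, best of ``n_restarts`` random initializations by J.

    Deterministic under ``config.seed``. All-identical input is flagged
    degenerate and returns uniform memberships.
    """
    config = config or FCMConfig()
    X = np.asarray(table, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n <= config.c:
        raise ValueError(f"need n > c (got n={n}, c={config.c})")

    if np.allclose(X, X[0]):
        m = np.full((n, config.c), 1.0 / config.c)
        return FuzzySolution(
            memberships=m, centroids=np.tile(X[0], (config.c, 1)),
            objective=0.0, hard_labels=np.zeros(n, int),
            typicality=np.zeros(n), config=config, degenerate=True)

    best: FuzzySolution | None = None
    for r in range(config.n_restarts):
        rng = np.random.default_rng([config.seed, r])
        m = rng.dirichlet(np.ones(config.c), size=n)
        trace: list[float] = []
        J_prev = np.inf
        for _ in range(config.max_iterations):
            w = m**config.mu
            V = (w.T @ X) / w.sum(axis=0)[:, None]
            D2 = cdist(X, V, metric="sqeuclidean")
            J = float((w * D2).sum())
            trace.append(J)
            m = _fcm_memberships(D2, config.mu)
            if abs(J_prev - J) < config.tolerance:
                break
            J_prev = J
        sol = FuzzySolution(
            memberships=m, centroids=V, objective=trace[-1],
            hard_labels=np.argmax(m, axis=1),
            typicality=typicality_coefficients(m), config=config,
            objective_trace=trace)
        if best is None or sol.objective < best.objective:
            best = sol
    return best


def typicality_coefficients(memberships: np.ndarray) -> np.ndarray:
    """Gap between each row's largest and second-largest membership.

    For c = 2 this is |m_1 - m_2|; higher values indicate pulses well
    separated from the other clusters, lower values graded pulses.
    """
    m = np.asarray(memberships, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("memberships must be (n, c) with c >= 2")
    part = np.sort(m, axis=1)
    return part[:, -1] - part[:, -2]


@dataclass
class TypicalityThresholds:
    typical_above: float
    atypical_below: float
    rule: str

    def __post_init__(self) -> None:
        if not self.atypical_below < self.typical_above:
            raise ValueError("atypical_below must be less than typical_above")


def typicality_thresholds(
    coefficients,
    rule: str = "explicit",
    typical_above: float | None = None,
    atypical_below: float | None = None,
    quantiles: tuple[float, float] = (0.25, 0.75),
    labels=None,
) -> dict:
    """Flag typical and atypical calls given a thresholding rule.

    ``rule='explicit'`` uses user thresholds (a call is typical when its
    coefficient exceeds ``typical_above`` and atypical when below
    ``atypical_below``); ``rule='quantile'`` derives the two cut points
    from the coefficient distribution at the given quantiles. Returns the
    thresholds, per-call flags, overall typical/atypical proportions, and
    per-class typical proportions when ``labels`` are supplied.
    """
    coeffs = np.asarray(coefficients, dtype=float)
    if ((coeffs < 0) | (coeffs > 1)).any():
        raise ValueError("typicality coefficients must lie in [0, 1]")
    if rule == "explicit":
        if typical_above is None or atypical_below is None:
            raise ValueError(
                "rule='explicit' requires typical_above and atypical_below")
        thr = TypicalityThresholds(typical_above, atypical_below, "explicit")
    elif rule == "quantile":
        lo, hi = np.quantile(coeffs, quantiles)
        thr = TypicalityThresholds(float(hi), float(lo), "quantile")
    else:
        raise ValueError(f"unknown thresholding rule {rule!r} "
                         "(use 'explicit' or 'quantile')")
    typical = coeffs > thr.typical_above
    atypical = coeffs < thr.atypical_below
    out = {
        "thresholds": thr,
        "typical_flag": typical,
        "atypical_flag": atypical,
        "prop_typical": float(typical.mean()) if coeffs.size else float("nan"),
        "prop_atypical": float(atypical.mean()) if coeffs.size else float("nan"),
    }
    if labels is not None:
        labels = np.asarray(list(labels))
        out["per_class_prop_typical"] = {
            c: float(typical[labels == c].mean()) for c in sorted(set(labels))
        }
    return out


def connectivity(X: np.ndarray, labels: np.ndarray, n_neighbors: int = 10) -> float:
    """Sum over points of 1/j for each j-th nearest neighbor (j = 1..L)
    that does not share the point's cluster. 0 = perfectly connected."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    L = min(n_neighbors, n - 1)
    D = cdist(X, X)
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")[:, :L]
    total = 0.0
    for i in range(n):
        for j, nb in enumerate(order[i], start=1):
            if labels[nb] != labels[i]:
                total += 1.0 / j
    return total


def dunn_index(X: np.ndarray, labels: np.ndarray) -> float:
    """Min inter-cluster distance over max intra-cluster diameter."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("Dunn index requires at least 2 clusters")
    D = cdist(X, X)
    min_between = np.inf
    max_within = 0.0
    for a, b in itertools.combinations(uniq, 2):
        min_between = min(min_between, D[np.ix_(labels == a, labels == b)].min())
    for c in uniq:
        block = D[np.ix_(labels == c, labels == c)]
        if block.size:
            max_within = max(max_within, block.max())
    return float(min_between / max_within) if max_within > 0 else float("inf")


def _stability_measures(X: np.ndarray, full: FuzzySolution,
                        config: FCMConfig) -> dict[str, float]:
    """APN/AD/ADM/FOM by deleting one feature column at a time and
    re-clustering the reduced data with the same configuration."""
    n, p = X.shape
    D = cdist(X, X)
    full_labels = full.hard_labels
    apn, ad, adm, fom = [], [], [], []
    for col in range(p):
        reduced = np.delete(X, col, axis=1)
        sol = fuzzy_cmeans(reduced, config)
        red_labels = sol.hard_labels
        apn_i, ad_i, adm_i = [], [], []
        for i in range(n):
            same_full = full_labels == full_labels[i]
            same_red = red_labels == red_labels[i]
            inter = same_full & same_red
            apn_i.append(1.0 - inter.sum() / same_full.sum())
            ad_i.append(D[i, same_red].mean())
            cen_full = X[same_full].mean(axis=0)
            cen_red = X[same_red].mean(axis=0)
            adm_i.append(float(np.linalg.norm(cen_full - cen_red)))
        apn.append(np.mean(apn_i))
        ad.append(np.mean(ad_i))
        adm.append(np.mean(adm_i))
        y = X[:, col]
        ss = 0.0
        for c in np.unique(red_labels):
            mem = red_labels == c
            ss += float(((y[mem] - y[mem].mean()) ** 2).sum())
        fom.append(np.sqrt(ss / n))
    return {"APN": float(np.mean(apn)), "AD": float(np.mean(ad)),
            "ADM": float(np.mean(adm)), "FOM": float(np.mean(fom))}


def validity_report(
    table,
    candidates: list[FCMConfig],
    n_neighbors: int = 10,
    stability: bool = True,
) -> pd.DataFrame:
    """Internal-validity and stability measures for each candidate (c, mu).

    Candidates whose hard partition collapses to a single cluster are
    flagged (NaN measures) — this happens at large fuzzifiers when
    clusters merge.
    """
    X = np.asarray(table, dtype=float)
    rows = []
    for cfg in candidates:
        sol = fuzzy_cmeans(X, cfg)
        row: dict = {"c": cfg.c, "mu": cfg.mu,
                     "n_effective": sol.n_effective_clusters}
        if sol.n_effective_clusters < 2:
            row.update({m: np.nan for m in VALIDITY_MEASURES})
            row["flag"] = "collapsed"
        else:
            labels = sol.hard_labels
            _, mean_sil = silhouette_coefficients(X, labels)
            row["connectivity"] = connectivity(X, labels, n_neighbors)
            row["dunn_index"] = dunn_index(X, labels)
            row["silhouette_width"] = mean_sil
            if stability:
                row.update(_stability_measures(X, sol, cfg))
            else:
                row.update({m: np.nan for m in ("APN", "AD", "ADM", "FOM")})
            row["flag"] = None
        rows.append(row)
    return pd.DataFrame(rows)


def select_model(
    table,
    c_grid=range(2, 8),
    mu_grid=(1.1, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0),
    seed: int = 0,
    n_restarts: int = 5,
    n_neighbors: int = 10,
    stability: bool = True,
) -> tuple[FCMConfig, pd.DataFrame]:
    """Choose (c, mu) by majority vote over the seven validity measures.

    Each measure votes for the candidate where it is best (smallest for
    connectivity/APN/AD/ADM/FOM, largest for Dunn and silhouette width);
    ties break toward fewer clusters, then smaller mu. Returns the chosen
    configuration and the full per-candidate report with vote counts.
    """
    cands = [FCMConfig(c=c, mu=mu, seed=seed, n_restarts=n_restarts)
             for c in c_grid for mu in mu_grid]
    if not cands:
        raise ValueError("empty candidate grid")
    report = validity_report(table, cands, n_neighbors=n_neighbors,
                             stability=stability)
    votes = np.zeros(len(cands), dtype=int)
    for measure in VALIDITY_MEASURES:
        col = report[measure].to_numpy(dtype=float)
        if np.all(~np.isfinite(col)):
            continue
        masked = np.where(np.isfinite(col), col, np.inf if measure in _MINIMIZE else -np.inf)
        best = masked.min() if measure in _MINIMIZE else masked.max()
        winners = np.isclose(masked, best)
        votes[winners] += 1
    report["votes"] = votes
    # majority winner; ties -> fewer clusters, then smaller mu
    order = sorted(range(len(cands)),
                   key=lambda i: (-votes[i], cands[i].c, cands[i].mu))
    chosen = cands[order[0]]
    return chosen, report
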