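"""Supervised pulse-type classification: SVM protocol, confusion statistics,
recursive feature elimination, and nonparametric group-difference tests.

The protocol mirrors common bioacoustic practice: random (unstratified)
60/40 train/test splits repeated over iterations, support vector machines
with one of four kernels at default cost/gamma, per-class accuracies from
the row-normalized confusion matrix, SVM-RFE feature ranking by squared
linear weights, and Kruskal–Wallis tests followed by Dunn's pairwise
comparisons with Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

KERNELS = {"linear": "linear", "polynomial": "poly", "radial": "rbf",
           "sigmoid": "sigmoid"}


@dataclass
class ConfusionResult:
    matrix: pd.DataFrame  # true class (rows) x predicted class (columns)
    per_class_accuracy: dict[str, float]
    overall_accuracy: float
    iteration_accuracies: list[float] = field(default_factory=list)

    @property
    def accuracy_se(self) -> float:
        accs = self.iteration_accuracies
        if len(accs) < 2:
            return float("nan")
        return float(np.std(accs, ddof=1) / math.sqrt(len(accs)))


@dataclass
class FeatureRanking:
    ranked_features: list[str]  # most -> least influential
    elimination_trace: list[float]


def split_train_test(
    table: pd.DataFrame,
    train_frac: float = 0.6,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random unstratified split into disjoint, exhaustive train/test sets."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError(f"train_frac must be in (0, 1) (got {train_frac})")
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    n_train = min(max(int(round(train_frac * n)), 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return table.iloc[perm[:n_train]], table.iloc[perm[n_train:]]


def _confusion(y_true, y_pred, labels) -> pd.DataFrame:
    mat = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for t, p in zip(y_true, y_pred):
        mat.loc[t, p] += 1
    return mat


def _confusion_to_result(mat: pd.DataFrame) -> ConfusionResult:
    diag = np.diag(mat.to_numpy())
    row_sums = mat.sum(axis=1).to_numpy()
    per_class = {
        c: (diag[i] / row_sums[i] if row_sums[i] > 0 else float("nan"))
        for i, c in enumerate(mat.index)
    }
    total = row_sums.sum()
    overall = diag.sum() / total if total > 0 else float("nan")
    return ConfusionResult(matrix=mat, per_class_accuracy=per_class,
                           overall_accuracy=float(overall))


def train_eval_svm(
    train: pd.DataFrame,
    test: pd.DataFrame,
    kernel: str = "linear",
    label_col: str = "true_class",
    feature_cols: list[str] | None = None,
    standardize: bool = True,
) -> ConfusionResult:
    """Fit an SVM on the training rows, report confusion on the test rows.

    ``kernel`` is one of linear/polynomial/radial/sigmoid; cost and gamma
    stay at library defaults. Features are z-standardized (fit on train)
    unless ``standardize`` is False.
    """
    if kernel not in KERNELS:
        raise ValueError(f"kernel must be one of {sorted(KERNELS)} (got {kernel!r})")
    if feature_cols is None:
        feature_cols = [c for c in train.columns
                        if c != label_col and pd.api.types.is_numeric_dtype(train[c])]
    y_train = train[label_col].to_numpy()
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set contains a single class")
    X_train = train[feature_cols].to_numpy(dtype=float)
    X_test = test[feature_cols].to_numpy(dtype=float)
    if standardize:
        scaler = StandardScaler().fit(X_train)
        X_train, X_test = scaler.transform(X_train), scaler.transform(X_test)
    clf = SVC(kernel=KERNELS[kernel]).fit(X_train, y_train)
    y_pred = clf.predict(X_test)
    y_test = test[label_col].to_numpy()
    labels = sorted(set(y_train) | set(y_test))
    return _confusion_to_result(_confusion(y_test, y_pred, labels))


def svm_iterations(
    table: pd.DataFrame,
    kernel: str = "linear",
    label_col: str = "true_class",
    feature_cols: list[str] | None = None,
    train_frac: float = 0.6,
    iterations: int = 20,
    seed: int = 1,
    standardize: bool = True,
) -> ConfusionResult:
    """Repeated-split SVM driver: aggregates the confusion matrix and the
    per-iteration accuracies over ``iterations`` random 60/40 splits.

    Split seeds are ``seed, seed+1, ...`` so the protocol is reproducible
    from the starting seed alone.
    """
    agg: pd.DataFrame | None = None
    accs: list[float] = []
    for it in range(iterations):
        train, test = split_train_test(table, train_frac, seed=seed + it)
        res = train_eval_svm(train, test, kernel, label_col, feature_cols,
                             standardize)
        accs.append(res.overall_accuracy)
        agg = res.matrix if agg is None else agg.add(res.matrix, fill_value=0).astype(int)
    out = _confusion_to_result(agg)
    out.iteration_accuracies = accs
    out.overall_accuracy = float(np.mean(accs))
    return out


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def confusion_stats(matrix: pd.DataFrame) -> dict:
    """Row-normalized percentages of a labeled confusion matrix.

    Returns per-class accuracy (diagonal) and the full cross-class
    percentage matrix, both rounded half-up to integers for reporting, with
    exact proportions retained under ``proportions``. Zero rows yield NaN
    and are listed under ``undefined_classes``.
    """
    mat = matrix.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (mat < 0).any() or not np.allclose(mat, np.round(mat)):
        raise ValueError("confusion matrix must hold nonnegative integer counts")
    row_sums = mat.sum(axis=1)
    props = np.divide(mat, row_sums[:, None],
                      out=np.full_like(mat, np.nan), where=row_sums[:, None] > 0)
    classes = list(matrix.index)
    pct = pd.DataFrame(
        [[_round_half_up(100 * p) if np.isfinite(p) else np.nan for p in row]
         for row in props],
        index=classes, columns=matrix.columns)
    return {
        "per_class_accuracy_pct": {c: pct.loc[c, c] for c in classes},
        "percent_matrix": pct,
        "proportions": pd.DataFrame(props, index=classes, columns=matrix.columns),
        "undefined_classes": [c for c, s in zip(classes, row_sums) if s == 0],
    }


def rfe_rank(
    table: pd.DataFrame,
    label_col: str = "true_class",
    feature_cols: list[str] | None = None,
    seed: int = 0,
    kernel: str = "linear",
    standardize: bool = True,
) -> FeatureRanking:
    """SVM recursive feature elimination ranking.

    Repeatedly fits a linear SVM, scores each surviving feature by its
    summed squared weight across the one-vs-one decision functions, drops
    the weakest, and records the training accuracy at each step. The
    returned ranking runs from most to least influential (a permutation of
    the feature set). Only the linear kernel is supported: the weight-based
    criterion is undefined otherwise.
    """
    if kernel != "linear":
        raise ValueError("rfe_rank requires the linear kernel (weight-based criterion)")
    if feature_cols is None:
        feature_cols = [c for c in table.columns
                        if c != label_col and pd.api.types.is_numeric_dtype(table[c])]
    if len(feature_cols) < 1:
        raise ValueError("need at least one feature")
    X = table[feature_cols].to_numpy(dtype=float)
    if standardize:
        X = StandardScaler().fit_transform(X)
    y = table[label_col].to_numpy()

    surviving = list(range(len(feature_cols)))
    eliminated: list[int] = []
    trace: list[float] = []
    while len(surviving) > 1:
        clf = SVC(kernel="linear").fit(X[:, surviving], y)
        trace.append(float(clf.score(X[:, surviving], y)))
        scores = np.sum(clf.coef_**2, axis=0)
        weakest = int(np.argmin(scores))
        eliminated.append(surviving.pop(weakest))
    clf = SVC(kernel="linear").fit(X[:, surviving], y) if len(set(y)) > 1 else None
    if clf is not None:
        trace.append(float(clf.score(X[:, surviving], y)))
    order = surviving + eliminated[::-1]  # survivor = most influential
    return FeatureRanking(
        ranked_features=[feature_cols[i] for i in order],
        elimination_trace=trace)


def _dunn_pairs(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's z statistics on mean ranks with tie-corrected variance."""
    ranks = stats.rankdata(values)
    n = len(values)
    uniq, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1)) if n > 1 else 0.0
    labels = sorted(set(groups))
    mean_ranks = {g: ranks[groups == g].mean() for g in labels}
    sizes = {g: int((groups == g).sum()) for g in labels}
    rows = []
    for i, g1 in enumerate(labels):
        for g2 in labels[i + 1:]:
            var = (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[g1] + 1.0 / sizes[g2])
            z = (mean_ranks[g1] - mean_ranks[g2]) / math.sqrt(var) if var > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group1": g1, "group2": g2, "z": z, "p": p})
    return pd.DataFrame(rows)


def group_tests(
    feature_values: pd.DataFrame,
    group_labels,
    feature_cols: list[str] | None = None,
    fdr_method: str = "fdr_bh",
) -> dict[str, dict]:
    """Kruskal–Wallis test per feature, with Dunn's pairwise post-hoc
    comparisons and Benjamini–Hochberg adjustment within each feature.

    Returns, per feature, the KW ``H``/``df``/``p`` and a pairwise table
    with raw and adjusted p-values. All-identical values are flagged with
    ``H = 0, p = 1``.
    """
    groups = np.asarray(list(group_labels))
    labels = sorted(set(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if feature_cols is None:
        feature_cols = [c for c in feature_values.columns
                        if pd.api.types.is_numeric_dtype(feature_values[c])]
    report: dict[str, dict] = {}
    for feat in feature_cols:
        vals = feature_values[feat].to_numpy(dtype=float)
        samples = [vals[groups == g] for g in labels]
        if any(len(s) == 0 for s in samples):
            raise ValueError(f"empty group for feature {feat}")
        if np.all(vals == vals[0]):
            report[feat] = {"H": 0.0, "df": len(labels) - 1, "p": 1.0,
                            "pairwise": None, "flag": "constant"}
            continue
        H, p = stats.kruskal(*samples)
        pairs = _dunn_pairs(vals, groups)
        pairs["p_adj"] = multipletests(pairs["p"], method=fdr_method)[1]
        report[feat] = {"H": float(H), "df": len(labels) - 1, "p": float(p),
                        "pairwise": pairs, "flag": None}
    return report
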