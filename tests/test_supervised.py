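"""Tests of the SVM classification protocol, confusion statistics, RFE
ranking, and nonparametric group tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import longcall as lc

# The published six-type confusion matrix (rows = human label, columns =
# SVM assignment) used as a printed-derivable fixture.
TABLE4 = pd.DataFrame(
    [[5, 5, 3, 0, 0, 2],
     [0, 2, 13, 0, 0, 0],
     [0, 9, 39, 8, 1, 2],
     [0, 2, 9, 41, 1, 19],
     [0, 0, 0, 22, 14, 21],
     [0, 0, 0, 15, 4, 176]],
    index=list(["HU", "VO", "HR", "LR", "IN", "SI"]),
    columns=list(["HU", "VO", "HR", "LR", "IN", "SI"]))


def separable_table(n=60, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0.0, 0.3, (n // 2, 3))
    X1 = rng.normal(4.0, 0.3, (n // 2, 3))
    df = pd.DataFrame(np.vstack([X0, X1]), columns=["f1", "f2", "f3"])
    df["true_class"] = ["a"] * (n // 2) + ["b"] * (n // 2)
    return df


class TestSplit:
    def test_sizes(self):
        df = separable_table(10)
        train, test = lc.split_train_test(df, 0.6, seed=0)
        assert len(train) == 6 and len(test) == 4

    def test_deterministic(self):
        df = separable_table(20)
        t1, _ = lc.split_train_test(df, 0.6, seed=3)
        t2, _ = lc.split_train_test(df, 0.6, seed=3)
        pd.testing.assert_frame_equal(t1, t2)

    def test_partition(self):
        df = separable_table(21)
        train, test = lc.split_train_test(df, 0.6, seed=1)
        union = pd.concat([train, test]).sort_index()
        pd.testing.assert_frame_equal(union, df)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            lc.split_train_test(separable_table(), 1.2)


class TestSVM:
    def test_separable_classes_perfect_accuracy(self):
        df = separable_table()
        train, test = lc.split_train_test(df, 0.6, seed=0)
        res = lc.train_eval_svm(train, test, "linear")
        assert res.overall_accuracy == pytest.approx(1.0)

    def test_permutation_null_matches_base_rate(self):
        """With labels shuffled, accuracy converges to the majority-class
        base rate."""
        rng = np.random.default_rng(0)
        df = separable_table(100)
        df["true_class"] = rng.permutation(df["true_class"].to_numpy())
        res = lc.svm_iterations(df, iterations=20, seed=1)
        base = df["true_class"].value_counts(normalize=True).max()
        assert abs(res.overall_accuracy - base) < 0.15

    def test_intermediate_class_least_accurate(self, graded_table):
        """On two-archetype data with a graded bridge, the planted
        intermediary class is hardest to classify."""
        table, _, _ = graded_table
        feats = lc.synthetic.feature_columns(table)
        res = lc.svm_iterations(table[feats + ["true_class"]],
                                iterations=5, seed=1)
        acc = res.per_class_accuracy
        assert acc["IN"] <= min(acc["SI"], acc["HR"])

    def test_single_class_training_rejected(self):
        df = separable_table()
        df["true_class"] = "a"
        train, test = lc.split_train_test(df, 0.6, seed=0)
        with pytest.raises(ValueError, match="single class"):
            lc.train_eval_svm(train, test)

    def test_unknown_kernel_rejected(self):
        df = separable_table()
        train, test = lc.split_train_test(df, 0.6, seed=0)
        with pytest.raises(ValueError, match="kernel"):
            lc.train_eval_svm(train, test, kernel="rbf2")

    def test_confusion_row_sums_conserved(self):
        df = separable_table()
        train, test = lc.split_train_test(df, 0.6, seed=2)
        res = lc.train_eval_svm(train, test)
        counts = test["true_class"].value_counts()
        for cls in res.matrix.index:
            assert res.matrix.loc[cls].sum() == counts.get(cls, 0)


class TestConfusionStats:
    def test_published_confusion_percentages(self):
        """Row-normalized percentages of the printed confusion matrix:
        LR 57% correct, VO->HR 87%, IN->LR 39%, HU 33%."""
        out = lc.confusion_stats(TABLE4)
        assert out["per_class_accuracy_pct"]["LR"] == 57
        assert out["percent_matrix"].loc["VO", "HR"] == 87
        assert out["percent_matrix"].loc["IN", "LR"] == 39
        assert out["per_class_accuracy_pct"]["HU"] == 33
        assert out["percent_matrix"].loc["LR", "SI"] == 26
        assert out["per_class_accuracy_pct"]["SI"] == 90

    def test_identity_matrix_all_perfect(self):
        mat = pd.DataFrame(np.eye(3, dtype=int) * 7,
                           index=list("abc"), columns=list("abc"))
        out = lc.confusion_stats(mat)
        assert all(v == 100 for v in out["per_class_accuracy_pct"].values())

    def test_zero_row_flagged(self):
        mat = pd.DataFrame([[3, 0], [0, 0]], index=list("ab"), columns=list("ab"))
        out = lc.confusion_stats(mat)
        assert out["undefined_classes"] == ["b"]


class TestRFE:
    def test_informative_feature_ranked_first(self):
        """One informative + one noise feature: the informative feature wins
        the top rank in >= 18/20 seeded runs."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 60
            y = np.repeat(["a", "b"], n // 2)
            df = pd.DataFrame({
                "signal": np.where(y == "a", 0.0, 3.0) + rng.normal(0, 0.5, n),
                "noise": rng.normal(0, 1.0, n),
                "true_class": y,
            })
            rank = lc.rfe_rank(df, seed=seed)
            wins += rank.ranked_features[0] == "signal"
        assert wins >= 18

    def test_single_feature_trivial(self):
        df = separable_table()
        rank = lc.rfe_rank(df, feature_cols=["f1"])
        assert rank.ranked_features == ["f1"]

    def test_ranking_is_permutation(self):
        df = separable_table()
        rank = lc.rfe_rank(df)
        assert sorted(rank.ranked_features) == ["f1", "f2", "f3"]

    def test_nonlinear_kernel_rejected(self):
        with pytest.raises(ValueError, match="linear"):
            lc.rfe_rank(separable_table(), kernel="radial")


class TestGroupTests:
    def test_constant_values_flagged(self):
        df = pd.DataFrame({"f": [1.0] * 6})
        rep = lc.group_tests(df, list("aabbcc"))
        assert rep["f"]["H"] == 0.0
        assert rep["f"]["p"] == 1.0
        assert rep["f"]["flag"] == "constant"

    def test_fully_separated_groups_rank_arithmetic(self):
        """Groups {1,2,3},{4,5,6},{7,8,9}: mean ranks 2/5/8, no ties, so
        var = (N(N+1)/12)(1/3+1/3) = 5 and the Dunn z values are 3/sqrt(5)
        (adjacent pairs) and 6/sqrt(5) (extremes); KW is significant."""
        df = pd.DataFrame({"f": [1, 2, 3, 4, 5, 6, 7, 8, 9.0]})
        rep = lc.group_tests(df, list("aaabbbccc"))
        assert rep["f"]["p"] < 0.05
        pw = rep["f"]["pairwise"].set_index(["group1", "group2"])
        assert abs(pw.loc[("a", "b"), "z"]) == pytest.approx(3 / np.sqrt(5))
        assert abs(pw.loc[("a", "c"), "z"]) == pytest.approx(6 / np.sqrt(5))
        assert pw.loc[("a", "c"), "p"] < 0.05

    def test_kw_statistic_matches_rank_formula(self):
        """Brute-force KW from the rank-sum formula on 15 random values."""
        rng = np.random.default_rng(4)
        vals = rng.normal(size=15)
        groups = np.array(list("aaaaabbbbbccccc"))
        df = pd.DataFrame({"f": vals})
        rep = lc.group_tests(df, groups)
        ranks = stats.rankdata(vals)
        N = len(vals)
        H = 12.0 / (N * (N + 1)) * sum(
            (groups == g).sum() * ranks[groups == g].mean() ** 2
            for g in "abc") - 3 * (N + 1)
        assert rep["f"]["H"] == pytest.approx(H)

    def test_bh_adjustment_ordering(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"f": np.concatenate([
            rng.normal(0, 1, 10), rng.normal(1, 1, 10), rng.normal(3, 1, 10)])})
        rep = lc.group_tests(df, ["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        pw = rep["f"]["pairwise"]
        assert (pw["p_adj"] >= pw["p"] - 1e-12).all()
        # BH preserves p-value ordering
        order = pw.sort_values("p")
        assert order["p_adj"].is_monotonic_increasing

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            lc.group_tests(pd.DataFrame({"f": [1.0, 2.0]}), ["a", "a"])
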