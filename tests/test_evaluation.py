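import math

import numpy as np
import pytest

from mirdap.errors import ConfigurationError, DataError, UnknownEntityError
from mirdap.evaluation import (ConfusionCounts, cross_validate, metrics,
                               pr_curve, rank_candidates, roc_auc)
from mirdap.fusion import FeatureTable
from mirdap.io_formats import AssociationSet, NamedMatrix
from mirdap.lmt import make_classifier


def pair_counting_auc(scores, labels):
    """Independent oracle: Mann-Whitney pair statistic with half-ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestMetrics:
    def test_perfect_prediction(self):
        m = metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert m["accuracy"] == 1.0 and m["mcc"] == 1.0

    def test_hand_worked_counts(self):
        m = metrics(ConfusionCounts(tp=3, tn=4, fp=1, fn=2))
        assert m["accuracy"] == pytest.approx(0.7)
        assert m["sensitivity"] == pytest.approx(0.6)
        assert m["precision"] == pytest.approx(0.75)
        assert m["mcc"] == pytest.approx(10 / math.sqrt(600), abs=1e-6)
        assert m["mcc"] == pytest.approx(0.4082, abs=1e-4)

    def test_zero_denominator_flagged(self):
        m = metrics(ConfusionCounts(tp=3, tn=0, fp=2, fn=0))
        assert m["mcc"] == 0.0 and "mcc" in m["zero_denominator"]
        assert m["precision"] == pytest.approx(0.6)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(DataError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_exhaustive_small_confusion_oracle(self):
        # every confusion matrix with total <= 12 against direct formulas
        for tp in range(13):
            for tn in range(13 - tp):
                for fp in range(13 - tp - tn):
                    for fn in range(13 - tp - tn - fp):
                        if tp + tn + fp + fn == 0:
                            continue
                        m = metrics(ConfusionCounts(tp, tn, fp, fn))
                        total = tp + tn + fp + fn
                        assert m["accuracy"] == pytest.approx(
                            (tp + tn) / total, abs=1e-12)
                        if tp + fn:
                            assert m["sensitivity"] == pytest.approx(
                                tp / (tp + fn), abs=1e-12)
                        den = math.sqrt((tp + fp) * (tp + fn)
                                        * (tn + fp) * (tn + fn))
                        if den:
                            assert m["mcc"] == pytest.approx(
                                (tp * tn - fp * fn) / den, abs=1e-12)


class TestAuc:
    def test_scores_equal_labels(self):
        assert roc_auc([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0

    def test_anti_scores(self):
        assert roc_auc([1, 0, 1, 0], [0, 1, 0, 1]) == 0.0

    def test_null_distribution(self):
        rng = np.random.default_rng(0)
        scores = rng.random(10000)
        labels = rng.integers(0, 2, 10000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        scores = rng.choice(np.linspace(0, 1, 11), size=n)  # force ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels) == pytest.approx(
            pair_counting_auc(scores, labels), abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            roc_auc([0.2, 0.8], [1, 1])

    def test_pr_curve_shape(self):
        df = pr_curve([0.1, 0.9, 0.4], [0, 1, 1])
        assert set(df.columns) == {"recall", "precision", "threshold"}


def balanced_table(n=100, width=4, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, width))
    y = np.zeros(n, dtype=int)
    y[: n // 2] = 1
    X[:, 0] += 2.0 * y  # informative attribute
    pairs = [(f"d{i}", f"m{i}") for i in range(n)]
    return FeatureTable(pairs=pairs, labels=y, features=X)


class TestCrossValidation:
    def test_fold_partition_contract(self):
        table = balanced_table()
        report = cross_validate(table, make_classifier("random_forest", 0),
                                k=5, seed=1)
        sizes = [f["n_test"] for f in report.per_fold]
        assert sum(sizes) == 100
        assert max(sizes) - min(sizes) <= 1

    def test_same_seed_identical_metrics(self):
        table = balanced_table()
        r1 = cross_validate(table, make_classifier("random_forest", 0), seed=2)
        r2 = cross_validate(table, make_classifier("random_forest", 0), seed=2)
        assert r1.per_fold == r2.per_fold

    def test_class_smaller_than_folds_rejected(self):
        table = balanced_table(n=8)
        with pytest.raises(DataError):
            cross_validate(table, make_classifier("random_forest", 0), k=5)

    def test_k_below_two_rejected(self):
        with pytest.raises(ConfigurationError):
            cross_validate(balanced_table(), make_classifier("random_forest", 0),
                           k=1)

    def test_report_layout(self, tmp_path):
        table = balanced_table()
        report = cross_validate(table, make_classifier("random_forest", 0),
                                k=4, seed=0)
        report.to_tsv(tmp_path / "report.tsv")
        lines = (tmp_path / "report.tsv").read_text().splitlines()
        assert len(lines) == 1 + 4 + 1  # header, folds, average
        assert lines[-1].startswith("average")
        assert report.std["auc"] >= 0.0


class ConstantScores:
    """Stub classifier mapping each row to a fixed score (for ranking tests)."""

    def __init__(self, mapping):
        self.mapping = mapping

    def predict_proba(self, X):
        p = np.array([self.mapping[i] for i in range(len(X))])
        return np.column_stack([1 - p, p])


class TestRanking:
    def setup_method(self):
        self.assoc = AssociationSet(
            ["dA", "dB"], ["m1", "m2", "m3"],
            np.array([[1, 0, 0], [0, 1, 0]]))
        n_d, n_m = 2, 3
        self.dsim = NamedMatrix(["dA", "dB"], ["dA", "dB"], np.eye(2))
        self.rsim = NamedMatrix(["m1", "m2", "m3"], ["m1", "m2", "m3"],
                                np.eye(3))
        self.rseq = NamedMatrix(["m1", "m2", "m3"], ["dim0"], np.zeros((3, 1)))

    def test_top_n_and_known_flags(self):
        model = ConstantScores({0: 0.9, 1: 0.4, 2: 0.6})
        df = rank_candidates(model, "dA", self.assoc, self.dsim, self.rsim,
                             self.rseq, n=2)
        assert list(df["mirna"]) == ["m1", "m3"]
        assert list(df["known"]) == [True, False]

    def test_n_larger_than_candidates(self):
        model = ConstantScores({0: 0.5, 1: 0.5, 2: 0.5})
        df = rank_candidates(model, "dA", self.assoc, self.dsim, self.rsim,
                             self.rseq, n=30)
        assert len(df) == 3

    def test_ties_break_by_name(self):
        model = ConstantScores({0: 0.5, 1: 0.5, 2: 0.5})
        df = rank_candidates(model, "dB", self.assoc, self.dsim, self.rsim,
                             self.rseq, n=3)
        assert list(df["mirna"]) == ["m1", "m2", "m3"]

    def test_exclude_known(self):
        model = ConstantScores({0: 0.9, 1: 0.4, 2: 0.6})
        df = rank_candidates(model, "dA", self.assoc, self.dsim, self.rsim,
                             self.rseq, n=3, include_known=False)
        assert "m1" not in set(df["mirna"])

    def test_unknown_disease_rejected(self):
        model = ConstantScores({0: 0.5, 1: 0.5, 2: 0.5})
        with pytest.raises(UnknownEntityError):
            rank_candidates(model, "nope", self.assoc, self.dsim, self.rsim,
                            self.rseq)
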