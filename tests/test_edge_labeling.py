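import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lepin import (ComplexSet, ConfusionCounts, WeightedPIN, build_lepin,
                   classification_metrics, generate_edge_feature_data,
                   label_edges, rank_auc, subsampled_cv)
from lepin.edge_labeling import C_EDGE, NC_EDGE, UNLABELED


class TestLabelEdges:
    def test_co_members_are_c_edges(self):
        pin = WeightedPIN.from_edges([("a", "b", 0.5)])
        gold = ComplexSet.from_iterable([{"a", "b"}])
        assert label_edges(pin, gold)[0].label == C_EDGE

    def test_universe_non_co_members_are_nc_edges(self):
        pin = WeightedPIN.from_edges([("a", "c", 0.5)])
        gold = ComplexSet.from_iterable([{"a", "b"}, {"c", "d"}])
        assert label_edges(pin, gold)[0].label == NC_EDGE

    def test_outside_universe_is_unlabeled(self):
        pin = WeightedPIN.from_edges([("a", "x", 0.5)])
        gold = ComplexSet.from_iterable([{"a", "b"}])
        assert label_edges(pin, gold)[0].label == UNLABELED

    def test_labels_partition_all_edges(self):
        pin = WeightedPIN.from_edges(
            [("a", "b", .5), ("a", "c", .5), ("a", "x", .5), ("b", "c", .5)])
        gold = ComplexSet.from_iterable([{"a", "b"}, {"c", "d"}])
        labels = label_edges(pin, gold)
        assert len(labels) == pin.number_of_edges()
        counts = {C_EDGE: 0, NC_EDGE: 0, UNLABELED: 0}
        for l in labels:
            counts[l.label] += 1
        assert sum(counts.values()) == pin.number_of_edges()
        assert counts == {C_EDGE: 1, NC_EDGE: 2, UNLABELED: 1}


class TestClassificationMetrics:
    def test_perfect_classifier(self):
        rep = classification_metrics(ConfusionCounts(TP=10, TN=10, FP=0, FN=0))
        assert (rep.ACC, rep.SEN, rep.SPE, rep.PRE, rep.F1, rep.MCC) == \
            (1, 1, 1, 1, 1, 1)

    def test_hand_worked_confusion_table(self):
        rep = classification_metrics(ConfusionCounts(TP=2, FP=1, TN=3, FN=0))
        assert rep.ACC == pytest.approx(5 / 6)
        assert rep.SEN == 1
        assert rep.SPE == pytest.approx(0.75)
        assert rep.PRE == pytest.approx(2 / 3)
        assert rep.F1 == pytest.approx(0.8)
        assert rep.MCC == pytest.approx(6 / np.sqrt(72))

    def test_degenerate_precision_is_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            rep = classification_metrics(ConfusionCounts(TP=0, FP=0, TN=3, FN=2))
        assert rep.PRE == 0.0
        assert any("PRE" in r.message for r in caplog.records)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(ConfusionCounts())

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50), st.integers(0, 50))
    def test_metric_identities_on_random_tables(self, tp, fp, tn, fn):
        if tp + fn == 0 or tn + fp == 0:
            return
        cc = ConfusionCounts(tp, fp, tn, fn)
        rep = classification_metrics(cc)
        assert rep.F1 == pytest.approx(
            2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0)
        prev_pos = (tp + fn) / cc.total
        assert rep.ACC == pytest.approx(
            prev_pos * rep.SEN + (1 - prev_pos) * rep.SPE)
        assert -1.0 <= rep.MCC <= 1.0


class TestRankAuc:
    def test_perfect_and_reversed_rankings(self):
        y = np.array([0, 0, 1, 1])
        assert rank_auc(y, [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert rank_auc(y, [0.9, 0.8, 0.2, 0.1]) == 0.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, size=1000)
        s = rng.random(1000)
        assert rank_auc(y, s) == pytest.approx(0.5, abs=0.05)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, size=200)
        s = rng.random(200)
        assert rank_auc(y, s) == pytest.approx(roc_auc_score(y, s))


class TestSubsampledCV:
    def test_balanced_training_rounds_arithmetic(self, centroid_factory):
        X, y = generate_edge_feature_data(20, 200, separation=2, seed=0)
        calls = []

        def factory(seed):
            clf = centroid_factory(seed)
            orig_fit = clf.fit

            def fit(Xf, yf):
                calls.append(np.bincount(np.asarray(yf).astype(int), minlength=2))
                return orig_fit(Xf, yf)
            clf.fit = fit
            return clf

        res = subsampled_cv(X, y, folds=10, seed=1, classifier_factory=factory)
        for counts in calls:
            assert counts[0] == counts[1] == 18  # 1:1 balance, 9/10 of 20
        # every edge held out exactly once
        assert not np.isnan(res.heldout_probability).any()
        assert sorted(np.bincount(res.fold_of_row)) == [22] * 10

    def test_separable_features_give_perfect_aggregate(self, centroid_factory):
        X, y = generate_edge_feature_data(100, 400, separation=8, seed=2)
        res = subsampled_cv(X, y, folds=10, seed=2,
                            classifier_factory=centroid_factory)
        assert res.report.SEN == 1.0
        assert res.report.SPE == 1.0

    def test_same_seed_reproduces_folds(self, centroid_factory):
        X, y = generate_edge_feature_data(30, 100, separation=3, seed=4)
        r1 = subsampled_cv(X, y, seed=9, classifier_factory=centroid_factory)
        r2 = subsampled_cv(X, y, seed=9, classifier_factory=centroid_factory)
        assert np.array_equal(r1.fold_of_row, r2.fold_of_row)
        assert np.array_equal(r1.heldout_probability, r2.heldout_probability)

    def test_too_small_class_suggests_fewer_folds(self):
        X, y = generate_edge_feature_data(5, 100, separation=1, seed=0)
        with pytest.raises(ValueError, match="fewer folds"):
            subsampled_cv(X, y, folds=10)


class TestBuildLepin:
    def _pin_features(self):
        from lepin import featurize_edges
        pin = WeightedPIN.from_edges([("a", "b", 1.0), ("b", "c", 1.0)])
        import pandas as pd
        feats = pd.DataFrame(
            [[0.9], [0.1]],
            index=pd.MultiIndex.from_tuples([("a", "b"), ("b", "c")]),
            columns=["f"])
        return pin, feats

    class ConstantClassifier:
        def __init__(self, p):
            self.p = p

        def fit(self, X, y):
            return self

        def predict_probability(self, X):
            return np.full(len(X), self.p)

    def test_constant_classifier_sets_all_weights(self):
        pin, feats = self._pin_features()
        lepin = build_lepin(pin, self.ConstantClassifier(0.7), feats)
        assert all(d["weight"] == 0.7 for _, _, d in lepin.edges(data=True))

    def test_pinned_training_labels(self):
        pin, feats = self._pin_features()
        lepin = build_lepin(pin, self.ConstantClassifier(0.7), feats,
                            pin_training_labels={frozenset(("a", "b")): True})
        assert lepin.weight("a", "b") == 1.0
        assert lepin.weight("b", "c") == 0.7

    def test_missing_feature_rows_rejected(self):
        pin, feats = self._pin_features()
        with pytest.raises(ValueError, match="lack feature rows"):
            build_lepin(pin, self.ConstantClassifier(0.5), feats.iloc[:1])

    def test_output_is_valid_pin(self, centroid_factory):
        rng = np.random.default_rng(0)
        import pandas as pd
        pin = WeightedPIN.from_edges(
            [(f"n{i}", f"n{i+1}", 1.0) for i in range(10)])
        pairs = [(u, v) if u <= v else (v, u) for u, v in pin.edges()]
        feats = pd.DataFrame(rng.random((len(pairs), 3)),
                             index=pd.MultiIndex.from_tuples(pairs))
        clf = centroid_factory(0).fit(feats.to_numpy(),
                                      rng.integers(0, 2, len(pairs)))
        lepin = build_lepin(pin, clf, feats)
        assert all(0.0 <= d["weight"] <= 1.0
                   for _, _, d in lepin.edges(data=True))
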