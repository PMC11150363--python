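"""BAG computation, the voting ensemble and confusion-count metrics.

The metric implementations are pinned against brute-force counting oracles
(exhaustive over all small label/prediction combinations) and the AUC
against the Mann-Whitney U normalisation and sklearn's independent
implementation.
"""

import itertools

import numpy as np
import pytest

from brainage import (
    AgePrediction,
    classification_metrics,
    classify_ad,
    compute_bag,
    ensemble_predict,
    fit_classifiers,
    roc_points,
)


class TestComputeBag:
    def test_paper_style_example(self):
        assert compute_bag([(75.0, 77.6)])[0] == pytest.approx(2.6)

    def test_equal_ages_give_zero(self):
        assert compute_bag([(60.0, 60.0)])[0] == 0.0

    def test_vector_preserves_order_and_length(self):
        pairs = [(60.0, 62.0), (70.0, 69.0), (50.0, 55.0)]
        out = compute_bag(pairs)
        np.testing.assert_allclose(out, [2.0, -1.0, 5.0])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            compute_bag([(np.nan, 60.0)])

    def test_ageprediction_bag_identity(self):
        p = AgePrediction("s", 70.0, 76.5, "AD")
        assert p.bag == pytest.approx(76.5 - 70.0)


class TestEnsemble:
    def test_separable_bags_fit_perfectly(self):
        bag = np.array([-2.0, -1.5, -1.0, -0.5, 4.0, 4.5, 5.0, 5.5])
        labels = ["CN"] * 4 + ["AD"] * 4
        model = fit_classifiers(bag, labels, seed=0)
        for name, prob in model.base_probabilities(bag).items():
            pred = np.where(prob >= 0.5, "AD", "CN")
            assert (pred == np.array(labels)).all(), name

    def test_shuffled_labels_give_chance_accuracy_out_of_sample(self, rng):
        """Label-permuted training data carries no signal to held-out samples."""
        bag = rng.normal(0, 3, size=300)
        labels = np.array(["CN", "AD"] * 150)[rng.permutation(300)]
        model = fit_classifiers(bag[:200], labels[:200], seed=1)
        pred, _ = ensemble_predict(model, bag[200:])
        acc = np.mean(pred == labels[200:])
        assert 0.35 < acc < 0.65  # chance level up to sampling noise

    def test_same_seed_identical_decisions(self, rng):
        bag = rng.normal(0, 3, size=60)
        labels = ["AD" if b > 0 else "CN" for b in bag]
        probe = np.linspace(-6, 6, 50)
        m1 = fit_classifiers(bag, labels, seed=9)
        m2 = fit_classifiers(bag, labels, seed=9)
        p1, q1 = ensemble_predict(m1, probe)
        p2, q2 = ensemble_predict(m2, probe)
        assert (p1 == p2).all()
        np.testing.assert_array_equal(q1, q2)

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError):
            fit_classifiers(np.array([1.0, 2.0]), ["CN", "CN"], seed=0)

    def test_vote_rule_matches_enumeration_oracle(self):
        """All 2^4 vote patterns against a brute-force rule implementation."""

        class _Stub:
            def __init__(self, p):
                self.p = p

            def predict_proba(self, x):
                return np.column_stack([1 - np.full(len(x), self.p),
                                        np.full(len(x), self.p)])

        from brainage.bag_ad import EnsembleModel

        for votes in itertools.product([0, 1], repeat=4):
            for tie_prob in (0.3, 0.7):
                # voting classifiers get probability .9/.1; in a tie the mean
                # probability decides, so give tied patterns a controlled mean
                probs = [0.9 if v else 0.1 for v in votes]
                if sum(votes) == 2:
                    probs = [tie_prob] * 4
                model = EnsembleModel(
                    classifiers={f"c{i}": _Stub(p) for i, p in enumerate(probs)},
                    seed=0,
                )
                labels, mean_prob = ensemble_predict(model, np.zeros(1))
                n_ad = sum(p >= 0.5 for p in probs)
                if n_ad > 2:
                    expected = "AD"
                elif n_ad < 2:
                    expected = "CN"
                else:
                    expected = "AD" if np.mean(probs) > 0.5 else "CN"
                assert labels[0] == expected, (votes, tie_prob)
                assert mean_prob[0] == pytest.approx(np.mean(probs))

    def test_two_two_tie_broken_by_mean_probability(self):
        class _Stub:
            def __init__(self, p):
                self.p = p

            def predict_proba(self, x):
                return np.column_stack([1 - np.full(len(x), self.p),
                                        np.full(len(x), self.p)])

        from brainage.bag_ad import EnsembleModel

        model = EnsembleModel(
            classifiers={"a": _Stub(0.95), "b": _Stub(0.95),
                         "c": _Stub(0.45), "d": _Stub(0.45)},
            seed=0,
        )
        labels, prob = ensemble_predict(model, np.zeros(1))
        assert prob[0] == pytest.approx(0.7)
        assert labels[0] == "AD"


def confusion_oracle(truth, pred):
    """Direct tally, written independently of the implementation."""
    tp = sum(1 for t, p in zip(truth, pred) if t == "AD" and p == "AD")
    fp = sum(1 for t, p in zip(truth, pred) if t == "CN" and p == "AD")
    fn = sum(1 for t, p in zip(truth, pred) if t == "AD" and p == "CN")
    tn = sum(1 for t, p in zip(truth, pred) if t == "CN" and p == "CN")
    return tp, fp, fn, tn


def mann_whitney_auc(truth, scores):
    """AUC as the normalised Mann-Whitney U statistic (tie-free scores)."""
    pos = [s for t, s in zip(truth, scores) if t == "AD"]
    neg = [s for t, s in zip(truth, scores) if t == "CN"]
    wins = sum(1 for p in pos for n in neg if p > n)
    ties = sum(1 for p in pos for n in neg if p == n)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestClassificationMetrics:
    def test_toy_confusion_closed_form(self):
        truth = ["AD"] * 3 + ["CN"] * 1 + ["AD"] * 2 + ["CN"] * 4
        pred = ["AD"] * 3 + ["AD"] * 1 + ["CN"] * 2 + ["CN"] * 4
        r = classification_metrics(truth, pred)
        assert (r.tp, r.fp, r.fn, r.tn) == (3, 1, 2, 4)
        assert r.precision == pytest.approx(0.75)
        assert r.recall == pytest.approx(0.6)
        assert r.f1 == pytest.approx(2 / 3)
        assert r.accuracy == pytest.approx(0.7)

    def test_perfect_predictions(self):
        truth = ["AD", "CN", "AD", "CN"]
        probs = np.array([0.9, 0.1, 0.8, 0.2])
        r = classification_metrics(truth, truth, probs)
        assert r.precision == r.recall == r.f1 == r.accuracy == 1.0
        assert r.auc == pytest.approx(1.0)

    def test_exhaustive_counting_oracle_small_inputs(self):
        """All truth/prediction combinations of size 4 against the oracle."""
        for truth in itertools.product(["CN", "AD"], repeat=4):
            for pred in itertools.product(["CN", "AD"], repeat=4):
                r = classification_metrics(truth, pred)
                tp, fp, fn, tn = confusion_oracle(truth, pred)
                assert (r.tp, r.fp, r.fn, r.tn) == (tp, fp, fn, tn)
                assert tp + fp + fn + tn == 4
                if tp + fp:
                    assert r.precision == pytest.approx(tp / (tp + fp))
                if tp + fn:
                    assert r.recall == pytest.approx(tp / (tp + fn))
                assert r.accuracy == pytest.approx((tp + tn) / 4)

    def test_auc_equals_mann_whitney_on_tie_free_scores(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 9))
            truth = ["AD" if rng.random() < 0.5 else "CN" for _ in range(n)]
            if len(set(truth)) < 2:
                continue
            scores = rng.permutation(n) / n  # distinct, tie-free
            r = classification_metrics(truth, truth, scores)
            assert r.auc == pytest.approx(mann_whitney_auc(truth, scores), abs=1e-12)

    def test_auc_matches_sklearn_cross_check(self, rng):
        from sklearn.metrics import roc_auc_score

        truth = ["AD" if rng.random() < 0.4 else "CN" for _ in range(30)]
        scores = rng.random(30)
        r = classification_metrics(truth, truth, scores)
        y = [1 if t == "AD" else 0 for t in truth]
        assert r.auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self, rng):
        truth = ["AD" if rng.random() < 0.5 else "CN" for _ in range(20)]
        scores = rng.random(20)
        r1 = classification_metrics(truth, truth, scores)
        r2 = classification_metrics(truth, truth, np.exp(3 * scores))
        assert r1.auc == pytest.approx(r2.auc, abs=1e-12)

    def test_zero_denominator_reports_nan_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="brainage"):
            r = classification_metrics(["AD", "AD"], ["CN", "CN"])
        assert np.isnan(r.precision)
        assert r.recall == 0.0


class TestClassifyAD:
    def test_well_separated_cohort_classified(self, rng):
        preds = []
        for i in range(40):
            bag = rng.normal(0, 1)
            preds.append(AgePrediction(f"cn{i}", 60.0, 60.0 + bag, "CN"))
        for i in range(40):
            bag = rng.normal(8, 1)
            preds.append(AgePrediction(f"ad{i}", 60.0, 60.0 + bag, "AD"))
        report = classify_ad(preds, seed=3)
        assert report.accuracy == 1.0
        assert report.auc == 1.0
        assert set(report.per_classifier) == {
            "logistic_regression", "svm", "adaboost", "xgboost"
        }

    def test_deterministic_per_seed(self, rng):
        preds = [AgePrediction(f"s{i}", 60.0, 60.0 + rng.normal(4 if i % 2 else 0, 2),
                               "AD" if i % 2 else "CN") for i in range(60)]
        r1 = classify_ad(preds, seed=5)
        r2 = classify_ad(preds, seed=5)
        assert r1.to_dict() == r2.to_dict()
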