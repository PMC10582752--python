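"""Feature extraction, K-means baselines and CDP benchmarking metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gaitmix import CohortConfig, simulate_cohort
from gaitmix.evaluation import (EvalError, FEATURE_SETS, auroc_mann_whitney,
                                compute_features, evaluate, kmeans_baseline)


@pytest.fixture(scope="module")
def features(default_cohort):
    subjects, gait, visits = default_cohort
    return compute_features(gait, subjects, visits)


class TestFeatures:
    def test_constant_speed_walk(self):
        subjects = pd.DataFrame({
            "subject_id": ["A"], "cohort": ["MS"], "age": [40.0],
            "bmi": [27.0]})
        gait = pd.DataFrame({"subject_id": "A", "visit": 0,
                             "minute": range(6), "speed_ft_min": 300.0})
        visits = pd.DataFrame({"subject_id": ["A"], "visit": [0],
                               "edss": [2.0], "t25fw": [4.0], "hpt9": [20.0],
                               "sdmt": [55.0], "pasat": [50.0]})
        f = compute_features(gait, subjects, visits).iloc[0]
        assert f.six_mw_td == pytest.approx(1800.0)
        assert f.delta_6mw == pytest.approx(0.0)
        assert f.six_mw_min1 == pytest.approx(300.0)

    def test_delta_is_last_minus_first_minute(self):
        """Minute-0 speed 303 and minute-5 speed 290 give a within-walk
        change of -13 ft/min."""
        speeds = [303.0, 300, 298, 296, 293, 290]
        subjects = pd.DataFrame({"subject_id": ["A"], "cohort": ["MS"],
                                 "age": [40.0], "bmi": [27.0]})
        gait = pd.DataFrame({"subject_id": "A", "visit": 0,
                             "minute": range(6), "speed_ft_min": speeds})
        visits = pd.DataFrame({"subject_id": ["A"], "visit": [0],
                               "edss": [2.0], "t25fw": [4.0], "hpt9": [20.0],
                               "sdmt": [55.0], "pasat": [50.0]})
        f = compute_features(gait, subjects, visits).iloc[0]
        assert f.delta_6mw == pytest.approx(-13.0)

    def test_missing_minute_propagates(self):
        subjects = pd.DataFrame({"subject_id": ["A"], "cohort": ["MS"],
                                 "age": [40.0], "bmi": [27.0]})
        gait = pd.DataFrame({"subject_id": "A", "visit": 0,
                             "minute": range(5),  # minute 5 absent
                             "speed_ft_min": 300.0})
        visits = pd.DataFrame({"subject_id": ["A"], "visit": [0],
                               "edss": [2.0], "t25fw": [4.0], "hpt9": [20.0],
                               "sdmt": [55.0], "pasat": [50.0]})
        f = compute_features(gait, subjects, visits).iloc[0]
        assert np.isnan(f.delta_6mw) and np.isnan(f.six_mw_td)

    def test_default_cohort_features_complete(self, features):
        assert len(features) == 62
        assert features.drop(columns="subject_id").notna().all().all()


class TestKMeans:
    def test_clear_separation_is_seed_invariant(self, features):
        f = features.copy()
        half = len(f) // 2
        f["six_mw_td"] = np.r_[np.full(half, 500.0),
                               np.full(len(f) - half, 2500.0)]
        for c in ("six_mw_min1", "delta_6mw", "age", "bmi"):
            f[c] = np.r_[np.random.default_rng(0).normal(0, 1, half),
                         np.random.default_rng(1).normal(10, 1, len(f) - half)]
        labels1 = kmeans_baseline(f, "kmeans_6mw", seed=0).table
        labels2 = kmeans_baseline(f, "kmeans_6mw", seed=99).table
        assert (labels1.label == labels2.label).all()
        assert set(labels1.label[:half]) == {"HRP"}  # slower walkers

    def test_degenerate_identical_rows(self, features):
        f = features.copy()
        for c in f.columns[1:]:
            f[c] = 1.0
        out = kmeans_baseline(f, "kmeans_edss", seed=0)
        assert out.degenerate
        assert out.table.label.isna().all()

    def test_feature_set_columns(self, features):
        assert FEATURE_SETS["kmeans_edss"] == ("age", "bmi", "edss")
        out = kmeans_baseline(features, "kmeans_edss", seed=0)
        assert set(out.table.label) <= {"HRP", "LRP"}
        with pytest.raises(EvalError):
            kmeans_baseline(features, "nope", seed=0)

    def test_affine_rescaling_invariance(self, features):
        """Standardization makes the partition invariant to affine feature
        rescaling."""
        scaled = features.copy()
        scaled["age"] = scaled["age"] * 12.0 + 7.0
        scaled["six_mw_td"] = scaled["six_mw_td"] / 5280.0
        a = kmeans_baseline(features, "kmeans_6mw", seed=3).table
        b = kmeans_baseline(scaled, "kmeans_6mw", seed=3).table
        assert (a.label == b.label).all()

    def test_too_few_complete_cases(self, features):
        f = features.head(1)
        with pytest.raises(EvalError):
            kmeans_baseline(f, "kmeans_6mw", seed=0)


def _preds(labels, scores, ids=None):
    ids = ids or [f"S{i}" for i in range(len(labels))]
    return pd.DataFrame({"subject_id": ids, "label": labels, "score": scores})


def _truth(confirmed, ids=None):
    ids = ids or [f"S{i}" for i in range(len(confirmed))]
    return pd.DataFrame({"subject_id": ids, "confirmed": confirmed})


class TestEvaluate:
    def test_perfect_prediction(self):
        labels = ["HRP"] * 5 + ["LRP"] * 5
        scores = [0.9] * 5 + [0.1] * 5
        rep = evaluate(_preds(labels, scores), _truth([True] * 5 + [False] * 5))
        assert rep.tp == 5 and rep.tn == 5 and rep.fp == rep.fn == 0
        for m in ("accuracy", "ppv", "npv", "sensitivity", "specificity"):
            assert rep.metrics.loc[m, "estimate"] == 1.0
        assert rep.auroc == 1.0

    def test_confusion_arithmetic(self):
        # TP=3, FP=1, FN=2, TN=4
        labels = ["HRP"] * 4 + ["LRP"] * 6
        truth = [True, True, True, False] + [True, True] + [False] * 4
        rep = evaluate(_preds(labels, [0.5] * 10), _truth(truth))
        assert (rep.tp, rep.fp, rep.fn, rep.tn) == (3, 1, 2, 4)
        m = rep.metrics.estimate
        assert m.accuracy == pytest.approx(0.7)
        assert m.ppv == pytest.approx(0.75)
        assert m.npv == pytest.approx(2 / 3)
        assert m.sensitivity == pytest.approx(0.6)
        assert m.specificity == pytest.approx(0.8)
        # PPV consistency identity
        prev = rep.prevalence
        ppv = (m.sensitivity * prev
               / (m.sensitivity * prev + (1 - m.specificity) * (1 - prev)))
        assert abs(ppv - m.ppv) < 1e-9

    def test_complete_separation_auroc(self):
        rep = evaluate(_preds(["HRP", "HRP", "LRP", "LRP"],
                              [0.9, 0.8, 0.7, 0.6]),
                       _truth([True, True, False, False]))
        assert rep.auroc == 1.0

    def test_single_class_truth_auroc_missing(self):
        rep = evaluate(_preds(["HRP", "LRP"], [0.9, 0.1]),
                       _truth([True, True]))
        assert rep.auroc is None and "single-class" in rep.auroc_missing_reason

    def test_label_flip_duality(self):
        rng = np.random.default_rng(2)
        truth = rng.random(30) < 0.4
        labels = np.where(rng.random(30) < 0.5, "HRP", "LRP")
        a = evaluate(_preds(labels, rng.random(30)), _truth(list(truth)))
        flipped = np.where(labels == "HRP", "LRP", "HRP")
        b = evaluate(_preds(flipped, rng.random(30)), _truth(list(truth)))
        assert b.metrics.estimate.accuracy == \
            pytest.approx(1 - a.metrics.estimate.accuracy)
        assert b.metrics.estimate.sensitivity == \
            pytest.approx(1 - a.metrics.estimate.sensitivity)

    def test_pure_function(self):
        preds = _preds(["HRP", "LRP", "HRP"], [0.8, 0.2, 0.6])
        truth = _truth([True, False, False])
        a = evaluate(preds, truth)
        b = evaluate(preds, truth)
        assert a.to_dict() == b.to_dict()


class TestAuroc:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_concordant_pair_enumeration(self, seed):
        """Mann-Whitney AUROC equals the brute-force proportion of
        concordant pairs (ties 1/2) exactly on small instances."""
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 20)
        truth = np.zeros(n, bool)
        truth[:rng.integers(1, n - 1)] = True
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        ours = auroc_mann_whitney(scores, truth)
        pos = scores[truth]
        neg = scores[~truth]
        conc = sum(1.0 if p > q else 0.5 if p == q else 0.0
                   for p, q in itertools.product(pos, neg))
        assert ours == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-12)

    def test_delong_ci_brackets_estimate(self):
        rng = np.random.default_rng(3)
        truth = rng.random(40) < 0.4
        scores = rng.random(40) + truth * 0.3
        rep = evaluate(_preds(np.where(truth, "HRP", "LRP"), scores),
                       _truth(list(truth)))
        lo, hi = rep.auroc_ci
        assert lo <= rep.auroc <= hi
        assert rep.auroc == pytest.approx(
            auroc_mann_whitney(scores, truth), abs=1e-12)
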