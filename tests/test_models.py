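"""Classifier schemes: CV, LOSO, importances, window analysis."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from premac import models
from premac.features import FeatureMatrix
from premac.labeling import LabeledDataset, oversample_minority


def _blob_dataset(n=400, sep=4.0, n_features=6, seed=0, subject_id="s",
                  shift=0.0):
    """Two Gaussian classes separated by ``sep`` standard deviations."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.normal(size=(n, n_features))
    X[:, 0] += sep * y + shift
    fm = FeatureMatrix(np.arange(n, dtype=np.int64) * 67,
                       pd.DataFrame(X, columns=[f"f{i}" for i in range(n_features)]))
    return LabeledDataset(fm, y, 90.0, subject_id)


class TestCrossvalIndividual:
    def test_separable_data_near_perfect(self):
        res = models.crossval_individual(_blob_dataset(sep=8.0), "rf", seed=0)
        assert res.accuracy >= 0.99
        assert res.tp + res.fp + res.fn + res.tn == res.n

    def test_permuted_labels_at_chance(self):
        d = _blob_dataset(n=1200, sep=8.0, seed=1)
        d = oversample_minority(d, seed=0)  # exactly balanced
        acc = models.label_permutation_control(d, "rf", seed=0)
        assert 0.45 <= acc <= 0.55

    def test_deterministic_given_seed(self):
        d = _blob_dataset(seed=2)
        a = models.crossval_individual(d, "rf", seed=7)
        b = models.crossval_individual(d, "rf", seed=7)
        assert a.accuracy == b.accuracy
        np.testing.assert_array_equal(a.confusion, b.confusion)

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(models.ModelError, match="unknown"):
            models.crossval_individual(_blob_dataset(), "boosted-frogs")

    def test_single_class_rejected(self):
        d = _blob_dataset()
        d = dataclasses.replace(d, labels=np.zeros(d.n, dtype=int))
        with pytest.raises(models.ModelError):
            models.crossval_individual(d, "rf")

    @pytest.mark.parametrize("algorithm", models.ALGORITHMS)
    def test_all_seven_families_run(self, algorithm):
        d = _blob_dataset(n=200, sep=3.0, seed=3)
        res = models.crossval_individual(d, algorithm, seed=0)
        assert 0.0 <= res.accuracy <= 1.0

    def test_holdout_reports_confusion(self):
        res = models.holdout_individual(_blob_dataset(sep=8.0), "rf", seed=0)
        assert res.n == 80  # 20% of 400
        assert res.accuracy >= 0.95


class TestLoso:
    def test_homogeneous_cohort_transfers(self):
        ds = [_blob_dataset(seed=s, subject_id=f"s{s}", sep=6.0)
              for s in range(3)]
        loso = models.loso_group(ds, "rf", seed=0)
        indiv = np.mean([models.crossval_individual(d, "rf", seed=0).accuracy
                         for d in ds])
        assert abs(loso.mean_accuracy - indiv) <= 0.05

    def test_heterogeneous_cohort_degrades(self):
        # subject-specific class separation directions
        ds = []
        for s in range(3):
            rng = np.random.default_rng(s)
            y = rng.integers(0, 2, 400)
            X = rng.normal(size=(400, 6))
            X[:, s] += 6.0 * y  # the informative feature differs per subject
            fm = FeatureMatrix(np.arange(400, dtype=np.int64),
                               pd.DataFrame(X, columns=[f"f{i}" for i in range(6)]))
            ds.append(LabeledDataset(fm, y, 90.0, f"s{s}"))
        loso = models.loso_group(ds, "rf", seed=0)
        indiv = np.mean([models.crossval_individual(d, "rf", seed=0).accuracy
                         for d in ds])
        assert loso.mean_accuracy < indiv

    def test_held_out_rows_never_trained_on(self, monkeypatch):
        """Leakage audit via a recording classifier stub."""
        seen: dict[str, np.ndarray] = {}

        class Recorder:
            def __init__(self):
                self.X = None

            def fit(self, X, y):
                self.X = X.copy()
                return self

            def predict(self, X):
                key = str(len(seen))
                seen[key] = (self.X, X)
                return np.zeros(len(X), dtype=int)

        monkeypatch.setattr(models, "make_classifier",
                            lambda alg, seed=0: Recorder())
        # give every row a unique fingerprint value
        ds = []
        for s in range(3):
            d = _blob_dataset(n=50, seed=s, subject_id=f"s{s}")
            d.features.values["f0"] = np.arange(50) + 1000 * s
            ds.append(d)
        models.loso_group(ds, "rf", seed=0)
        assert len(seen) == 3
        for X_train, X_test in seen.values():
            assert not set(X_train[:, 0]) & set(X_test[:, 0])

    def test_single_class_subject_flagged(self):
        good = [_blob_dataset(seed=s, subject_id=f"s{s}") for s in range(2)]
        bad = dataclasses.replace(_blob_dataset(seed=9, subject_id="s_bad"),
                                  labels=np.zeros(400, dtype=int))
        loso = models.loso_group(good + [bad], "rf", seed=0)
        assert loso.flagged == ["s_bad"]
        assert set(loso.per_subject) == {"s0", "s1"}

    def test_too_few_subjects_rejected(self):
        with pytest.raises(models.ModelError):
            models.loso_group([_blob_dataset()], "rf")


class TestFeatureImportance:
    def test_importances_sum_to_one(self):
        d = _blob_dataset(sep=4.0)
        rf = models.fit_rf(d, seed=0)
        per_feat, per_mod = models.feature_importance(
            rf, d.features.columns, {c: "m" for c in d.features.columns})
        assert per_feat.sum() == pytest.approx(1.0, abs=1e-9)
        assert (per_feat >= 0).all()
        assert per_mod.sum() == pytest.approx(1.0, abs=1e-9)

    def test_planted_signal_ranks_first(self):
        d = _blob_dataset(sep=6.0, n_features=8, seed=5)  # signal in f0 only
        rf = models.fit_rf(d, seed=0)
        per_feat, _ = models.feature_importance(
            rf, d.features.columns, {c: "m" for c in d.features.columns})
        assert per_feat.index[0] == "f0"

    def test_modality_sums_equal_brute_force(self):
        d = _blob_dataset(n_features=6)
        rf = models.fit_rf(d, seed=0)
        grouping = {f"f{i}": ("even" if i % 2 == 0 else "odd")
                    for i in range(6)}
        per_feat, per_mod = models.feature_importance(rf, d.features.columns,
                                                      grouping)
        even = sum(per_feat[f"f{i}"] for i in range(0, 6, 2))
        assert per_mod["even"] == pytest.approx(even, abs=1e-12)

    def test_non_rf_model_rejected(self):
        clf = models.make_classifier("knn")
        with pytest.raises(models.ModelError):
            models.feature_importance(clf, ["a"], {"a": "m"})


class TestWindowSensitivity:
    def test_each_window_balanced_after_oversampling(self):
        d = _blob_dataset(n=300, seed=6)
        out = oversample_minority(d, seed=0)
        n0, n1 = out.class_counts
        assert n0 == n1

    def test_nonpositive_window_rejected(self):
        with pytest.raises(models.ModelError):
            models.window_sensitivity([], "rf", windows=(0.0,))


def test_evaluation_report_serializes(tmp_path):
    import json

    ds = [_blob_dataset(seed=s, subject_id=f"s{s}") for s in range(2)]
    report = models.evaluate_cohort(ds, ("rf",), mode="both", seed=0)
    doc = report.as_dict()
    text = json.dumps(doc)
    back = json.loads(text)
    assert back["individualized_mean"]["rf"] == pytest.approx(
        report.individualized_mean("rf"))
    assert set(back["group"]["rf"]["per_subject"]) == {"s0", "s1"}
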