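import numpy as np
import pandas as pd
import pytest

from eegtopo.classify import (
    DEFAULT_GRIDS,
    crossval_eval,
    make_classifier,
    select_features,
    tune_and_validate,
    univariate_accuracy,
)


def make_table(n_per_class=50, n_features=5, offset=0.0, seed=0, rows_per_subject=1):
    """Synthetic feature table: two Gaussian clouds separated by `offset` SD."""
    rng = np.random.default_rng(seed)
    rows = []
    for label, shift in (("patient", offset), ("control", 0.0)):
        for s in range(n_per_class):
            sid = f"{label}_{s}"
            for b in range(1, rows_per_subject + 1):
                feats = rng.normal(shift, 1.0, n_features)
                rows.append([sid, b, label, *feats])
    cols = ["subject_id", "band_index", "label"] + [f"f{i}" for i in range(1, n_features + 1)]
    return pd.DataFrame(rows, columns=cols)


class TestCrossvalEval:
    def test_separable_clouds_all_classifiers(self):
        table = make_table(n_per_class=30, offset=10.0, seed=1)
        report = crossval_eval(table, k=5, seed=0)
        for name, metrics in report.metrics.items():
            assert metrics["accuracy"] >= 0.99, name
            assert 0 <= metrics["f1"] <= 1

    def test_permuted_labels_near_chance(self):
        table = make_table(n_per_class=50, offset=10.0, seed=2)
        rng = np.random.default_rng(0)
        table["label"] = rng.permutation(table["label"].to_numpy())
        # permuting breaks one-row-per-subject grouping assumptions; use rows
        report = crossval_eval(table, classifiers=("LR",), k=5, seed=0, grouped=False)
        assert 0.35 <= report.accuracy("LR") <= 0.65

    def test_too_many_folds_rejected(self):
        table = make_table(n_per_class=4, offset=1.0)
        with pytest.raises(ValueError, match="folds"):
            crossval_eval(table, k=5, seed=0)

    def test_single_class_rejected(self):
        table = make_table(n_per_class=10)
        table = table[table["label"] == "patient"]
        with pytest.raises(ValueError, match="two classes"):
            crossval_eval(table, k=2, seed=0)

    def test_f1_consistent_with_confusions(self):
        table = make_table(n_per_class=30, offset=1.0, seed=3)
        report = crossval_eval(table, classifiers=("LR",), k=5, seed=0)
        cms = np.sum(report.confusions["LR"], axis=0)
        tn, fp, fn, tp = cms.ravel()
        p = tp / (tp + fp)
        r = tp / (tp + fn)
        # fold-averaged F1 tracks the pooled-confusion F1
        assert report.metrics["LR"]["f1"] == pytest.approx(2 * p * r / (p + r), abs=0.1)

    def test_determinism(self):
        table = make_table(n_per_class=20, offset=1.0, seed=4)
        a = crossval_eval(table, classifiers=("GBM",), k=5, seed=7)
        b = crossval_eval(table, classifiers=("GBM",), k=5, seed=7)
        assert a.metrics == b.metrics
        for fa, fb in zip(a.fold_assignments, b.fold_assignments):
            np.testing.assert_array_equal(fa, fb)

    def test_grouped_folds_keep_subjects_together(self):
        table = make_table(n_per_class=10, offset=1.0, rows_per_subject=5, seed=5)
        report = crossval_eval(table, classifiers=("LR",), k=5, seed=0, grouped=True)
        subj = table["subject_id"].to_numpy()
        seen = {}
        for fold_id, test_idx in enumerate(report.fold_assignments):
            for s in subj[test_idx]:
                seen.setdefault(s, set()).add(fold_id)
        assert all(len(folds) == 1 for folds in seen.values())

    def test_standardization_fit_inside_training_fold(self):
        """The scaler statistics inside a fitted fold pipeline must come
        from that fold's training rows, not from the full table."""
        table = make_table(n_per_class=20, offset=2.0, seed=6)
        X = table[[f"f{i}" for i in range(1, 6)] + ["band_index"]].to_numpy(dtype=float)
        y = table["label"].to_numpy()
        from sklearn.model_selection import StratifiedKFold

        train, _ = next(StratifiedKFold(5, shuffle=True, random_state=0).split(X, y))
        clf = make_classifier("LR", seed=0)
        clf.fit(X[train], y[train])
        fold_mean = clf.named_steps["scale"].mean_
        np.testing.assert_allclose(fold_mean, X[train].mean(axis=0))
        assert not np.allclose(fold_mean, X.mean(axis=0))


class TestUnivariateSelection:
    def test_leak_feature_scores_one(self):
        table = make_table(n_per_class=50, offset=0.0, seed=7)
        table["f1"] = (table["label"] == "patient").astype(float)
        assert univariate_accuracy(table, "f1", seed=0) == 1.0

    def test_uninformative_feature_near_chance(self):
        table = make_table(n_per_class=100, offset=0.0, seed=8)
        acc = univariate_accuracy(table, "f2", test_size=0.3, seed=0)
        assert 0.30 <= acc <= 0.70

    def test_constant_feature_majority_rate(self):
        table = make_table(n_per_class=50, offset=0.0, seed=9)
        table["f3"] = 1.0
        acc = univariate_accuracy(table, "f3", seed=0)
        assert acc == pytest.approx(0.5, abs=0.1)

    @pytest.mark.parametrize(
        "threshold,expected", [(0.55, ["a", "b"]), (0.60, ["a"])]
    )
    def test_threshold_filter_inclusive(self, threshold, expected):
        accs = {"a": 0.62, "b": 0.55, "c": 0.50}
        assert select_features(accs, threshold) == expected

    def test_empty_selection_warns(self):
        with pytest.warns(UserWarning, match="falling back"):
            chosen = select_features({"a": 0.4}, 0.6)
        assert chosen == []


class TestTuneAndValidate:
    def test_tuning_does_no_harm_on_separable_data(self):
        """Post-tuning accuracy stays within 0.02 of plain CV over seeds."""
        for seed in range(10):
            table = make_table(n_per_class=15, offset=6.0, seed=seed)
            plain = crossval_eval(table, classifiers=("LR",), k=5, seed=seed)
            tuned = tune_and_validate(table, classifier="LR", k=5, seed=seed)
            assert tuned.metrics["LR"]["accuracy"] >= plain.metrics["LR"]["accuracy"] - 0.02

    def test_singleton_grid_matches_plain_cv(self):
        table = make_table(n_per_class=20, offset=2.0, seed=11)
        plain = crossval_eval(table, classifiers=("LR",), k=5, seed=0)
        tuned = tune_and_validate(table, grid={"model__C": [1.0]}, classifier="LR", k=5, seed=0)
        assert tuned.metrics["LR"]["accuracy"] == pytest.approx(
            plain.metrics["LR"]["accuracy"], abs=1e-12
        )

    def test_empty_grid_rejected(self):
        table = make_table(n_per_class=10, offset=2.0)
        with pytest.raises(ValueError, match="empty"):
            tune_and_validate(table, grid={}, classifier="LR", k=2, seed=0)

    def test_chosen_params_logged(self):
        table = make_table(n_per_class=15, offset=2.0, seed=12)
        tuned = tune_and_validate(table, classifier="LR", k=3, seed=0)
        assert len(tuned.chosen_params["LR"]) == 3
        for params in tuned.chosen_params["LR"]:
            assert params["model__C"] in DEFAULT_GRIDS["LR"]["model__C"]
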