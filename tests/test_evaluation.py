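import numpy as np
import pytest

from cancerlectin.evaluation import (
    CLASSIFIERS,
    ConfusionCounts,
    RfParams,
    auc_rank,
    auc_trapezoid,
    compare_classifiers,
    confusion,
    cross_validate,
    metrics,
    random_subset_baseline,
    roc_points,
)

from conftest import gaussian_matrix


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(tp=10, fp=0, tn=10, fn=0))
        assert (m.sn, m.sp, m.acc, m.mcc) == (1, 1, 1, 1)

    def test_chance_classifier(self):
        m = metrics(ConfusionCounts(tp=5, fp=5, tn=5, fn=5))
        assert (m.sn, m.sp, m.acc, m.mcc) == (0.5, 0.5, 0.5, 0)

    def test_plug_in_oracle(self):
        m = metrics(ConfusionCounts(tp=8, fp=3, tn=7, fn=2))
        assert m.sn == pytest.approx(0.8)
        assert m.sp == pytest.approx(0.7)
        assert m.acc == pytest.approx(0.75)
        expected_mcc = (8 * 7 - 3 * 2) / np.sqrt((8 + 2) * (8 + 3) * (7 + 3) * (7 + 2))
        assert m.mcc == pytest.approx(expected_mcc, abs=1e-12)

    def test_zero_marginal_gives_zero_mcc(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert m.mcc == 0.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(0, 0, 0, 0)


class TestRoc:
    def test_trapezoid_equals_rank_statistic(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            y = rng.integers(0, 2, size=60)
            if y.min() == y.max():
                continue
            # coarse scores force ties, exercising the midrank handling
            scores = np.round(rng.uniform(size=60), 1)
            fpr, tpr = roc_points(y, scores)
            assert auc_trapezoid(fpr, tpr) == pytest.approx(
                auc_rank(y, scores), abs=1e-9
            )

    def test_monotone_curve(self):
        rng = np.random.default_rng(1)
        y = np.r_[np.zeros(20, dtype=int), np.ones(20, dtype=int)]
        fpr, tpr = roc_points(y, rng.uniform(size=40))
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)
        assert fpr[0] == tpr[0] == 0 and fpr[-1] == tpr[-1] == 1

    def test_perfect_scores(self):
        y = np.array([0, 0, 1, 1])
        fpr, tpr = roc_points(y, np.array([0.1, 0.2, 0.8, 0.9]))
        assert auc_trapezoid(fpr, tpr) == 1.0


class TestCrossValidate:
    def test_folds_partition_samples(self):
        fm = gaussian_matrix((30, 30), d=5, seed=0)
        report = cross_validate(fm, RfParams(trees=10), smote_mode="off", seed=0)
        assignment = report.fold_assignment
        assert np.all(assignment >= 0)
        sizes = np.bincount(assignment)
        assert sizes.sum() == 60
        assert sizes.max() - sizes.min() <= 1

    def test_pooled_accuracy_from_summed_counts(self):
        fm = gaussian_matrix((30, 30), d=5, shift=1.0, seed=1)
        report = cross_validate(fm, RfParams(trees=20), smote_mode="off", seed=1)
        c = report.pooled_counts
        assert report.pooled.acc == pytest.approx((c.tp + c.tn) / c.n)
        assert c.n == 60

    def test_separable_blobs_high_accuracy(self):
        fm = gaussian_matrix((100, 100), d=10, shift=4.0, seed=2)
        report = cross_validate(fm, RfParams(trees=30), smote_mode="off", seed=2)
        assert report.pooled.acc >= 0.95
        assert report.auc >= 0.99

    def test_seed_determinism(self):
        fm = gaussian_matrix((25, 20), d=5, shift=1.0, seed=3)
        r1 = cross_validate(fm, RfParams(trees=15), seed=4)
        r2 = cross_validate(fm, RfParams(trees=15), seed=4)
        assert r1.to_dict() == r2.to_dict()

    def test_presplit_smote_balances_before_cv(self):
        fm = gaussian_matrix((40, 25), d=5, shift=1.0, seed=5)
        report = cross_validate(fm, RfParams(trees=10), smote_mode="pre_split", seed=5)
        assert report.pooled_counts.n == 80  # 40 + 40 after balancing

    def test_per_fold_smote_keeps_test_rows_real(self):
        fm = gaussian_matrix((40, 25), d=5, shift=1.0, seed=6)
        report = cross_validate(fm, RfParams(trees=10), smote_mode="per_fold", seed=6)
        assert report.pooled_counts.n == 65  # only the real rows are scored

    def test_unknown_smote_mode(self):
        fm = gaussian_matrix((10, 10), d=2, seed=7)
        with pytest.raises(ValueError, match="smote_mode"):
            cross_validate(fm, smote_mode="sometimes")


class TestCompareClassifiers:
    def test_table_structure(self):
        fm = gaussian_matrix((25, 25), d=5, shift=2.0, seed=8)
        table = compare_classifiers(fm, ["rf", "naive_bayes"], seed=0)
        assert list(table["classifier"]) == ["rf", "naive_bayes"]
        assert set(table.columns) == {"classifier", "sn", "sp", "acc", "mcc", "auc"}
        assert table.notna().all().all()

    def test_duplicate_entry_is_deterministic(self):
        fm = gaussian_matrix((20, 20), d=4, shift=1.0, seed=9)
        table = compare_classifiers(fm, ["rf", "rf"], seed=1)
        assert table.iloc[0, 1:].tolist() == table.iloc[1, 1:].tolist()

    def test_rf_beats_majority_dummy_on_separable_data(self):
        fm = gaussian_matrix((30, 30), d=5, shift=3.0, seed=10)
        table = compare_classifiers(fm, ["rf", "dummy"], seed=2).set_index("classifier")
        assert table.loc["rf", "acc"] > table.loc["dummy", "acc"]

    def test_unknown_name_lists_supported(self):
        fm = gaussian_matrix((10, 10), d=2, seed=11)
        with pytest.raises(ValueError, match="supported"):
            compare_classifiers(fm, ["weka"])
        assert "rf" in CLASSIFIERS


def test_random_subset_baseline_shape():
    fm = gaussian_matrix((20, 20), d=12, shift=1.0, n_informative=3, seed=12)
    df = random_subset_baseline(fm, n_features=4, rounds=3, rf=RfParams(trees=10), seed=0)
    assert len(df) == 4  # 3 rounds + mean row
    assert df.iloc[-1]["round"] == -1


def test_confusion_counts_sum():
    y = np.array([0, 1, 1, 0, 1])
    p = np.array([0, 1, 0, 1, 1])
    c = confusion(y, p)
    assert (c.tp, c.fp, c.tn, c.fn) == (2, 1, 1, 1)
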