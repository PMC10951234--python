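"""Split plans and metrics; every metric is checked against a brute-force
oracle on small instances."""

import numpy as np
import pytest

from stresslearn import (
    compute_metrics,
    make_chronological_five_fold,
    make_loso_online,
    make_stratified_five_fold,
    micro_f1,
    pr_auc,
    precision_at_recall,
    roc_auc_micro,
)


# ---------------------------------------------------------------------- #
# brute-force oracles
# ---------------------------------------------------------------------- #

def oracle_micro_f1(y_true, y_pred, classes=(1, 2, 3)):
    tp = fp = fn = 0
    for c in classes:
        tp += sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp += sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn += sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    return 2 * prec * rec / (prec + rec) if prec + rec else 0.0


def oracle_roc_auc(y, s):
    """Concordant-pair fraction with half credit for score ties."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    total = conc = 0.0
    for p in pos:
        for n in neg:
            total += 1
            conc += 1.0 if p > n else (0.5 if p == n else 0.0)
    return conc / total


def oracle_pr_points(y, s):
    """(precision, recall) at every distinct threshold, decreasing recall."""
    y = np.asarray(y)
    s = np.asarray(s)
    pts = []
    for t in sorted(set(s)):
        pred = s >= t
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        rec = tp / (y == 1).sum()
        prec = tp / (tp + fp) if tp + fp else 1.0
        pts.append((t, prec, rec))
    return pts


def oracle_average_precision(y, s):
    pts = oracle_pr_points(y, s)
    # step sum over decreasing thresholds: AP = sum (R_i - R_{i+1}) * P_i
    ap = 0.0
    prev_rec = 0.0
    for t, prec, rec in sorted(pts, key=lambda p: -p[0]):
        ap += (rec - prev_rec) * prec
        prev_rec = rec
    return ap


def oracle_precision_at_recall(y, s, r):
    cands = [(t, prec) for t, prec, rec in oracle_pr_points(y, s) if rec >= r]
    return max(cands)[1]  # largest threshold


# ---------------------------------------------------------------------- #
# metric tests
# ---------------------------------------------------------------------- #

class TestMicroF1:
    def test_perfect_and_all_wrong(self):
        assert micro_f1([1, 2, 3], [1, 2, 3]) == 1.0
        assert micro_f1([1, 2, 3], [2, 3, 1]) == 0.0

    def test_hand_worked_example(self):
        assert micro_f1([1, 1, 2, 3], [1, 2, 2, 3]) == pytest.approx(0.75)

    def test_equals_accuracy_for_single_label_predictions(self, rng):
        y = rng.integers(1, 4, 50)
        p = rng.integers(1, 4, 50)
        assert micro_f1(y, p) == pytest.approx(np.mean(y == p))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            micro_f1([], [])


class TestCurveMetrics:
    def test_perfect_separation(self):
        y = [0, 0, 1, 1]
        s = [0.1, 0.2, 0.8, 0.9]
        assert roc_auc_micro(y, s, classes=(1,)) == 1.0
        assert pr_auc(y, s) == 1.0
        assert precision_at_recall(y, s, 0.9) == 1.0

    def test_constant_scores_give_prevalence_precision(self):
        y = [0, 1, 0, 1, 1]
        s = [0.5] * 5
        assert precision_at_recall(y, s, 0.9) == pytest.approx(3 / 5)

    def test_single_class_auc_is_nan_with_warning(self):
        with pytest.warns(UserWarning):
            assert np.isnan(pr_auc([1, 1, 1], [0.1, 0.2, 0.3]))

    def test_no_positives_rejected_for_precision_at_recall(self):
        with pytest.raises(ValueError):
            precision_at_recall([0, 0], [0.1, 0.2], 0.9)


def test_metric_battery_matches_brute_force_oracles():
    """1000 random instances of <= 8 examples: micro-F1, binary ROC AUC,
    PR AUC, and precision@recall>=0.9 all agree exactly with exhaustive
    enumeration (scores drawn from a coarse grid to exercise ties)."""
    rng = np.random.default_rng(42)
    checked = {"f1": 0, "roc": 0, "ap": 0, "par": 0}
    for _ in range(1000):
        n = int(rng.integers(2, 9))
        y3 = rng.integers(1, 4, n)
        p3 = rng.integers(1, 4, n)
        assert micro_f1(y3, p3) == pytest.approx(oracle_micro_f1(y3, p3))
        checked["f1"] += 1

        yb = rng.integers(0, 2, n)
        s = rng.choice([0.1, 0.25, 0.5, 0.75, 0.9], size=n)
        if 0 < yb.sum() < n:
            assert roc_auc_micro(yb, s, classes=(1,)) == pytest.approx(
                oracle_roc_auc(yb, s))
            assert pr_auc(yb, s) == pytest.approx(oracle_average_precision(yb, s))
            checked["roc"] += 1
            checked["ap"] += 1
        if yb.sum() > 0:
            assert precision_at_recall(yb, s, 0.9) == pytest.approx(
                oracle_precision_at_recall(yb, s, 0.9))
            checked["par"] += 1
    assert checked["f1"] == 1000 and min(checked.values()) > 300


# ---------------------------------------------------------------------- #
# split plans
# ---------------------------------------------------------------------- #

class TestStratifiedFiveFold:
    def test_round_robin_within_cells(self, tiny_dataset):
        plan = make_stratified_five_fold(tiny_dataset, seed=0)
        plan.validate(len(tiny_dataset))
        # per (subject, label) cell, fold counts differ by at most one
        for subject in tiny_dataset.subject_list:
            for label in (1, 2, 3):
                cell = set(np.where((tiny_dataset.subjects == subject)
                                    & (tiny_dataset.labels == label))[0])
                if not cell:
                    continue
                sizes = [len(cell & set(t)) for _, t in plan.folds]
                assert max(sizes) - min(sizes) <= 1

    def test_seed_reproducibility(self, tiny_dataset):
        a = make_stratified_five_fold(tiny_dataset, seed=9)
        b = make_stratified_five_fold(tiny_dataset, seed=9)
        for (_, ta), (_, tb) in zip(a.folds, b.folds):
            np.testing.assert_array_equal(ta, tb)

    def test_balanced_synthetic_cells_deal_evenly(self):
        from stresslearn.preprocess import StressDataset

        n = 30  # one subject, 10 examples of each label -> 2 per label per fold
        ds = StressDataset(
            X=np.zeros((n, 1, 24, 2)), covariates=np.zeros((n, 1)),
            labels=np.repeat([1, 2, 3], 10),
            subjects=np.array(["a"] * n), dates=np.array(["2024-01-01"] * n),
        )
        plan = make_stratified_five_fold(ds, seed=0)
        for _, test in plan.folds:
            assert len(test) == 6
            assert [np.sum(ds.labels[test] == c) for c in (1, 2, 3)] == [2, 2, 2]


class TestChronologicalFiveFold:
    def test_contiguous_blocks_partition(self, tiny_dataset):
        plan = make_chronological_five_fold(tiny_dataset)
        plan.validate(len(tiny_dataset))

    def test_blocks_ordered_in_time_per_subject(self, tiny_dataset):
        plan = make_chronological_five_fold(tiny_dataset)
        for subject in tiny_dataset.subject_list:
            prev_last = None
            for _, test in plan.folds:
                mine = [i for i in test if tiny_dataset.subjects[i] == subject]
                if not mine:
                    continue
                dates = sorted(tiny_dataset.dates[mine])
                if prev_last is not None:
                    assert dates[0] > prev_last
                prev_last = dates[-1]


class TestLosoOnline:
    def test_one_plan_per_subject(self, tiny_dataset):
        plans = make_loso_online(tiny_dataset)
        assert [p.subject for p in plans] == tiny_dataset.subject_list

    def test_zero_increment_excludes_held_out_subject(self, tiny_dataset):
        for plan in make_loso_online(tiny_dataset):
            k, train, test = plan.increments[0]
            assert k == 0
            assert plan.subject not in set(tiny_dataset.subjects[train])
            assert set(tiny_dataset.subjects[test]) == {plan.subject}

    def test_increments_nested_and_disjoint_from_test(self, tiny_dataset):
        for plan in make_loso_online(tiny_dataset):
            prev_train = None
            for k, train, test in plan.increments:
                assert not set(train) & set(test)
                if prev_train is not None:
                    assert set(prev_train) <= set(train)
                prev_train = train

    def test_requires_two_subjects(self, tiny_dataset):
        solo = tiny_dataset.subset(
            np.where(tiny_dataset.subjects == tiny_dataset.subject_list[0])[0])
        with pytest.raises(ValueError):
            make_loso_online(solo)


def test_compute_metrics_reports_all_fields(rng):
    y = rng.integers(1, 4, 40)
    proba = rng.dirichlet(np.ones(3), size=40)
    m = compute_metrics(y, proba)
    for key in ("micro_f1", "roc_auc_micro", "pr_auc", "precision_at_recall90"):
        assert 0.0 <= m[key] <= 1.0
    assert m["n"] == 40
    assert sum(m[f"count_class{c}"] for c in (1, 2, 3)) == 40


def test_external_predictions_scored_and_validated(tiny_dataset, tmp_path):
    import pandas as pd

    from stresslearn import score_external_predictions

    rng = np.random.default_rng(1)
    proba = rng.dirichlet(np.ones(3), size=len(tiny_dataset))
    df = pd.DataFrame({"subject_id": tiny_dataset.subjects,
                       "date": tiny_dataset.dates,
                       "p1": proba[:, 0], "p2": proba[:, 1], "p3": proba[:, 2]})
    path = tmp_path / "ext.csv"
    df.to_csv(path, index=False)
    m = score_external_predictions(tiny_dataset, str(path))
    assert 0.0 <= m["micro_f1"] <= 1.0 and m["n"] == len(tiny_dataset)

    df.iloc[1:].to_csv(path, index=False)
    with pytest.raises(ValueError, match="missing"):
        score_external_predictions(tiny_dataset, str(path))
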