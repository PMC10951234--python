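"""Evaluation schemas and metrics.

Three cross-validation schemas cover warm-start and cold-start use:

* ``stratified5`` — five folds stratified by subject *and* stress level
  (each fold sees every subject's label mix);
* ``chrono5`` — per-subject chronological segmentation into five
  contiguous blocks, testing robustness to temporal drift;
* ``loso`` — leave-one-subject-out with weekly online learning: the
  held-out subject's data is added one week at a time, the k=0 increment
  being the pure cold-start case served by the generic head.

Metrics are micro-averaged (each element of the label-indicator matrix is
a decision): micro-F1 — which for single-label multiclass predictions
equals plain accuracy — micro ROC AUC, PR AUC (average precision, a step
interpolation of the precision-recall curve), and precision at the most
conservative operating point whose recall still reaches 0.9.  Binary
metrics come from the 3-class probabilities with median and above-median
classes merged into the positive class.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    f1_score,
    precision_recall_curve,
    roc_auc_score,
)

from .model import StressModel, TrainConfig, merge_to_binary, train_model

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------- #
# split plans
# ---------------------------------------------------------------------- #

@dataclass
class SplitPlan:
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train ids, test ids)
    schema: str

    def validate(self, n: int) -> None:
        test_all = np.concatenate([t for _, t in self.folds])
        if len(np.unique(test_all)) != n or len(test_all) != n:
            raise ValueError("test folds must partition the dataset")


@dataclass
class OnlineLearningPlan:
    """Weekly-increment schedule for one held-out subject.

    ``increments[k] = (weeks_included, train_ids, test_ids)``: train on all
    other subjects plus the held-out subject's first k weeks; test on the
    subject's remaining days.  Increments are nested.
    """

    subject: str
    increments: list[tuple[int, np.ndarray, np.ndarray]]


def make_stratified_five_fold(dataset, seed: int = 0, n_folds: int = 5) -> SplitPlan:
    """Shuffle each (subject, label) cell and deal round-robin into folds."""
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for subject in dataset.subject_list:
        for label in (1, 2, 3):
            cell = np.where((dataset.subjects == subject) & (dataset.labels == label))[0]
            if len(cell) == 0:
                continue
            if len(cell) < n_folds:
                logger.warning("subject %s label %d has only %d examples",
                               subject, label, len(cell))
            cell = rng.permutation(cell)
            for i, idx in enumerate(cell):
                folds[i % n_folds].append(int(idx))
    all_idx = np.arange(len(dataset))
    plan = SplitPlan(
        folds=[(np.setdiff1d(all_idx, np.array(f, dtype=int)), np.sort(np.array(f, dtype=int)))
               for f in folds],
        schema="stratified5",
    )
    plan.validate(len(dataset))
    return plan


def make_chronological_five_fold(dataset, n_folds: int = 5) -> SplitPlan:
    """Per subject, sort by date and cut into contiguous blocks; fold f
    tests on every subject's f-th block (rotating, so each block serves as
    test once)."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for subject in dataset.subject_list:
        idx = np.where(dataset.subjects == subject)[0]
        idx = idx[np.argsort(dataset.dates[idx])]
        for f, block in enumerate(np.array_split(idx, n_folds)):
            folds[f].extend(block.tolist())
    all_idx = np.arange(len(dataset))
    plan = SplitPlan(
        folds=[(np.setdiff1d(all_idx, np.array(f, dtype=int)), np.sort(np.array(f, dtype=int)))
               for f in folds],
        schema="chrono5",
    )
    plan.validate(len(dataset))
    return plan


def make_loso_online(dataset, week_length_days: int = 7) -> list[OnlineLearningPlan]:
    """One plan per subject; weeks are 7-day blocks anchored at the
    subject's first observed day (k=0 = zero held-out data)."""
    subjects = dataset.subject_list
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least two subjects")
    all_idx = np.arange(len(dataset))
    plans = []
    for subject in subjects:
        held = np.where(dataset.subjects == subject)[0]
        others = np.setdiff1d(all_idx, held)
        days = np.array([np.datetime64(d) for d in dataset.dates[held]])
        week_of = ((days - days.min()).astype("timedelta64[D]").astype(int)
                   // week_length_days)
        max_week = int(week_of.max())
        if max_week < 2:
            logger.warning("subject %s has under 2 weeks of data; plan truncated", subject)
        increments = []
        for k in range(0, max_week + 1):
            included = held[week_of < k]
            test = held[week_of >= k]
            if len(test) == 0:
                break
            increments.append((k, np.concatenate([others, included]), test))
        plans.append(OnlineLearningPlan(subject=subject, increments=increments))
    return plans


# ---------------------------------------------------------------------- #
# metrics
# ---------------------------------------------------------------------- #

def micro_f1(y_true, y_pred, n_classes: int = 3) -> float:
    """Micro-averaged F1 over the label-indicator matrix (for single-label
    multiclass predictions this equals accuracy)."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty input")
    return float(f1_score(y_true, y_pred, average="micro"))


def _indicator(y, classes) -> np.ndarray:
    return np.stack([(np.asarray(y) == c).astype(float) for c in classes], axis=1)


def roc_auc_micro(y_true, scores, classes=(1, 2, 3)) -> float:
    """ROC AUC over the flattened indicator/score pairs."""
    ind = _indicator(y_true, classes).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if len(np.unique(ind)) < 2:
        warnings.warn("single-class input: ROC AUC undefined")
        return float("nan")
    return float(roc_auc_score(ind, s))


def pr_auc(y_true_binary, scores) -> float:
    """Area under the precision-recall curve (average precision)."""
    y = np.asarray(y_true_binary, dtype=int)
    if y.sum() == 0 or y.sum() == len(y):
        warnings.warn("single-class input: PR AUC undefined")
        return float("nan")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def precision_at_recall(y_true_binary, scores, r: float = 0.9) -> float:
    """Precision at the largest threshold whose recall still reaches r.

    The most conservative qualifying operating point: walk the PR curve
    toward higher thresholds and stop at the last point with recall >= r.
    """
    y = np.asarray(y_true_binary, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.sum() == 0:
        raise ValueError("precision_at_recall requires at least one positive")
    prec, rec, thr = precision_recall_curve(y, s)
    # curve points i = 0..len(thr)-1 correspond to thresholds thr[i], recall
    # non-increasing in i; the final (1, 0) sentinel point has no threshold
    ok = np.where(rec[:-1] >= r)[0]
    return float(prec[ok[-1]])


def compute_metrics(y_true, proba) -> dict:
    """All headline metrics from 3-class labels and probabilities."""
    proba = np.asarray(proba, dtype=float)
    y_true = np.asarray(y_true)
    y_pred = 1 + np.argmax(proba, axis=1)
    binary = merge_to_binary(proba)
    y_bin = (y_true >= 2).astype(int)
    out = {
        "micro_f1": micro_f1(y_true, y_pred),
        "roc_auc_micro": roc_auc_micro(y_true, proba),
        "n": int(len(y_true)),
    }
    for c in (1, 2, 3):
        out[f"count_class{c}"] = int((y_true == c).sum())
    if 0 < y_bin.sum() < len(y_bin):
        out["pr_auc"] = pr_auc(y_bin, binary[:, 1])
        out["precision_at_recall90"] = precision_at_recall(y_bin, binary[:, 1], r=0.9)
    else:
        out["pr_auc"] = float("nan")
        out["precision_at_recall90"] = float("nan")
    return out


@dataclass
class MetricsReport:
    schema: str
    rows: list[dict] = field(default_factory=list)

    def aggregate(self) -> dict:
        agg = {}
        keys = [k for k in (self.rows[0] if self.rows else {})
                if isinstance(self.rows[0][k], float)]
        for k in keys:
            vals = np.array([r[k] for r in self.rows], dtype=float)
            vals = vals[np.isfinite(vals)]
            if len(vals):
                agg[f"{k}_mean"] = float(vals.mean())
                agg[f"{k}_std"] = float(vals.std())
        return agg

    def to_dict(self) -> dict:
        return {"schema": self.schema, "folds": self.rows, "aggregate": self.aggregate()}

    def save(self, path: str) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2, default=float)


# ---------------------------------------------------------------------- #
# harnesses
# ---------------------------------------------------------------------- #

def run_schema(model_factory, dataset, plan: SplitPlan,
               cfg: TrainConfig | None = None, seed: int = 0) -> MetricsReport:
    """Train and score one model per fold; aggregate mean +/- std.

    ``model_factory(subjects, seed)`` must return an untrained model.
    Fold failures are recorded in the report and do not stop other folds.
    """
    report = MetricsReport(schema=plan.schema)
    for f, (train_idx, test_idx) in enumerate(plan.folds):
        try:
            train, test = dataset.subset(train_idx), dataset.subset(test_idx)
            model = model_factory(sorted(set(train.subjects)), seed + f)
            train_model(model, train, cfg, seed=seed + f)
            proba = model.predict_proba(test)
            row = {"fold": f, **compute_metrics(test.labels, proba)}
        except Exception as exc:  # propagate per-fold, continue others
            logger.exception("fold %d failed", f)
            row = {"fold": f, "error": str(exc)}
        report.rows.append(row)
    return report


def run_online(model_factory, dataset, plans: list[OnlineLearningPlan],
               cfg: TrainConfig | None = None, seed: int = 0,
               fine_tune_epochs: int = 5,
               retrain_from_scratch: bool = False) -> MetricsReport:
    """Leave-one-subject-out online learning.

    For each held-out subject a base model is trained on everyone else
    (k=0 predictions come from the generic head).  Each weekly increment
    then either fine-tunes the running model on the augmented training set
    for ``fine_tune_epochs`` epochs, or retrains from scratch.
    """
    cfg = cfg or TrainConfig()
    report = MetricsReport(schema="loso-online")
    for p_i, plan in enumerate(plans):
        base_subjects = sorted(set(dataset.subjects) - {plan.subject})
        model = model_factory(base_subjects, seed + p_i)
        k0, train0, test0 = plan.increments[0]
        assert plan.subject not in set(dataset.subjects[train0])
        train_model(model, dataset.subset(train0), cfg, seed=seed + p_i)
        proba = model.predict_proba(dataset.subset(test0), generic=True)
        report.rows.append({"subject": plan.subject, "weeks": 0,
                            **compute_metrics(dataset.labels[test0], proba)})
        for k, train_idx, test_idx in plan.increments[1:]:
            if retrain_from_scratch:
                model = model_factory(base_subjects, seed + p_i)
                train_model(model, dataset.subset(train0), cfg, seed=seed + p_i)
            model.add_subject(plan.subject)
            ft_cfg = TrainConfig(epochs=fine_tune_epochs, batch_size=cfg.batch_size,
                                 lr=cfg.lr, branch_lr=cfg.branch_lr, loss=cfg.loss,
                                 with_generic=cfg.with_generic,
                                 tau0=cfg.tau_min, tau_min=cfg.tau_min)
            train_model(model, dataset.subset(train_idx), ft_cfg,
                        seed=seed + 1000 + 31 * p_i + k)
            proba = model.predict_proba(dataset.subset(test_idx))
            report.rows.append({"subject": plan.subject, "weeks": k,
                                **compute_metrics(dataset.labels[test_idx], proba)})
    return report


def online_curve(report: MetricsReport, metric: str = "micro_f1") -> "pd.DataFrame":
    """Mean +/- std of a metric against weeks of included data."""
    import pandas as pd

    df = pd.DataFrame(report.rows)
    return (df.groupby("weeks")[metric].agg(["mean", "std", "count"])
            .reset_index())


def score_external_predictions(dataset, csv_path: str) -> dict:
    """Score a third-party model's predictions against a dataset.

    The CSV carries ``subject_id, date, p1, p2, p3`` (3-class
    probabilities); rows are matched to the dataset on (subject, date) and
    every dataset example must be covered.  Lets baselines that are out of
    scope for this package (e.g. models needing GPS features) enter the
    same comparison tables.
    """
    import pandas as pd

    ext = pd.read_csv(csv_path, dtype={"subject_id": str, "date": str})
    key = {(s, d): i for i, (s, d) in enumerate(zip(ext["subject_id"], ext["date"]))}
    rows = []
    for s, d in zip(dataset.subjects, dataset.dates):
        if (str(s), str(d)) not in key:
            raise ValueError(f"external predictions missing ({s}, {d})")
        rows.append(key[(str(s), str(d))])
    proba = ext.loc[rows, ["p1", "p2", "p3"]].to_numpy(dtype=float)
    if not np.allclose(proba.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("external probabilities must sum to 1 per row")
    return compute_metrics(dataset.labels, proba)
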