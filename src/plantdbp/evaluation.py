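"""Classifier evaluation: confusion-matrix metrics, 5-fold CV, threshold sweeps.

Four statistics summarise a binary confusion matrix:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    MCC         = (TP*TN - FN*FP) / sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP))

Accuracy alone is misleading on imbalanced (realistic, ~10:1) sets; the
Matthews correlation coefficient is the balanced quality measure used to
rank models. Cross-validation is stratified 5-fold with the grid search
re-run inside every fold; the summary matrix pools the per-fold counts.

For proteome-wide annotation, the probability threshold is chosen from a
sweep of predicted-set sizes against the expected DNA-binding fraction of
a proteome (~6%): the smallest threshold whose predicted set does not
exceed the expected count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .datasets import DNA_BP, LabeledDataset
from .model import GridSearchConfig, PredictionRecord, grid_search_train, predict

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.TP + other.TP, self.TN + other.TN,
            self.FP + other.FP, self.FN + other.FN,
        )


@dataclass(frozen=True)
class MetricsReport:
    """Metrics at full precision; ``None`` marks an undefined denominator."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    mcc: float | None

    def rounded(self, ndigits: int = 2) -> dict[str, float | None]:
        """Display rounding only — computations stay at full precision."""
        return {
            name: (None if value is None else round(value, ndigits))
            for name, value in vars(self).items()
        }


def confusion_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, sensitivity, specificity and MCC from one matrix."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    sens = cm.TP / (cm.TP + cm.FN) if cm.TP + cm.FN else None
    spec = cm.TN / (cm.TN + cm.FP) if cm.TN + cm.FP else None
    denom = (
        (cm.TP + cm.FN) * (cm.TP + cm.FP) * (cm.TN + cm.FN) * (cm.TN + cm.FP)
    )
    mcc = (cm.TP * cm.TN - cm.FN * cm.FP) / math.sqrt(denom) if denom else None
    return MetricsReport(
        accuracy=(cm.TP + cm.TN) / cm.total,
        sensitivity=sens,
        specificity=spec,
        mcc=mcc,
    )


def confusion_from_predictions(
    predictions: Sequence[PredictionRecord], truth: Mapping[str, str]
) -> ConfusionMatrix:
    tp = tn = fp = fn = 0
    for pred in predictions:
        actual_pos = truth[pred.protein_id] == DNA_BP
        predicted_pos = pred.predicted_label == DNA_BP
        if predicted_pos and actual_pos:
            tp += 1
        elif predicted_pos:
            fp += 1
        elif actual_pos:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp, tn, fp, fn)


def evaluate_on(
    model, test_set: LabeledDataset
) -> tuple[MetricsReport, ConfusionMatrix]:
    """Held-out test-set evaluation of a trained model."""
    preds = predict(model, test_set.records)
    truth = dict(zip([r.id for r in test_set.records], test_set.labels))
    cm = confusion_from_predictions(preds, truth)
    return confusion_metrics(cm), cm


def cross_validate(
    dataset: LabeledDataset,
    k: int = 5,
    grid_config: GridSearchConfig | None = None,
    seed: int | None = None,
) -> tuple[MetricsReport, list[tuple[MetricsReport, ConfusionMatrix]]]:
    """Stratified k-fold CV with grid search re-run per fold.

    Every entry is tested exactly once; the summary report is computed on
    the pooled confusion matrix (stable for small folds), with per-fold
    reports returned alongside.
    """
    if dataset.n_pos == 0 or dataset.n_neg == 0:
        raise ValueError("cross-validation needs both classes")
    if k > min(dataset.n_pos, dataset.n_neg):
        raise ValueError(
            f"k={k} exceeds the smaller class count "
            f"({min(dataset.n_pos, dataset.n_neg)})"
        )
    grid_config = grid_config or GridSearchConfig(seed=seed or 0)
    y = np.array([1 if label == DNA_BP else 0 for label in dataset.labels])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled = ConfusionMatrix(0, 0, 0, 0)
    per_fold = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        train = LabeledDataset(
            [dataset.entries[i] for i in train_idx],
            provenance=f"{dataset.provenance}_cvfold{fold}_train",
            seed=seed,
        )
        test = LabeledDataset(
            [dataset.entries[i] for i in test_idx],
            provenance=f"{dataset.provenance}_cvfold{fold}_test",
            seed=seed,
        )
        model, _ = grid_search_train(train, grid_config)
        report, cm = evaluate_on(model, test)
        per_fold.append((report, cm))
        pooled = pooled + cm
    return confusion_metrics(pooled), per_fold


@dataclass(frozen=True)
class ThresholdSweepRow:
    threshold: float
    n_predicted: int  # predicted DNA-binding with probability_score >= threshold
    n_goa_db: int
    n_goa_other: int
    n_goa_unknown: int


def threshold_sweep(
    predictions: Sequence[PredictionRecord],
    goa_classes: Mapping[str, str] | None,
    thresholds: Sequence[float],
) -> list[ThresholdSweepRow]:
    """Predicted-set sizes (total and per annotation class) per threshold.

    Counting is inclusive (score >= threshold) over predictions labelled
    DNA-binding. ``goa_classes`` maps protein id to one of GOA_DB,
    GOA_OTHER, GOA_UNKNOWN; proteins missing from the map count as
    GOA_UNKNOWN.
    """
    thresholds = list(thresholds)
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be sorted ascending")
    goa_classes = goa_classes or {}
    rows = []
    positives = [p for p in predictions if p.predicted_label == DNA_BP]
    for t in thresholds:
        hits = [p for p in positives if p.probability_score >= t]
        classes = [goa_classes.get(p.protein_id, "GOA_UNKNOWN") for p in hits]
        rows.append(
            ThresholdSweepRow(
                threshold=t,
                n_predicted=len(hits),
                n_goa_db=classes.count("GOA_DB"),
                n_goa_other=classes.count("GOA_OTHER"),
                n_goa_unknown=classes.count("GOA_UNKNOWN"),
            )
        )
    for a, b in zip(rows, rows[1:]):  # totals must shrink as the bar rises
        assert b.n_predicted <= a.n_predicted
    return rows


def expected_dbp_count(proteome_size: int, expected_fraction: float = 0.06) -> int:
    """Round-half-up expected number of DNA-binding proteins in a proteome."""
    return int(math.floor(expected_fraction * proteome_size + 0.5))


def select_threshold(
    sweep: Sequence[ThresholdSweepRow] | Mapping[float, int],
    proteome_size: int,
    expected_fraction: float = 0.06,
) -> float:
    """Smallest threshold whose predicted set fits the expected count.

    The expected count is the ~6% DNA-binding fraction of the proteome,
    rounded half-up. If every threshold over-predicts, the largest is
    returned with a warning.
    """
    if isinstance(sweep, Mapping):
        items = sorted(sweep.items())
    else:
        items = [(row.threshold, row.n_predicted) for row in sweep]
    if not items:
        raise ValueError("empty threshold sweep")
    expected = expected_dbp_count(proteome_size, expected_fraction)
    for threshold, count in items:
        if count <= expected:
            return threshold
    logger.warning(
        "no threshold yields <= %d predictions; returning the largest (%.2f)",
        expected, items[-1][0],
    )
    return items[-1][0]


def sweep_to_frame(sweep: Sequence[ThresholdSweepRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in sweep])


def metrics_to_frame(reports: Mapping[str, MetricsReport], ndigits: int = 2) -> pd.DataFrame:
    rows = []
    for name, rep in reports.items():
        row: dict[str, object] = {"evaluation": name}
        row.update(rep.rounded(ndigits))
        rows.append(row)
    return pd.DataFrame(rows)
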