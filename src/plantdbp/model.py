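"""The RBF-kernel support-vector classifier with probability scores.

A soft-margin SVM over the 20-dimensional composition vector, radial
basis kernel, with cost C and kernel width gamma selected by grid search
(stratified inner cross-validation, accuracy as the selection metric,
ties broken toward the smoother model: smaller C, then smaller gamma).
The final model is refit on the full training set with Platt-style
sigmoid probability calibration, so every prediction carries a
probability score in [0.5, 1.0] — the posterior of the predicted class —
which downstream thresholding (e.g. >= 0.85 for proteome annotation)
relies on.

Composition fractions already live in [0, 1]; they are used raw, with no
extra scaling, and the fixed residue order is written into model files so
feature columns can never silently permute.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .datasets import DNA_BP, NON_DNA_BP, LabeledDataset
from .features import composition_matrix
from .sequences import CANONICAL_RESIDUES, ProteinRecord

_FORMAT_VERSION = 1


def _default_cost_grid() -> tuple[float, ...]:
    return tuple(2.0 ** np.arange(-5, 16, 2))  # 2^-5 .. 2^15, step x4


def _default_gamma_grid() -> tuple[float, ...]:
    return tuple(2.0 ** np.arange(-15, 4, 2))  # 2^-15 .. 2^3, step x4


@dataclass(frozen=True)
class GridSearchConfig:
    """Cost/gamma grid and inner-CV settings for model selection."""

    cost_grid: tuple[float, ...] = field(default_factory=_default_cost_grid)
    gamma_grid: tuple[float, ...] = field(default_factory=_default_gamma_grid)
    inner_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cost_grid or not self.gamma_grid:
            raise ValueError("grids must be non-empty")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")

    @classmethod
    def small(cls, seed: int = 0) -> "GridSearchConfig":
        """5x5 grid suited to datasets of a few hundred sequences."""
        return cls(
            cost_grid=tuple(2.0 ** np.arange(-1, 8, 2)),
            gamma_grid=tuple(2.0 ** np.arange(-7, 2, 2)),
            seed=seed,
        )


@dataclass
class TrainedModel:
    """A fitted, probability-calibrated RBF-SVM."""

    svc: CalibratedClassifierCV
    cost: float
    gamma: float
    feature_order: tuple[str, ...]
    training_provenance: str
    seed: int

    def __post_init__(self) -> None:
        if self.feature_order != tuple(CANONICAL_RESIDUES):
            raise ValueError("model feature order does not match the canonical residue order")


@dataclass(frozen=True)
class PredictionRecord:
    """One protein's predicted class and calibrated probabilities."""

    protein_id: str
    predicted_label: str  # DNA_BP or NON_DNA_BP
    probability_score: float  # posterior of the predicted class, in [0.5, 1.0]
    p_dna_bp: float  # posterior of the DNA_BP class, in [0, 1]


def _design(dataset: LabeledDataset) -> tuple[np.ndarray, np.ndarray]:
    X = composition_matrix(dataset.records).to_numpy()
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values in dataset")
    y = np.array([1 if label == DNA_BP else 0 for label in dataset.labels])
    return X, y


def _inner_cv_accuracy(
    X: np.ndarray, y: np.ndarray, cost: float, gamma: float,
    folds: int, seed: int,
) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for train_idx, test_idx in skf.split(X, y):
        clf = SVC(kernel="rbf", C=cost, gamma=gamma)
        clf.fit(X[train_idx], y[train_idx])
        correct += int((clf.predict(X[test_idx]) == y[test_idx]).sum())
    return correct / len(y)


def grid_search_train(
    dataset: LabeledDataset,
    config: GridSearchConfig | None = None,
) -> tuple[TrainedModel, pd.DataFrame]:
    """Select (C, gamma) by stratified inner CV and refit with calibration.

    Returns the trained model and a grid report with the inner-CV
    accuracy of every (cost, gamma) pair. The selected pair maximises
    accuracy; ties go to the smaller cost, then the smaller gamma.
    """
    config = config or GridSearchConfig()
    if dataset.n_pos == 0 or dataset.n_neg == 0:
        raise ValueError("training dataset must contain both classes")
    X, y = _design(dataset)
    rows = []
    best: tuple[float, float, float] | None = None  # (acc, cost, gamma)
    for cost in sorted(config.cost_grid):
        for gamma in sorted(config.gamma_grid):
            acc = _inner_cv_accuracy(X, y, cost, gamma, config.inner_folds, config.seed)
            rows.append({"cost": cost, "gamma": gamma, "cv_accuracy": acc})
            if best is None or acc > best[0]:
                best = (acc, cost, gamma)
    assert best is not None
    _, cost, gamma = best
    # sigmoid (Platt-style) probability calibration, refit on the full set;
    # calibration folds shrink with the smaller class so tiny sets still train
    calib_folds = min(config.inner_folds, dataset.n_pos, dataset.n_neg)
    svc = CalibratedClassifierCV(
        SVC(kernel="rbf", C=cost, gamma=gamma),
        method="sigmoid",
        ensemble=False,
        cv=StratifiedKFold(n_splits=calib_folds, shuffle=True, random_state=config.seed),
    )
    svc.fit(X, y)
    model = TrainedModel(
        svc=svc,
        cost=cost,
        gamma=gamma,
        feature_order=tuple(CANONICAL_RESIDUES),
        training_provenance=dataset.provenance,
        seed=config.seed,
    )
    return model, pd.DataFrame(rows)


def predict(model: TrainedModel, records: Sequence[ProteinRecord]) -> list[PredictionRecord]:
    """Predict every record, preserving input order."""
    if not records:
        return []
    X = composition_matrix(records).to_numpy()
    pos_col = int(np.where(model.svc.classes_ == 1)[0][0])
    proba = model.svc.predict_proba(X)[:, pos_col]
    out = []
    for rec, p in zip(records, proba):
        label = DNA_BP if p >= 0.5 else NON_DNA_BP
        out.append(
            PredictionRecord(
                protein_id=rec.id,
                predicted_label=label,
                probability_score=float(max(p, 1.0 - p)),
                p_dna_bp=float(p),
            )
        )
    return out


def predictions_to_frame(predictions: Sequence[PredictionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [p.protein_id for p in predictions],
            "predicted_label": [p.predicted_label for p in predictions],
            "p_dna_bp": [p.p_dna_bp for p in predictions],
            "probability_score": [p.probability_score for p in predictions],
        }
    )


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a model as a self-describing pickled archive.

    The file embeds a format version, the residue feature order, the
    selected hyperparameters, and training provenance; loading verifies
    all of these before handing back a usable model.
    """
    payload = {
        "format": "plantdbp-model",
        "format_version": _FORMAT_VERSION,
        "feature_order": list(model.feature_order),
        "cost": model.cost,
        "gamma": model.gamma,
        "training_provenance": model.training_provenance,
        "seed": model.seed,
        "svc": model.svc,
    }
    with Path(path).open("wb") as handle:
        pickle.dump(payload, handle)


def load_model(path: str | Path) -> TrainedModel:
    """Load a model saved by :func:`save_model`; round-trips bit-identically."""
    try:
        with Path(path).open("rb") as handle:
            payload = pickle.load(handle)
    except (pickle.UnpicklingError, EOFError, AttributeError) as exc:
        raise ValueError(f"corrupt or truncated model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != "plantdbp-model":
        raise ValueError(f"{path} is not a plantdbp model file")
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {payload.get('format_version')!r}"
        )
    if tuple(payload["feature_order"]) != tuple(CANONICAL_RESIDUES):
        raise ValueError(
            "model feature order does not match this build's canonical residue order"
        )
    return TrainedModel(
        svc=payload["svc"],
        cost=payload["cost"],
        gamma=payload["gamma"],
        feature_order=tuple(payload["feature_order"]),
        training_provenance=payload["training_provenance"],
        seed=payload["seed"],
    )
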