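"""Repeated per-patient half-split evaluation protocol.

For each repeat, independently for every patient, half of that patient's
clips are randomly assigned to training (ceil of half when odd) and the rest
to testing.  The classifier pipeline — feature z-scoring, cross-validated
choice of the regularization constant C, SVM fit — is run on the training
half only, predictions are made on the held-out half, and clip-level
accuracy is recorded.  The split/fit/test cycle is repeated (5 times by
default) with seeds ``base_seed + r`` and the per-repeat accuracies are
averaged into the report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .svm import (
    DEFAULT_C_GRID,
    KernelSpec,
    SVMModel,
    TrainingSet,
    predict,
    select_C,
    solve_dual,
)

__all__ = [
    "LabeledClip",
    "SplitPlan",
    "EvaluationReport",
    "half_split_per_patient",
    "accuracy",
    "run_experiment",
]


@dataclass(frozen=True)
class LabeledClip:
    """One clip's gist feature with its provenance and class label."""

    clip_id: str
    patient_id: str
    feature: np.ndarray
    label: int  # +1 normal, -1 abnormal
    recording_id: str = ""  # parent recording, for the strict grouping mode

    def __post_init__(self) -> None:
        feature = np.asarray(self.feature, dtype=np.float64)
        if feature.ndim != 1 or not np.all(np.isfinite(feature)):
            raise ValueError("clip feature must be a finite 1-D vector")
        if self.label not in (1, -1):
            raise ValueError(f"label must be +1 or -1, got {self.label}")
        object.__setattr__(self, "feature", feature)


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint train/test clip-id sets whose union covers the dataset."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int


@dataclass(frozen=True)
class EvaluationReport:
    """Per-repeat test accuracies of the protocol and their mean."""

    repeat_accuracies: tuple[float, ...]
    mean_accuracy: float
    n_repeats: int
    seeds: tuple[int, ...]
    config: dict

    def to_json(self) -> str:
        payload = {
            "repeat_accuracies": list(self.repeat_accuracies),
            "mean_accuracy": self.mean_accuracy,
            "n_repeats": self.n_repeats,
            "seeds": list(self.seeds),
            "config": self.config,
            "config_hash": hashlib.sha256(
                json.dumps(self.config, sort_keys=True).encode()
            ).hexdigest()[:16],
        }
        return json.dumps(payload, sort_keys=True, indent=2)


def half_split_per_patient(
    clips: Sequence[LabeledClip],
    seed: int,
    group_by_recording: bool = False,
) -> SplitPlan:
    """Randomly assign half of each patient's clips to training.

    Clips are permuted per patient with a generator seeded by ``seed``
    (patients visited in sorted order, so the plan is deterministic); the
    first ceil(n/2) go to training, the rest to testing.  With
    ``group_by_recording`` the unit permuted is the parent recording, so
    sibling clips of one recording never straddle the split.
    """
    rng = np.random.default_rng(seed)
    by_patient: dict[str, list[LabeledClip]] = {}
    for c in clips:
        by_patient.setdefault(c.patient_id, []).append(c)

    train: list[str] = []
    test: list[str] = []
    for pid in sorted(by_patient):
        group = sorted(by_patient[pid], key=lambda c: c.clip_id)
        if len(group) < 2:
            raise ValueError(
                f"patient {pid!r} has only {len(group)} clip(s); "
                "the half-split needs at least 2"
            )
        if group_by_recording:
            recs = sorted({c.recording_id or c.clip_id for c in group})
            order = rng.permutation(len(recs))
            n_train = -(-len(recs) // 2)
            train_recs = {recs[i] for i in order[:n_train]}
            for c in group:
                (train if (c.recording_id or c.clip_id) in train_recs else test).append(c.clip_id)
        else:
            order = rng.permutation(len(group))
            n_train = -(-len(group) // 2)  # ceil
            for pos, i in enumerate(order):
                (train if pos < n_train else test).append(group[i].clip_id)
    return SplitPlan(train_ids=tuple(train), test_ids=tuple(test), seed=seed)


def accuracy(predictions: Sequence[int], labels: Sequence[int]) -> float:
    """Fraction of predictions matching the labels."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.size == 0:
        raise ValueError("cannot compute accuracy of zero predictions")
    if predictions.shape != labels.shape:
        raise ValueError(
            f"length mismatch: {predictions.shape} predictions vs "
            f"{labels.shape} labels"
        )
    return float(np.mean(predictions == labels))


def _zscore_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std < 1e-12, 1.0, std)
    return mean, std


def _fit_on_train(
    X_train: np.ndarray,
    y_train: np.ndarray,
    spec: KernelSpec,
    c_grid: Sequence[float],
    k_folds: int,
    seed: int,
) -> tuple[SVMModel, np.ndarray, np.ndarray]:
    """Fit scaler + C selection + SVM on training data only (no leakage)."""
    mean, std = _zscore_stats(X_train)
    Xs = (X_train - mean) / std
    train = TrainingSet(Xs, y_train)
    C = select_C(train, grid=c_grid, k=k_folds, spec=spec, seed=seed)
    model = solve_dual(train, C=C, spec=spec)
    return model, mean, std


def run_experiment(
    dataset: Sequence[LabeledClip],
    n_repeats: int = 5,
    base_seed: int = 0,
    spec: KernelSpec = KernelSpec(),
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    k_folds: int = 5,
    group_by_recording: bool = False,
) -> EvaluationReport:
    """Run the repeated per-patient half-split protocol on labeled clips.

    Repeat r uses split seed ``base_seed + r``; scaling statistics and the
    cross-validated C are computed on that repeat's training half only.
    Returns per-repeat clip-level accuracies and their arithmetic mean.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty dataset")
    labels = {c.label for c in dataset}
    if labels != {1, -1}:
        raise ValueError("dataset must contain both normal and abnormal clips")
    by_id = {c.clip_id: c for c in dataset}
    if len(by_id) != len(dataset):
        raise ValueError("clip_ids must be unique")

    accs = []
    seeds = []
    for r in range(n_repeats):
        seed = base_seed + r
        plan = half_split_per_patient(dataset, seed, group_by_recording)
        tr = [by_id[i] for i in plan.train_ids]
        te = [by_id[i] for i in plan.test_ids]
        y_train = np.array([c.label for c in tr], dtype=float)
        if np.unique(y_train).size < 2:
            raise ValueError(f"training half of repeat {r} contains one class only")
        X_train = np.stack([c.feature for c in tr])
        model, mean, std = _fit_on_train(X_train, y_train, spec, c_grid, k_folds, seed)
        X_test = (np.stack([c.feature for c in te]) - mean) / std
        preds = predict(model, X_test)
        accs.append(accuracy(preds, [c.label for c in te]))
        seeds.append(seed)

    config = {
        "kernel": {"family": spec.family, "c": spec.c, "d": spec.d, "sigma": spec.sigma},
        "c_grid": [float(c) for c in c_grid],
        "k_folds": k_folds,
        "base_seed": base_seed,
        "n_repeats": n_repeats,
        "group_by_recording": group_by_recording,
        "n_clips": len(dataset),
        "n_patients": len({c.patient_id for c in dataset}),
    }
    return EvaluationReport(
        repeat_accuracies=tuple(accs),
        mean_accuracy=float(np.mean(accs)),
        n_repeats=n_repeats,
        seeds=tuple(seeds),
        config=config,
    )
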