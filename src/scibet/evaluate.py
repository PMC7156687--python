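"""Hold-out evaluation harness: stratified splits, metrics and cross-validation.

Mirrors the standard benchmarking protocol for supervised cell-type
annotation: per-type stratified 7:3 train/test splits repeated with fresh
seeds, overall accuracy, balanced accuracy (unweighted mean of per-type
recalls, robust to class imbalance), labelled confusion matrices, even
per-type down-sampling, and a false-positive rate for rejection benchmarks.
Feature selection and training see only the training cells of each split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics

from .matrix import ExpressionMatrix, LabelVector, ValidationError, align_genes
from .etest import entropy_delta, group_mean_expression, select_features
from .model import train
from .classify import UNASSIGNED_LABEL, predict

__all__ = [
    "SplitPlan",
    "EvalReport",
    "CrossValidationResult",
    "stratified_split",
    "accuracy",
    "balanced_accuracy",
    "confusion_matrix",
    "downsample_even",
    "false_positive_rate",
    "evaluate_split",
    "cross_validate",
]


@dataclass
class SplitPlan:
    train_cell_names: list[str]
    test_cell_names: list[str]
    seed: int
    ratio: float


@dataclass
class EvalReport:
    accuracy: float
    balanced_accuracy: float
    confusion: pd.DataFrame
    fpr: float | None = None


@dataclass
class CrossValidationResult:
    reports: list[EvalReport]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([r.accuracy for r in self.reports]))

    @property
    def mean_balanced_accuracy(self) -> float:
        return float(np.mean([r.balanced_accuracy for r in self.reports]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "repeat": np.arange(len(self.reports)),
                "accuracy": [r.accuracy for r in self.reports],
                "balanced_accuracy": [r.balanced_accuracy for r in self.reports],
            }
        )


def stratified_split(labels: LabelVector, ratio: float = 0.7, seed: int = 0) -> SplitPlan:
    """Per-type sampling without replacement into train/test at ``ratio``.

    The train count per type is round-half-up of ``ratio·n_type``, clamped so
    both sides keep at least one cell; types with a single cell are rejected.
    """
    if not 0.0 < ratio < 1.0:
        raise ValidationError("ratio must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    cells = np.asarray(labels.cell_names)
    lab = np.asarray(labels.labels)
    train_cells: list[str] = []
    test_cells: list[str] = []
    for t in sorted(set(labels.labels)):
        members = cells[lab == t]
        if members.size < 2:
            raise ValidationError(f"cell type {t!r} has fewer than 2 cells")
        n_train = int(np.floor(ratio * members.size + 0.5))
        n_train = min(max(n_train, 1), members.size - 1)
        perm = rng.permutation(members.size)
        train_cells.extend(members[perm[:n_train]].tolist())
        test_cells.extend(members[perm[n_train:]].tolist())
    return SplitPlan(train_cells, test_cells, seed, ratio)


def _check_lengths(truth, predicted) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(list(truth), dtype=object)
    p = np.asarray(list(predicted), dtype=object)
    if t.size != p.size:
        raise ValidationError(f"{t.size} truth labels vs {p.size} predictions")
    return t, p


def accuracy(truth, predicted) -> float:
    """Fraction of cells whose predicted label equals the truth."""
    t, p = _check_lengths(truth, predicted)
    return float(skmetrics.accuracy_score(t, p))


def balanced_accuracy(truth, predicted) -> float:
    """Unweighted mean of per-type recalls over the types present in truth.

    Predicted labels outside the truth set (notably "unassigned") count as
    wrong for every type, so their zero-support recall rows are ignored.
    """
    t, p = _check_lengths(truth, predicted)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pred-only classes have undefined recall
        return float(skmetrics.balanced_accuracy_score(t, p))


def confusion_matrix(truth, predicted, normalize: str = "none") -> pd.DataFrame:
    """Labelled confusion counts, optionally normalized per origin label.

    ``none`` returns raw counts with true types on rows and predicted types
    on columns.  ``by_truth_row`` divides each row by its cell count.
    ``by_truth_column`` returns the transposed layout (origin labels as
    columns, each summing to 1), the convention used in published heatmaps.
    """
    t, p = _check_lengths(truth, predicted)
    counts = pd.crosstab(
        pd.Series(t, name="truth"), pd.Series(p, name="predicted"), dropna=False
    )
    if normalize == "none":
        return counts
    frac = counts.div(counts.sum(axis=1), axis=0)
    if normalize == "by_truth_row":
        return frac
    if normalize == "by_truth_column":
        return frac.T
    raise ValidationError(f"unknown normalization {normalize!r}")


def downsample_even(labels: LabelVector, n_per_type: int, seed: int = 0) -> list[str]:
    """Sample exactly ``n_per_type`` cells of every type, without replacement."""
    if n_per_type < 1:
        raise ValidationError("n_per_type must be >= 1")
    rng = np.random.default_rng(seed)
    cells = np.asarray(labels.cell_names)
    lab = np.asarray(labels.labels)
    chosen: list[str] = []
    for t in sorted(set(labels.labels)):
        members = cells[lab == t]
        if members.size < n_per_type:
            raise ValidationError(
                f"cell type {t!r} has {members.size} cells < n_per_type={n_per_type}"
            )
        idx = rng.choice(members.size, size=n_per_type, replace=False)
        chosen.extend(members[np.sort(idx)].tolist())
    return chosen


def false_positive_rate(negatives_truth, unassigned) -> float:
    """Fraction of should-be-rejected cells that were nevertheless assigned."""
    neg = np.asarray(negatives_truth, dtype=bool)
    una = np.asarray(unassigned, dtype=bool)
    if neg.size != una.size:
        raise ValidationError("negatives_truth and unassigned differ in length")
    if neg.sum() == 0:
        raise ValidationError("no negative cells: FPR undefined")
    return float((neg & ~una).sum() / neg.sum())


def evaluate_split(
    m: ExpressionMatrix,
    labels: LabelVector,
    plan: SplitPlan,
    k_features: int = 500,
    pseudocount: float = 1.0,
) -> EvalReport:
    """Select markers and train on the split's training cells only, then score the test cells."""
    train_m = m.select_cells(plan.train_cell_names)
    train_lab = labels.subset(plan.train_cell_names)
    table = entropy_delta(group_mean_expression(train_m, train_lab), pseudocount)
    features = select_features(table, k_features)
    model = train(train_m, train_lab, features, pseudocount)
    test_m = align_genes(features, m.select_cells(plan.test_cell_names)).matrix
    result = predict(model, test_m)
    truth = labels.subset(plan.test_cell_names).labels
    return EvalReport(
        accuracy=accuracy(truth, result.labels),
        balanced_accuracy=balanced_accuracy(truth, result.labels),
        confusion=confusion_matrix(truth, result.labels),
    )


def cross_validate(
    m: ExpressionMatrix,
    labels: LabelVector,
    k_features: int = 500,
    n_repeats: int = 50,
    ratio: float = 0.7,
    seed: int = 0,
) -> CrossValidationResult:
    """Repeated stratified hold-out validation.

    Each repeat (seeded ``seed + repeat`` for auditability) draws a fresh
    split, runs marker selection and training on the training cells alone,
    and scores the held-out cells.
    """
    reports = [
        evaluate_split(m, labels, stratified_split(labels, ratio, seed + i), k_features)
        for i in range(n_repeats)
    ]
    return CrossValidationResult(reports)
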