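"""Cross-validation protocols, classification metrics and the ablation harness.

Folds are always subject-disjoint: mirrored copies carry the subject id of
their source example, so a held-out subject's mirrored walks can never leak
into training.  Binary metrics follow the usual confusion-count formulas and
are reported as percentages rounded half-up to two decimals, with undefined
denominators reported as ``None`` rather than zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import ValidationError
from .features import DatasetViews
from .model import HybridModel, HybridModelConfig, TrainOptions, train_model
from .skeleton import GaitDataset

__all__ = [
    "ConfusionCounts",
    "FoldPlan",
    "loso_split",
    "kfold_split",
    "confusion_matrix",
    "binary_metrics",
    "cross_validate",
    "run_ablation",
    "ABLATION_COMBOS",
]

ABLATION_COMBOS: tuple[tuple[str, ...], ...] = (
    ("params",),
    ("angles",),
    ("skeleton",),
    ("params", "angles"),
    ("params", "skeleton"),
    ("angles", "skeleton"),
    ("params", "angles", "skeleton"),
)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts (positive class = disorder/patient)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(cls, y_true: np.ndarray, y_pred: np.ndarray,
                    positive: int = 1) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t, pos_p = y_true == positive, y_pred == positive
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
        )


@dataclass(frozen=True)
class FoldPlan:
    """Subject-level train/test split plan."""

    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    protocol: str
    seed: int | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for train, test in self.folds:
            overlap = set(train) & set(test)
            if overlap:
                raise ValidationError(f"subjects in both train and test: {overlap}")
            dup = seen & set(test)
            if dup:
                raise ValidationError(f"subjects tested in multiple folds: {dup}")
            seen |= set(test)

    def __len__(self) -> int:
        return len(self.folds)


def loso_split(ds: GaitDataset) -> FoldPlan:
    """Leave-one-subject-out: one fold per subject."""
    subjects = ds.subject_ids
    if len(subjects) < 2:
        raise ValidationError("leave-one-subject-out requires at least 2 subjects")
    folds = tuple(
        (tuple(s for s in subjects if s != held_out), (held_out,))
        for held_out in subjects
    )
    return FoldPlan(folds=folds, protocol="loso")


def kfold_split(ds: GaitDataset, k: int, seed: int = 0) -> FoldPlan:
    """Subject-disjoint k-fold split with a seeded subject shuffle."""
    if k < 2:
        raise ValidationError("k must be at least 2")
    subjects = ds.subject_ids
    if len(subjects) < k:
        raise ValidationError(f"need at least {k} subjects for {k}-fold CV")
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    chunks = [tuple(order[i::k]) for i in range(k)]
    folds = tuple(
        (tuple(s for s in subjects if s not in set(test)), test)
        for test in chunks
    )
    return FoldPlan(folds=folds, protocol="kfold", seed=seed)


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """``C x C`` matrix with rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValidationError("label vectors must have equal length")
    for name, y in (("true", y_true), ("predicted", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValidationError(f"{name} label out of range [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def binary_metrics(cc: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy, sensitivity, specificity, precision as display percentages.

    Each metric is ``None`` when its denominator is zero.
    """
    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else _round2(100.0 * num / den)

    return {
        "accuracy": ratio(cc.tp + cc.tn, cc.total),
        "sensitivity": ratio(cc.tp, cc.tp + cc.fn),
        "specificity": ratio(cc.tn, cc.tn + cc.fp),
        "precision": ratio(cc.tp, cc.tp + cc.fp),
    }


def _validation_subjects(train_subjects: list[str], seed: int,
                         fraction: float) -> set[str]:
    """A seeded fraction of training subjects (at least one) for early stopping."""
    if fraction <= 0.0:
        return set()
    rng = np.random.default_rng(seed)
    n_val = max(1, int(round(fraction * len(train_subjects))))
    if n_val >= len(train_subjects):
        return set()
    idx = rng.permutation(len(train_subjects))[:n_val]
    return {train_subjects[i] for i in idx}


def cross_validate(
    views: DatasetViews,
    plan: FoldPlan,
    config: HybridModelConfig,
    opts: TrainOptions | None = None,
    val_fraction: float = 0.1,
) -> dict:
    """Train per fold and pool held-out predictions.

    A ``val_fraction`` of training subjects is held out for early stopping;
    with ``val_fraction=0`` each fold trains on all its subjects for the full
    epoch budget.  Returns pooled ``y_true``/``y_pred``, per-fold accuracies
    and histories.
    """
    opts = opts or TrainOptions()
    subjects = np.asarray(views.subjects)
    y_true_all, y_pred_all = [], []
    fold_acc, histories = [], []
    for fold_i, (train_subj, test_subj) in enumerate(plan.folds):
        train_subj = list(train_subj)
        test_mask = np.isin(subjects, list(test_subj))
        val_subj = _validation_subjects(train_subj, opts.seed + fold_i,
                                        val_fraction)
        val_mask = np.isin(subjects, list(val_subj))
        train_mask = ~test_mask & ~val_mask
        if not train_mask.any():
            raise ValidationError(f"fold {fold_i}: empty training split")
        tr = views.subset(np.flatnonzero(train_mask))
        te = views.subset(np.flatnonzero(test_mask))
        model = HybridModel(config)
        if val_mask.any():
            va = views.subset(np.flatnonzero(val_mask))
            hist = train_model(model, tr.views(), tr.labels, va.views(),
                               va.labels, opts)
        else:
            hist = train_model(model, tr.views(), tr.labels, opts=opts)
        y_pred, _ = model.predict(te.views())
        y_true_all.append(te.labels)
        y_pred_all.append(np.atleast_1d(y_pred))
        fold_acc.append(float(np.mean(np.atleast_1d(y_pred) == te.labels)))
        histories.append(hist)
    y_true = np.concatenate(y_true_all)
    y_pred = np.concatenate(y_pred_all)
    return {
        "y_true": y_true,
        "y_pred": y_pred,
        "pooled_accuracy": float(np.mean(y_pred == y_true)),
        "fold_accuracies": fold_acc,
        "mean_fold_accuracy": float(np.mean(fold_acc)),
        "histories": histories,
    }


def run_ablation(
    views: DatasetViews,
    plan: FoldPlan,
    config: HybridModelConfig,
    opts: TrainOptions | None = None,
    combos: tuple[tuple[str, ...], ...] = ABLATION_COMBOS,
    val_fraction: float = 0.1,
) -> pd.DataFrame:
    """Cross-validate every input-branch combination.

    Unused encoding branches are deactivated (not built) per configuration.
    Returns one row per combination with pooled accuracy and, for binary
    tasks, sensitivity/specificity/precision.
    """
    from dataclasses import replace

    rows = []
    for combo in combos:
        cfg = replace(config, branches=tuple(combo))
        result = cross_validate(views, plan, cfg, opts, val_fraction)
        row = {
            "inputs": "+".join(combo),
            "n_inputs": len(combo),
            "accuracy": _round2(100.0 * result["pooled_accuracy"]),
            "mean_fold_accuracy": _round2(100.0 * result["mean_fold_accuracy"]),
        }
        if config.n_classes == 2:
            cc = ConfusionCounts.from_labels(result["y_true"], result["y_pred"])
            row.update(binary_metrics(cc))
        rows.append(row)
    return pd.DataFrame(rows)
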