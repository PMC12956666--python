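"""Multiclass evaluation: confusion matrices, agreement metrics, splits,
cross-validation and the two ablation studies.

Conventions: confusion rows are true classes, columns predicted, in 1..K code
order.  Precision/recall with a zero denominator are set to 0 (not NaN) so
macro aggregates stay defined on degenerate predictions.  The 70/30 split and
the 5-fold protocol are stratified by default and fully seeded; CV re-fits
standardization inside each fold so no information leaks across folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import DEFAULT_BANDS, N_AMPLITUDE_FEATURES
from .gmdh import DEFAULT_SCHEDULE, FitConfig, fit_gmdh, predict

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "confusion_matrix",
    "cohen_kappa",
    "per_class_prf",
    "evaluate_predictions",
    "train_test_split",
    "stratified_kfold_indices",
    "cross_validate",
    "depth_ablation",
    "ablation_schedule",
    "feature_subset_ablation",
    "feature_group_mask",
]


@dataclass
class ConfusionMatrix:
    """K×K integer counts; rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    """counts[i][j] = #{n : true = i+1, predicted = j+1}."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size and not (
        (1 <= y_true).all() and (y_true <= n_classes).all()
        and (1 <= y_pred).all() and (y_pred <= n_classes).all()
    ):
        raise ValueError(f"class codes must lie in 1..{n_classes}")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true - 1, y_pred - 1), 1)
    return ConfusionMatrix(counts)


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement κ = (p_o − p_e) / (1 − p_e)."""
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm.counts) / total
    marg = cm.counts.sum(axis=1) @ cm.counts.sum(axis=0)
    p_e = marg / total**2
    if p_e >= 1.0:
        raise ValueError("kappa undefined: chance agreement is 1 "
                         "(all mass in one row/column cell)")
    return float((p_o - p_e) / (1 - p_e))


def per_class_prf(cm: ConfusionMatrix) -> dict:
    """Per-class precision/recall/F1/support plus macro and weighted means."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(cm.counts).astype(np.float64)
    support = cm.counts.sum(axis=1)
    colsum = cm.counts.sum(axis=0)
    precision = np.divide(diag, colsum, out=np.zeros_like(diag), where=colsum > 0)
    recall = np.divide(diag, support, out=np.zeros_like(diag), where=support > 0)
    pr_sum = precision + recall
    f1 = np.divide(2 * precision * recall, pr_sum,
                   out=np.zeros_like(diag), where=pr_sum > 0)
    w = support / cm.total
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "support": support,
        "macro_precision": float(precision.mean()),
        "macro_recall": float(recall.mean()),
        "macro_f1": float(f1.mean()),
        "weighted_precision": float(precision @ w),
        "weighted_recall": float(recall @ w),
        "weighted_f1": float(f1 @ w),
    }


@dataclass
class EvaluationReport:
    """Confusion matrix with the derived global and per-class metrics."""

    confusion: ConfusionMatrix
    accuracy: float
    kappa: float
    per_class: dict
    class_labels: tuple[str, ...] | None = None

    def to_dict(self) -> dict:
        pc = self.per_class
        labels = self.class_labels or tuple(
            str(k + 1) for k in range(self.confusion.n_classes))
        return {
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "macro_precision": pc["macro_precision"],
            "macro_recall": pc["macro_recall"],
            "macro_f1": pc["macro_f1"],
            "weighted_precision": pc["weighted_precision"],
            "weighted_recall": pc["weighted_recall"],
            "weighted_f1": pc["weighted_f1"],
            "per_class": {
                lab: {
                    "precision": float(pc["precision"][k]),
                    "recall": float(pc["recall"][k]),
                    "f1": float(pc["f1"][k]),
                    "support": int(pc["support"][k]),
                }
                for k, lab in enumerate(labels)
            },
            "confusion": self.confusion.counts.tolist(),
        }

    def to_text(self) -> str:
        d = self.to_dict()
        lines = [
            f"accuracy            {100 * d['accuracy']:.2f} %",
            f"Cohen's kappa       {d['kappa']:.4f}",
            f"macro precision     {d['macro_precision']:.4f}",
            f"macro recall        {d['macro_recall']:.4f}",
            f"macro F1            {d['macro_f1']:.4f}",
            f"weighted F1         {d['weighted_f1']:.4f}",
            "",
            f"{'class':<8}{'precision':>10}{'recall':>10}{'f1':>10}{'support':>10}",
        ]
        for lab, row in d["per_class"].items():
            lines.append(f"{lab:<8}{row['precision']:>10.4f}{row['recall']:>10.4f}"
                         f"{row['f1']:>10.4f}{row['support']:>10d}")
        return "\n".join(lines)


def evaluate_predictions(y_true, y_pred, n_classes: int,
                         class_labels=None) -> EvaluationReport:
    cm = confusion_matrix(y_true, y_pred, n_classes)
    return EvaluationReport(
        confusion=cm,
        accuracy=float(np.trace(cm.counts) / cm.total),
        kappa=cohen_kappa(cm),
        per_class=per_class_prf(cm),
        class_labels=tuple(class_labels) if class_labels is not None else None,
    )


def train_test_split(labels, test_fraction: float = 0.30, seed: int = 0,
                     stratify: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Seeded disjoint/exhaustive (train, test) index sets.

    With ``stratify`` (the default) class proportions are preserved to
    rounding; 480 balanced rows at 0.30 give the study's 336/144 split.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    labels = np.asarray(labels)
    n = labels.size
    rng = np.random.default_rng(seed)
    if not stratify:
        perm = rng.permutation(n)
        n_test = int(round(test_fraction * n))
        return np.sort(perm[n_test:]), np.sort(perm[:n_test])
    test_parts = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} needs >= 2 rows for a stratified split")
        idx = rng.permutation(idx)
        n_test = int(round(test_fraction * idx.size))
        test_parts.append(idx[:n_test])
    test = np.sort(np.concatenate(test_parts))
    train = np.setdiff1d(np.arange(n), test)
    return train, test


def stratified_kfold_indices(labels, k: int, seed: int = 0) -> list[np.ndarray]:
    """k disjoint, exhaustive test folds preserving class proportions."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(f"class {cls!r} has support {idx.size} < k={k}")
        idx = rng.permutation(idx)
        for pos, sample in enumerate(idx):
            folds[pos % k].append(int(sample))
    return [np.sort(np.array(f, dtype=np.int64)) for f in folds]


def cross_validate(features, labels, config: FitConfig | None = None,
                   k: int = 5, seed: int = 0) -> dict:
    """Stratified k-fold CV: one full GMDH fit per fold.

    Every sample is tested exactly once; standardization is re-fitted within
    each training fold by :func:`~eegmdh.gmdh.fit_gmdh` itself.
    """
    X = np.asarray(features, dtype=np.float64)
    codes = np.asarray(labels, dtype=np.int64)
    config = config or FitConfig()
    folds = stratified_kfold_indices(codes, k, seed=seed)
    accuracies = []
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(codes.size), test_idx)
        model = fit_gmdh(X[train_idx], codes[train_idx], config)
        pred = predict(model, X[test_idx])
        accuracies.append(float(np.mean(pred == codes[test_idx])))
    acc = np.array(accuracies)
    return {
        "fold_accuracies": accuracies,
        "mean_accuracy": float(acc.mean()),
        "sd_accuracy": float(acc.std(ddof=1)) if k > 1 else 0.0,
        "folds": folds,
    }


def ablation_schedule(depth: int, base: tuple[int, ...] = DEFAULT_SCHEDULE,
                      extension_width: int = 5) -> tuple[int, ...]:
    """Schedule for a depth-d variant: truncate the base, or extend it by
    repeating the final width (the base ends at 5)."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if depth <= len(base):
        return base[:depth]
    return base + (extension_width,) * (depth - len(base))


def depth_ablation(features, labels, depths, config: FitConfig | None = None,
                   seed: int = 0, test_fraction: float = 0.30) -> dict[int, float]:
    """Held-out accuracy per network depth on a shared 70/30 split."""
    depths = list(depths)
    if not depths:
        raise ValueError("depth list must be non-empty")
    X = np.asarray(features, dtype=np.float64)
    codes = np.asarray(labels, dtype=np.int64)
    base = config or FitConfig()
    train, test = train_test_split(codes, test_fraction, seed=seed)
    result: dict[int, float] = {}
    for d in depths:
        cfg = FitConfig(schedule=ablation_schedule(d, base.schedule),
                        internal_split_fraction=base.internal_split_fraction,
                        max_candidate_pairs=base.max_candidate_pairs,
                        seed=base.seed, encoding_mode=base.encoding_mode)
        model = fit_gmdh(X[train], codes[train], cfg)
        result[d] = float(np.mean(predict(model, X[test]) == codes[test]))
    return result


FEATURE_GROUPS = ("frequency", "time", "all")


def feature_group_mask(group: str, n_channels: int,
                       n_bands: int = len(DEFAULT_BANDS)) -> np.ndarray:
    """Column indices for a feature subset of the electrode-major layout.

    ``frequency`` keeps the band powers and the dominant frequency (n_bands+1
    columns per electrode); ``time`` keeps mean/std/median/ptp; ``all`` keeps
    everything.
    """
    block = n_bands + N_AMPLITUDE_FEATURES
    if group == "all":
        return np.arange(n_channels * block)
    if group == "frequency":
        local = np.arange(n_bands + 1)
    elif group == "time":
        local = np.arange(n_bands + 1, block)
    else:
        raise ValueError(f"unknown feature group {group!r}; "
                         f"expected one of {FEATURE_GROUPS}")
    return np.concatenate([c * block + local for c in range(n_channels)])


def feature_subset_ablation(features, labels, groups=FEATURE_GROUPS,
                            config: FitConfig | None = None,
                            n_channels: int = 16,
                            n_bands: int = len(DEFAULT_BANDS),
                            seed: int = 0,
                            test_fraction: float = 0.30) -> dict[str, float]:
    """Held-out accuracy per feature subset on a shared 70/30 split."""
    X = np.asarray(features, dtype=np.float64)
    codes = np.asarray(labels, dtype=np.int64)
    cfg = config or FitConfig()
    train, test = train_test_split(codes, test_fraction, seed=seed)
    result: dict[str, float] = {}
    for group in groups:
        cols = feature_group_mask(group, n_channels, n_bands)
        model = fit_gmdh(X[np.ix_(train, cols)], codes[train], cfg)
        result[group] = float(np.mean(predict(model, X[np.ix_(test, cols)]) == codes[test]))
    return result
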