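"""Metrics, cross-validation and experiment sweeps.

Performance is summarized by a 4x4 confusion matrix (rows = true
labels, columns = predicted labels, category order: low-level signal,
single fetal heartbeat, multiple heartbeats, artifact) and the derived
percentages

    accuracy  = trace / total x 100          (multiclass form)
    precision = TP / (TP + FP) x 100         (one-vs-rest per class)
    recall    = TP / (TP + FN) x 100
    F-measure = 2 x precision x recall / (precision + recall)

Cross-validation rotates the validation block through six balanced
folds; the budget sweep retrains at shrinking labeled-data budgets, the
noise sweep varies the consistency-noise amplitude, and condition
stratification splits validation results by acquisition regime
(NST vs labor). `compare_methods` runs a paired t-test on matched
per-segment softmax scores from two training schemes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from dusbeat.segmentation import CATEGORIES
from dusbeat.dataset_builder import (
    DatasetSpec,
    FoldSplit,
    SegmentCorpus,
    make_budget_subsets,
    make_folds,
)
from dusbeat.ssl_model import (
    Conv1dNet,
    ModelConfig,
    TrainConfig,
    build_model,
    predict,
    train,
)


@dataclass
class ConfusionMatrix:
    """4x4 counts; rows true, columns predicted, canonical order."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(CATEGORIES)
        if self.counts.shape != (k, k):
            raise ValueError(f"confusion matrix must be {k}x{k}")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, class_index: int) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) for one class against the rest."""
        tp = int(self.counts[class_index, class_index])
        fp = int(self.counts[:, class_index].sum() - tp)
        fn = int(self.counts[class_index, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, tn, fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


@dataclass
class MetricsReport:
    accuracy: float
    per_class: pd.DataFrame  # index = category, columns = precision/recall/f_measure
    fold_index: int | str = "pooled"
    condition: str = "all"


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must have equal length")
    k = len(CATEGORIES)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Correct fraction of all evaluated segments, as a percentage."""
    if cm.total == 0:
        warnings.warn("empty confusion matrix; accuracy reported as 0")
        return 0.0
    return float(np.trace(cm.counts) / cm.total * 100.0)


def precision_recall_f(cm: ConfusionMatrix, class_index: int) -> tuple[float, float, float]:
    """One-vs-rest precision, recall and F-measure (percent).

    A degenerate denominator (no predicted or no true positives) yields
    0 with a warning rather than NaN, so sweep tables stay total.
    """
    tp, fp, _tn, fn = cm.one_vs_rest(class_index)
    if tp + fp == 0:
        warnings.warn(f"class {CATEGORIES[class_index]}: no predicted positives")
        precision = 0.0
    else:
        precision = tp / (tp + fp) * 100.0
    if tp + fn == 0:
        warnings.warn(f"class {CATEGORIES[class_index]}: no true positives")
        recall = 0.0
    else:
        recall = tp / (tp + fn) * 100.0
    if precision + recall == 0:
        f = 0.0
    else:
        f = 2.0 * precision * recall / (precision + recall)
    return float(precision), float(recall), float(f)


def metrics_report(
    cm: ConfusionMatrix, fold_index: int | str = "pooled", condition: str = "all"
) -> MetricsReport:
    rows = {}
    for i, cat in enumerate(CATEGORIES):
        p, r, f = precision_recall_f(cm, i)
        rows[cat] = {"precision": p, "recall": r, "f_measure": f}
    return MetricsReport(
        accuracy=accuracy(cm),
        per_class=pd.DataFrame(rows).T,
        fold_index=fold_index,
        condition=condition,
    )


def round_display(value: float) -> float:
    """Round half away from zero to one decimal (e.g. 84.25 -> 84.3)."""
    return float(np.floor(np.abs(value) * 10.0 + 0.5) / 10.0 * np.sign(value))


# ---------------------------------------------------------------------------
# cross-validation and sweeps

@dataclass
class FoldResult:
    fold_index: int
    cm: ConfusionMatrix
    report: MetricsReport
    true_class_prob: np.ndarray  # per-segment softmax prob of the true class
    pred_labels: np.ndarray
    validation_ids: np.ndarray
    conditions: np.ndarray


@dataclass
class CvResult:
    mode: str
    budget: int
    folds: list[FoldResult]
    pooled: ConfusionMatrix
    pooled_report: MetricsReport

    @property
    def fold_accuracies(self) -> np.ndarray:
        return np.array([accuracy(f.cm) for f in self.folds])

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def accuracy_range(self) -> float:
        """max - min of per-fold accuracies (spread across folds)."""
        a = self.fold_accuracies
        return float(a.max() - a.min())


def _train_one_fold(
    corpus: SegmentCorpus,
    split: FoldSplit,
    budget_ids: np.ndarray,
    mode: str,
    train_config: TrainConfig,
    model_config: ModelConfig,
    model_seed: int,
) -> FoldResult:
    model = build_model(model_config, seed=model_seed)
    X_lab, y_lab = corpus.X(budget_ids), corpus.y(budget_ids)
    X_unl = corpus.X(split.unlabeled_ids) if mode == "semi" else None
    train(model, X_lab, y_lab, X_unl, mode, train_config)
    X_val, y_val = corpus.X(split.validation_ids), corpus.y(split.validation_ids)
    pred = predict(model, X_val)
    cm = confusion_matrix(y_val, pred.labels)
    conditions = corpus.subset(split.validation_ids).index["condition"].to_numpy()
    return FoldResult(
        fold_index=split.fold_index,
        cm=cm,
        report=metrics_report(cm, fold_index=split.fold_index),
        true_class_prob=pred.probabilities[np.arange(len(y_val)), y_val],
        pred_labels=pred.labels,
        validation_ids=split.validation_ids,
        conditions=conditions,
    )


def cross_validate(
    corpus: SegmentCorpus,
    splits: list[FoldSplit],
    mode: str,
    budget: int,
    train_config: TrainConfig,
    model_config: ModelConfig | None = None,
    seed: int = 0,
) -> CvResult:
    """k-fold training/evaluation at one labeled-data budget."""
    model_config = model_config or ModelConfig()
    folds = []
    for split in splits:
        train_df = corpus.index[corpus.index["segment_id"].isin(split.train_ids)]
        subsets = make_budget_subsets(train_df, (budget,), seed=(seed * 131 + split.fold_index) % 2**31)
        fold_tc = TrainConfig(**{**train_config.__dict__,
                                 "seed": (train_config.seed * 1009 + split.fold_index) % 2**31})
        folds.append(
            _train_one_fold(
                corpus, split, subsets[budget], mode, fold_tc,
                model_config, model_seed=(seed * 7919 + split.fold_index) % 2**31,
            )
        )
    pooled = ConfusionMatrix(np.sum([f.cm.counts for f in folds], axis=0))
    return CvResult(
        mode=mode, budget=budget, folds=folds,
        pooled=pooled, pooled_report=metrics_report(pooled),
    )


def budget_sweep(
    corpus: SegmentCorpus,
    splits: list[FoldSplit],
    budgets: tuple[int, ...],
    modes: tuple[str, ...],
    train_config: TrainConfig,
    model_config: ModelConfig | None = None,
    seeds: tuple[int, ...] = (0,),
    epochs_by_budget: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Accuracy vs labeled-data budget for each training mode.

    Returns one row per (budget, mode, seed) with the mean fold
    accuracy and the per-fold accuracy range. ``epochs_by_budget``
    optionally rebalances the schedule so small budgets still receive
    a useful number of optimizer steps.
    """
    rows = []
    for seed in seeds:
        for budget in budgets:
            for mode in modes:
                overrides = {"seed": seed}
                if epochs_by_budget is not None:
                    overrides["epochs"] = epochs_by_budget[budget]
                tc = TrainConfig(**{**train_config.__dict__, **overrides})
                res = cross_validate(
                    corpus, splits, mode, budget, tc, model_config, seed=seed
                )
                rows.append(
                    dict(
                        budget=budget, mode=mode, seed=seed,
                        mean_accuracy=res.mean_accuracy,
                        accuracy_range=res.accuracy_range,
                    )
                )
    return pd.DataFrame(rows)


def noise_sweep(
    corpus: SegmentCorpus,
    splits: list[FoldSplit],
    amplitudes: tuple[float, ...] = (0.01, 0.03, 0.05, 0.07, 0.1, 0.3, 0.5),
    budget: int = 8000,
    train_config: TrainConfig | None = None,
    model_config: ModelConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Semi-supervised accuracy vs consistency-noise amplitude.

    Amplitude 0 degenerates to the supervised baseline (the KL term
    vanishes identically). The best amplitude is the max-mean-accuracy
    row of the returned table.
    """
    train_config = train_config or TrainConfig()
    rows = []
    for amp in amplitudes:
        tc = TrainConfig(**{**train_config.__dict__, "noise_amplitude": amp, "seed": seed})
        mode = "semi" if amp > 0 else "supervised"
        res = cross_validate(corpus, splits, mode, budget, tc, model_config, seed=seed)
        rows.append(dict(noise_amplitude=amp, mean_accuracy=res.mean_accuracy,
                         accuracy_range=res.accuracy_range))
    return pd.DataFrame(rows)


def stratify_by_condition(result: CvResult, corpus: SegmentCorpus) -> dict[str, MetricsReport]:
    """Per-acquisition-condition metrics over the combined folds."""
    out = {}
    for condition in ("nst", "labor"):
        counts = np.zeros((len(CATEGORIES), len(CATEGORIES)), dtype=np.int64)
        for f in result.folds:
            keep = f.conditions == condition
            if not keep.any():
                continue
            y_val = corpus.y(f.validation_ids)
            np.add.at(counts, (y_val[keep], f.pred_labels[keep]), 1)
        out[condition] = metrics_report(ConfusionMatrix(counts), condition=condition)
    return out


def compare_methods(
    semi_scores: np.ndarray, supervised_scores: np.ndarray
) -> dict[str, float]:
    """Paired t-test on matched per-segment true-class probabilities.

    Scores must be aligned segment-for-segment. Identical score sets
    return statistic 0 and p-value 1 (no evidence of a difference).
    """
    semi_scores = np.asarray(semi_scores, dtype=np.float64)
    supervised_scores = np.asarray(supervised_scores, dtype=np.float64)
    if semi_scores.shape != supervised_scores.shape:
        raise ValueError("score arrays must be aligned")
    diff = semi_scores - supervised_scores
    if np.allclose(diff, 0.0):
        return {"statistic": 0.0, "p_value": 1.0, "mean_difference": 0.0}
    t = stats.ttest_rel(semi_scores, supervised_scores)
    return {
        "statistic": float(t.statistic),
        "p_value": float(t.pvalue),
        "mean_difference": float(diff.mean()),
    }
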