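"""Recording-wise leave-one-out cross-validation and performance metrics.

Metrics follow the standard confusion-matrix formulas with stressed as the
positive class:

    accuracy  = (TP + TN) / (TP + TN + FP + FN) * 100%
    precision = TP / (TP + FP) * 100%
    recall    = TP / (TP + FN) * 100%
    F1        = 2 * precision * recall / (precision + recall)

Accuracy/precision/recall are reported as percentages, F1 and AUC on [0, 1].
A zero denominator yields NaN (undefined), never silently 0.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import ConfigError, DataError
from .model import ArchConfig, SampleTriple, TrainConfig, build_model
from .preprocess import undersample


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary counts with stressed (label 1) as the positive class."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise DataError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(tp=int(((y_true == 1) & (y_pred == 1)).sum()),
                   tn=int(((y_true == 0) & (y_pred == 0)).sum()),
                   fp=int(((y_true == 0) & (y_pred == 1)).sum()),
                   fn=int(((y_true == 1) & (y_pred == 0)).sum()))


def _ratio_pct(num: int, den: int) -> float:
    return num / den * 100.0 if den > 0 else math.nan


def metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy/precision/recall in percent, F1 on [0, 1]; NaN when undefined."""
    if cm.total == 0:
        raise DataError("cannot compute metrics of an empty confusion matrix")
    precision = _ratio_pct(cm.tp, cm.tp + cm.fp)
    recall = _ratio_pct(cm.tp, cm.tp + cm.fn)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = math.nan
    else:
        f1 = 2 * precision * recall / (precision + recall) / 100.0
    return {"accuracy": _ratio_pct(cm.tp + cm.tn, cm.total),
            "precision": precision, "recall": recall, "f1": f1}


def class_metrics(cm: ConfusionMatrix) -> dict[str, dict[str, float]]:
    """Per-class metrics: the relaxed row swaps the class roles (TP<->TN, FP<->FN)."""
    swapped = ConfusionMatrix(tp=cm.tn, tn=cm.tp, fp=cm.fn, fn=cm.fp)
    return {"stressed": metrics(cm), "relaxed": metrics(swapped)}


def auc(scores, labels) -> float:
    """Rank-based AUC: P(random stressed score > random relaxed score), ties 1/2."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise DataError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores)))


def loro_split(samples: list[SampleTriple]) -> list[tuple[list[str], str]]:
    """Leave-one-recording-out folds: one (train ids, test id) pair per recording."""
    ids = sorted({s.recording_id for s in samples})
    if len(ids) < 2:
        raise ConfigError(f"leave-one-recording-out needs >= 2 recordings, got {len(ids)}")
    return [([i for i in ids if i != test_id], test_id) for test_id in ids]


@dataclass
class FoldResult:
    recording_id: str
    cm: ConfusionMatrix
    metrics: dict[str, float]
    auc: float
    n_train: int
    train_recording_ids: tuple[str, ...] = ()
    #: exhaustive identities of the training samples, for leakage audits
    train_sample_ids: tuple[tuple[str, float], ...] = ()


@dataclass
class EvalReport:
    """Per-fold results plus summed confusion matrix and overall metrics."""

    per_fold: list[FoldResult]
    aggregated: ConfusionMatrix
    overall: dict

    def to_dict(self) -> dict:
        return {
            "per_fold": [{"recording_id": f.recording_id,
                          "confusion": vars(f.cm), "metrics": f.metrics,
                          "auc": f.auc, "n_train": f.n_train,
                          "train_recordings": list(f.train_recording_ids)}
                         for f in self.per_fold],
            "aggregated": vars(self.aggregated),
            "overall": self.overall,
        }


def run_cv(samples: list[SampleTriple], arch: ArchConfig, train_cfg: TrainConfig,
           balance_mode: str = "fold") -> EvalReport:
    """Leave-one-recording-out evaluation with from-scratch training per fold.

    ``balance_mode='fold'`` undersamples inside each training fold only
    (leakage-safe); ``'global'`` undersamples the whole pool once before
    splitting, replicating a pre-CV balancing protocol.  Each fold trains a
    fresh model with a fold-specific seed derived from ``train_cfg.seed``.
    """
    if balance_mode not in ("fold", "global"):
        raise ConfigError(f"unknown balance_mode {balance_mode!r}")
    base_seed = train_cfg.seed
    if balance_mode == "global":
        samples = undersample(samples, seed=base_seed)
    folds = loro_split(samples)
    per_fold: list[FoldResult] = []
    agg = ConfusionMatrix()
    all_scores: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    for k, (train_ids, test_id) in enumerate(folds):
        train = [s for s in samples if s.recording_id != test_id]
        test = [s for s in samples if s.recording_id == test_id]
        if balance_mode == "fold":
            train = undersample(train, seed=base_seed + 10_000 + k)
        model = build_model(arch, seed=base_seed + k)
        fold_cfg = dataclasses.replace(train_cfg, seed=base_seed + k)
        if fold_cfg.epochs > 0:
            model.train(train, fold_cfg)
        probs, preds = model.predict(test)
        y = np.array([s.label for s in test])
        cm = ConfusionMatrix.from_labels(y, preds)
        fold_auc = auc(probs, y) if len(set(y.tolist())) == 2 else math.nan
        per_fold.append(FoldResult(test_id, cm, metrics(cm), fold_auc, len(train),
                                   tuple(sorted({s.recording_id for s in train})),
                                   tuple((s.recording_id, float(s.start_s))
                                         for s in train)))
        agg = agg + cm
        all_scores.append(probs)
        all_labels.append(y)
    defined = [f.auc for f in per_fold if not math.isnan(f.auc)]
    per_class = class_metrics(agg)
    overall = {
        "accuracy": metrics(agg)["accuracy"],
        "per_class": per_class,
        "macro_precision": float(np.mean([per_class[c]["precision"] for c in per_class])),
        "macro_recall": float(np.mean([per_class[c]["recall"] for c in per_class])),
        "macro_f1": float(np.mean([per_class[c]["f1"] for c in per_class])),
        "auc_mean": float(np.mean(defined)) if defined else math.nan,
        "auc_pooled": auc(np.concatenate(all_scores), np.concatenate(all_labels)),
        "n_samples": agg.total,
    }
    return EvalReport(per_fold, agg, overall)


def grid_search(samples: list[SampleTriple], grid: dict[str, list], arch: ArchConfig,
                balance_mode: str = "fold"):
    """Exhaustive hyperparameter search scored by LORO validation accuracy.

    ``grid`` maps ``learning_rate`` / ``batch_size`` / ``epochs`` to candidate
    lists.  Ties break to the first combination in lexicographic grid order;
    combinations whose configuration is invalid score NaN and are never chosen.
    """
    keys = ("learning_rate", "batch_size", "epochs")
    axes = [sorted(grid.get(k, [TrainConfig().__getattribute__(k)])) for k in keys]
    combos = list(itertools.product(*axes))
    if not combos:
        raise ConfigError("empty hyperparameter grid")
    table = []
    best_cfg, best_acc = None, -math.inf
    for lr, bs, ep in combos:
        row = {"learning_rate": lr, "batch_size": bs, "epochs": ep}
        try:
            cfg = TrainConfig(lr, bs, ep, seed=0)
            report = run_cv(samples, arch, cfg, balance_mode)
            row["accuracy"] = report.overall["accuracy"]
        except ConfigError:
            cfg, row["accuracy"] = None, math.nan
        table.append(row)
        if cfg is not None and row["accuracy"] > best_acc:
            best_cfg, best_acc = cfg, row["accuracy"]
    if best_cfg is None:
        raise ConfigError("no valid combination in the grid")
    return best_cfg, table
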