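"""Confusion-matrix metrics: per-class precision/recall/F1, macro and
support-weighted aggregates, dataset split summaries, and a paired
t-test for model comparison.

Reports keep full precision internally; 4-decimal presentation values
are produced only at serialization time (round-half-even).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


class VocabularyError(ValueError):
    """Label outside the declared class vocabulary."""


@dataclass
class ConfusionMatrix:
    """C x C count matrix, rows = actual class, columns = predicted."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        c = len(self.class_names)
        if self.counts.shape != (c, c):
            raise ValueError("counts must be C x C")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.counts, index=list(self.class_names), columns=list(self.class_names)
        ).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(counts=df.to_numpy(), class_names=tuple(df.columns))


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int
    degenerate: bool = False


@dataclass
class MetricsReport:
    class_names: tuple[str, ...]
    per_class: list[ClassMetrics]
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    total: int

    def presentation(self, ndigits: int = 4) -> dict:
        """Rounded view matching printed-report conventions."""
        r = lambda x: round(float(x), ndigits)
        return {
            "per_class": {
                name: {
                    "precision": r(m.precision),
                    "recall": r(m.recall),
                    "f1": r(m.f1),
                    "support": m.support,
                }
                for name, m in zip(self.class_names, self.per_class)
            },
            "accuracy": r(self.accuracy),
            "macro": {
                "precision": r(self.macro_precision),
                "recall": r(self.macro_recall),
                "f1": r(self.macro_f1),
            },
            "weighted": {
                "precision": r(self.weighted_precision),
                "recall": r(self.weighted_recall),
                "f1": r(self.weighted_f1),
            },
            "total": self.total,
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "full_precision": {
                "per_class": {
                    name: {
                        "precision": m.precision,
                        "recall": m.recall,
                        "f1": m.f1,
                        "support": m.support,
                    }
                    for name, m in zip(self.class_names, self.per_class)
                },
                "accuracy": self.accuracy,
                "macro": [self.macro_precision, self.macro_recall, self.macro_f1],
                "weighted": [self.weighted_precision, self.weighted_recall, self.weighted_f1],
            },
            "presentation": self.presentation(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def confusion_matrix(y_true, y_pred, class_names) -> ConfusionMatrix:
    """Count matrix with counts[a][p] = #{i : true=a, pred=p}."""
    names = tuple(class_names)
    index = {n: i for i, n in enumerate(names)}
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    counts = np.zeros((len(names), len(names)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        ti = index.get(t, t if isinstance(t, (int, np.integer)) else None)
        pi = index.get(p, p if isinstance(p, (int, np.integer)) else None)
        if ti is None or pi is None or not (0 <= ti < len(names) and 0 <= pi < len(names)):
            raise VocabularyError(f"label outside vocabulary: {(t, p)}")
        counts[ti, pi] += 1
    return ConfusionMatrix(counts=counts, class_names=names)


def class_metrics(cm: ConfusionMatrix, class_index: int) -> ClassMetrics:
    """One-vs-rest precision, recall and F1 for a single class.

    Zero-denominator metrics are defined as 0 and flagged degenerate.
    """
    c = cm.counts
    tp = int(c[class_index, class_index])
    fp = int(c[:, class_index].sum() - tp)
    fn = int(c[class_index, :].sum() - tp)
    degenerate = False
    if tp + fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1, degenerate = 0.0, True
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return ClassMetrics(
        precision=precision,
        recall=recall,
        f1=f1,
        support=tp + fn,
        degenerate=degenerate,
    )


def aggregate_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Full report: accuracy plus macro and support-weighted aggregates."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    per_class = [class_metrics(cm, i) for i in range(len(cm.class_names))]
    sup = cm.supports.astype(np.float64)
    w = sup / sup.sum()
    prec = np.array([m.precision for m in per_class])
    rec = np.array([m.recall for m in per_class])
    f1 = np.array([m.f1 for m in per_class])
    return MetricsReport(
        class_names=cm.class_names,
        per_class=per_class,
        accuracy=float(np.trace(cm.counts) / cm.total),
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()),
        weighted_precision=float(prec @ w),
        weighted_recall=float(rec @ w),
        weighted_f1=float(f1 @ w),
        total=cm.total,
    )


def dataset_summary(
    labels: np.ndarray,
    split_assignment: np.ndarray,
    class_names: tuple[str, ...],
) -> pd.DataFrame:
    """Per-class train/test counts, totals and split percentages (1 d.p.)."""
    labels = np.asarray(labels)
    split = np.asarray(split_assignment)
    rows = []
    n_train = int((split == "train").sum())
    n_test = int((split == "test").sum())
    for ci, name in enumerate(class_names):
        tr = int(((labels == ci) & (split == "train")).sum())
        te = int(((labels == ci) & (split == "test")).sum())
        rows.append(
            {
                "class": name,
                "train": tr,
                "test": te,
                "total": tr + te,
                "train_pct": round(100.0 * tr / n_train, 1) if n_train else 0.0,
                "test_pct": round(100.0 * te / n_test, 1) if n_test else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    total_row = {
        "class": "total",
        "train": df["train"].sum(),
        "test": df["test"].sum(),
        "total": df["total"].sum(),
        "train_pct": 100.0,
        "test_pct": 100.0,
    }
    return pd.concat([df, pd.DataFrame([total_row])], ignore_index=True)


def summary_from_counts(
    train_counts: dict[str, int], test_counts: dict[str, int]
) -> pd.DataFrame:
    """Split summary straight from per-class count dictionaries."""
    names = tuple(train_counts)
    labels, split = [], []
    for ci, name in enumerate(names):
        labels += [ci] * train_counts[name] + [ci] * test_counts[name]
        split += ["train"] * train_counts[name] + ["test"] * test_counts[name]
    return dataset_summary(np.array(labels), np.array(split), names)


@dataclass
class PairedComparison:
    mean_diff: float
    t_statistic: float
    p_value: float
    degenerate: bool = False


def paired_comparison(metrics_a, metrics_b) -> PairedComparison:
    """Two-sided paired t-test on per-class metric values.

    Zero-variance differences are flagged degenerate; all-zero
    differences report t = 0, p = 1.
    """
    a = np.asarray(metrics_a, dtype=np.float64)
    b = np.asarray(metrics_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    d = a - b
    n = len(d)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedComparison(0.0, 0.0, 1.0, degenerate=True)
        return PairedComparison(mean, np.nan, np.nan, degenerate=True)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedComparison(mean, float(t), float(p))
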