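"""Confusion matrices and the study's metrics, with repeat aggregation.

The seizure experiment reports accuracy, sensitivity and specificity of the
binary interictal-vs-preictal decision (positive class = preictal, the
seizure-warning event). The sleep experiment reports accuracy, Cohen's kappa
κ = (p_o − p_e)/(1 − p_e) and the macro-averaged F1 over the five stages.
Repeats aggregate as mean ± sample standard deviation.

Degenerate denominators (an empty margin, chance agreement p_e = 1) yield an
explicit ``None`` ("undefined") rather than a silent zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Marker for metrics with a zero denominator.
UNDEFINED = None


def confusion_matrix(
    true_labels: np.ndarray, predicted_labels: np.ndarray, label_order: tuple[str, ...]
) -> np.ndarray:
    """K×K count matrix; entry (i, j) = # samples of true class i predicted j."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label arrays differ in length")
    lut = {s: i for i, s in enumerate(label_order)}
    unknown = sorted((set(true_labels.tolist()) | set(predicted_labels.tolist())) - set(label_order))
    if unknown:
        raise ValueError(f"label(s) {unknown} not in label order {label_order}")
    k = len(label_order)
    ti = np.array([lut[s] for s in true_labels.tolist()], dtype=int)
    pi = np.array([lut[s] for s in predicted_labels.tolist()], dtype=int)
    return np.bincount(ti * k + pi, minlength=k * k).reshape(k, k)


def accuracy(confusion: np.ndarray) -> float:
    total = confusion.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(confusion) / total)


def binary_metrics(confusion: np.ndarray, positive_index: int = 1) -> dict:
    """Accuracy, sensitivity TP/(TP+FN) and specificity TN/(TN+FP) for a 2×2
    matrix whose rows are true classes; ``positive_index`` selects which
    row/column is the positive (event) class."""
    confusion = np.asarray(confusion)
    if confusion.shape != (2, 2):
        raise ValueError(f"binary metrics need a 2x2 matrix, got {confusion.shape}")
    p = positive_index
    n = 1 - p
    tp, fn = confusion[p, p], confusion[p, n]
    tn, fp = confusion[n, n], confusion[n, p]
    return {
        "accuracy": accuracy(confusion),
        "sensitivity": float(tp / (tp + fn)) if tp + fn > 0 else UNDEFINED,
        "specificity": float(tn / (tn + fp)) if tn + fp > 0 else UNDEFINED,
    }


def cohen_kappa(confusion: np.ndarray) -> float | None:
    """Chance-corrected agreement (p_o − p_e)/(1 − p_e); None when p_e = 1."""
    confusion = np.asarray(confusion, dtype=np.float64)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = confusion.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(confusion) / total
    p_e = float((confusion.sum(axis=1) * confusion.sum(axis=0)).sum()) / total**2
    if abs(1 - p_e) < 1e-12:
        return UNDEFINED
    return float((p_o - p_e) / (1 - p_e))


def f1_macro(confusion: np.ndarray) -> float:
    """Unweighted mean per-class F1 = 2PR/(P+R); zero-support classes are
    excluded from the mean (a supported class never predicted scores 0)."""
    confusion = np.asarray(confusion, dtype=np.float64)
    scores = []
    for i in range(confusion.shape[0]):
        support = confusion[i].sum()
        if support == 0:
            continue
        tp = confusion[i, i]
        predicted = confusion[:, i].sum()
        precision = tp / predicted if predicted > 0 else 0.0
        recall = tp / support
        f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
        scores.append(f1)
    if not scores:
        raise ValueError("no class has any support")
    return float(np.mean(scores))


@dataclass
class EvalReport:
    """Confusion matrix with derived metrics for one evaluation run."""

    confusion: np.ndarray
    label_order: tuple[str, ...]
    repeat_index: int = 0
    positive_label: str | None = None
    metrics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=int)
        if (self.confusion < 0).any():
            raise ValueError("confusion counts must be non-negative")
        k = self.confusion.shape[0]
        if self.confusion.shape != (k, k) or k != len(self.label_order):
            raise ValueError("confusion shape does not match label order")
        m = {"accuracy": accuracy(self.confusion), "kappa": cohen_kappa(self.confusion),
             "f1_macro": f1_macro(self.confusion)}
        if k == 2:
            pos = self.positive_label or self.label_order[1]
            m.update(binary_metrics(self.confusion, positive_index=self.label_order.index(pos)))
        self.metrics = m

    @property
    def n_classes(self) -> int:
        return len(self.label_order)

    def to_dict(self) -> dict:
        return {
            "label_order": list(self.label_order),
            "confusion": self.confusion.tolist(),
            "repeat_index": self.repeat_index,
            "metrics": self.metrics,
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def from_predictions(
    true_labels: np.ndarray,
    predicted_labels: np.ndarray,
    label_order: tuple[str, ...],
    repeat_index: int = 0,
    positive_label: str | None = None,
) -> EvalReport:
    return EvalReport(
        confusion=confusion_matrix(true_labels, predicted_labels, label_order),
        label_order=tuple(label_order),
        repeat_index=repeat_index,
        positive_label=positive_label,
    )


def aggregate(reports: list[EvalReport]) -> dict:
    """Mean ± sample std (n−1) of every defined metric across repeats.

    A single report yields std 0 with ``single_report`` flagged. Mixed class
    counts are an error.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    ks = {r.n_classes for r in reports}
    if len(ks) > 1:
        raise ValueError(f"reports have mixed class counts: {sorted(ks)}")
    out: dict[str, dict] = {}
    for key in reports[0].metrics:
        values = [r.metrics[key] for r in reports if r.metrics.get(key) is not UNDEFINED]
        if not values:
            out[key] = {"mean": UNDEFINED, "std": UNDEFINED, "n": 0}
            continue
        mean = float(np.mean(values))
        std = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        out[key] = {"mean": mean, "std": std, "n": len(values), "single_report": len(values) == 1}
    return out


def format_mean_std(mean: float, std: float, percent: bool = True) -> str:
    """Render a metric the way result tables print it, e.g. ``92.67 (±0.45%)``."""
    if percent:
        return f"{100 * mean:.2f} (±{100 * std:.2f}%)"
    return f"{mean:.3f} (±{std:.3f})"


def plot_confusion(report: EvalReport, path: str | Path) -> None:
    """Render the confusion matrix to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = report.n_classes
    fig, ax = plt.subplots(figsize=(1.2 * k + 2, 1.2 * k + 1.5))
    ax.imshow(report.confusion, cmap="Blues")
    ax.set_xticks(range(k), report.label_order)
    ax.set_yticks(range(k), report.label_order)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(k):
        for j in range(k):
            ax.text(j, i, str(report.confusion[i, j]), ha="center", va="center", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
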