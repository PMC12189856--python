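"""Classification metrics and the channel-wise raw-EEG statistical screen.

``evaluate`` reports a 2x2 confusion matrix with accuracy and macro-averaged
precision/recall/F1 (macro is the default because frame-level class counts
are typically imbalanced; micro and weighted averaging are available).

``channel_screen`` reproduces the classical univariate screen on raw EEG:
per subject and channel the mean signal value is taken as the statistical
unit, and the two groups are compared per channel with a two-sample t-test
and a one-way ANOVA. With two groups and equal-variance t-tests the two are
the same test (t^2 = F), which the table makes directly checkable. No
multiple-testing correction is applied by default; Benjamini–Hochberg
adjusted q-values can be added per test family.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .synthetic import Recording

__all__ = ["EvaluationReport", "channel_screen", "evaluate"]


@dataclass(frozen=True)
class EvaluationReport:
    confusion_matrix: np.ndarray  # rows: true class, cols: predicted
    accuracy: float
    precision: float
    recall: float
    f1: float
    support: tuple[int, ...]
    class_names: tuple[str, ...]
    average: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.confusion_matrix,
            index=[f"true_{c}" for c in self.class_names],
            columns=[f"pred_{c}" for c in self.class_names],
        )

    def summary(self) -> str:
        lines = [self.to_frame().to_string(), ""]
        for name in ("accuracy", "precision", "recall", "f1"):
            lines.append(f"{name:>9}: {getattr(self, name):.4f} ({self.average})")
        return "\n".join(lines)

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(
            {
                "metric": ["accuracy", "precision", "recall", "f1"],
                "value": [self.accuracy, self.precision, self.recall, self.f1],
                "average": self.average,
            }
        ).to_csv(path, index=False)
        return path


def evaluate(
    predictions: Sequence[int] | np.ndarray,
    labels: Sequence[int] | np.ndarray,
    class_names: tuple[str, str] = ("HC", "PD"),
    average: str = "macro",
) -> EvaluationReport:
    """Confusion matrix and accuracy/precision/recall/F1 for two classes."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError(
            f"predictions ({predictions.shape}) and labels ({labels.shape}) differ in length"
        )
    n_classes = len(class_names)
    cm = confusion_matrix(labels, predictions, labels=np.arange(n_classes))
    precision, recall, f1, support = precision_recall_fscore_support(
        labels,
        predictions,
        labels=np.arange(n_classes),
        average=average,
        zero_division=0,
    )
    return EvaluationReport(
        confusion_matrix=cm,
        accuracy=float((predictions == labels).mean()),
        precision=float(precision),
        recall=float(recall),
        f1=float(f1),
        support=tuple(int(np.sum(labels == k)) for k in range(n_classes)),
        class_names=class_names,
        average=average,
    )


def channel_screen(
    recordings: Sequence[Recording],
    equal_var: bool = True,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-channel two-group comparison of subject-level mean amplitudes.

    Returns a table with one row per channel: t statistic, t-test p-value,
    F statistic, ANOVA p-value (and BH-adjusted q-values when ``fdr``).
    ``equal_var=True`` (Student's t) keeps the two-group identity t^2 = F
    exact; set ``equal_var=False`` for Welch's t.
    """
    groups: dict[str, list[np.ndarray]] = {}
    for rec in recordings:
        groups.setdefault(rec.label, []).append(rec.signal.mean(axis=0))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {sorted(groups)}")
    (la, a), (lb, b) = sorted(groups.items())
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    a = np.vstack(a)  # subjects x channels
    b = np.vstack(b)
    t_stat, t_p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    f_stat, f_p = stats.f_oneway(a, b, axis=0)
    table = pd.DataFrame(
        {
            "channel": np.arange(a.shape[1]) + 1,
            "t_stat": t_stat,
            "t_test_p": t_p,
            "anova_F": f_stat,
            "anova_p": f_p,
        }
    )
    if fdr:
        table["t_test_q"] = _benjamini_hochberg(table["t_test_p"].to_numpy())
        table["anova_q"] = _benjamini_hochberg(table["anova_p"].to_numpy())
    return table


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q
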