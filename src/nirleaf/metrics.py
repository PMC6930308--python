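"""Per-class classification metrics and report rendering.

All metrics are one-vs-rest, derived from the multiclass confusion matrix:
for class *c*, TP is the diagonal entry, FN the rest of its row, FP the rest
of its column and TN everything else.  Sensitivity = TP/(TP+FN), specificity
= TN/(TN+FP), accuracy = (TP+TN)/total.  Undefined metrics (empty
denominator) surface as NaN, never as silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError


@dataclass
class ConfusionMatrix:
    """Counts with rows = true class, columns = assigned class."""

    counts: np.ndarray
    class_order: tuple

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def micro_accuracy(self) -> float:
        """Overall fraction of correctly assigned samples (trace/total)."""
        return float(np.trace(self.counts)) / self.total


def confusion(true_labels, assigned, class_order) -> ConfusionMatrix:
    """Multiclass confusion matrix over ``class_order``."""
    true_labels = np.asarray(true_labels)
    assigned = np.asarray(assigned)
    if true_labels.shape != assigned.shape:
        raise ValidationError("true and assigned label lengths differ")
    class_order = tuple(class_order)
    pos = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, a in zip(true_labels, assigned):
        if t not in pos or a not in pos:
            raise ValidationError(f"label {t if t not in pos else a!r} "
                                  "not in class_order")
        counts[pos[t], pos[a]] += 1
    return ConfusionMatrix(counts=counts, class_order=class_order)


def per_class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """One-vs-rest sensitivity, specificity, accuracy per class."""
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    rows = []
    c = cm.counts
    total = cm.total
    for i, cls in enumerate(cm.class_order):
        tp = c[i, i]
        fn = c[i].sum() - tp
        fp = c[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        rows.append({
            "class": cls,
            "sensitivity": sens,
            "specificity": spec,
            "accuracy": (tp + tn) / total,
        })
    return pd.DataFrame(rows)


def accuracy_from_rates(sensitivity: float, specificity: float,
                        n_pos: int, n_neg: int) -> float:
    """Per-class accuracy (%) reconstructed from printed one-vs-rest rates.

    Published sensitivity/specificity are rounded versions of integer count
    ratios, so the counts are first reconstructed as the nearest integers
    (TP = round(sens * n_pos), TN = round(spec * n_neg)); the returned
    accuracy then reproduces the printed percentage exactly.
    """
    if n_pos <= 0 or n_neg < 0:
        raise ValidationError("class sizes must be positive")
    tp = round(sensitivity * n_pos)
    tn = round(specificity * n_neg)
    return 100.0 * (tp + tn) / (n_pos + n_neg)


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ("model", "class", "evaluation", "sensitivity",
                  "specificity", "accuracy_percent", "n_lv", "n_variables")


def build_report(
    per_model: dict[str, dict[str, pd.DataFrame]],
    n_lv: dict[str, int],
    n_variables: dict[str, int],
) -> pd.DataFrame:
    """Assemble the combined report table.

    ``per_model`` maps model name ("full_spectrum"/"truncated") to a mapping
    of evaluation name ("cross_validation"/"test") to a per-class metrics
    frame from :func:`per_class_metrics`.
    """
    rows = []
    for model_name, evals in per_model.items():
        for eval_name, df in evals.items():
            for _, r in df.iterrows():
                rows.append({
                    "model": model_name,
                    "class": r["class"],
                    "evaluation": eval_name,
                    "sensitivity": r["sensitivity"],
                    "specificity": r["specificity"],
                    "accuracy_percent": 100.0 * r["accuracy"],
                    "n_lv": n_lv[model_name],
                    "n_variables": n_variables[model_name],
                })
    return pd.DataFrame(rows, columns=list(REPORT_COLUMNS))


def format_report(report: pd.DataFrame) -> str:
    """Aligned text table with rates to 3 decimals and accuracy to one
    decimal percent (e.g. ``96.7%``)."""
    lines = []
    header = (f"{'model':<14} {'class':<12} {'evaluation':<17} "
              f"{'sens':>6} {'spec':>6} {'accuracy':>9}")
    lines.append(header)
    lines.append("-" * len(header))
    for _, r in report.iterrows():
        sens = "  nan" if pd.isna(r["sensitivity"]) else f"{r['sensitivity']:.3f}"
        spec = "  nan" if pd.isna(r["specificity"]) else f"{r['specificity']:.3f}"
        lines.append(
            f"{r['model']:<14} {r['class']:<12} {r['evaluation']:<17} "
            f"{sens:>6} {spec:>6} {r['accuracy_percent']:>8.1f}%"
        )
    return "\n".join(lines)


def write_report(report: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    report.to_csv(path, index=False)
    return path
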