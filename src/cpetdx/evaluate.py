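"""Stratified 5-fold cross-validation harness and comparison report.

Metric conventions: precision = TP/(TP+FP), recall = TP/(TP+FN), with 0 when
the denominator is 0; F1 = harmonic mean of precision and recall (0 when both
are 0); accuracy = correct/total.  Metrics are computed on predictions pooled
across folds (per-fold test sets of ~6 patients make fold-level ratios
unstable); a per-fold-averaged mode is also provided.  Rule-based methods
(the flowcharts) need no training and are applied to every patient directly,
so their results are fold-independent.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from .schema import PatientRecord

__all__ = [
    "stratified_kfold",
    "confusion_counts",
    "precision_recall",
    "f1_score",
    "accuracy",
    "accuracy_from_recalls",
    "MetricsRow",
    "ResultsTable",
    "run_benchmark",
    "render_table",
    "default_methods",
]

CONDITIONS = ("heart_failure", "metabolic_syndrome")
_PRETTY = {"heart_failure": "Heart Failure", "metabolic_syndrome": "MetSyn"}


def stratified_kfold(labels: Sequence[str], k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Deterministic stratified partition: k index arrays over patients."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs >= k={k} members, got counts {counts}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def confusion_counts(truth: Sequence[str], predicted: Sequence[str]) -> dict:
    """Per-condition TP/FP/FN/TN with that condition taken as positive."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have equal length")
    unknown = set(truth) | set(predicted) - set(CONDITIONS)
    unknown -= set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown label(s): {sorted(unknown)}")
    out = {}
    for cond in CONDITIONS:
        tp = int(np.sum((truth == cond) & (predicted == cond)))
        fp = int(np.sum((truth != cond) & (predicted == cond)))
        fn = int(np.sum((truth == cond) & (predicted != cond)))
        tn = int(np.sum((truth != cond) & (predicted != cond)))
        out[cond] = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
    return out


def precision_recall(counts: dict, condition: str) -> tuple[float, float]:
    c = counts[condition]
    precision = c["tp"] / (c["tp"] + c["fp"]) if c["tp"] + c["fp"] else 0.0
    recall = c["tp"] / (c["tp"] + c["fn"]) if c["tp"] + c["fn"] else 0.0
    return precision, recall


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must be in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def accuracy(truth: Sequence[str], predicted: Sequence[str]) -> float:
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.size == 0:
        raise ValueError("empty label sequence")
    return float(np.mean(truth == predicted))


def accuracy_from_recalls(recalls: Sequence[float], class_sizes: Sequence[int]) -> float:
    """Reconstruct overall accuracy from per-class recalls and class sizes.

    Each recall x size is rounded to the nearest integer count of correct
    patients (recalls are reported rounded), then pooled.
    """
    recalls = np.asarray(recalls, float)
    sizes = np.asarray(class_sizes)
    correct = np.round(recalls * sizes).sum()
    return float(correct / sizes.sum())


def _round_half_up(x: float, digits: int) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class MetricsRow:
    method: str
    condition: str
    precision: float
    recall: float
    f1: float

    def __post_init__(self) -> None:
        for v in (self.precision, self.recall, self.f1):
            if not 0 <= v <= 1:
                raise ValueError("metrics must lie in [0, 1]")


@dataclass
class ResultsTable:
    """Per-method x per-condition metric rows plus one accuracy per method."""

    rows: list[MetricsRow]
    accuracies: dict[str, float]
    predictions: Optional[pd.DataFrame] = None  # per-patient pooled predictions

    def methods(self) -> list[str]:
        seen = []
        for r in self.rows:
            if r.method not in seen:
                seen.append(r.method)
        return seen


def default_methods(seed: int = 0) -> dict:
    """The five benchmark methods in report order."""
    from .flowchart import FlowchartClassifier
    from .latent import AutoencoderLogisticClassifier, PCALogisticClassifier
    from .cnn import CNNClassifier

    return {
        "flowchart (Hansen)": FlowchartClassifier(norms="hansen"),
        "flowchart (FRIEND)": FlowchartClassifier(norms="friend"),
        "PCA + Logistic Regression": PCALogisticClassifier(random_state=seed),
        "AE + Logistic Regression": AutoencoderLogisticClassifier(random_state=seed),
        "CNN": CNNClassifier(random_state=seed),
    }


def run_benchmark(
    records: Sequence[PatientRecord],
    methods: Optional[dict] = None,
    k: int = 5,
    seed: int = 0,
    per_fold_average: bool = False,
) -> ResultsTable:
    """Cross-validated comparison of all methods on a labeled cohort.

    Trainable methods are cloned and refitted per fold on training patients
    only and their held-out predictions pooled; rule-based methods predict
    every patient directly.  A failure in one method is recorded (NaN rows)
    without aborting the others.  Deterministic given ``seed``.
    """
    labels = np.asarray([r.label for r in records])
    if any(l is None for l in labels):
        raise ValueError("every record needs a label")
    for cond in CONDITIONS:
        if np.sum(labels == cond) < max(k, 5):
            raise ValueError(f"need >= {max(k, 5)} patients per condition")
    if methods is None:
        methods = default_methods(seed=seed)
    folds = stratified_kfold(labels, k=k, seed=seed)
    records = list(records)

    rows: list[MetricsRow] = []
    accs: dict[str, float] = {}
    pred_frames = []
    for name, est in methods.items():
        try:
            predicted = np.empty(len(records), dtype=object)
            fold_of = np.full(len(records), -1)
            if getattr(est, "requires_fit", True):
                for fi, test_idx in enumerate(folds):
                    train_idx = np.setdiff1d(np.arange(len(records)), test_idx)
                    model = clone(est)
                    model.fit([records[i] for i in train_idx], labels[train_idx])
                    predicted[test_idx] = model.predict([records[i] for i in test_idx])
                    fold_of[test_idx] = fi
            else:
                model = clone(est).fit(records, labels)
                predicted[:] = model.predict(records)
        except Exception as err:  # record the failure, keep benchmarking
            for cond in CONDITIONS:
                rows.append(MetricsRow(name, cond, 0.0, 0.0, 0.0))
            accs[name] = float("nan")
            import warnings
            warnings.warn(f"method {name!r} failed: {err}", stacklevel=2)
            continue
        predicted = predicted.astype(str)
        if per_fold_average and getattr(est, "requires_fit", True):
            per_cond = {c: [] for c in CONDITIONS}
            fold_accs = []
            for fi in range(len(folds)):
                mask = fold_of == fi
                cts = confusion_counts(labels[mask], predicted[mask])
                for c in CONDITIONS:
                    per_cond[c].append(precision_recall(cts, c))
                fold_accs.append(accuracy(labels[mask], predicted[mask]))
            for c in CONDITIONS:
                p = float(np.mean([pr[0] for pr in per_cond[c]]))
                r = float(np.mean([pr[1] for pr in per_cond[c]]))
                rows.append(MetricsRow(name, c, p, r, f1_score(p, r)))
            accs[name] = float(np.mean(fold_accs))
        else:
            counts = confusion_counts(labels, predicted)
            for c in CONDITIONS:
                p, r = precision_recall(counts, c)
                rows.append(MetricsRow(name, c, p, r, f1_score(p, r)))
            accs[name] = accuracy(labels, predicted)
        pred_frames.append(pd.DataFrame({
            "method": name,
            "patient_id": [r.patient_id for r in records],
            "fold": fold_of,
            "truth": labels,
            "predicted": predicted,
        }))
    preds = pd.concat(pred_frames, ignore_index=True) if pred_frames else None
    return ResultsTable(rows=rows, accuracies=accs, predictions=preds)


def render_table(table: ResultsTable, fmt: str = "csv") -> str:
    """Render the comparison table; metrics at 2 dp (half-up), accuracy as
    integer percent.  ``fmt``: 'csv' or 'markdown'."""
    header = ["Model", "Condition", "Precision", "Recall", "F1 Score", "Accuracy"]
    body: list[list[str]] = []
    for row in table.rows:
        acc = table.accuracies[row.method]
        acc_str = "" if np.isnan(acc) else str(int(_round_half_up(100 * acc, 0)))
        body.append([
            row.method,
            _PRETTY.get(row.condition, row.condition),
            f"{_round_half_up(row.precision, 2):.2f}",
            f"{_round_half_up(row.recall, 2):.2f}",
            f"{_round_half_up(row.f1, 2):.2f}",
            acc_str,
        ])
    if fmt == "csv":
        buf = _io.StringIO()
        pd.DataFrame(body, columns=header).to_csv(buf, index=False, lineterminator="\n")
        return buf.getvalue()
    if fmt == "markdown":
        widths = [max(len(h), *(len(r[i]) for r in body)) for i, h in enumerate(header)]
        seen = set()
        lines = ["| " + " | ".join(h.ljust(w) for h, w in zip(header, widths)) + " |",
                 "|-" + "-|-".join("-" * w for w in widths) + "-|"]
        for r in body:
            cells = list(r)
            if cells[0] in seen:
                cells[5] = ""  # accuracy printed once per method
            else:
                seen.add(cells[0])
            lines.append("| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {fmt!r}")
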