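"""Clinical classification metrics and cross-regime comparison reports.

The positive class is arrhythmia (label 1) throughout.  Metrics whose
denominator is zero raise :class:`UndefinedMetricError` rather than
reporting 0.0 — a sensitivity of "0" on a test set with no positives would
fabricate a clinical claim.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cost import ComparativeMetrics, RunSummary, derived_metrics
from .errors import UndefinedMetricError
from .protocols import RunHistory

REPORT_SCHEMA_VERSION = 1
POSITIVE_CLASS = 1  # arrhythmia


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Accuracy plus the critical medical metrics; None marks an undefined
    (zero-denominator) value."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None


def confusion(predictions: np.ndarray, labels: np.ndarray) -> ConfusionCounts:
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    pos = labels == POSITIVE_CLASS
    pred_pos = predictions == POSITIVE_CLASS
    return ConfusionCounts(
        tp=int(np.sum(pred_pos & pos)),
        tn=int(np.sum(~pred_pos & ~pos)),
        fp=int(np.sum(pred_pos & ~pos)),
        fn=int(np.sum(~pred_pos & pos)),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        raise UndefinedMetricError(f"{name} undefined: zero denominator")
    return num / den


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    return _ratio(c.tp + c.tn, c.n, "accuracy")


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN): arrhythmic beats correctly flagged."""
    return _ratio(c.tp, c.tp + c.fn, "sensitivity")


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP): normal beats correctly cleared."""
    return _ratio(c.tn, c.tn + c.fp, "specificity")


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP)."""
    return _ratio(c.tp, c.tp + c.fp, "precision")


def f1(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and sensitivity."""
    p = precision(c)
    s = sensitivity(c)
    if p + s == 0:
        raise UndefinedMetricError("f1 undefined: precision + sensitivity is zero")
    return 2.0 * p * s / (p + s)


def metric_set(c: ConfusionCounts) -> MetricSet:
    """All metrics at once, with undefined values surfaced as None."""

    def safe(fn):
        try:
            return fn(c)
        except UndefinedMetricError:
            return None

    return MetricSet(
        accuracy=safe(accuracy),
        sensitivity=safe(sensitivity),
        specificity=safe(specificity),
        precision=safe(precision),
        f1=safe(f1),
    )


# ---------------------------------------------------------------------------
# run comparison


def summarize_run(hist: RunHistory) -> RunSummary:
    """Collapse a RunHistory into the comparison-table row shape."""
    return RunSummary(
        final_accuracy=hist.final_accuracy,
        total_energy_kj=hist.ledger.total_kj,
        computation_kj=hist.ledger.compute_kj,
        communication_kj=hist.ledger.comm_kj,
        total_tflops=hist.ledger.total_tflops,
        total_time_s=hist.wall_clock_s,
    )


def compare_runs(
    runs: dict[str, RunHistory | RunSummary],
    baseline: str | None = None,
    contender: str | None = None,
) -> dict:
    """Comparison-table report plus derived metrics for (baseline, contender).

    ``runs`` maps run names to histories or pre-built summaries; by default
    the first run is the baseline (centralized role) and the second the
    contender (federated role).
    """
    if len(runs) < 2:
        raise ValueError("compare_runs needs at least two runs")
    summaries = {
        name: (summarize_run(r) if isinstance(r, RunHistory) else r)
        for name, r in runs.items()
    }
    names = list(summaries)
    baseline = baseline or names[0]
    contender = contender or names[1]
    derived = derived_metrics(summaries[baseline], summaries[contender])
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "positive_class": "arrhythmia (label 1)",
        "runs": {name: vars(s) for name, s in summaries.items()},
        "baseline": baseline,
        "contender": contender,
        "derived": vars(derived),
    }


def write_report_json(path: str | Path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)


def read_report_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_report_csv(path: str | Path, report: dict) -> None:
    """The table rows only: one line per run, metric columns."""
    fields = [
        "run", "final_accuracy", "total_energy_kj", "computation_kj",
        "communication_kj", "total_tflops", "total_time_s",
    ]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(fields)
        for name, s in report["runs"].items():
            w.writerow([name] + [s[k] for k in fields[1:]])
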