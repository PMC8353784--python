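"""Deployment evaluation: alert/truth matching and the field performance metrics.

Metrics follow the deployment-study conventions: sensitivity, specificity,
precision and accuracy as percentages; F1 as the harmonic mean of precision
and recall on the fraction scale; the false-alarm interval in days of use per
false positive. Accuracy is computed against the total number of classified
windows, the quantity a long-running deployment actually reports. Undefined
ratios (zero denominators) are reported as NaN, never coerced to 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

DEFAULT_MATCH_TOLERANCE_MS = 10_000


@dataclass
class ConfusionCounts:
    """Window-level confusion counts over a deployment period.

    ``fn`` may include undetected falls that never produced an alert window,
    so tp+fp+tn+fn may exceed ``total_windows`` by up to the fall count.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    total_windows: int
    recording_days: float
    n_failed: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn", "total_windows", "n_failed"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.recording_days <= 0:
            raise ValueError("recording_days must be positive")


@dataclass
class PerformanceReport:
    """Derived deployment metrics; percentages on the 0-100 scale, full precision."""

    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    f1: float
    daily_false_alarm_rate: float
    days_per_false_alarm: float
    failure_rate: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NaN",
                      RuntimeWarning)
        return float("nan")
    return num / den


def performance(counts: ConfusionCounts) -> PerformanceReport:
    """Compute the deployment metrics from confusion counts.

    Rounding to presentation precision happens only in report rendering; the
    returned report carries full precision.
    """
    sens = 100.0 * _ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    spec = 100.0 * _ratio(counts.tn, counts.tn + counts.fp, "specificity")
    prec = 100.0 * _ratio(counts.tp, counts.tp + counts.fp, "precision")
    acc = 100.0 * _ratio(counts.tp + counts.tn, counts.total_windows, "accuracy")
    p, r = prec / 100.0, sens / 100.0
    if math.isnan(p) or math.isnan(r) or (p + r) == 0:
        warnings.warn("f1 undefined; reported as NaN", RuntimeWarning)
        f1 = float("nan")
    else:
        f1 = 2.0 * p * r / (p + r)
    return PerformanceReport(
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        accuracy=acc,
        f1=f1,
        daily_false_alarm_rate=counts.fp / counts.recording_days,
        days_per_false_alarm=_ratio(counts.recording_days, counts.fp,
                                    "days_per_false_alarm"),
        failure_rate=_ratio(counts.n_failed, counts.total_windows, "failure_rate"),
    )


def match_events(
    alert_times: Sequence[int],
    truth_times: Sequence[int],
    tolerance_ms: int = DEFAULT_MATCH_TOLERANCE_MS,
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of alerts to ground-truth falls.

    Each truth fall (in time order) is matched to the nearest unmatched alert
    within ±tolerance; matched pairs are true positives, leftover alerts
    false positives, leftover falls false negatives. Conservation holds by
    construction: tp + fn = len(truth), tp + fp = len(alerts).
    """
    alerts = sorted(int(t) for t in alert_times)
    matched = [False] * len(alerts)
    tp = 0
    for t_fall in sorted(int(t) for t in truth_times):
        best, best_dist = None, tolerance_ms + 1
        for i, t_alert in enumerate(alerts):
            if matched[i]:
                continue
            dist = abs(t_alert - t_fall)
            if dist < best_dist:
                best, best_dist = i, dist
        if best is not None and best_dist <= tolerance_ms:
            matched[best] = True
            tp += 1
    fp = matched.count(False)
    fn = len(truth_times) - tp
    assert tp + fn == len(truth_times) and tp + fp == len(alerts)
    return tp, fp, fn


def per_participant_report(
    counts_by_participant: Mapping[str, ConfusionCounts],
) -> pd.DataFrame:
    """Per-participant metric table plus mean / SD / n summary rows.

    A participant enters a metric's average only when that metric is defined
    for them (e.g. sensitivity needs at least one true fall); the ``n`` row
    records how many participants each average includes.
    """
    if not counts_by_participant:
        raise ValueError("at least one participant required")
    rows = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for pid, counts in counts_by_participant.items():
            rows[pid] = performance(counts).as_dict()
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "participant_id"
    summary = pd.DataFrame(
        {
            "mean": table.mean(skipna=True),
            "sd": table.std(ddof=1, skipna=True),
            "n": table.notna().sum(),
        }
    ).T
    summary.index = pd.Index(["mean", "sd", "n"], name="participant_id")
    return pd.concat([table, summary])


def render_report_md(report: PerformanceReport, counts: ConfusionCounts) -> str:
    """Render a metrics table at presentation precision."""

    def pct(x: float, digits: int = 1) -> str:
        return "n/a" if math.isnan(x) else f"{x:.{digits}f} %"

    lines = [
        "| Metric | Value |",
        "|---|---|",
        f"| Recording days | {counts.recording_days:g} |",
        f"| Sample size (5 s windows) | {counts.total_windows} |",
        f"| True positives | {counts.tp} |",
        f"| True negatives | {counts.tn} |",
        f"| False positives | {counts.fp} |",
        f"| False negatives | {counts.fn} |",
        f"| Sensitivity | {pct(report.sensitivity)} |",
        f"| Specificity | {pct(report.specificity, 4)} |",
        f"| Precision | {pct(report.precision)} |",
        f"| Accuracy | {pct(report.accuracy, 4)} |",
        f"| F1-score | "
        + ("n/a" if math.isnan(report.f1) else f"{report.f1:.3f}") + " |",
        f"| Daily false alarm rate | {report.daily_false_alarm_rate:.3f} /day |",
        f"| Days per false alarm | "
        + ("n/a" if math.isnan(report.days_per_false_alarm)
           else f"{report.days_per_false_alarm:.1f}") + " |",
    ]
    return "\n".join(lines) + "\n"
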