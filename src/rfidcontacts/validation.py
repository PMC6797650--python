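"""Construct-validity machinery: dyad-second classification and agreement.

The sensor log and a ground-truth log (human-coded video) are compared on
the dyad-second grid: every second of every dyad is classified as true
positive, false positive, false negative, or true negative, and the usual
indices follow —

    sensitivity = TP / (TP + FN)        (true-positive rate)
    specificity = TN / (TN + FP)        (true-negative rate)
    accuracy    = (TP + TN) / (TP + FP + FN + TN)

Accuracy weights every dyad-second equally, which is why it serves as the
single optimization index for cutoff sweeps; the Youden-style sum
sensitivity + specificity is carried along as the relative alternative.

Inter-rater agreement between two binary codings of the same seconds is
summarized with Cohen's κ, the chance-corrected agreement rate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .events import (
    ContactEvent,
    DyadRaster,
    EventLog,
    ValidationError,
    rasterize,
)

__all__ = [
    "ConfusionCounts",
    "ValidityMetrics",
    "ValidationReport",
    "confusion_counts",
    "validity_metrics",
    "merge_rater_codings",
    "cohens_kappa",
    "validate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Dyad-second classification counts; the four sum to D x S."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")
            object.__setattr__(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_table(self) -> pd.DataFrame:
        """2x2 classification table: rows = truth, columns = observed."""
        return pd.DataFrame(
            [[self.tp, self.fn], [self.fp, self.tn]],
            index=pd.Index(["positive", "negative"], name="truth"),
            columns=pd.Index(["positive", "negative"], name="observed"),
        )

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}


@dataclass(frozen=True)
class ValidityMetrics:
    """Derived validity indices; NaN marks an undefined ratio."""

    sensitivity: float
    specificity: float
    accuracy: float

    @property
    def youden_sum(self) -> float:
        """Sensitivity + specificity (in [0, 2])."""
        return self.sensitivity + self.specificity

    def as_percentages(self, ndigits: int = 1) -> dict:
        """Metrics on the 0-100 scale, rounded for reporting."""
        return {
            "sensitivity_pct": round(self.sensitivity * 100, ndigits),
            "specificity_pct": round(self.specificity * 100, ndigits),
            "accuracy_pct": round(self.accuracy * 100, ndigits),
        }

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "youden_sum": self.youden_sum,
        }


def confusion_counts(observed: DyadRaster, truth: DyadRaster) -> ConfusionCounts:
    """Cell-by-cell classification of an observed raster against truth."""
    if observed.data.shape != truth.data.shape:
        raise ValidationError(
            f"raster shapes differ: observed {observed.data.shape} vs truth {truth.data.shape}"
        )
    if observed.dyads != truth.dyads:
        raise ValidationError("rasters index different dyads")
    o, t = observed.data, truth.data
    tp = int(np.sum(o & t))
    fp = int(np.sum(o & ~t))
    fn = int(np.sum(~o & t))
    tn = int(np.sum(~o & ~t))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def validity_metrics(counts: ConfusionCounts) -> ValidityMetrics:
    """Sensitivity, specificity and accuracy from classification counts.

    A ratio whose denominator is zero (no positive-truth or no
    negative-truth cells) is reported as NaN rather than raised.
    """
    if counts.total == 0:
        raise ValidationError("cannot compute metrics from all-zero counts")
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    sensitivity = counts.tp / pos if pos > 0 else math.nan
    specificity = counts.tn / neg if neg > 0 else math.nan
    accuracy = (counts.tp + counts.tn) / counts.total
    return ValidityMetrics(sensitivity=sensitivity, specificity=specificity, accuracy=accuracy)


def merge_rater_codings(log_a: EventLog, log_b: EventLog, split_time: int) -> EventLog:
    """Splice two raters' codings at ``split_time``.

    The merged log takes rater A before the split and rater B from the
    split on, truncating events at the boundary, so each rater accounts
    for their share of the coded time.
    """
    if log_a.roster != log_b.roster:
        raise ValidationError("rater logs must share a roster")
    if log_a.window != log_b.window:
        raise ValidationError("rater logs must share a window")
    t0, t1 = log_a.window
    if not (t0 <= split_time <= t1):
        raise ValidationError(f"split time {split_time} outside window [{t0}, {t1})")
    events = []
    for e in log_a.events:
        if e.start < split_time:
            events.append(ContactEvent(e.id_a, e.id_b, e.start, min(e.end, split_time)))
    for e in log_b.events:
        if e.end > split_time:
            events.append(ContactEvent(e.id_a, e.id_b, max(e.start, split_time), e.end))
    return EventLog(events, roster=log_a.roster, window=log_a.window)


def cohens_kappa(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Cohen's κ for two binary codings of the same units.

    κ = (p_o − p_e) / (1 − p_e), with p_e the chance agreement implied by
    the raters' marginal label frequencies.  When both raters are constant
    and identical (p_e = 1 with perfect observed agreement) κ is taken as
    1 by convention; constant-but-disagreeing raters give κ = 0.
    """
    a = np.asarray(labels_a).astype(bool)
    b = np.asarray(labels_b).astype(bool)
    if a.ndim != 1 or b.ndim != 1 or a.shape != b.shape:
        raise ValidationError(f"label sequences must be 1-D and equal length, got {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValidationError(f"need at least 2 labels, got {a.size}")
    p_o = float(np.mean(a == b))
    pa, pb = float(a.mean()), float(b.mean())
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else math.nan
    return (p_o - p_e) / (1 - p_e)


@dataclass
class ValidationReport:
    """Raw and processed construct-validity results for one log pair."""

    raw_counts: ConfusionCounts
    raw_metrics: ValidityMetrics
    processed_counts: ConfusionCounts
    processed_metrics: ValidityMetrics
    steps: list[dict]

    def to_dict(self) -> dict:
        return {
            "steps": self.steps,
            "raw": {"counts": self.raw_counts.to_dict(), "metrics": self.raw_metrics.to_dict()},
            "processed": {
                "counts": self.processed_counts.to_dict(),
                "metrics": self.processed_metrics.to_dict(),
            },
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_text(self) -> str:
        lines = []
        for name, counts, metrics in (
            ("raw", self.raw_counts, self.raw_metrics),
            ("processed", self.processed_counts, self.processed_metrics),
        ):
            pct = metrics.as_percentages()
            lines.append(
                f"{name:>9}: TP={counts.tp} FP={counts.fp} FN={counts.fn} TN={counts.tn}  "
                f"sensitivity={pct['sensitivity_pct']}% specificity={pct['specificity_pct']}% "
                f"accuracy={pct['accuracy_pct']}%"
            )
        if self.steps:
            lines.append(f"    steps: {self.steps}")
        return "\n".join(lines)


def validate(observed: EventLog, truth: EventLog, config=None) -> ValidationReport:
    """Construct validity of ``observed`` against ``truth``, before and
    after applying a processing configuration.

    ``config`` is a :class:`rfidcontacts.preprocessing.ProcessingConfig`
    (or None for no processing, in which case raw and processed results
    coincide).
    """
    from .preprocessing import ProcessingConfig, apply_pipeline

    if observed.roster != truth.roster or observed.window != truth.window:
        raise ValidationError("observed and truth logs must share roster and window")
    if config is None:
        config = ProcessingConfig([])
    truth_raster = rasterize(truth)
    raw_counts = confusion_counts(rasterize(observed), truth_raster)
    processed = apply_pipeline(observed, config)
    processed_counts = confusion_counts(rasterize(processed), truth_raster)
    return ValidationReport(
        raw_counts=raw_counts,
        raw_metrics=validity_metrics(raw_counts),
        processed_counts=processed_counts,
        processed_metrics=validity_metrics(processed_counts),
        steps=config.to_dicts(),
    )
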