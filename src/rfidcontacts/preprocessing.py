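"""Event-log cleaning strategies for flickering proximity-sensor data.

Three strategies, applicable alone or in sequence:

``min_duration``
    Delete events strictly shorter than a cutoff — the classic guard
    against incidental signals between passers-by.

``interpolate``
    Merge consecutive same-dyad events whose separating gap is at most a
    cutoff.  This repairs "flicker": one continuous interaction fragmented
    into several short on-intervals because body movement interrupts the
    line of sight between badges.

``triadic_closure``
    If A is in contact with both B and C at second t, impute a B-C contact
    at t.  Conversation groups are cliques (people interact pairwise with
    every co-member), so missing within-group edges can be recovered this
    way.  Iterating closes triads opened by the previous imputation round;
    per-second clique components are the fixpoint.

A sweep evaluates one strategy over a grid of parameter values against a
ground-truth log, scoring each with dyad-second validity metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .events import (
    ConfigError,
    ContactEvent,
    EventLog,
    ValidationError,
    events_from_raster,
    rasterize,
)
from . import validation

__all__ = [
    "Step",
    "ProcessingConfig",
    "SweepResult",
    "filter_min_duration",
    "interpolate_gaps",
    "close_triads",
    "apply_pipeline",
    "sweep",
]

STEP_KINDS = ("min_duration", "interpolate", "triadic_closure")

# parameter aliases accepted in config files, per step kind
_PARAM_ALIASES = {
    "min_duration": ("value", "cutoff_s", "cutoff"),
    "interpolate": ("value", "max_gap_s", "max_gap"),
    "triadic_closure": ("value", "iterations"),
}


@dataclass(frozen=True)
class Step:
    """One processing step: a kind from ``STEP_KINDS`` and its parameter.

    The parameter is a duration cutoff in seconds (``min_duration``), a
    maximum gap in seconds (``interpolate``), or an iteration count
    (``triadic_closure``); always a non-negative integer.
    """

    kind: str
    value: int

    def __post_init__(self) -> None:
        if self.kind not in STEP_KINDS:
            raise ConfigError(f"unknown processing step {self.kind!r}; expected one of {STEP_KINDS}")
        if int(self.value) < 0:
            raise ConfigError(f"step {self.kind!r} parameter must be >= 0, got {self.value}")
        object.__setattr__(self, "value", int(self.value))

    def to_dict(self) -> dict:
        return {"kind": self.kind, "value": self.value}


@dataclass
class ProcessingConfig:
    """Ordered sequence of processing steps.  Order is significant.

    The recommended combined default — interpolate gaps of up to 75 s,
    then delete events shorter than 55 s — is available as
    :meth:`recommended`.
    """

    steps: list[Step] = field(default_factory=list)

    @classmethod
    def recommended(cls) -> "ProcessingConfig":
        return cls([Step("interpolate", 75), Step("min_duration", 55)])

    @classmethod
    def from_dicts(cls, items: Iterable[dict]) -> "ProcessingConfig":
        steps = []
        for item in items:
            if "kind" not in item:
                raise ConfigError(f"processing step needs a 'kind': {item}")
            kind = item["kind"]
            if kind not in _PARAM_ALIASES:
                raise ConfigError(f"unknown processing step {kind!r}; expected one of {STEP_KINDS}")
            value = None
            for key in _PARAM_ALIASES[kind]:
                if key in item:
                    value = item[key]
                    break
            if value is None:
                raise ConfigError(f"step {kind!r} is missing its parameter ({_PARAM_ALIASES[kind]})")
            steps.append(Step(kind, value))
        return cls(steps)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ProcessingConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if doc is None:
            return cls([])
        if isinstance(doc, dict):
            doc = doc.get("steps", [])
        if not isinstance(doc, list):
            raise ConfigError(f"processing config must be a list of steps, got {type(doc).__name__}")
        return cls.from_dicts(doc)

    def to_dicts(self) -> list[dict]:
        return [s.to_dict() for s in self.steps]


# ---------------------------------------------------------------------------
# the three strategies
# ---------------------------------------------------------------------------

def filter_min_duration(log: EventLog, cutoff_s: int) -> EventLog:
    """Delete events strictly shorter than ``cutoff_s`` seconds."""
    if cutoff_s < 0:
        raise ValidationError(f"cutoff must be >= 0, got {cutoff_s}")
    kept = [e for e in log.events if e.duration >= cutoff_s]
    return EventLog(kept, roster=log.roster, window=log.window)


def interpolate_gaps(log: EventLog, max_gap_s: int) -> EventLog:
    """Merge same-dyad events separated by gaps of at most ``max_gap_s`` seconds.

    Merging is transitive along chains of events, so the operation is
    idempotent for a fixed gap and monotone in the gap.  The gap test is
    inclusive ("at most").
    """
    if max_gap_s < 0:
        raise ValidationError(f"max gap must be >= 0, got {max_gap_s}")
    by_dyad: dict[tuple, list[ContactEvent]] = {}
    for e in log.events:
        by_dyad.setdefault(e.dyad, []).append(e)
    merged: list[ContactEvent] = []
    for (a, b), evs in by_dyad.items():
        evs.sort(key=lambda e: e.start)
        cur_start, cur_end = evs[0].start, evs[0].end
        for e in evs[1:]:
            if e.start - cur_end <= max_gap_s:
                cur_end = max(cur_end, e.end)
            else:
                merged.append(ContactEvent(a, b, cur_start, cur_end))
                cur_start, cur_end = e.start, e.end
        merged.append(ContactEvent(a, b, cur_start, cur_end))
    return EventLog(merged, roster=log.roster, window=log.window)


def close_triads(log: EventLog, iterations: int, _chunk_s: int = 20_000) -> EventLog:
    """Iteratively impute the missing edge of open triads, second by second.

    One iteration: simultaneously for every second t, add dyad {B, C}
    whenever some A is in contact with both B and C at t.  Updates within
    an iteration are synchronous (computed from the pre-iteration state),
    so the result does not depend on participant order.  Stops early at a
    fixpoint.
    """
    if iterations < 0:
        raise ValidationError(f"iterations must be >= 0, got {iterations}")
    if iterations == 0 or not log.events:
        return EventLog(log.events, roster=log.roster, window=log.window)
    raster = rasterize(log)
    ids = log.sorted_roster()
    pos = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    pairs = [(pos[a], pos[b]) for a, b in raster.dyads]
    data = raster.data
    for lo in range(0, data.shape[1], _chunk_s):
        hi = min(lo + _chunk_s, data.shape[1])
        adj = np.zeros((hi - lo, n, n), dtype=bool)
        for d, (i, j) in enumerate(pairs):
            adj[:, i, j] = adj[:, j, i] = data[d, lo:hi]
        for _ in range(iterations):
            paths = np.matmul(adj.astype(np.uint8), adj.astype(np.uint8)) > 0
            new = adj | paths
            new[:, np.arange(n), np.arange(n)] = False
            if np.array_equal(new, adj):
                break
            adj = new
        for d, (i, j) in enumerate(pairs):
            data[d, lo:hi] = adj[:, i, j]
    return events_from_raster(raster, roster=log.roster)


_STEP_FUNCS = {
    "min_duration": filter_min_duration,
    "interpolate": interpolate_gaps,
    "triadic_closure": close_triads,
}


def apply_pipeline(log: EventLog, config: ProcessingConfig) -> EventLog:
    """Apply the configured steps in order, each on the previous output."""
    out = log
    for step in config.steps:
        out = _STEP_FUNCS[step.kind](out, step.value)
    return out


# ---------------------------------------------------------------------------
# cutoff sweeps
# ---------------------------------------------------------------------------

DEFAULT_CUTOFF_GRID = list(range(0, 155, 5))
DEFAULT_CLOSURE_GRID = [0, 1, 2, 3, 4]

_CRITERIA = ("accuracy", "youden_sum")


@dataclass
class SweepResult:
    """Validity metrics of one strategy over a parameter grid.

    ``optimum_value`` attains the maximal criterion; ties break toward the
    smallest parameter value.
    """

    strategy: str
    criterion: str
    grid: list[int]
    counts: list["validation.ConfusionCounts"]
    metrics: list["validation.ValidityMetrics"]

    @property
    def scores(self) -> list[float]:
        return [getattr(m, self.criterion) for m in self.metrics]

    @property
    def optimum_index(self) -> int:
        scores = self.scores
        return int(np.argmax(scores))  # argmax takes the first (smallest) on ties

    @property
    def optimum_value(self) -> int:
        return self.grid[self.optimum_index]

    @property
    def optimum_score(self) -> float:
        return self.scores[self.optimum_index]

    def to_frame(self):
        import pandas as pd

        rows = []
        for value, c, m in zip(self.grid, self.counts, self.metrics):
            rows.append(
                {
                    "value": value,
                    "tp": c.tp,
                    "fp": c.fp,
                    "fn": c.fn,
                    "tn": c.tn,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "accuracy": m.accuracy,
                }
            )
        return pd.DataFrame(rows)


def sweep(
    strategy: str,
    grid: Sequence[int],
    observed: EventLog,
    truth: EventLog,
    criterion: str = "accuracy",
) -> SweepResult:
    """Apply ``strategy`` to ``observed`` at each grid value and score it
    against ``truth`` on the dyad-second grid.

    The default criterion is accuracy (one index, every second weighted
    equally); ``youden_sum`` (sensitivity + specificity) is the
    alternative.
    """
    if strategy not in STEP_KINDS:
        raise ConfigError(f"unknown strategy {strategy!r}; expected one of {STEP_KINDS}")
    if criterion not in _CRITERIA:
        raise ConfigError(f"unknown criterion {criterion!r}; expected one of {_CRITERIA}")
    if not grid:
        raise ValidationError("sweep grid is empty")
    if observed.roster != truth.roster or observed.window != truth.window:
        raise ValidationError("observed and truth logs must share roster and window")
    truth_raster = rasterize(truth)
    func = _STEP_FUNCS[strategy]
    counts, metrics = [], []
    for value in grid:
        processed = func(observed, value)
        c = validation.confusion_counts(rasterize(processed), truth_raster)
        counts.append(c)
        metrics.append(validation.validity_metrics(c))
    return SweepResult(strategy, criterion, list(grid), counts, metrics)
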