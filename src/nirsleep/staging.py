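"""Behavioral sleep-stage coding: codability scoring, timelines, reliability.

Infant sleep is coded from video in 15-s epochs as quiet sleep (QS), active
sleep (AS) or awake. Each behavioral criterion carries a percentage weight;
an epoch's codability score is the summed weight of the criteria that were
actually observable in that epoch (0 when nothing was visible, 100 when all
were). Subjects whose mean score falls below the codability threshold are
excluded. Epoch labels are merged into stage timelines with explicit
transitions, and inter-rater reliability is quantified with the two-way
random-effects absolute-agreement single-measure intraclass correlation,
ICC(2,1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

EPOCH_LENGTH_S = 15.0

Stage = Literal["QS", "AS", "awake"]

__all__ = [
    "Criterion",
    "CodingScheme",
    "Epoch",
    "CodingSheet",
    "SleepTimeline",
    "default_coding_scheme",
    "score_epoch",
    "assess_codability",
    "derive_timeline",
    "icc_agreement",
]


@dataclass(frozen=True)
class Criterion:
    name: str
    applicability: Literal["QS", "AS", "both"]
    weight: float  # percent of the 100% epoch total


@dataclass
class CodingScheme:
    """Weighted behavioral criteria for staging 15-s epochs.

    For each sleep stage the applicable criteria (stage-specific plus shared)
    must sum to 100%. Criteria that are mutually exclusive between stages
    (REM vs no-REM, regular vs irregular respiration) carry higher weights
    than behaviors that can occur in either stage.
    """

    criteria: list[Criterion]
    epoch_length_s: float = EPOCH_LENGTH_S
    codability_threshold_pct: float = 65.0

    def __post_init__(self) -> None:
        by_name = {c.name for c in self.criteria}
        if len(by_name) != len(self.criteria):
            raise ValueError("duplicate criterion names")
        if any(c.weight <= 0 for c in self.criteria):
            raise ValueError("criterion weights must be positive")
        for stage in ("QS", "AS"):
            total = sum(c.weight for c in self.applicable(stage))
            if abs(total - 100.0) > 1e-9:
                raise ValueError(f"{stage} criteria weights sum to {total}, not 100")

    def applicable(self, stage: str) -> list[Criterion]:
        """Criteria observable in the given stage (shared criteria included).

        Awake epochs are scored against the QS set: codability reflects what
        is visible on video (respiration, limbs, eyes), not the stage itself.
        """
        stage = "QS" if stage == "awake" else stage
        return [c for c in self.criteria if c.applicability in (stage, "both")]

    def weight_of(self, name: str) -> float:
        for c in self.criteria:
            if c.name == name:
                return c.weight
        raise KeyError(f"unknown criterion {name!r}")


def default_coding_scheme() -> CodingScheme:
    """Default weight table (synthetic stand-in for an unpublished scheme).

    The exact published criterion weights are not available; this table
    honors the stated structure — stage-exclusive behaviors (REM presence,
    respiration regularity) weigh more than behaviors shared between stages
    (startles) — and is fully overridable via configuration.
    """
    return CodingScheme(
        criteria=[
            Criterion("eyes_closed_no_rem", "QS", 35.0),
            Criterion("regular_respiration", "QS", 35.0),
            Criterion("minimal_movement", "QS", 20.0),
            Criterion("rem_present", "AS", 35.0),
            Criterion("irregular_respiration", "AS", 35.0),
            Criterion("random_movements", "AS", 20.0),
            Criterion("startles", "both", 10.0),
        ]
    )


@dataclass
class Epoch:
    start_s: float
    stage: Stage
    criteria_observed: frozenset[str]
    score: float


@dataclass
class CodingSheet:
    """One subject's per-epoch stage labels and codability scores."""

    subject_id: str
    epochs: list[Epoch]

    def __post_init__(self) -> None:
        for i, e in enumerate(self.epochs):
            expected = i * EPOCH_LENGTH_S + self.epochs[0].start_s
            if abs(e.start_s - expected) > 1e-6:
                raise ValueError("epochs must be contiguous 15-s segments")
            if not 0 <= e.score <= 100:
                raise ValueError("epoch scores must lie in [0, 100]")

    @property
    def stages(self) -> list[Stage]:
        return [e.stage for e in self.epochs]


@dataclass
class SleepTimeline:
    """Merged stage intervals plus the transitions between them."""

    intervals: list[tuple[float, float, Stage]]
    transitions: list[tuple[float, Stage, Stage]] = field(default_factory=list)

    @property
    def start_s(self) -> float:
        return self.intervals[0][0]

    @property
    def end_s(self) -> float:
        return self.intervals[-1][1]

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def stage_at(self, t: float) -> Stage:
        """Stage covering time t (right-open intervals; end maps to last)."""
        if not self.start_s <= t <= self.end_s:
            raise ValueError(f"time {t} outside coded span")
        for start, end, stage in self.intervals:
            if start <= t < end:
                return stage
        return self.intervals[-1][2]

    def stages_in(self, t0: float, t1: float) -> set[Stage]:
        """All stages whose interval overlaps [t0, t1)."""
        if t0 < self.start_s or t1 > self.end_s:
            raise ValueError("span not covered by timeline")
        return {
            stage
            for start, end, stage in self.intervals
            if start < t1 and end > t0
        }

    def epoch_labels(self) -> list[Stage]:
        """Stage label of each 15-s epoch across the coded span."""
        n = int(round(self.duration_s / EPOCH_LENGTH_S))
        return [
            self.stage_at(self.start_s + (i + 0.5) * EPOCH_LENGTH_S) for i in range(n)
        ]


def score_epoch(criteria_observed: Iterable[str], scheme: CodingScheme) -> float:
    """Sum of the weights of the criteria that could be observed, in [0, 100]."""
    total = sum(scheme.weight_of(name) for name in set(criteria_observed))
    if total > 100.0 + 1e-9:
        raise ValueError("observed criteria exceed the 100% stage total")
    return float(total)


def assess_codability(sheet: CodingSheet, scheme: CodingScheme):
    """Mean epoch score and the inclusion flag.

    Subjects are excluded when the mean score is strictly below the
    threshold, so a mean of exactly 65% is retained.
    """
    if not sheet.epochs:
        raise ValueError("coding sheet has no epochs")
    mean_score = float(np.mean([e.score for e in sheet.epochs]))
    return mean_score, mean_score >= scheme.codability_threshold_pct


def derive_timeline(sheet: CodingSheet) -> SleepTimeline:
    """Merge consecutive same-stage epochs into intervals, log transitions."""
    if not sheet.epochs:
        raise ValueError("coding sheet has no epochs")
    intervals: list[tuple[float, float, Stage]] = []
    transitions: list[tuple[float, Stage, Stage]] = []
    for e in sheet.epochs:
        end = e.start_s + EPOCH_LENGTH_S
        if intervals and intervals[-1][2] == e.stage:
            start, _, stage = intervals[-1]
            intervals[-1] = (start, end, stage)
        else:
            if intervals:
                transitions.append((e.start_s, intervals[-1][2], e.stage))
            intervals.append((e.start_s, end, e.stage))
    return SleepTimeline(intervals=intervals, transitions=transitions)


def icc_agreement(ratings, variant: str = "absolute") -> float:
    """Intraclass correlation from a subjects x raters matrix.

    ``absolute`` is ICC(2,1): two-way random effects, absolute agreement,
    single measure. ``consistency`` is the corresponding ICC(3,1), provided
    for diagnostic comparison. Computed from the two-way ANOVA mean squares:

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
        ICC(3,1) = (MSR - MSE) / (MSR + (k-1) MSE)
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    if np.isnan(m).any():
        raise ValueError("missing cells are not supported")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_total = ((m - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if variant == "absolute":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif variant == "consistency":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if denom <= 0:
        raise ZeroDivisionError("ICC undefined: no between-subject variance")
    return float((msr - mse) / denom)
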