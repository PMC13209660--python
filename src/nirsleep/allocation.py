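"""Assignment of subjects and trials to sleep-stage groups per analysis.

Every trial is labeled with the sleep stage covering its span (``mixed``
when a transition falls inside it; such trials are always discarded).
Subjects who stay in one sleep stage contribute all their valid trials to
that stage's group. Subjects who transition are retained only if a
continuous run of trials in a single stage still satisfies the paradigm's
minimum-valid-trial rules:

* social selectivity: at least three valid non-vocal (N) and three valid
  vocal (V) trials in the same stage within a continuous block of six
  trials (the earliest qualifying block wins);
* HaND Fam1: at least three valid Fam1 trials in one stage;
* HaND habituation: a single stage across trials 1-15 plus >= 3 valid Fam1
  and >= 3 valid Fam3 trials;
* HaND novelty: >= 3 valid Fam3 trials directly followed by >= 3 valid
  novel trials, all in one stage with no invalid or mixed trial inside the
  run.

A subject contributes to at most one sleep-stage group per analysis, but
may contribute different stages to different analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import pandas as pd

from .staging import SleepTimeline
from .synthetic import Event, hand_epoch_of_trial

SLEEP_STAGES = ("QS", "AS")

__all__ = [
    "TrialRecord",
    "AllocationResult",
    "label_trials",
    "allocate_social",
    "allocate_hand",
    "build_analysis_groups",
]


@dataclass(frozen=True)
class TrialRecord:
    index: int
    condition: str
    onset_s: float
    duration_s: float
    motion_valid: bool
    stage: Literal["QS", "AS", "awake", "mixed"]

    @property
    def within_trial_transition(self) -> bool:
        return self.stage == "mixed"

    @property
    def usable(self) -> bool:
        """Valid, in a sleep stage, no transition inside the trial."""
        return self.motion_valid and self.stage in SLEEP_STAGES


@dataclass
class AllocationResult:
    analysis: str
    group: Literal["QS", "AS", "excluded"]
    retained_trial_indices: dict[str, list[int]] = field(default_factory=dict)
    reason: str = ""


def label_trials(
    events: Sequence[Event],
    timeline: SleepTimeline,
    valid: Sequence[bool],
) -> list[TrialRecord]:
    """Attach sleep-stage labels to trials.

    A trial's stage is the timeline stage covering onset..offset; ``mixed``
    if any stage change occurs inside the trial.
    """
    if len(events) != len(valid):
        raise ValueError("events and validity flags must align")
    records = []
    for i, ev in enumerate(events):
        stages = timeline.stages_in(ev.onset_s, ev.onset_s + ev.duration_s)
        stage = stages.pop() if len(stages) == 1 else "mixed"
        records.append(
            TrialRecord(i, ev.condition, ev.onset_s, ev.duration_s, bool(valid[i]), stage)
        )
    return records


def _retained(trials: Sequence[TrialRecord], stage: str) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for t in trials:
        if t.motion_valid and t.stage == stage:
            out.setdefault(t.condition, []).append(t.index)
    return out


def allocate_social(trials: Sequence[TrialRecord]) -> AllocationResult:
    """Sleep-stage group for the 16-trial social-selectivity run.

    Stage-constant subjects keep all valid trials. Transitioning subjects
    are scanned for the earliest window of six consecutive trials that all
    share one sleep stage and contain >= 3 valid N and >= 3 valid V trials;
    invalid trials occupy positions in the window but contribute nothing,
    while mixed or awake trials disqualify it.
    """
    if len(trials) != 16:
        raise ValueError("social run must have 16 labeled trials")
    stages = {t.stage for t in trials if t.stage != "mixed"}
    if len(stages) == 1 and (stage := stages.pop()) in SLEEP_STAGES:
        return AllocationResult("social", stage, _retained(trials, stage),
                                "stage constant")
    for start in range(len(trials) - 5):
        window = trials[start : start + 6]
        w_stages = {t.stage for t in window}
        if len(w_stages) != 1 or (stage := next(iter(w_stages))) not in SLEEP_STAGES:
            continue
        n_valid = sum(1 for t in window if t.motion_valid and t.condition == "N")
        v_valid = sum(1 for t in window if t.motion_valid and t.condition == "V")
        if n_valid >= 3 and v_valid >= 3:
            retained = _retained(window, stage)
            return AllocationResult("social", stage, retained,
                                    f"block of six trials {start + 1}-{start + 6}")
    return AllocationResult("social", "excluded", {},
                            "no single-stage block of six trials with 3+3 valid")


def _hand_epochs(trials: Sequence[TrialRecord]) -> dict[str, list[TrialRecord]]:
    out: dict[str, list[TrialRecord]] = {}
    for t in trials:
        out.setdefault(hand_epoch_of_trial(t.index), []).append(t)
    return out


def allocate_hand(
    trials: Sequence[TrialRecord],
    analysis: Literal["fam1", "habituation", "novelty"],
) -> AllocationResult:
    """Sleep-stage group for one HaND analysis (25 labeled trials)."""
    if len(trials) != 25:
        raise ValueError("HaND run must have 25 labeled trials")
    ep = _hand_epochs(trials)
    name = f"hand_{analysis}"

    if analysis == "fam1":
        for stage in SLEEP_STAGES:
            fam1 = [t for t in ep["Fam1"] if t.motion_valid and t.stage == stage]
            if len(fam1) >= 3:
                return AllocationResult(
                    name, stage, {"Fam1": [t.index for t in fam1]}, "3+ valid Fam1"
                )
        return AllocationResult(name, "excluded", {}, "fewer than 3 valid Fam1 in one stage")

    if analysis == "habituation":
        fam_all = ep["Fam1"] + ep["Fam2"] + ep["Fam3"]
        stages = {t.stage for t in fam_all}
        if len(stages) == 1 and (stage := stages.pop()) in SLEEP_STAGES:
            fam1 = [t.index for t in ep["Fam1"] if t.motion_valid]
            fam3 = [t.index for t in ep["Fam3"] if t.motion_valid]
            if len(fam1) >= 3 and len(fam3) >= 3:
                return AllocationResult(
                    name, stage, {"Fam1": fam1, "Fam3": fam3},
                    "one stage through Fam1-Fam3",
                )
            return AllocationResult(name, "excluded", {}, "fewer than 3 valid Fam1 or Fam3")
        return AllocationResult(name, "excluded", {}, "stage change within Fam1-Fam3")

    if analysis == "novelty":
        # maximal contiguous run of valid single-stage trials spanning the
        # Fam3 -> novel boundary (trials 15|16, 0-based 14|15)
        for stage in SLEEP_STAGES:
            def run_ok(t: TrialRecord) -> bool:
                return t.motion_valid and t.stage == stage

            if not (run_ok(trials[14]) and run_ok(trials[15])):
                continue
            lo = 14
            while lo > 10 and run_ok(trials[lo - 1]):
                lo -= 1
            hi = 15
            while hi < 19 and run_ok(trials[hi + 1]):
                hi += 1
            fam3 = [t.index for t in trials[lo:15]]
            novel = [t.index for t in trials[15 : hi + 1]]
            if len(fam3) >= 3 and len(novel) >= 3:
                return AllocationResult(
                    name, stage, {"Fam3": fam3, "novel": novel},
                    "contiguous valid Fam3->novel run",
                )
        return AllocationResult(
            name, "excluded", {}, "no 3+3 contiguous valid Fam3->novel run in one stage"
        )

    raise ValueError(f"unknown HaND analysis {analysis!r}")


def build_analysis_groups(
    manifest: pd.DataFrame,
    allocations: dict[str, dict[str, AllocationResult]],
    trials_by_subject: dict[str, Sequence[TrialRecord]] | None = None,
) -> pd.DataFrame:
    """Tidy table of per-subject group membership for every analysis.

    ``allocations`` maps subject_id -> analysis name -> AllocationResult.
    The ``stage_constant`` column marks subjects who never left their
    initial sleep stage during the paradigm; only those subjects enter the
    data-quality comparisons.
    """
    rows = []
    for sid, per_analysis in allocations.items():
        constant = None
        if trials_by_subject is not None and sid in trials_by_subject:
            stages = {t.stage for t in trials_by_subject[sid]}
            constant = len(stages) == 1 and next(iter(stages)) in SLEEP_STAGES
        for analysis, res in per_analysis.items():
            rows.append(
                {
                    "subject_id": sid,
                    "analysis": analysis,
                    "group": res.group,
                    "stage_constant": constant,
                    "retained_trials": ";".join(
                        f"{c}:{','.join(map(str, ix))}"
                        for c, ix in sorted(res.retained_trial_indices.items())
                    ),
                    "reason": res.reason,
                }
            )
    table = pd.DataFrame(rows)
    if not table.empty:
        dup = table.duplicated(subset=["subject_id", "analysis"])
        if dup.any():
            raise ValueError("a subject appears more than once for an analysis")
    return table
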