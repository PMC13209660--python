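"""Independent brute-force oracles shared by the unit and acceptance tests.

These deliberately re-derive the allocation decisions by enumerating every
candidate window/run, staying independent of the package's implementation.
"""

import numpy as np

from nirsleep.allocation import SLEEP_STAGES, TrialRecord


def oracle_social(trials):
    """Enumerate all six-trial windows per the stated retention rules."""
    sleep_stages = {t.stage for t in trials if t.stage != "mixed"}
    if len(sleep_stages) == 1 and next(iter(sleep_stages)) in SLEEP_STAGES:
        return next(iter(sleep_stages))
    for start in range(11):
        win = trials[start : start + 6]
        for stage in SLEEP_STAGES:
            if all(t.stage == stage for t in win):
                n = sum(t.motion_valid and t.condition == "N" for t in win)
                v = sum(t.motion_valid and t.condition == "V" for t in win)
                if n >= 3 and v >= 3:
                    return stage
    return "excluded"


def oracle_hand(trials, analysis):
    if analysis == "fam1":
        for stage in SLEEP_STAGES:
            if sum(t.motion_valid and t.stage == stage for t in trials[:5]) >= 3:
                return stage
        return "excluded"
    if analysis == "habituation":
        for stage in SLEEP_STAGES:
            if all(t.stage == stage for t in trials[:15]):
                f1 = sum(t.motion_valid for t in trials[:5])
                f3 = sum(t.motion_valid for t in trials[10:15])
                if f1 >= 3 and f3 >= 3:
                    return stage
        return "excluded"
    # novelty: any contiguous all-valid single-stage run crossing the
    # Fam3|novel boundary with >= 3 trials on each side
    for stage in SLEEP_STAGES:
        for lo in range(10, 13):          # >= 3 Fam3 trials: lo <= 12
            for hi in range(17, 20):      # >= 3 novel trials: hi >= 17
                run = trials[lo : hi + 1]
                if all(t.motion_valid and t.stage == stage for t in run):
                    return stage
    return "excluded"


def random_trials(rng, n, conds):
    """Random stage sequences covering constant, transitioning, oscillating
    and mixed-trial subjects, with random motion validity."""
    stages = []
    cur = rng.choice(["QS", "AS", "awake"])
    for _ in range(n):
        if rng.random() < 0.15:
            cur = rng.choice(["QS", "AS", "awake", "mixed"])
        stages.append(cur)
        if cur == "mixed":
            cur = rng.choice(["QS", "AS"])
    valid = rng.random(n) > 0.2
    return [
        TrialRecord(i, conds[i], 18.0 * i, 8.0, bool(valid[i]), stages[i])
        for i in range(n)
    ]
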