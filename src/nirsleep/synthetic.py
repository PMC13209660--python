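"""Synthetic infant fNIRS cohorts with known ground truth.

Builds everything the downstream pipeline consumes: stimulus schedules for
the two auditory paradigms, Markov-chain sleep-stage timelines in 15-s
epochs, behavioral coding sheets with configurable observability, and raw
dual-wavelength intensity recordings produced by a forward model —
stage-dependent hemodynamic response amplitudes convolved with a
double-gamma HRF, habituation decay across familiarization epochs, shared
cardiac plus respiratory and drift physiology, and sleep-stage-dependent
motion artifacts — so that every preprocessing and analysis stage can be
validated against planted parameters.

Paradigm structure mirrors the study designs: the social-selectivity run
presents 8 vocal (V) and 8 non-vocal (N) 8-s trials in a fixed pseudo-random
order with 10-12 s silent baselines; the habituation-and-novelty-detection
(HaND) run presents 25 8-s sentence trials (15 female-speaker familiarization,
5 male-speaker novel, 5 female post-test) each preceded by a 10-s baseline,
grouped into epochs Fam1 (1-5), Fam2 (6-10), Fam3 (11-15), novel (16-20) and
post (21-25).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .staging import (
    EPOCH_LENGTH_S,
    CodingScheme,
    CodingSheet,
    Epoch,
    SleepTimeline,
    Stage,
    default_coding_scheme,
    derive_timeline,
    score_epoch,
)

__all__ = [
    "Event",
    "ParadigmSpec",
    "ProbeLayout",
    "HRFParams",
    "NoiseParams",
    "SubjectParams",
    "StageDynamics",
    "RawRecording",
    "CohortConfig",
    "SubjectData",
    "EXTINCTION_COEFFS",
    "social_paradigm",
    "hand_paradigm",
    "hand_epoch_of_trial",
    "double_gamma_hrf",
    "generate_stimulus_schedule",
    "simulate_sleep_timeline",
    "simulate_coding_sheet",
    "simulate_recording",
    "generate_cohort",
]

# Tabulated specific extinction coefficients, 1/(mM cm), at the two laser
# wavelengths (standard compiled hemoglobin spectra).
EXTINCTION_COEFFS = {
    780: {"HbO": 0.7360, "HbR": 1.1022},
    850: {"HbO": 1.0580, "HbR": 0.6913},
}


@dataclass(frozen=True)
class Event:
    onset_s: float
    duration_s: float
    condition: str


@dataclass(frozen=True)
class ParadigmSpec:
    """Timing and condition structure of one auditory run."""

    name: Literal["social_selectivity", "hand"]
    trial_duration_s: float
    baseline_duration_s: tuple[float, float]  # (lo, hi); fixed when lo == hi
    trial_sequence: tuple[str, ...]
    block_average_range_s: tuple[float, float]

    def __post_init__(self) -> None:
        if self.name == "social_selectivity":
            counts = {c: self.trial_sequence.count(c) for c in ("V", "N")}
            if counts != {"V": 8, "N": 8} or len(self.trial_sequence) != 16:
                raise ValueError("social run needs exactly 8 V and 8 N trials")
        elif self.name == "hand":
            if len(self.trial_sequence) != 25:
                raise ValueError("HaND run has exactly 25 trials")


# Fixed pseudo-random condition order for the social run (the published order
# is not available; alternating pairs is the shipped default, configurable).
_SOCIAL_DEFAULT_ORDER = ("V", "V", "N", "N") * 4

_HAND_EPOCHS = ("Fam1",) * 5 + ("Fam2",) * 5 + ("Fam3",) * 5 + ("novel",) * 5 + ("post",) * 5


def hand_epoch_of_trial(index: int) -> str:
    """Epoch label (Fam1/Fam2/Fam3/novel/post) of HaND trial ``index`` (0-based)."""
    return _HAND_EPOCHS[index]


def social_paradigm(order: Sequence[str] = _SOCIAL_DEFAULT_ORDER) -> ParadigmSpec:
    return ParadigmSpec(
        name="social_selectivity",
        trial_duration_s=8.0,
        baseline_duration_s=(10.0, 12.0),
        trial_sequence=tuple(order),
        block_average_range_s=(-4.0, 20.0),
    )


def hand_paradigm() -> ParadigmSpec:
    return ParadigmSpec(
        name="hand",
        trial_duration_s=8.0,
        baseline_duration_s=(10.0, 10.0),
        trial_sequence=_HAND_EPOCHS,
        block_average_range_s=(-4.0, 18.0),
    )


@dataclass(frozen=True)
class ProbeLayout:
    """Bilateral frontal-temporal array: 18 channels, 9 per hemisphere."""

    n_channels: int = 18
    wavelengths_nm: tuple[int, int] = (780, 850)
    source_detector_separation_cm: float = 2.0
    sampling_rate_hz: float = 10.0

    @property
    def channel_ids(self) -> range:
        return range(1, self.n_channels + 1)

    def hemisphere(self, channel_id: int) -> str:
        return "left" if channel_id <= self.n_channels // 2 else "right"


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma HRF timing; the infant HRF is not firmly established,
    so the peak is configurable (7 s default) with a late undershoot."""

    peak_s: float = 7.0
    undershoot_s: float = 16.0
    dispersion: float = 1.0
    undershoot_ratio: float = 1 / 6
    duration_s: float = 30.0


@dataclass(frozen=True)
class NoiseParams:
    """Physiological and instrumental noise amplitudes, in OD units."""

    cardiac_freq_hz: float = 2.5  # infant heart rate, inside the 1.5-3.5 Hz band
    cardiac_amp: float = 0.004
    resp_freq_hz: float = 0.8
    resp_amp: float = 0.003
    drift_amp: float = 0.004
    drift_band_hz: tuple[float, float] = (0.002, 0.015)
    white_amp: float = 0.002

    def __post_init__(self) -> None:
        if not 1.5 <= self.cardiac_freq_hz <= 3.5:
            raise ValueError("cardiac frequency must sit in the SCI band [1.5, 3.5] Hz")


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject generative parameters.

    response_amplitude maps condition -> stage -> peak HbO change (uM);
    habituation_decay maps stage -> multiplicative amplitude factor applied
    per successive HaND familiarization epoch (Fam2 gets decay^1, Fam3
    decay^2, ...); artifact_rate_per_min maps stage -> expected motion
    artifacts per minute (AS >= QS by default).
    """

    response_amplitude: Mapping[str, Mapping[str, float]]
    hbr_ratio: float = -0.35
    hbr_lag_s: float = 1.0
    habituation_decay: Mapping[str, float] = field(
        default_factory=lambda: {"QS": 1.0, "AS": 0.25}
    )
    hrf_params: HRFParams = HRFParams()
    noise_params: NoiseParams = NoiseParams()
    artifact_rate_per_min: Mapping[str, float] = field(
        default_factory=lambda: {"QS": 0.15, "AS": 0.6, "awake": 1.0}
    )
    response_channels: tuple[int, ...] | None = None  # None -> all channels
    i0: float = 1.0
    seed: int = 0


@dataclass(frozen=True)
class StageDynamics:
    """Epoch-level Markov chain over {QS, AS, awake} plus coder visibility."""

    initial_stage_probs: Mapping[str, float] = field(
        default_factory=lambda: {"QS": 0.5, "AS": 0.5}
    )
    epoch_transition_probs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "QS": {"QS": 0.97, "AS": 0.02, "awake": 0.01},
            "AS": {"QS": 0.02, "AS": 0.96, "awake": 0.02},
            "awake": {"QS": 0.05, "AS": 0.15, "awake": 0.80},
        }
    )
    mean_observability: float = 0.9

    _STAGES = ("QS", "AS", "awake")

    def __post_init__(self) -> None:
        for stage, row in self.epoch_transition_probs.items():
            total = sum(row.get(s, 0.0) for s in self._STAGES)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"transition row for {stage} sums to {total}, not 1")

    def row(self, stage: str) -> np.ndarray:
        r = self.epoch_transition_probs[stage]
        return np.array([r.get(s, 0.0) for s in self._STAGES])


@dataclass
class RawRecording:
    """Dual-wavelength intensity series with its events and probe layout."""

    intensity: np.ndarray  # [channel, wavelength, time], strictly positive
    events: list[Event]
    layout: ProbeLayout
    subject_id: str = ""

    def __post_init__(self) -> None:
        if np.any(self.intensity <= 0):
            raise ValueError("intensity must be strictly positive everywhere")
        onsets = [e.onset_s for e in self.events]
        if onsets != sorted(onsets):
            raise ValueError("events must be sorted by onset")
        n_t = self.intensity.shape[2]
        span = n_t / self.layout.sampling_rate_hz
        if self.events and self.events[-1].onset_s + self.events[-1].duration_s > span:
            raise ValueError("event extends past the end of the recording")

    @property
    def duration_s(self) -> float:
        return self.intensity.shape[2] / self.layout.sampling_rate_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.intensity.shape[2]) / self.layout.sampling_rate_hz


# ---------------------------------------------------------------------------
# stimulus schedules
# ---------------------------------------------------------------------------

def generate_stimulus_schedule(paradigm: ParadigmSpec, seed: int) -> list[Event]:
    """Trial onsets/durations/labels with jittered silent baselines.

    Deterministic for a given seed; baseline gaps are drawn uniformly from
    the paradigm's range (fixed when the range is degenerate). The schedule
    starts after one leading baseline period.
    """
    if paradigm.name not in ("social_selectivity", "hand"):
        raise ValueError(f"unknown paradigm {paradigm.name!r}")
    rng = np.random.default_rng(seed)
    lo, hi = paradigm.baseline_duration_s
    events: list[Event] = []
    t = float(rng.uniform(lo, hi)) if hi > lo else lo
    for label in paradigm.trial_sequence:
        events.append(Event(onset_s=round(t, 3), duration_s=paradigm.trial_duration_s,
                            condition=label))
        gap = float(rng.uniform(lo, hi)) if hi > lo else lo
        t += paradigm.trial_duration_s + gap
    return events


# ---------------------------------------------------------------------------
# sleep timelines and coding sheets
# ---------------------------------------------------------------------------

def simulate_sleep_timeline(
    n_epochs: int, dynamics: StageDynamics, seed: int
) -> SleepTimeline:
    """Draw an epoch-level stage sequence from the Markov chain."""
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    rng = np.random.default_rng(seed)
    stages = list(StageDynamics._STAGES)
    init = np.array([dynamics.initial_stage_probs.get(s, 0.0) for s in stages])
    init = init / init.sum()
    labels = [stages[rng.choice(len(stages), p=init)]]
    for _ in range(n_epochs - 1):
        labels.append(stages[rng.choice(len(stages), p=dynamics.row(labels[-1]))])
    sheet = CodingSheet(
        subject_id="",
        epochs=[
            Epoch(i * EPOCH_LENGTH_S, s, frozenset(), 100.0)
            for i, s in enumerate(labels)
        ],
    )
    return derive_timeline(sheet)


def simulate_coding_sheet(
    timeline: SleepTimeline,
    scheme: CodingScheme,
    dynamics: StageDynamics,
    seed: int,
    subject_id: str = "",
) -> CodingSheet:
    """Emulate a human coder: each applicable criterion of the epoch's true
    stage is marked observed with probability ``mean_observability``."""
    rng = np.random.default_rng(seed)
    epochs: list[Epoch] = []
    for i, stage in enumerate(timeline.epoch_labels()):
        applicable = scheme.applicable(stage)
        observed = frozenset(
            c.name for c in applicable if rng.uniform() < dynamics.mean_observability
        )
        epochs.append(
            Epoch(
                start_s=timeline.start_s + i * EPOCH_LENGTH_S,
                stage=stage,
                criteria_observed=observed,
                score=score_epoch(observed, scheme),
            )
        )
    return CodingSheet(subject_id=subject_id, epochs=epochs)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def double_gamma_hrf(fs: float, p: HRFParams) -> np.ndarray:
    """Canonical double-gamma impulse response sampled at ``fs`` Hz."""
    t = np.arange(0, p.duration_s, 1.0 / fs)
    shape1 = p.peak_s / p.dispersion + 1.0
    shape2 = p.undershoot_s / p.dispersion + 1.0
    h = gamma_dist.pdf(t, shape1, scale=p.dispersion) - p.undershoot_ratio * gamma_dist.pdf(
        t, shape2, scale=p.dispersion
    )
    return h


def _response_kernel(paradigm: ParadigmSpec, fs: float, p: HRFParams) -> np.ndarray:
    """HRF convolved with the trial boxcar, normalized to unit peak so a
    planted amplitude equals the peak concentration change."""
    h = double_gamma_hrf(fs, p)
    boxcar = np.ones(int(round(paradigm.trial_duration_s * fs)))
    k = np.convolve(boxcar, h)
    return k / np.abs(k).max()


def forward_od(
    hbo_um: np.ndarray,
    hbr_um: np.ndarray,
    layout: ProbeLayout,
    dpf: tuple[float, float] = (5.22, 4.23),
    extinction: Mapping[int, Mapping[str, float]] = EXTINCTION_COEFFS,
) -> np.ndarray:
    """Map concentration changes (uM) to per-wavelength optical densities via
    the modified Beer-Lambert law. Returns [channel, wavelength, time]."""
    d = layout.source_detector_separation_cm
    out = np.empty((hbo_um.shape[0], 2, hbo_um.shape[1]))
    for w, wl in enumerate(layout.wavelengths_nm):
        eps = extinction[wl]
        out[:, w, :] = (
            (eps["HbO"] * hbo_um + eps["HbR"] * hbr_um) / 1000.0 * d * dpf[w]
        )
    return out


def simulate_recording(
    schedule: Sequence[Event],
    timeline: SleepTimeline,
    params: SubjectParams,
    layout: ProbeLayout | None = None,
    seed: int | None = None,
    paradigm: ParadigmSpec | None = None,
) -> RawRecording:
    """Generate one raw dual-wavelength recording.

    Concentration traces are HRF-convolved condition regressors whose
    amplitude depends on the sleep stage at trial onset, with habituation
    decay over HaND familiarization epochs; HbR is a delayed, negatively
    scaled copy of HbO. Concentrations map to optical density through the
    Beer-Lambert forward model and to intensity as I = I0 exp(-dOD);
    physiological noise is added in OD (so intensity stays positive) and
    motion artifacts (spikes and baseline steps, Poisson counts with
    stage-dependent rates) are applied in intensity space.
    """
    layout = layout or ProbeLayout()
    paradigm = paradigm or (
        hand_paradigm() if len(schedule) == 25 else social_paradigm()
    )
    rng = np.random.default_rng(params.seed if seed is None else seed)
    fs = layout.sampling_rate_hz
    post = paradigm.block_average_range_s[1] + 10.0
    needed = (schedule[-1].onset_s + schedule[-1].duration_s + post) if schedule else 60.0
    if schedule and schedule[-1].onset_s + schedule[-1].duration_s > timeline.end_s:
        raise ValueError("stimulus schedule extends past the coded timeline")
    duration = max(timeline.duration_s, needed)
    n_t = int(round(duration * fs))
    t = np.arange(n_t) / fs

    kernel = _response_kernel(paradigm, fs, params.hrf_params)
    drive = np.zeros(n_t)
    hbo = np.zeros((layout.n_channels, n_t))
    for i, ev in enumerate(schedule):
        stage = timeline.stage_at(ev.onset_s)
        amp = params.response_amplitude.get(ev.condition, {}).get(stage, 0.0)
        if paradigm.name == "hand":
            epoch_idx = {"Fam1": 0, "Fam2": 1, "Fam3": 2, "novel": 0, "post": 0}[
                hand_epoch_of_trial(i)
            ]
            amp *= params.habituation_decay.get(stage, 1.0) ** epoch_idx
        if amp == 0.0:
            continue
        onset_i = int(round(ev.onset_s * fs))
        seg = kernel[: n_t - onset_i]
        drive[onset_i : onset_i + seg.size] += amp * seg
    gains = np.ones(layout.n_channels)
    if params.response_channels is not None:
        gains[:] = 0.0
        gains[[c - 1 for c in params.response_channels]] = 1.0
    hbo = gains[:, None] * drive[None, :]
    lag = int(round(params.hbr_lag_s * fs))
    hbr = params.hbr_ratio * np.roll(hbo, lag, axis=1)
    if lag:
        hbr[:, :lag] = 0.0

    dod = forward_od(hbo, hbr, layout)

    np_ = params.noise_params
    if np_.cardiac_amp or np_.resp_amp or np_.drift_amp or np_.white_amp:
        phase_c = rng.uniform(0, 2 * math.pi, size=layout.n_channels)
        f_c = np.clip(np_.cardiac_freq_hz + rng.normal(0, 0.1), 1.5, 3.5)
        cardiac = np.sin(2 * math.pi * f_c * t[None, :] + phase_c[:, None])
        # the cardiac pulse is shared across wavelengths (same vascular
        # origin), with slightly different optical weighting
        for w, scale in enumerate((1.0, 0.8)):
            dod[:, w, :] += np_.cardiac_amp * scale * cardiac
        phase_r = rng.uniform(0, 2 * math.pi, size=layout.n_channels)
        resp = np.sin(2 * math.pi * np_.resp_freq_hz * t[None, :] + phase_r[:, None])
        dod += np_.resp_amp * resp[:, None, :]
        for ch in range(layout.n_channels):
            for w in range(2):
                f_d = rng.uniform(*np_.drift_band_hz)
                ph = rng.uniform(0, 2 * math.pi)
                dod[ch, w, :] += np_.drift_amp * np.sin(2 * math.pi * f_d * t + ph)
                dod[ch, w, :] += rng.normal(0, np_.white_amp, size=n_t)

    intensity = params.i0 * np.exp(-dod)

    # stage-dependent motion artifacts: spikes and baseline steps that hit a
    # majority of channels simultaneously (gross head/body movement)
    for start_s, end_s, stage in timeline.intervals:
        end_s = min(end_s, duration)
        if end_s <= start_s:
            continue
        rate = params.artifact_rate_per_min.get(stage, 0.0)
        n_art = rng.poisson(rate * (end_s - start_s) / 60.0)
        for _ in range(n_art):
            at = rng.uniform(start_s, end_s)
            at_i = int(at * fs)
            n_aff = rng.integers(int(0.55 * layout.n_channels), layout.n_channels + 1)
            channels = rng.choice(layout.n_channels, size=n_aff, replace=False)
            amp_od = rng.uniform(0.6, 1.5) * rng.choice([-1.0, 1.0])
            if rng.uniform() < 0.6:  # transient spike, ~0.5 s
                width = int(0.5 * fs)
                bump = amp_od * np.exp(
                    -0.5 * ((np.arange(n_t) - at_i) / (width / 2.0)) ** 2
                )
                factor = np.exp(-bump)
            else:  # baseline step lasting 5-15 s
                dur_i = int(rng.uniform(5, 15) * fs)
                factor = np.ones(n_t)
                factor[at_i : at_i + dur_i] = math.exp(-amp_od)
            intensity[channels] *= factor[None, None, :]

    if np.any(intensity <= 0):
        raise ValueError("noise amplitudes drove intensity non-positive")
    return RawRecording(
        intensity=intensity, events=list(schedule), layout=layout
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def default_amplitudes(paradigm_name: str) -> dict[str, dict[str, float]]:
    """Default planted response amplitudes (uM peak HbO), per condition and
    sleep stage, on the order of published infant auditory responses.

    Defaults plant the qualitative structure the analyses probe: a robust
    response to both social conditions in both stages, and a HaND initial
    response that is larger in AS than QS. These are simulation settings,
    not empirical claims.
    """
    if paradigm_name == "social_selectivity":
        return {
            "V": {"QS": 0.7, "AS": 0.7},
            "N": {"QS": 1.3, "AS": 1.3},
        }
    return {lbl: {"QS": 0.35, "AS": 1.4} for lbl in ("Fam1", "Fam2", "Fam3", "novel", "post")}


@dataclass(frozen=True)
class CohortConfig:
    """Composition of one synthetic cohort.

    group_sizes maps "QS"/"AS" to subject counts (subjects in a group start
    in that stage; with ``stage_constant=True`` they stay in it for the whole
    run, emulating the stage-constant subsets used for data-quality tables).
    ``amplitude_sd`` is the between-subject SD applied multiplicatively to
    the planted amplitudes; ``low_observability_fraction`` subjects are
    generated with poor video visibility to exercise the codability
    exclusion.
    """

    paradigm: Literal["social_selectivity", "hand"] = "social_selectivity"
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"QS": 18, "AS": 21}
    )
    stage_constant: bool = True
    transition_dynamics: StageDynamics | None = None
    amplitude_sd: float = 0.45
    mean_observability: float = 0.92
    low_observability_fraction: float = 0.0
    artifact_rate_per_min: Mapping[str, float] = field(
        default_factory=lambda: {"QS": 0.15, "AS": 0.6, "awake": 1.0}
    )
    noise_params: NoiseParams = NoiseParams()
    amplitudes: Mapping[str, Mapping[str, float]] | None = None
    habituation_decay: Mapping[str, float] = field(
        default_factory=lambda: {"QS": 1.0, "AS": 0.25}
    )


@dataclass
class SubjectData:
    """One simulated subject: recording, schedule, coding sheet, truth."""

    subject_id: str
    group: str
    recording: RawRecording
    events: list[Event]
    coding_sheet: CodingSheet
    timeline: SleepTimeline
    params: SubjectParams
    mean_observability: float


def _constant_dynamics(stage: str, observability: float) -> StageDynamics:
    rows = {s: {s: 1.0} for s in ("QS", "AS", "awake")}
    return StageDynamics(
        initial_stage_probs={stage: 1.0},
        epoch_transition_probs=rows,
        mean_observability=observability,
    )


def generate_cohort(
    config: CohortConfig,
    seed: int,
    scheme: CodingScheme | None = None,
    layout: ProbeLayout | None = None,
) -> tuple[list[SubjectData], pd.DataFrame]:
    """Simulate a full cohort; returns subjects and a ground-truth manifest.

    Deterministic for (config, seed): per-subject generators are seeded from
    a spawned SeedSequence. The manifest records the planted group, stage
    sequence, amplitudes and observability per subject.
    """
    scheme = scheme or default_coding_scheme()
    layout = layout or ProbeLayout()
    paradigm = (
        social_paradigm() if config.paradigm == "social_selectivity" else hand_paradigm()
    )
    base_amp = config.amplitudes or default_amplitudes(config.paradigm)
    ss = np.random.SeedSequence(seed)
    n_total = sum(config.group_sizes.values())
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_total)]

    subjects: list[SubjectData] = []
    rows = []
    i = 0
    for group, n in config.group_sizes.items():
        for _ in range(n):
            sid = f"sub-{i + 1:03d}"
            sub_seed = child_seeds[i]
            rng = np.random.default_rng(sub_seed)
            obs = config.mean_observability
            if rng.uniform() < config.low_observability_fraction:
                obs = rng.uniform(0.2, 0.55)
            schedule = generate_stimulus_schedule(paradigm, seed=sub_seed)
            run_len = schedule[-1].onset_s + schedule[-1].duration_s + 30.0
            n_epochs = int(math.ceil(run_len / EPOCH_LENGTH_S))
            if config.stage_constant or config.transition_dynamics is None:
                dyn = _constant_dynamics(group, obs)
            else:
                dyn = replace(
                    config.transition_dynamics,
                    initial_stage_probs={group: 1.0},
                    mean_observability=obs,
                )
            timeline = simulate_sleep_timeline(n_epochs, dyn, seed=sub_seed + 1)
            amp = {
                cond: {
                    st: max(0.0, a * rng.normal(1.0, config.amplitude_sd))
                    for st, a in stages.items()
                }
                for cond, stages in base_amp.items()
            }
            params = SubjectParams(
                response_amplitude=amp,
                habituation_decay=dict(config.habituation_decay),
                noise_params=config.noise_params,
                artifact_rate_per_min=dict(config.artifact_rate_per_min),
                seed=sub_seed + 2,
            )
            recording = simulate_recording(
                schedule, timeline, params, layout=layout, paradigm=paradigm
            )
            recording.subject_id = sid
            sheet = simulate_coding_sheet(
                timeline, scheme, dyn, seed=sub_seed + 3, subject_id=sid
            )
            subjects.append(
                SubjectData(sid, group, recording, schedule, sheet, timeline, params, obs)
            )
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "paradigm": config.paradigm,
                    "seed": sub_seed,
                    "mean_observability": round(obs, 6),
                    "stage_sequence": "".join(
                        {"QS": "Q", "AS": "A", "awake": "W"}[s]
                        for s in timeline.epoch_labels()
                    ),
                    "amplitudes": ";".join(
                        f"{c}:{st}={v:.6f}"
                        for c, sts in sorted(amp.items())
                        for st, v in sorted(sts.items())
                    ),
                }
            )
            i += 1
    manifest = pd.DataFrame(rows)
    return subjects, manifest
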