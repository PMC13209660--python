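"""File interchange: long-format CSV recordings, BIDS-style event TSVs,
coding-sheet CSVs, YAML coding schemes and minimal SNIRF (HDF5) files."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .staging import CodingScheme, CodingSheet, Criterion, Epoch
from .synthetic import Event, ProbeLayout, RawRecording

__all__ = [
    "write_recording_csv",
    "read_recording_csv",
    "write_events_tsv",
    "read_events_tsv",
    "write_coding_sheet_csv",
    "read_coding_sheet_csv",
    "write_scheme_yaml",
    "read_scheme_yaml",
    "write_snirf",
    "read_snirf",
]


def write_recording_csv(recording: RawRecording, path: str | Path) -> None:
    """Long format: time_s, channel, wavelength_nm, intensity."""
    n_ch, n_wl, n_t = recording.intensity.shape
    t = recording.time_s
    frames = []
    for w, wl in enumerate(recording.layout.wavelengths_nm):
        df = pd.DataFrame(
            {
                "time_s": np.tile(t, n_ch),
                "channel": np.repeat(np.arange(1, n_ch + 1), n_t),
                "wavelength_nm": wl,
                "intensity": recording.intensity[:, w, :].ravel(),
            }
        )
        frames.append(df)
    pd.concat(frames).sort_values(["channel", "wavelength_nm", "time_s"]).to_csv(
        path, index=False
    )


def read_recording_csv(
    path: str | Path, events: list[Event] | None = None, layout: ProbeLayout | None = None
) -> RawRecording:
    df = pd.read_csv(path)
    channels = np.sort(df["channel"].unique())
    wavelengths = tuple(int(w) for w in np.sort(df["wavelength_nm"].unique()))
    n_t = df["time_s"].nunique()
    layout = layout or ProbeLayout(
        n_channels=len(channels), wavelengths_nm=wavelengths
    )
    intensity = np.empty((len(channels), len(wavelengths), n_t))
    for ci, ch in enumerate(channels):
        for wi, wl in enumerate(wavelengths):
            sub = df[(df["channel"] == ch) & (df["wavelength_nm"] == wl)]
            intensity[ci, wi, :] = sub.sort_values("time_s")["intensity"].to_numpy()
    return RawRecording(intensity=intensity, events=events or [], layout=layout)


def write_events_tsv(events: list[Event], path: str | Path) -> None:
    pd.DataFrame(
        {
            "onset": [e.onset_s for e in events],
            "duration": [e.duration_s for e in events],
            "trial_type": [e.condition for e in events],
        }
    ).to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> list[Event]:
    df = pd.read_csv(path, sep="\t")
    return [
        Event(float(r.onset), float(r.duration), str(r.trial_type))
        for r in df.itertuples()
    ]


def write_coding_sheet_csv(sheet: CodingSheet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "epoch_index": range(len(sheet.epochs)),
            "epoch_start_s": [e.start_s for e in sheet.epochs],
            "stage": [e.stage for e in sheet.epochs],
            "criteria_observed": [
                ";".join(sorted(e.criteria_observed)) for e in sheet.epochs
            ],
            "score": [e.score for e in sheet.epochs],
        }
    ).to_csv(path, index=False)


def read_coding_sheet_csv(path: str | Path, subject_id: str = "") -> CodingSheet:
    df = pd.read_csv(path).sort_values("epoch_index")
    epochs = [
        Epoch(
            start_s=float(r.epoch_start_s),
            stage=str(r.stage),
            criteria_observed=frozenset(
                str(r.criteria_observed).split(";")
            ) if isinstance(r.criteria_observed, str) and r.criteria_observed else frozenset(),
            score=float(r.score),
        )
        for r in df.itertuples()
    ]
    return CodingSheet(subject_id=subject_id, epochs=epochs)


def write_scheme_yaml(scheme: CodingScheme, path: str | Path) -> None:
    data = {
        "epoch_length_s": scheme.epoch_length_s,
        "codability_threshold_pct": scheme.codability_threshold_pct,
        "criteria": [
            {"name": c.name, "applicability": c.applicability, "weight": c.weight}
            for c in scheme.criteria
        ],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_scheme_yaml(path: str | Path) -> CodingScheme:
    data = yaml.safe_load(Path(path).read_text())
    return CodingScheme(
        criteria=[
            Criterion(c["name"], c["applicability"], float(c["weight"]))
            for c in data["criteria"]
        ],
        epoch_length_s=float(data.get("epoch_length_s", 15.0)),
        codability_threshold_pct=float(data.get("codability_threshold_pct", 65.0)),
    )


# ---------------------------------------------------------------------------
# SNIRF (Shared Near Infrared Spectroscopy Format, an HDF5 schema)
# ---------------------------------------------------------------------------

def write_snirf(recording: RawRecording, path: str | Path) -> None:
    """Write a minimal continuous-wave SNIRF file.

    Covers dataTimeSeries/time, a measurementList (one entry per
    channel x wavelength), probe wavelengths, and stim groups per condition.
    """
    n_ch, n_wl, n_t = recording.intensity.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        series = recording.intensity.reshape(n_ch * n_wl, n_t).T  # time x measurement
        data.create_dataset("dataTimeSeries", data=series)
        data.create_dataset("time", data=recording.time_s)
        for m in range(n_ch * n_wl):
            ch, w = divmod(m, n_wl)
            ml = data.create_group(f"measurementList{m + 1}")
            ml.create_dataset("sourceIndex", data=ch + 1)
            ml.create_dataset("detectorIndex", data=ch + 1)
            ml.create_dataset("wavelengthIndex", data=w + 1)
            ml.create_dataset("dataType", data=1)  # CW amplitude
            ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.array(recording.layout.wavelengths_nm, dtype=float))
        conditions = sorted({e.condition for e in recording.events})
        for i, cond in enumerate(conditions):
            evs = [e for e in recording.events if e.condition == cond]
            stim = nirs.create_group(f"stim{i + 1}")
            stim.create_dataset("name", data=cond)
            stim.create_dataset(
                "data",
                data=np.array([[e.onset_s, e.duration_s, 1.0] for e in evs]),
            )


def read_snirf(path: str | Path) -> RawRecording:
    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        data = nirs["data1"]
        series = np.asarray(data["dataTimeSeries"])  # time x measurement
        time = np.asarray(data["time"])
        wavelengths = tuple(int(w) for w in np.asarray(nirs["probe"]["wavelengths"]))
        n_wl = len(wavelengths)
        n_ch = series.shape[1] // n_wl
        intensity = series.T.reshape(n_ch, n_wl, -1)
        events = []
        for key in sorted(k for k in nirs.keys() if k.startswith("stim")):
            stim = nirs[key]
            name = stim["name"][()]
            if isinstance(name, bytes):
                name = name.decode()
            for onset, dur, _ in np.asarray(stim["data"]):
                events.append(Event(float(onset), float(dur), str(name)))
        events.sort(key=lambda e: e.onset_s)
        fs = 1.0 / float(np.median(np.diff(time)))
        layout = ProbeLayout(n_channels=n_ch, wavelengths_nm=wavelengths,
                             sampling_rate_hz=fs)
    return RawRecording(intensity=intensity, events=events, layout=layout)
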