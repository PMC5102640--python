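"""Plain-text readers/writers for the pipeline's on-disk formats.

Recordings travel as long-format CSV (time_s, channel, wavelength_nm,
intensity), events as BIDS-dialect TSV (onset, duration, trial_type),
subject metadata and ground truth as JSON, and processed signals as wide
CSV (time_s, ch01_HbO, ch01_HbR, ...).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from nirsmark.optics_preproc import HemoSignals
from nirsmark.synth_cohort import EventSchedule, GroundTruth, RawRecording

__all__ = [
    "write_recording",
    "read_recording",
    "write_events",
    "read_events",
    "write_ground_truth",
    "write_hemo",
    "read_hemo",
]


def write_events(schedule: EventSchedule, path: Path) -> None:
    df = pd.DataFrame(
        [
            {"onset": o, "duration": d, "trial_type": c}
            for o, d, c in schedule.events
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_events(path: Path, total_duration_s: float | None = None) -> EventSchedule:
    df = pd.read_csv(path, sep="\t")
    events = tuple(
        (float(r.onset), float(r.duration), str(r.trial_type))
        for r in df.itertuples()
    )
    if total_duration_s is None:
        total_duration_s = events[-1][0] + events[-1][1] + 10.0
    return EventSchedule(events=events, total_duration_s=total_duration_s)


def write_recording(rec: RawRecording, out_dir: Path) -> None:
    """One subject -> <id>_intensity.csv, <id>_events.tsv, <id>_subject.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_ch, _, n_t = rec.intensity.shape
    t = np.arange(n_t) / rec.fs
    frames = []
    for ch in range(n_ch):
        for wi, wl in enumerate(rec.wavelengths):
            frames.append(
                pd.DataFrame(
                    {
                        "time_s": t,
                        "channel": ch + 1,
                        "wavelength_nm": wl,
                        "intensity": rec.intensity[ch, wi],
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(
        out_dir / f"{rec.subject_id}_intensity.csv", index=False
    )
    write_events(rec.schedule, out_dir / f"{rec.subject_id}_events.tsv")
    meta = {
        "subject_id": rec.subject_id,
        "age": rec.age,
        "group": rec.group,
        "fs": rec.fs,
        "wavelengths_nm": list(rec.wavelengths),
        "total_duration_s": rec.schedule.total_duration_s,
    }
    (out_dir / f"{rec.subject_id}_subject.json").write_text(
        json.dumps(meta, indent=2)
    )


def read_recording(out_dir: Path, subject_id: str) -> RawRecording:
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / f"{subject_id}_subject.json").read_text())
    df = pd.read_csv(out_dir / f"{subject_id}_intensity.csv")
    schedule = read_events(
        out_dir / f"{subject_id}_events.tsv", meta["total_duration_s"]
    )
    wavelengths = tuple(meta["wavelengths_nm"])
    channels = sorted(df["channel"].unique())
    n_t = df["time_s"].nunique()
    intensity = np.empty((len(channels), len(wavelengths), n_t))
    for ci, ch in enumerate(channels):
        for wi, wl in enumerate(wavelengths):
            sub = df[(df["channel"] == ch) & (df["wavelength_nm"] == wl)]
            intensity[ci, wi] = sub.sort_values("time_s")["intensity"].to_numpy()
    return RawRecording(
        subject_id=meta["subject_id"],
        age=meta["age"],
        group=meta["group"],
        fs=meta["fs"],
        intensity=intensity,
        schedule=schedule,
        wavelengths=wavelengths,
    )


def write_ground_truth(truths: list[GroundTruth], ids: list[str], path: Path) -> None:
    payload = [
        {
            "subject_id": sid,
            "group": t.group,
            "amplitude_uM": t.amplitude.tolist(),
            "latency_s": t.latency.tolist(),
            "width": t.width.tolist(),
            "artifact_trials": sorted(t.artifact_trials),
            "hbr_ratio": t.hbr_ratio,
            "seed": t.seed,
        }
        for sid, t in zip(ids, truths)
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def write_hemo(
    hemo: HemoSignals, subject_id: str, out_dir: Path, meta: dict | None = None
) -> None:
    """Wide CSV (time_s, chXX_HbO, chXX_HbR, ...) plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = {"time_s": np.arange(hemo.n_samples) / hemo.fs}
    for ch in range(hemo.n_channels):
        data[f"ch{ch + 1:02d}_HbO"] = hemo.hbo[ch]
        data[f"ch{ch + 1:02d}_HbR"] = hemo.hbr[ch]
    pd.DataFrame(data).to_csv(out_dir / f"{subject_id}_hemo.csv", index=False)
    sidecar = {"fs": hemo.fs, "provenance": hemo.provenance}
    sidecar.update(meta or {})
    (out_dir / f"{subject_id}_hemo.json").write_text(json.dumps(sidecar, indent=2))


def read_hemo(out_dir: Path, subject_id: str) -> tuple[HemoSignals, dict]:
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / f"{subject_id}_hemo.json").read_text())
    df = pd.read_csv(out_dir / f"{subject_id}_hemo.csv")
    hbo_cols = sorted(c for c in df.columns if c.endswith("_HbO"))
    hbr_cols = sorted(c for c in df.columns if c.endswith("_HbR"))
    hemo = HemoSignals(
        hbo=df[hbo_cols].to_numpy().T,
        hbr=df[hbr_cols].to_numpy().T,
        fs=meta["fs"],
        provenance=meta.get("provenance", {}),
    )
    return hemo, meta


def list_subjects(out_dir: Path, suffix: str) -> list[str]:
    """Subject ids inferred from ``<id><suffix>`` filenames in a directory."""
    return sorted(
        p.name[: -len(suffix)]
        for p in Path(out_dir).glob(f"*{suffix}")
    )
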