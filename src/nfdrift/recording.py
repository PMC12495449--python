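"""Trial-structured EEG containers and plain-text I/O.

A :class:`TrialRecording` is one 60-s (by default) multichannel EEG epoch
with its task metadata: subject, condition (Control / 1Hz / 5Hz / 10Hz),
within-condition trial index 1..8 and global trial index 1..32.  Cohorts are
written one CSV per trial plus a JSON sidecar and a manifest CSV, so a run
round-trips through ordinary text files; EDF files can be ingested through
:mod:`mne` when it is installed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

CONDITION_LABELS = ("Control", "1Hz", "5Hz", "10Hz")
DEFAULT_CHANNELS = ("Fz", "Cz", "Pz")


@dataclass
class TrialRecording:
    """One trial epoch: ``samples`` is channels × time in microvolts."""

    subject_id: str
    condition: str
    trial_index: int
    global_trial_index: int
    channel_labels: tuple[str, ...]
    sampling_rate: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"samples must be (n_channels={len(self.channel_labels)}, n_times); "
                f"got shape {self.samples.shape}"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.condition not in CONDITION_LABELS:
            raise ValueError(f"condition must be one of {CONDITION_LABELS}, got {self.condition!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.channel_labels.index(label)]

    def with_samples(self, samples: np.ndarray) -> "TrialRecording":
        return replace(self, samples=np.asarray(samples, dtype=float))

    def meta(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "condition": self.condition,
            "trial_index": int(self.trial_index),
            "global_trial_index": int(self.global_trial_index),
            "channel_labels": list(self.channel_labels),
            "sampling_rate": float(self.sampling_rate),
            "n_samples": int(self.n_samples),
        }


def save_cohort(recordings: list[TrialRecording], out_dir: str | Path) -> Path:
    """Write one CSV + JSON sidecar per trial and a manifest CSV; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        stem = f"{rec.subject_id}_{rec.condition}_t{rec.trial_index:02d}"
        csv_path = out_dir / f"{stem}.csv"
        df = pd.DataFrame(rec.samples.T, columns=list(rec.channel_labels))
        df.insert(0, "time_s", np.arange(rec.n_samples) / rec.sampling_rate)
        df.to_csv(csv_path, index=False, float_format="%.6f")
        (out_dir / f"{stem}.json").write_text(json.dumps(rec.meta(), indent=1))
        rows.append({"subject": rec.subject_id, "condition": rec.condition,
                     "trial": rec.trial_index, "global_trial": rec.global_trial_index,
                     "path": csv_path.name})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def _load_trial_csv(path: Path, meta: dict) -> TrialRecording:
    df = pd.read_csv(path)
    channels = tuple(meta["channel_labels"])
    return TrialRecording(
        subject_id=meta["subject_id"], condition=meta["condition"],
        trial_index=meta["trial_index"], global_trial_index=meta["global_trial_index"],
        channel_labels=channels, sampling_rate=meta["sampling_rate"],
        samples=df[list(channels)].to_numpy().T,
    )


def _load_trial_edf(path: Path, meta: dict) -> TrialRecording:
    import mne  # optional dependency, EDF ingest only

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    picks = [ch for ch in meta.get("channel_labels", raw.ch_names) if ch in raw.ch_names]
    data = raw.get_data(picks=picks) * 1e6  # volts → microvolts
    return TrialRecording(
        subject_id=meta["subject_id"], condition=meta["condition"],
        trial_index=meta["trial_index"], global_trial_index=meta["global_trial_index"],
        channel_labels=tuple(picks), sampling_rate=float(raw.info["sfreq"]), samples=data,
    )


def load_cohort(manifest_path: str | Path) -> list[TrialRecording]:
    """Read a cohort back from a manifest written by :func:`save_cohort`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    out: list[TrialRecording] = []
    for row in pd.read_csv(manifest_path).itertuples():
        path = base / str(row.path)
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        else:
            meta = {"subject_id": str(row.subject), "condition": str(row.condition),
                    "trial_index": int(row.trial), "global_trial_index": int(row.global_trial)}
        if path.suffix.lower() == ".edf":
            out.append(_load_trial_edf(path, meta))
        else:
            out.append(_load_trial_csv(path, meta))
    return out
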