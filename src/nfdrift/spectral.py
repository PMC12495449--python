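"""Welch band power in decibels and its pooled z-standardization.

Per-trial power spectral densities are estimated by averaged Hamming-windowed
periodograms: the signal is split into the longest segments giving at most
``max_segments`` segments at the configured overlap (8 at 50% by default, so a
57-s trial yields exactly 8 segments), each segment is detrended, tapered and
Fourier transformed, and the periodograms are averaged into a density in
µV²/Hz.  Densities are mapped to dB (10·log10) to approximate normality and
reduced to four band means — theta 4–8, alpha 8–12, SMR 12–15, beta
15–30 Hz — over half-open bins [low, high), so no frequency bin is counted in
two bands.  Band powers are finally z-scored per (electrode, band), pooled
over all subjects, conditions and trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .recording import TrialRecording

#: Canonical band edges in Hz, half-open [low, high).
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "smr": (12.0, 15.0),
    "beta": (15.0, 30.0),
}

#: dB floor applied before log-transform (µV²/Hz).
POWER_FLOOR = 1e-12


class SpectralError(ValueError):
    pass


@dataclass(frozen=True)
class SpectralConfig:
    max_segments: int = 8
    overlap_fraction: float = 0.5
    window: str = "hamming"
    bin_spacing: float = 0.305
    detrend: str | bool = "constant"

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_fraction < 1):
            raise SpectralError("overlap_fraction must be in [0, 1)")
        if self.max_segments < 1:
            raise SpectralError("max_segments must be >= 1")
        if self.bin_spacing <= 0:
            raise SpectralError("bin_spacing must be positive")

    def segment_length(self, n_samples: int) -> int:
        """Longest segment length yielding <= max_segments at the overlap."""
        denom = 1.0 + (self.max_segments - 1) * (1.0 - self.overlap_fraction)
        return max(1, int(n_samples / denom))

    def n_segments(self, n_samples: int) -> int:
        nperseg = self.segment_length(n_samples)
        step = nperseg - int(nperseg * self.overlap_fraction)
        return 1 + (n_samples - nperseg) // step

    def nfft(self, n_samples: int, fs: float) -> int:
        # the reporting grid cannot be coarser than the natural segment grid;
        # zero-padding only ever refines it
        return max(self.segment_length(n_samples), math.ceil(fs / self.bin_spacing))


@dataclass
class PSD:
    """One channel's power spectral density with its provenance."""

    frequencies: np.ndarray  # Hz, 0..Nyquist
    power: np.ndarray        # µV²/Hz (or dB after to_db)
    metadata: dict = field(default_factory=dict)
    in_db: bool = False

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise SpectralError("frequency grid and power must align")


def welch_psd(recording: TrialRecording, config: SpectralConfig | None = None) -> dict[str, PSD]:
    """Averaged-periodogram PSD per channel (density scaling, µV²/Hz)."""
    config = config or SpectralConfig()
    n = recording.n_samples
    fs = recording.sampling_rate
    nperseg = config.segment_length(n)
    if n < nperseg or nperseg < 8:
        raise SpectralError(
            f"trial {recording.subject_id}/{recording.condition}/t{recording.trial_index} "
            "too short for one Welch segment"
        )
    freqs, pxx = signal.welch(
        recording.samples, fs=fs, window=config.window, nperseg=nperseg,
        noverlap=int(nperseg * config.overlap_fraction),
        nfft=config.nfft(n, fs),
        detrend=config.detrend, scaling="density", axis=-1,
    )
    meta_common = recording.meta()
    meta_common["n_segments"] = config.n_segments(n)
    out = {}
    for i, ch in enumerate(recording.channel_labels):
        md = dict(meta_common, electrode=ch, config=config)
        out[ch] = PSD(frequencies=freqs, power=pxx[i], metadata=md)
    return out


def to_db(psd: PSD) -> PSD:
    """10·log10 of power, with a 1e-12 µV²/Hz floor so zeros stay finite."""
    if psd.in_db:
        return psd
    power_db = 10.0 * np.log10(np.maximum(psd.power, POWER_FLOOR))
    return PSD(psd.frequencies, power_db, dict(psd.metadata), in_db=True)


def band_power(psd_db: PSD, band_edges: tuple[float, float]) -> float:
    """Arithmetic mean of dB bins with low <= f < high."""
    low, high = band_edges
    mask = (psd_db.frequencies >= low) & (psd_db.frequencies < high)
    if not mask.any():
        raise SpectralError(f"no frequency bins inside band [{low}, {high})")
    return float(psd_db.power[mask].mean())


def band_power_table(recordings: list[TrialRecording],
                     config: SpectralConfig | None = None,
                     bands: dict[str, tuple[float, float]] | None = None) -> pd.DataFrame:
    """Tidy band-power table: one row per trial × electrode × band (dB)."""
    config = config or SpectralConfig()
    bands = bands or BANDS
    rows = []
    for rec in recordings:
        psds = welch_psd(rec, config)
        for ch, psd in psds.items():
            psd_db = to_db(psd)
            for band, edges in bands.items():
                rows.append({
                    "subject": rec.subject_id, "condition": rec.condition,
                    "trial_index": rec.trial_index,
                    "global_trial_index": rec.global_trial_index,
                    "electrode": ch, "band": band,
                    "power_db": band_power(psd_db, edges),
                })
    return pd.DataFrame(rows)


def save_psds_hdf5(psds: dict[str, PSD], path) -> None:
    """Optionally persist per-channel PSDs (frequency grid + power) to HDF5."""
    import h5py

    with h5py.File(path, "a") as f:
        for ch, psd in psds.items():
            meta = psd.metadata
            name = (f"{meta.get('subject_id', 'unknown')}/{meta.get('condition', 'na')}"
                    f"/t{meta.get('trial_index', 0):02d}/{ch}")
            grp = f.require_group(name)
            for key in ("frequencies", "power"):
                if key in grp:
                    del grp[key]
            grp.create_dataset("frequencies", data=psd.frequencies)
            grp.create_dataset("power", data=psd.power)
            grp.attrs["in_db"] = psd.in_db


def zscore_powers(records: pd.DataFrame,
                  group_cols: tuple[str, ...] = ("electrode", "band")) -> pd.DataFrame:
    """Fill ``power_z``: z-scores pooled across subjects within each group.

    Each (electrode, band) group — pooled over all subjects, conditions and
    trials — ends up with mean 0 and SD 1 (ddof=0).
    """
    df = records.copy()

    def _z(g: pd.Series) -> pd.Series:
        if len(g) < 2:
            raise SpectralError("standardization groups need >= 2 records")
        sd = g.std(ddof=0)
        if sd == 0:
            raise SpectralError("zero-variance standardization group")
        return (g - g.mean()) / sd

    df["power_z"] = df.groupby(list(group_cols), group_keys=False)["power_db"].transform(_z)
    return df
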