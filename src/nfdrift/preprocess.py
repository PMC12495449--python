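"""Per-trial EEG conditioning: zero-phase filtering, edge trimming, artifact stage.

The chain mirrors standard narrowband neurofeedback preprocessing: a 6th-order
Butterworth high-pass at 0.5 Hz plus a 2nd-order IIR notch at the mains
frequency, both applied forward-backward so phase relationships are preserved,
followed by removal of the first 2 s and last 1 s of each trial to discard
filter transients (60 s → 57 s).  Ocular-component removal is a pluggable
stage: component selection is inherently manual/visual, so the default remover
is the identity and real-data users supply their own decomposition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import signal

from .recording import TrialRecording


class PreprocessingError(ValueError):
    pass


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase high-pass + notch specification.

    ``notch_q`` sets the notch bandwidth (bw = notch_freq / Q); the default
    Q = 35 gives ≈ 1.4 Hz around 50 Hz.
    """

    highpass_cutoff: float = 0.5
    highpass_order: int = 6
    notch_freq: float = 50.0
    notch_order: int = 2
    notch_q: float = 35.0

    def __post_init__(self) -> None:
        if self.highpass_order < 1 or self.notch_order < 1:
            raise PreprocessingError("filter orders must be >= 1")
        if self.highpass_cutoff <= 0 or self.notch_freq <= 0:
            raise PreprocessingError("cutoff frequencies must be positive")

    def highpass_sos(self, fs: float) -> np.ndarray:
        if self.highpass_cutoff >= fs / 2 or self.notch_freq >= fs / 2:
            raise PreprocessingError("cutoffs must lie strictly inside (0, Nyquist)")
        return signal.butter(self.highpass_order, self.highpass_cutoff,
                             btype="highpass", fs=fs, output="sos")

    def notch_ba(self, fs: float) -> tuple[np.ndarray, np.ndarray]:
        if self.notch_freq >= fs / 2:
            raise PreprocessingError("notch frequency must lie strictly below Nyquist")
        # iirnotch is the canonical 2nd-order notch; higher orders are cascaded
        b, a = signal.iirnotch(self.notch_freq, self.notch_q, fs=fs)
        n_cascades = max(1, self.notch_order // 2)
        bb, aa = b, a
        for _ in range(n_cascades - 1):
            bb, aa = np.convolve(bb, b), np.convolve(aa, a)
        return bb, aa

    def response_db(self, freq: float, fs: float) -> float:
        """Designed end-to-end magnitude response (dB) at ``freq`` for the
        forward-backward application (magnitude squared)."""
        w = 2 * math.pi * freq / fs
        _, h_hp = signal.sosfreqz(self.highpass_sos(fs), worN=[w])
        b, a = self.notch_ba(fs)
        _, h_n = signal.freqz(b, a, worN=[w])
        mag = (np.abs(h_hp[0]) * np.abs(h_n[0])) ** 2  # filtfilt squares the response
        return float(20 * np.log10(max(mag, 1e-300)))


@dataclass(frozen=True)
class TrimSpec:
    head_trim: float = 2.0
    tail_trim: float = 1.0

    def __post_init__(self) -> None:
        if self.head_trim < 0 or self.tail_trim < 0:
            raise PreprocessingError("trims must be non-negative")


def zero_phase_filter(recording: TrialRecording, spec: FilterSpec | None = None) -> TrialRecording:
    """Forward-backward high-pass + notch on every channel (phase preserving)."""
    spec = spec or FilterSpec()
    fs = recording.sampling_rate
    min_len = 3 * (max(spec.highpass_order, spec.notch_order) + 1)
    if recording.n_samples <= min_len:
        raise PreprocessingError(
            f"trial {recording.subject_id}/{recording.condition}/t{recording.trial_index} "
            f"too short ({recording.n_samples} samples) for stable zero-phase filtering"
        )
    sos = spec.highpass_sos(fs)
    b, a = spec.notch_ba(fs)
    x = signal.sosfiltfilt(sos, recording.samples, axis=-1)
    x = signal.filtfilt(b, a, x, axis=-1)
    return recording.with_samples(x)


def trim_trial(recording: TrialRecording, spec: TrimSpec | None = None) -> TrialRecording:
    """Drop head/tail seconds, sample-accurately: keep [round(h·fs), N − round(t·fs))."""
    spec = spec or TrimSpec()
    fs = recording.sampling_rate
    head = round(spec.head_trim * fs)
    tail = round(spec.tail_trim * fs)
    if head + tail >= recording.n_samples:
        raise PreprocessingError(
            f"trial {recording.subject_id}/{recording.condition}/t{recording.trial_index}: "
            f"duration {recording.duration:.2f}s too short for trims "
            f"({spec.head_trim}+{spec.tail_trim}s)"
        )
    return recording.with_samples(recording.samples[:, head:recording.n_samples - tail])


Remover = Callable[[TrialRecording], TrialRecording]


def identity_remover(recording: TrialRecording) -> TrialRecording:
    return recording


def remove_artifact_components(recording: TrialRecording,
                               remover: Remover = identity_remover) -> TrialRecording:
    """Pluggable artifact-removal stage (identity by default)."""
    try:
        out = remover(recording)
    except Exception as exc:  # propagate with trial context
        raise PreprocessingError(
            f"artifact remover failed on trial {recording.subject_id}/"
            f"{recording.condition}/t{recording.trial_index}: {exc}"
        ) from exc
    if out.samples.shape != recording.samples.shape:
        raise PreprocessingError("artifact remover changed the recording shape")
    return out


def regression_remover(reference: np.ndarray) -> Remover:
    """Remover that least-squares-projects known artifact time courses out of
    every channel (the regression alternative to manual component selection).

    ``reference`` is (n_components, n_times) or (n_times,).  The number of
    components removed is logged per trial.
    """
    ref = np.atleast_2d(np.asarray(reference, dtype=float))

    def _remove(recording: TrialRecording) -> TrialRecording:
        if ref.shape[1] != recording.n_samples:
            raise ValueError("artifact reference length does not match the trial")
        design = ref.T  # times × components
        coef, *_ = np.linalg.lstsq(design, recording.samples.T, rcond=None)
        cleaned = recording.samples - (design @ coef).T
        logging.getLogger(__name__).info(
            "removed %d artifact component(s) from %s/%s/t%d",
            ref.shape[0], recording.subject_id, recording.condition, recording.trial_index)
        return recording.with_samples(cleaned)

    _remove.n_components = ref.shape[0]  # type: ignore[attr-defined]
    return _remove


def preprocess_trial(recording: TrialRecording,
                     filter_spec: FilterSpec | None = None,
                     trim_spec: TrimSpec | None = None,
                     remover: Remover = identity_remover) -> TrialRecording:
    """filter → trim (deletes the filter transients) → artifact stage."""
    rec = zero_phase_filter(recording, filter_spec)
    rec = trim_trial(rec, trim_spec)
    return remove_artifact_components(rec, remover)
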