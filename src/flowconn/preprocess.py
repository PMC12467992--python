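"""Raw-EEG conditioning for the classifier track: trim, resample, filter, segment."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

SUPPORTED_RATES = (250.0, 500.0)


@dataclass
class RawRecording:
    """One participant's multichannel recording.

    ``signal`` is ``(n_channels, n_samples)``; 64 channels at 250 or 500 Hz
    in the study configuration, at least 30 s long.
    """

    signal: np.ndarray
    fs: float
    participant_id: str = ""
    label: str | None = None

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be (n_channels, n_samples)")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def validate(self, n_channels: int = 64, min_duration: float = 30.0) -> "RawRecording":
        if self.n_channels != n_channels:
            raise ValueError(
                f"expected {n_channels} channels, got {self.n_channels}")
        if self.fs not in SUPPORTED_RATES:
            raise ValueError(
                f"unsupported sampling rate {self.fs} Hz; allowed: "
                f"{SUPPORTED_RATES}")
        if self.duration < min_duration:
            raise ValueError(
                f"recording too short: {self.duration:.1f} s < {min_duration} s")
        return self


@dataclass
class Epoch:
    """Fixed-length segment of a preprocessed recording (one classifier sample)."""

    segment: np.ndarray
    participant_id: str
    label: str | None = None


def preprocess_recording(rec: RawRecording, trim_s: float = 4.0,
                         target_fs: float = 250.0, cutoff_hz: float = 100.0,
                         order: int = 5, zero_phase: bool = False) -> RawRecording:
    """Trim transient edges, resample to a uniform rate, low-pass filter.

    Mirrors the acquisition-uniformization chain: ``trim_s`` seconds are cut
    at each end, the signal is resampled to ``target_fs`` with an
    anti-aliased polyphase resampler, and an ``order``-th order Butterworth
    low-pass at ``cutoff_hz`` is applied.  The filter is causal (forward
    only) by default; ``zero_phase`` switches to filtfilt.
    """
    if rec.duration <= 2 * trim_s:
        raise ValueError(
            f"recording of {rec.duration:.1f} s too short to trim "
            f"{trim_s} s at each end")
    n_trim = int(round(trim_s * rec.fs))
    x = rec.signal[:, n_trim: rec.n_samples - n_trim]

    if rec.fs != target_fs:
        up = int(target_fs)
        down = int(rec.fs)
        g = np.gcd(up, down)
        x = signal.resample_poly(x, up // g, down // g, axis=-1)

    sos = signal.butter(order, cutoff_hz, btype="low", fs=target_fs,
                        output="sos")
    if zero_phase:
        x = signal.sosfiltfilt(sos, x, axis=-1)
    else:
        x = signal.sosfilt(sos, x, axis=-1)
    return RawRecording(signal=x, fs=target_fs,
                        participant_id=rec.participant_id, label=rec.label)


def segment_epochs(rec: RawRecording, epoch_len_s: float = 10.0) -> list:
    """Non-overlapping contiguous epochs from the start; trailing remainder dropped."""
    n_per = int(round(epoch_len_s * rec.fs))
    n_epochs = rec.n_samples // n_per
    if n_epochs == 0:
        warnings.warn(
            f"recording '{rec.participant_id}' shorter than one "
            f"{epoch_len_s} s epoch; returning no epochs", RuntimeWarning,
            stacklevel=2)
        return []
    return [Epoch(segment=rec.signal[:, k * n_per:(k + 1) * n_per],
                  participant_id=rec.participant_id, label=rec.label)
            for k in range(n_epochs)]
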