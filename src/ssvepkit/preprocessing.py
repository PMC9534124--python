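"""Recording container and the downsample → bandpass → epoch chain.

The analysis chain mirrors a standard SSVEP pipeline: decimate the raw
recording (2048 Hz acquisition) to 256 Hz, bandpass 2-54 Hz with a
zero-phase Butterworth filter, then cut epochs starting 0.135 s after
each stimulus onset to absorb the visual-pathway latency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy import signal

from .errors import ConfigurationError, EpochTruncationError, UnsupportedRateError

__all__ = [
    "Event",
    "EEGRecording",
    "Epoch",
    "downsample",
    "bandpass",
    "epoch_extract",
    "preprocess",
    "DEFAULT_LATENCY_S",
]

#: Visual-pathway response latency (s) applied between stimulus onset and
#: epoch start. A literature value; override per hardware if needed.
DEFAULT_LATENCY_S = 0.135

#: Electrode montage used in the study (parieto-occipital, 8 channels).
DEFAULT_CHANNELS = ("O1", "Oz", "O2", "PO7", "PO3", "POz", "PO4", "PO8")


class Event(NamedTuple):
    """Stimulus onset marker: sample index and target frequency label."""

    onset_sample: int
    target_hz: float


@dataclass
class EEGRecording:
    """Continuous multichannel EEG with an event table.

    ``data`` is channels x samples; ``events`` mark trial onsets with
    their target stimulation frequency.
    """

    data: np.ndarray = field(repr=False)
    fs: float
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    events: tuple[Event, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.channel_names = tuple(self.channel_names)
        self.events = tuple(Event(int(o), float(f)) for o, f in self.events)
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")
        if self.data.shape[0] != len(self.channel_names):
            raise ConfigurationError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_names)} channel names"
            )
        n = self.data.shape[1]
        for ev in self.events:
            if not 0 <= ev.onset_sample < n:
                raise ConfigurationError(f"event onset {ev.onset_sample} out of bounds")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class Epoch:
    """One trial's windowed EEG segment with its target label."""

    data: np.ndarray = field(repr=False)
    fs: float
    window_s: float
    target_frequency_hz: float

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def downsample(rec: EEGRecording, target_fs: float) -> EEGRecording:
    """Anti-alias filter and decimate to ``target_fs`` (integer factor).

    Uses polyphase resampling; event onsets are rescaled by the factor.
    """
    factor = rec.fs / target_fs
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise UnsupportedRateError(
            f"{rec.fs} Hz is not an integer multiple of {target_fs} Hz"
        )
    factor = int(round(factor))
    if factor == 1:
        return rec
    data = signal.resample_poly(rec.data, up=1, down=factor, axis=1)
    events = tuple(
        Event(int(round(ev.onset_sample / factor)), ev.target_hz) for ev in rec.events
    )
    return replace(rec, data=data, fs=target_fs, events=events)


def bandpass(
    rec: EEGRecording, low: float = 2.0, high: float = 54.0, order: int = 6
) -> EEGRecording:
    """Zero-phase Butterworth bandpass, applied forward-backward per channel.

    ``order`` is the design order of the underlying filter; the
    forward-backward pass doubles the effective magnitude order and
    cancels the phase response, so in-band sinusoids come out with zero
    lag.
    """
    if not 0 < low < high:
        raise ConfigurationError("need 0 < low < high")
    if high >= rec.fs / 2:
        raise ConfigurationError(f"high cutoff {high} Hz >= Nyquist {rec.fs / 2} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=data)


def epoch_extract(
    rec: EEGRecording,
    window_s: float,
    latency_s: float = DEFAULT_LATENCY_S,
) -> list[Epoch]:
    """Cut one epoch per event, offset by the visual latency.

    Each epoch covers the half-open sample range
    [round(onset + latency * fs), +round(window * fs)) and carries the
    event's target-frequency label. Epochs running past the end of the
    recording raise :class:`EpochTruncationError`; nothing is padded.
    """
    if window_s <= 0:
        raise ConfigurationError("window_s must be positive")
    n_epoch = int(round(window_s * rec.fs))
    epochs = []
    for ev in rec.events:
        start = int(round(ev.onset_sample + latency_s * rec.fs))
        stop = start + n_epoch
        if stop > rec.n_samples:
            raise EpochTruncationError(
                f"epoch [{start}, {stop}) exceeds recording length {rec.n_samples}"
            )
        epochs.append(
            Epoch(
                data=rec.data[:, start:stop].copy(),
                fs=rec.fs,
                window_s=window_s,
                target_frequency_hz=ev.target_hz,
            )
        )
    return epochs


def preprocess(
    rec: EEGRecording,
    target_fs: float = 256.0,
    low: float = 2.0,
    high: float = 54.0,
    order: int = 6,
) -> EEGRecording:
    """Downsample (if needed) then bandpass — the standard chain before epoching."""
    if rec.fs != target_fs:
        rec = downsample(rec, target_fs)
    return bandpass(rec, low=low, high=high, order=order)
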