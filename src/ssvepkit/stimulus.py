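"""Temporal profiles of the eight hybrid visual stimuli.

A hybrid stimulus combines a conventional SSVEP driver — a flickering
stimulus (FS, luminance square wave) or a pattern-reversal stimulus
(PRS, checkerboard-style reversals) — with a periodic size modulation
("motion") whose waveform is one of none / square / triangular / sine.
The nominal frequency f counts full on-off cycles per second for FS and
reversals per second for PRS; consequently the motion runs at f for FS
and at f/2 for PRS, so PRS hybrids drive a subharmonic (f/2) response.

Profiles are evaluated in continuous time and frame-quantized at the
monitor refresh rate, mirroring what an LCD actually presents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "BaseKind",
    "MotionWaveform",
    "StimulusSpec",
    "FrameSequence",
    "motion_frequency",
    "size_profile",
    "binary_state",
    "render_frame_table",
    "enumerate_stimuli",
]


class BaseKind(str, Enum):
    """Base stimulus type: luminance flicker or pattern reversal."""

    FS = "FS"
    PRS = "PRS"


class MotionWaveform(str, Enum):
    """Waveform of the periodic size modulation."""

    NONE = "none"
    SQUARE = "square"
    TRIANGULAR = "triangular"
    SINE = "sine"


#: Waveform order used everywhere a deterministic ordering is needed.
WAVEFORM_ORDER = (
    MotionWaveform.NONE,
    MotionWaveform.SQUARE,
    MotionWaveform.TRIANGULAR,
    MotionWaveform.SINE,
)


@dataclass(frozen=True)
class StimulusSpec:
    """One hybrid visual stimulus.

    Parameters
    ----------
    base_kind
        FS (flicker) or PRS (pattern reversal).
    motion_waveform
        Size-modulation waveform.
    stim_frequency_hz
        Nominal stimulation frequency f (cycles/s for FS, reversals/s
        for PRS). The study used 6, 6.67, 7.5 and 10 Hz.
    refresh_rate_hz
        Monitor refresh rate; 60 Hz in the study.
    modulation_ratio
        Peak relative size deviation r; radius spans [1 - r, 1 + r].
    base_size_deg
        Base stimulus size in degrees of visual angle (informational).
    """

    base_kind: BaseKind
    motion_waveform: MotionWaveform
    stim_frequency_hz: float
    refresh_rate_hz: float = 60.0
    modulation_ratio: float = 0.33
    base_size_deg: float = 5.7

    def __post_init__(self) -> None:
        object.__setattr__(self, "base_kind", BaseKind(self.base_kind))
        object.__setattr__(
            self, "motion_waveform", MotionWaveform(self.motion_waveform)
        )
        if self.stim_frequency_hz <= 0:
            raise ConfigurationError("stim_frequency_hz must be positive")
        if self.refresh_rate_hz <= 0:
            raise ConfigurationError("refresh_rate_hz must be positive")
        if self.stim_frequency_hz >= self.refresh_rate_hz / 2:
            raise ConfigurationError(
                "stim_frequency_hz must be below half the refresh rate"
            )
        if not 0 < self.modulation_ratio < 1:
            raise ConfigurationError("modulation_ratio must lie in (0, 1)")
        if self.base_size_deg <= 0:
            raise ConfigurationError("base_size_deg must be positive")

    @property
    def name(self) -> str:
        """Human-readable label, e.g. ``FS-Sine``."""
        return f"{self.base_kind.value}-{self.motion_waveform.value.capitalize()}"


@dataclass(frozen=True)
class FrameSequence:
    """Frame-quantized stimulus profile at the monitor refresh rate."""

    frame_times: np.ndarray = field(repr=False)
    binary_state: np.ndarray = field(repr=False)
    relative_radius: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not (
            len(self.frame_times)
            == len(self.binary_state)
            == len(self.relative_radius)
        ):
            raise ConfigurationError("frame table columns must have equal length")

    def __len__(self) -> int:
        return len(self.frame_times)


def motion_frequency(spec: StimulusSpec) -> float:
    """Frequency of the periodic size modulation in Hz.

    FS hybrids move at the stimulation frequency; PRS hybrids move at
    half of it, which places their motion response at the subharmonic
    of the reversal frequency.
    """
    if spec.base_kind is BaseKind.FS:
        return spec.stim_frequency_hz
    return spec.stim_frequency_hz / 2.0


def size_profile(waveform, f_m: float, r: float, t) -> np.ndarray:
    """Relative stimulus radius at time(s) ``t`` for a motion waveform.

    All periodic waveforms span [1 - r, 1 + r] with period 1/f_m:

    * ``none`` — constant 1 (no motion),
    * ``square`` — enlarged (1 + r) for the first half period, shrunk
      (1 - r) for the second,
    * ``triangular`` — linear ramp from 1 - r up to 1 + r over the first
      half period, back down over the second,
    * ``sine`` — 1 + r sin(2π f_m t), starting at the base size.
    """
    waveform = MotionWaveform(waveform)
    t = np.asarray(t, dtype=float)
    if f_m <= 0:
        raise ConfigurationError("motion frequency must be positive")
    if not 0 < r < 1:
        raise ConfigurationError("modulation ratio must lie in (0, 1)")

    if waveform is MotionWaveform.NONE:
        return np.ones_like(t)
    phase = (t * f_m) % 1.0
    if waveform is MotionWaveform.SQUARE:
        return np.where(phase < 0.5, 1.0 + r, 1.0 - r)
    if waveform is MotionWaveform.TRIANGULAR:
        tri = np.where(phase < 0.5, 2.0 * phase, 2.0 * (1.0 - phase))
        return 1.0 - r + 2.0 * r * tri
    # sine
    return 1.0 + r * np.sin(2.0 * np.pi * f_m * t)


def binary_state(spec: StimulusSpec, t) -> np.ndarray:
    """Flicker / pattern state in {0, 1} at time(s) ``t``.

    FS toggles 2f times per second (a full on-off cycle every 1/f s);
    PRS reverses f times per second (full pattern period 2/f s). The
    state is 1 on [0, 1/rate) and follows the parity of floor(rate * t),
    a left-closed convention that is deterministic at frame boundaries.
    """
    t = np.asarray(t, dtype=float)
    rate = (
        2.0 * spec.stim_frequency_hz
        if spec.base_kind is BaseKind.FS
        else spec.stim_frequency_hz
    )
    return (np.floor(rate * t).astype(np.int64) % 2 == 0).astype(np.int8)


def render_frame_table(spec: StimulusSpec, duration_s: float) -> FrameSequence:
    """Sample the stimulus at frame instants k / refresh_rate.

    Produces floor(duration * refresh) frames. The size profile is
    driven at :func:`motion_frequency`, i.e. halved for PRS hybrids.
    """
    if duration_s <= 0:
        raise ConfigurationError("duration must be positive")
    n_frames = int(np.floor(duration_s * spec.refresh_rate_hz + 1e-9))
    k = np.arange(n_frames)
    times = k / spec.refresh_rate_hz
    f_m = motion_frequency(spec)
    return FrameSequence(
        frame_times=times,
        binary_state=binary_state(spec, times),
        relative_radius=size_profile(
            spec.motion_waveform, f_m, spec.modulation_ratio, times
        ),
    )


def enumerate_stimuli(
    frequency_hz: float,
    refresh_rate_hz: float = 60.0,
    modulation_ratio: float = 0.33,
) -> list[StimulusSpec]:
    """The eight hybrid stimuli at one frequency, in canonical order.

    Order: FS then PRS, each with waveforms none, square, triangular,
    sine — so the first element is FS-None and the last PRS-Sine.
    """
    return [
        StimulusSpec(
            base_kind=kind,
            motion_waveform=wave,
            stim_frequency_hz=frequency_hz,
            refresh_rate_hz=refresh_rate_hz,
            modulation_ratio=modulation_ratio,
        )
        for kind in (BaseKind.FS, BaseKind.PRS)
        for wave in WAVEFORM_ORDER
    ]
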