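"""Synthetic SSVEP/SSMVEP session generator.

Emulates the spectral structure of steady-state responses to the hybrid
stimuli: sinusoidal components at the harmonics h*f (h = 1..5) of the
stimulation frequency, optionally a subharmonic component at f/2
(pattern-reversal hybrids, whose size modulation runs at half the
reversal rate), embedded in 1/f^alpha background noise across an
8-channel parieto-occipital montage. The evoked response starts 0.135 s
after stimulus onset, matching the visual-pathway latency used when
epoching.

The generator is fully seeded: one `numpy` Generator drives class
order, per-trial component phases, and the noise, so a session is
bit-reproducible from its config.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigurationError, ResolutionWarning
from .preprocessing import DEFAULT_CHANNELS, EEGRecording, Epoch, Event

__all__ = [
    "SimulationConfig",
    "SimulatedSession",
    "generate_trial",
    "generate_session",
    "estimate_component_amplitudes",
]

DEFAULT_FREQUENCIES = (6.0, 6.67, 7.5, 10.0)

#: Harmonic amplitude profile (arbitrary uV-scale units): dominant
#: fundamental, decaying harmonics — the shape reported for flicker
#: responses at occipital electrodes.
FS_AMPLITUDES = {1: 1.0, 2: 0.6, 3: 0.3, 4: 0.15, 5: 0.1}

#: Subharmonic amplitude added for pattern-reversal hybrid stimuli. The
#: size modulation at f/2 is a motion stimulus in its own right, so its
#: steady-state response is a main component on par with the fundamental,
#: not a weak harmonic.
SUBHARMONIC_AMPLITUDE = 1.0

#: Posterior-gradient channel gains: strongest at Oz, weaker laterally.
DEFAULT_CHANNEL_GAINS = (0.8, 1.0, 0.8, 0.5, 0.65, 0.85, 0.65, 0.5)

#: Band over which noise power is measured when converting SNR to sigma.
SNR_BAND = (1.0, 54.0)

OZ_INDEX = DEFAULT_CHANNELS.index("Oz")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated session.

    Defaults reproduce the experimental layout: four stimulation
    frequencies (6, 6.67, 7.5, 10 Hz), 5 trials per class, 5 s
    stimulation with a 3 s cue gap, 8 channels, 0.135 s latency.
    ``include_subharmonic`` selects the pattern-reversal-hybrid signal
    model (adds the f/2 component). ``snr_db``, when set, overrides
    ``noise_sigma`` so that component power over noise power in the
    1-54 Hz band at the Oz-equivalent channel equals the requested SNR.
    """

    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    component_amplitudes: Mapping[float, float] | None = None
    include_subharmonic: bool = False
    noise_alpha: float = 1.0
    noise_sigma: float = 2.5
    common_mode_fraction: float = 0.6
    snr_db: float | None = None
    latency_s: float = 0.135
    channel_gains: tuple[float, ...] = DEFAULT_CHANNEL_GAINS
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    phases: Mapping[float, float] | None = None
    fs: float = 256.0
    trial_s: float = 5.0
    inter_trial_gap_s: float = 3.0
    n_trials_per_class: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.channel_gains) != len(self.channel_names):
            raise ConfigurationError("channel_gains and channel_names length mismatch")
        if self.noise_alpha < 0 or self.noise_sigma < 0:
            raise ConfigurationError("noise parameters must be non-negative")
        if not 0.0 <= self.common_mode_fraction <= 1.0:
            raise ConfigurationError("common_mode_fraction must lie in [0, 1]")
        if self.trial_s <= 0 or self.fs <= 0 or self.n_trials_per_class < 1:
            raise ConfigurationError("invalid timing configuration")
        for h, amp in self.amplitudes.items():
            if amp < 0:
                raise ConfigurationError("component amplitudes must be >= 0")
            for f in self.frequencies:
                if amp > 0 and h * f >= self.fs / 2:
                    raise ConfigurationError(
                        f"component {h}x{f} Hz at or above Nyquist ({self.fs / 2} Hz)"
                    )

    @property
    def amplitudes(self) -> dict[float, float]:
        """Resolved component amplitude map (harmonic index -> amplitude)."""
        if self.component_amplitudes is not None:
            return {float(h): float(a) for h, a in self.component_amplitudes.items()}
        amps = {float(h): a for h, a in FS_AMPLITUDES.items()}
        if self.include_subharmonic:
            amps[0.5] = SUBHARMONIC_AMPLITUDE
        return amps

    @property
    def sigma(self) -> float:
        """Noise scale actually used (derived from ``snr_db`` when set)."""
        if self.snr_db is None:
            return self.noise_sigma
        gains = np.asarray(self.channel_gains)
        oz_gain = gains[OZ_INDEX] if len(gains) > OZ_INDEX else gains.max()
        sig_power = oz_gain**2 * sum(a**2 / 2 for a in self.amplitudes.values())
        if sig_power == 0:
            raise ConfigurationError("snr_db requires at least one nonzero amplitude")
        n_ref = int(round(self.trial_s * self.fs))
        frac = _band_power_fraction(n_ref, self.fs, self.noise_alpha, SNR_BAND)
        return float(np.sqrt(sig_power / (frac * 10.0 ** (self.snr_db / 10.0))))


@dataclass(frozen=True)
class SimulatedSession:
    """A generated recording plus its ground-truth labels and config echo."""

    recording: EEGRecording
    truth: tuple[float, ...]
    config: SimulationConfig


def _spectral_shape(n_samples: int, fs: float, alpha: float) -> np.ndarray:
    """Amplitude shaping |H(f)| ~ f^(-alpha/2) on the rfft grid (DC removed)."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-alpha / 2.0)
    return shape


def _band_power_fraction(
    n_samples: int, fs: float, alpha: float, band: tuple[float, float]
) -> float:
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape2 = _spectral_shape(n_samples, fs, alpha) ** 2
    total = shape2.sum()
    in_band = shape2[(freqs >= band[0]) & (freqs <= band[1])].sum()
    return float(in_band / total)


def pink_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    fs: float,
    alpha: float = 1.0,
) -> np.ndarray:
    """Unit-variance 1/f^alpha noise, independent per channel.

    White Gaussian noise is shaped in the frequency domain and each
    channel re-normalized to unit sample variance, so a caller's sigma
    multiplies through directly.
    """
    white = rng.standard_normal((n_channels, n_samples))
    if alpha == 0:
        return white / white.std(axis=1, keepdims=True)
    spec = np.fft.rfft(white, axis=1) * _spectral_shape(n_samples, fs, alpha)
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    return x / x.std(axis=1, keepdims=True)


def _background_noise(
    cfg: SimulationConfig, rng: np.random.Generator, n_samples: int
) -> np.ndarray:
    """Pink background with a spatially correlated (common-mode) fraction.

    EEG background activity is strongly correlated across neighbouring
    electrodes; a rank-one common component with fraction c plus
    independent residuals reproduces that while keeping each channel at
    unit variance, so ``cfg.sigma`` scales through directly.
    """
    n_ch = len(cfg.channel_gains)
    c = cfg.common_mode_fraction
    ind = pink_noise(rng, n_ch, n_samples, cfg.fs, cfg.noise_alpha)
    if c == 0.0:
        return ind
    common = pink_noise(rng, 1, n_samples, cfg.fs, cfg.noise_alpha)
    return np.sqrt(1.0 - c**2) * ind + c * common


def _signal_block(
    cfg: SimulationConfig,
    target_f: float,
    rng: np.random.Generator,
    n_samples: int,
) -> np.ndarray:
    """Gain-weighted harmonic sum for one trial; silent before the latency."""
    t = np.arange(n_samples) / cfg.fs
    active = t >= cfg.latency_s
    ts = t - cfg.latency_s
    gains = np.asarray(cfg.channel_gains)[:, None]
    sig = np.zeros(n_samples)
    for h, amp in sorted(cfg.amplitudes.items()):
        if amp == 0:
            continue
        phase = (
            float(cfg.phases.get(h, 0.0))
            if cfg.phases is not None
            else rng.uniform(0.0, 2.0 * np.pi)
        )
        sig = sig + amp * np.sin(2.0 * np.pi * h * target_f * ts + phase) * active
    return gains * sig[None, :]


def generate_trial(
    cfg: SimulationConfig, target_f: float, rng: np.random.Generator
) -> np.ndarray:
    """One stimulation trial (channels x samples): signal plus pink noise."""
    if float(target_f) not in [float(f) for f in cfg.frequencies]:
        raise ConfigurationError(f"{target_f} Hz is not in the candidate set")
    n = int(round(cfg.trial_s * cfg.fs))
    out = _signal_block(cfg, float(target_f), rng, n)
    if cfg.sigma > 0:
        out = out + cfg.sigma * _background_noise(cfg, rng, n)
    return out


def generate_session(cfg: SimulationConfig) -> SimulatedSession:
    """A full session: shuffled balanced trials separated by cue-length gaps.

    The background noise runs continuously through gaps and trials;
    evoked components are added from 0.135 s after each onset. The event
    table records every onset sample with its target frequency.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = np.repeat(np.asarray(cfg.frequencies, dtype=float), cfg.n_trials_per_class)
    rng.shuffle(labels)

    n_trial = int(round(cfg.trial_s * cfg.fs))
    n_gap = int(round(cfg.inter_trial_gap_s * cfg.fs))
    n_total = len(labels) * (n_gap + n_trial)
    n_ch = len(cfg.channel_gains)

    data = np.zeros((n_ch, n_total))
    if cfg.sigma > 0:
        data += cfg.sigma * _background_noise(cfg, rng, n_total)

    events = []
    for i, f in enumerate(labels):
        onset = n_gap + i * (n_gap + n_trial)
        data[:, onset : onset + n_trial] += _signal_block(cfg, float(f), rng, n_trial)
        events.append(Event(onset, float(f)))

    rec = EEGRecording(
        data=data, fs=cfg.fs, channel_names=cfg.channel_names, events=tuple(events)
    )
    return SimulatedSession(recording=rec, truth=tuple(labels), config=cfg)


def estimate_component_amplitudes(
    epoch: Epoch | np.ndarray,
    f: float,
    harmonics=(0.5, 1, 2),
    fs: float | None = None,
    channel: int = OZ_INDEX,
) -> dict[float, float]:
    """Single-channel DFT amplitude estimates at the components h*f.

    The amplitude of a sinusoid a*sin(2 pi h f t) is recovered as
    2|X_k|/N at the DFT bin nearest h*f; on a window covering an integer
    number of periods this is exact. A :class:`ResolutionWarning` is
    issued when h*f misses the nearest bin by more than a quarter bin,
    i.e. when the window length cannot resolve the component cleanly.
    """
    if isinstance(epoch, Epoch):
        x = epoch.data[channel]
        fs = epoch.fs
    else:
        arr = np.atleast_2d(np.asarray(epoch, dtype=float))
        x = arr[channel] if arr.shape[0] > channel else arr[0]
        if fs is None:
            raise ConfigurationError("fs is required for raw-array input")
    n = len(x)
    spectrum = np.abs(np.fft.rfft(x))
    bin_hz = fs / n
    out: dict[float, float] = {}
    for h in harmonics:
        target = float(h) * f
        k = int(round(target / bin_hz))
        if abs(target - k * bin_hz) > bin_hz / 4:
            warnings.warn(
                f"component {target} Hz is off the DFT grid (bin width {bin_hz} Hz)",
                ResolutionWarning,
                stacklevel=2,
            )
        out[float(h)] = 2.0 * spectrum[k] / n
    return out
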