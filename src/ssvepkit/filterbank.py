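"""Filter-bank CCA scoring and its subharmonic extension.

FBCCA decomposes an epoch into N_m sub-bands with increasing lower
cutoffs, scores each band with CCA against the harmonic template of a
candidate frequency, and combines the squared coefficients with weights

    w(m) = m**(-a) + b,          m = 1..N_m.

The subharmonic extension (sFBCCA) adds one more term for
pattern-reversal hybrid stimuli, whose size modulation at f/2 evokes a
subharmonic response: the epoch is filtered to a wide band reaching
below the lowest subharmonic (1-52 Hz), scored against the
subharmonic-extended template, and added with weight

    w_sub = m_sub**(-a) + b,     m_sub = 0.5 by default,

so the subharmonic term outweighs every ordinary sub-band term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .cca import build_reference, cca_coefficient
from .errors import ConfigurationError, ShortEpochWarning

__all__ = [
    "ScoringConfig",
    "subband_weight",
    "subharmonic_weight",
    "fbcca_score",
    "sfbcca_score",
    "classify",
]

DEFAULT_SUBBAND_EDGES = ((4.0, 52.0), (8.0, 52.0), (12.0, 52.0), (16.0, 52.0), (20.0, 52.0))

METHODS = ("cca", "fbcca", "sfbcca")


@dataclass(frozen=True)
class ScoringConfig:
    """Parameters of the CCA / FBCCA / sFBCCA scorers.

    ``w_sub_override`` replaces the computed subharmonic weight when set
    (``0.0`` reduces sFBCCA to FBCCA exactly). ``extended_reference_in_subbands``
    switches the ordinary sub-band terms to the subharmonic-extended
    template as well; the default keeps them on the plain template so
    the reduction at zero subharmonic weight is exact.
    """

    method: str = "fbcca"
    a: float = 1.25
    b: float = 0.25
    n_harmonics: int = 5
    subband_edges: tuple[tuple[float, float], ...] = DEFAULT_SUBBAND_EDGES
    m_sub: float = 0.5
    sub_band: tuple[float, float] = (1.0, 52.0)
    filter_order: int = 6
    w_sub_override: float | None = None
    extended_reference_in_subbands: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", str(self.method).lower())
        if self.method not in METHODS:
            raise ConfigurationError(f"unknown method {self.method!r}; use {METHODS}")
        if self.m_sub <= 0:
            raise ConfigurationError("m_sub must be positive")
        for lo, hi in (*self.subband_edges, self.sub_band):
            if not 0 < lo < hi:
                raise ConfigurationError(f"invalid band ({lo}, {hi})")

    @property
    def n_subbands(self) -> int:
        return len(self.subband_edges)

    @property
    def w_sub(self) -> float:
        if self.w_sub_override is not None:
            return float(self.w_sub_override)
        return subharmonic_weight(self.m_sub, self.a, self.b)


def subband_weight(m: int | float, a: float, b: float) -> float:
    """Weight of sub-band m: m**(-a) + b, decreasing in m for a > 0."""
    if m < 1:
        raise ConfigurationError("sub-band index m must be >= 1")
    return float(m) ** (-a) + b


def subharmonic_weight(m_sub: float, a: float, b: float) -> float:
    """Weight of the subharmonic term: m_sub**(-a) + b.

    With m_sub < 1 this exceeds w(1), reflecting the prominence of the
    f/2 component in pattern-reversal hybrid responses.
    """
    if m_sub <= 0:
        raise ConfigurationError("m_sub must be positive")
    return float(m_sub) ** (-a) + b


def _band_filter(
    X: np.ndarray, band: tuple[float, float], fs: float, order: int
) -> np.ndarray:
    lo, hi = band
    if hi >= fs / 2:
        raise ConfigurationError(f"band edge {hi} Hz >= Nyquist {fs / 2} Hz")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, X, axis=-1)


def _check_epoch_length(n_samples: int, fs: float) -> None:
    # the 4 Hz lower band edge has a ~fs/6-sample transient; below ~fs/2
    # samples the forward-backward pass is transient-dominated
    if n_samples < fs / 2:
        warnings.warn(
            f"epoch of {n_samples} samples is short for the filter bank at "
            f"{fs} Hz; coefficients may be transient-dominated",
            ShortEpochWarning,
            stacklevel=3,
        )


def _score_matrix(
    X: np.ndarray, frequencies, fs: float, cfg: ScoringConfig
) -> np.ndarray:
    """Scores for every candidate frequency, shared by all three methods."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    freqs = [float(f) for f in frequencies]
    n_s = X.shape[1]

    if cfg.method == "cca":
        refs = {
            f: build_reference(f, cfg.n_harmonics, n_s, fs, include_subharmonic=False)
            for f in freqs
        }
        return np.array([cca_coefficient(X, refs[f]).coefficient for f in freqs])

    _check_epoch_length(n_s, fs)
    plain = {
        f: build_reference(
            f, cfg.n_harmonics, n_s, fs,
            include_subharmonic=cfg.extended_reference_in_subbands,
        )
        for f in freqs
    }
    scores = np.zeros(len(freqs))
    for m, band in enumerate(cfg.subband_edges, start=1):
        Xm = _band_filter(X, band, fs, cfg.filter_order)
        w = subband_weight(m, cfg.a, cfg.b)
        for i, f in enumerate(freqs):
            rho = cca_coefficient(Xm, plain[f]).coefficient
            scores[i] += w * rho**2

    if cfg.method == "sfbcca":
        Xsub = _band_filter(X, cfg.sub_band, fs, cfg.filter_order)
        w_sub = cfg.w_sub
        for i, f in enumerate(freqs):
            ref = build_reference(
                f, cfg.n_harmonics, n_s, fs, include_subharmonic=True
            )
            rho = cca_coefficient(Xsub, ref).coefficient
            scores[i] += w_sub * rho**2
    return scores


def fbcca_score(X: np.ndarray, f: float, fs: float, cfg: ScoringConfig) -> float:
    """FBCCA score of one epoch for one candidate frequency."""
    cfg = _as_method(cfg, "fbcca")
    return float(_score_matrix(X, [f], fs, cfg)[0])


def sfbcca_score(X: np.ndarray, f: float, fs: float, cfg: ScoringConfig) -> float:
    """sFBCCA score: the FBCCA sum plus the weighted subharmonic term."""
    cfg = _as_method(cfg, "sfbcca")
    return float(_score_matrix(X, [f], fs, cfg)[0])


def _as_method(cfg: ScoringConfig, method: str) -> ScoringConfig:
    if cfg.method == method:
        return cfg
    from dataclasses import replace

    return replace(cfg, method=method)


def classify(
    X: np.ndarray, frequencies, fs: float, cfg: ScoringConfig
) -> tuple[float, np.ndarray]:
    """Frequency decision for one epoch under the configured method.

    Returns the predicted frequency and the score vector in the order
    of ``frequencies``; ties break toward the lowest frequency.
    """
    freqs = [float(f) for f in frequencies]
    scores = _score_matrix(X, freqs, fs, cfg)
    best = np.flatnonzero(scores == scores.max())
    pred = min(freqs[i] for i in best)
    return pred, scores
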