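"""Performance metrics and sweep drivers.

Accuracy and Wolpaw information transfer rate (ITR) per classification
decision, plus the two sweep drivers used throughout: window-size sweeps
comparing decoding methods, and the m_sub grid sweep probing the
subharmonic weight of sFBCCA.
"""

from __future__ import annotations

import logging
import math
from dataclasses import replace

import numpy as np
import pandas as pd

from . import filterbank
from .errors import ConfigurationError
from .preprocessing import DEFAULT_LATENCY_S, EEGRecording, epoch_extract
from .simulator import SimulatedSession

__all__ = ["itr", "accuracy", "wilson_interval", "classify_session", "window_sweep", "msub_sweep"]

logger = logging.getLogger(__name__)

DEFAULT_WINDOWS = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5)

SWEEP_COLUMNS = (
    "method",
    "window_s",
    "m_sub",
    "accuracy",
    "itr_bits_per_min",
    "n_trials",
    "seed",
)


def itr(p: float, n_classes: int, window_s: float) -> float:
    """Wolpaw information transfer rate in bits/min.

    ITR = (60/T) [log2 N + p log2 p + (1-p) log2((1-p)/(N-1))]

    with the convention 0*log2(0) = 0, so p = 1 gives (60/T) log2 N and
    p = 1/N gives 0. Below chance the formula is returned as computed
    (it can be positive); callers comparing regimes should treat
    sub-chance accuracies with care.
    """
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError(f"accuracy p={p} outside [0, 1]")
    if n_classes < 2:
        raise ConfigurationError("need at least 2 classes")
    if window_s <= 0:
        raise ConfigurationError("window_s must be positive")
    bits = math.log2(n_classes)
    if p > 0:
        bits += p * math.log2(p)
    if p < 1:
        bits += (1.0 - p) * math.log2((1.0 - p) / (n_classes - 1))
    return 60.0 / window_s * bits


def accuracy(predictions, truths) -> float:
    """Fraction of predictions matching the ground-truth labels."""
    predictions = list(predictions)
    truths = list(truths)
    if not predictions or len(predictions) != len(truths):
        raise ConfigurationError("predictions and truths must be equal-length, non-empty")
    hits = sum(
        1 for p, t in zip(predictions, truths) if math.isclose(float(p), float(t))
    )
    return hits / len(truths)


def wilson_interval(p: float, n: int, z: float = 1.96) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    if n <= 0:
        raise ConfigurationError("n must be positive")
    denom = 1.0 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1.0 - p) / n + z**2 / (4 * n**2)) / denom
    return max(0.0, center - half), min(1.0, center + half)


def classify_session(
    rec: EEGRecording,
    window_s: float,
    cfg: filterbank.ScoringConfig,
    frequencies=None,
    latency_s: float = DEFAULT_LATENCY_S,
) -> tuple[list[float], list[float]]:
    """Predict every trial of a recording at one window size.

    Returns (predictions, truths). ``frequencies`` defaults to the
    sorted set of labels present in the event table.
    """
    if frequencies is None:
        frequencies = sorted({ev.target_hz for ev in rec.events})
    epochs = epoch_extract(rec, window_s, latency_s=latency_s)
    preds, truths = [], []
    for ep in epochs:
        pred, _ = filterbank.classify(ep.data, frequencies, ep.fs, cfg)
        preds.append(pred)
        truths.append(ep.target_frequency_hz)
    return preds, truths


def _session_parts(session) -> tuple[EEGRecording, int]:
    if isinstance(session, SimulatedSession):
        return session.recording, session.config.seed
    return session, -1


def window_sweep(
    session,
    methods=("cca", "fbcca", "sfbcca"),
    windows=DEFAULT_WINDOWS,
    cfg: filterbank.ScoringConfig | None = None,
    frequencies=None,
    latency_s: float = DEFAULT_LATENCY_S,
) -> pd.DataFrame:
    """Accuracy and ITR per (method, window) cell.

    ``session`` may be a :class:`SimulatedSession` or a preprocessed
    :class:`EEGRecording`; each cell re-epochs the recording at its
    window length, classifies every trial, and reports the matched
    fraction and the Wolpaw ITR at that window.
    """
    rec, seed = _session_parts(session)
    cfg = cfg or filterbank.ScoringConfig()
    if frequencies is None:
        frequencies = sorted({ev.target_hz for ev in rec.events})
    rows = []
    for method in methods:
        mcfg = replace(cfg, method=method)
        for w in windows:
            preds, truths = classify_session(
                rec, w, mcfg, frequencies=frequencies, latency_s=latency_s
            )
            acc = accuracy(preds, truths)
            rows.append(
                {
                    "method": method,
                    "window_s": w,
                    "m_sub": mcfg.m_sub if method == "sfbcca" else np.nan,
                    "accuracy": acc,
                    "itr_bits_per_min": itr(acc, len(frequencies), w),
                    "n_trials": len(truths),
                    "seed": seed,
                }
            )
            logger.info("window_sweep %s w=%.2fs acc=%.3f", method, w, acc)
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def msub_sweep(
    session,
    m_sub_grid,
    windows=DEFAULT_WINDOWS,
    cfg: filterbank.ScoringConfig | None = None,
    frequencies=None,
    latency_s: float = DEFAULT_LATENCY_S,
) -> pd.DataFrame:
    """sFBCCA accuracy over a grid of subharmonic indices m_sub.

    Large m_sub drives the subharmonic weight toward b, approaching
    plain FBCCA behaviour; small m_sub emphasizes the f/2 term.
    """
    rec, seed = _session_parts(session)
    cfg = replace(cfg or filterbank.ScoringConfig(), method="sfbcca")
    if frequencies is None:
        frequencies = sorted({ev.target_hz for ev in rec.events})
    rows = []
    for m_sub in m_sub_grid:
        scfg = replace(cfg, m_sub=float(m_sub))
        for w in windows:
            preds, truths = classify_session(
                rec, w, scfg, frequencies=frequencies, latency_s=latency_s
            )
            acc = accuracy(preds, truths)
            rows.append(
                {
                    "method": "sfbcca",
                    "window_s": w,
                    "m_sub": float(m_sub),
                    "accuracy": acc,
                    "itr_bits_per_min": itr(acc, len(frequencies), w),
                    "n_trials": len(truths),
                    "seed": seed,
                }
            )
            logger.info("msub_sweep m_sub=%.3g w=%.2fs acc=%.3f", m_sub, w, acc)
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)
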