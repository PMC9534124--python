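"""Canonical correlation analysis against harmonic reference templates.

SSVEP frequency recognition scores a multichannel EEG epoch X against a
bank of sine/cosine templates Y_f, one per candidate stimulation
frequency f, and picks the frequency with the largest canonical
correlation

    rho_f = max_{w_x, w_y} corr(w_x' X, w_y' Y_f).

Templates hold sin/cos pairs at the harmonics h f, h = 1..N_h, and may
be extended with a subharmonic pair at f/2 for pattern-reversal hybrid
stimuli, whose size modulation runs at half the reversal rate.

The coefficient is computed by orthonormalizing the centered row spaces
of X and Y (rank-revealing pivoted QR) and taking the largest singular
value of the cross-projection — the numerically stable route to the
leading canonical correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .errors import ConfigurationError, DegenerateInputError

__all__ = ["CCAResult", "ReferenceSet", "build_reference", "cca_coefficient", "classify_cca"]

#: Relative rank tolerance for the pivoted-QR orthogonalization.
RANK_RTOL = 1e-10


def build_reference(
    f: float,
    n_harmonics: int,
    n_samples: int,
    fs: float,
    include_subharmonic: bool = False,
) -> np.ndarray:
    """Sine/cosine reference template for one candidate frequency.

    Rows are [sin(pi f n), cos(pi f n)] (the f/2 subharmonic pair, only
    when requested) followed by [sin(2 pi h f n), cos(2 pi h f n)] for
    h = 1..n_harmonics, evaluated on the grid n = 1/fs, 2/fs, ..., N_s/fs.
    Shape: (2 n_harmonics [+ 2], n_samples).
    """
    if f <= 0 or fs <= 0:
        raise ConfigurationError("frequency and sampling rate must be positive")
    if n_harmonics < 1:
        raise ConfigurationError("n_harmonics must be >= 1")
    if n_harmonics * f >= fs / 2:
        raise ConfigurationError(
            f"harmonic {n_harmonics}x{f} Hz is at or above Nyquist ({fs / 2} Hz)"
        )
    if n_samples < 2 * (n_harmonics + 1):
        raise ConfigurationError("n_samples too small for the requested template")

    n = np.arange(1, n_samples + 1) / fs
    rows = []
    if include_subharmonic:
        rows.append(np.sin(np.pi * f * n))
        rows.append(np.cos(np.pi * f * n))
    for h in range(1, n_harmonics + 1):
        rows.append(np.sin(2.0 * np.pi * h * f * n))
        rows.append(np.cos(2.0 * np.pi * h * f * n))
    return np.asarray(rows)


@dataclass(frozen=True)
class ReferenceSet:
    """Templates for every candidate frequency, built once per epoch length."""

    frequencies: tuple[float, ...]
    n_harmonics: int
    include_subharmonic: bool
    fs: float
    n_samples: int
    matrices: dict[float, np.ndarray] = field(repr=False)

    @classmethod
    def build(
        cls,
        frequencies,
        n_harmonics: int,
        n_samples: int,
        fs: float,
        include_subharmonic: bool = False,
    ) -> "ReferenceSet":
        freqs = tuple(float(f) for f in frequencies)
        if not freqs:
            raise ConfigurationError("frequency set must be non-empty")
        mats = {
            f: build_reference(f, n_harmonics, n_samples, fs, include_subharmonic)
            for f in freqs
        }
        return cls(
            frequencies=freqs,
            n_harmonics=n_harmonics,
            include_subharmonic=include_subharmonic,
            fs=fs,
            n_samples=n_samples,
            matrices=mats,
        )


@dataclass(frozen=True)
class CCAResult:
    """Leading canonical correlation and the weight vectors attaining it."""

    coefficient: float
    weights_x: np.ndarray = field(repr=False)
    weights_y: np.ndarray = field(repr=False)


def _orthonormal_basis(A: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Orthonormal basis of the column space of A (samples x dims).

    Returns (Q, R, piv, rank) from a pivoted economy QR with a relative
    tolerance on the diagonal of R, so rank-deficient inputs (constant
    or linearly dependent channels) are handled gracefully.
    """
    Q, R, piv = linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag.size == 0 or diag[0] == 0.0:
        raise DegenerateInputError("input has no variance after centering")
    rank = int(np.sum(diag > RANK_RTOL * diag[0]))
    return Q[:, :rank], R, piv, rank


def cca_coefficient(X: np.ndarray, Y: np.ndarray) -> CCAResult:
    """Largest canonical correlation between the row spaces of X and Y.

    Both inputs are (dims x samples); rows are mean-centered before
    correlation, matching the Pearson formulation. The result is
    invariant to invertible linear mixing of either input's rows and
    never decreases when rows are added to either side.

    Raises
    ------
    DegenerateInputError
        If either input is constant/all-zero after centering.
    ConfigurationError
        On sample-count mismatch or too few samples.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ConfigurationError("X and Y must have the same number of samples")
    if X.shape[1] <= X.shape[0] + Y.shape[0]:
        raise ConfigurationError("need more samples than total input dimensions")

    Xc = (X - X.mean(axis=1, keepdims=True)).T  # samples x dx
    Yc = (Y - Y.mean(axis=1, keepdims=True)).T
    Qx, _, _, rx = _orthonormal_basis(Xc)
    Qy, _, _, ry = _orthonormal_basis(Yc)

    U, s, Vt = linalg.svd(Qx.T @ Qy, full_matrices=False)
    rho = float(np.clip(s[0], 0.0, 1.0))

    # Recover weight vectors for the leading pair via least squares on the
    # centered data; cheap at these sizes and robust to rank deficiency.
    wx = linalg.lstsq(Xc, Qx @ U[:, 0])[0]
    wy = linalg.lstsq(Yc, Qy @ Vt[0, :])[0]
    return CCAResult(coefficient=rho, weights_x=wx, weights_y=wy)


def classify_cca(X: np.ndarray, refs: ReferenceSet) -> tuple[float, np.ndarray]:
    """Plain-CCA frequency decision for one epoch.

    Returns the predicted frequency and the score vector in the order of
    ``refs.frequencies``. Ties are broken toward the lowest frequency.
    """
    scores = np.array(
        [cca_coefficient(X, refs.matrices[f]).coefficient for f in refs.frequencies]
    )
    best = np.flatnonzero(scores == scores.max())
    pred = min(refs.frequencies[i] for i in best)
    return pred, scores
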