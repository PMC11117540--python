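"""Multiscale PCA (MSPCA) denoising of multichannel EEG.

The observed signal is modelled as Q = Q_EEG + Q_N: an information component
shared across channels plus uncorrelated artifact/noise. Denoising proceeds
in four steps:

1. a 5-level discrete wavelet transform (Symlet-4, symmetric extension) of
   every channel;
2. PCA across channels on each coefficient matrix (approximation and each
   detail band), keeping only the principal components retained by the
   Kaiser-style rule (eigenvalue strictly greater than the mean eigenvalue)
   and back-projecting;
3. the inverse wavelet transform of the cleaned coefficients;
4. a final across-channel PCA with the same retention rule on the
   reconstructed time-domain matrix.

Because the informative activity is correlated across electrodes while noise
is not, the retained components concentrate signal energy and the discarded
ones carry mostly noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = [
    "WaveletDecomposition",
    "wavelet_decompose",
    "wavelet_reconstruct",
    "kaiser_retain",
    "pca_denoise_matrix",
    "mspca_denoise",
]

DEFAULT_WAVELET = "sym4"
DEFAULT_LEVELS = 5
_DWT_MODE = "symmetric"


@dataclass
class WaveletDecomposition:
    """Per-channel DWT coefficients of a channels-by-time matrix.

    ``approx`` holds the level-``levels`` approximation coefficients
    (channels x n_approx); ``details[i]`` holds the detail coefficients of
    level ``i + 1`` (finest first ordering of ``pywt.wavedec`` reversed so
    that index 0 is level 1).
    """

    approx: np.ndarray
    details: list[np.ndarray]
    wavelet_name: str = DEFAULT_WAVELET
    levels: int = DEFAULT_LEVELS
    original_length: int = field(default=0)


def wavelet_decompose(
    signals: np.ndarray,
    wavelet: str = DEFAULT_WAVELET,
    levels: int = DEFAULT_LEVELS,
) -> WaveletDecomposition:
    """Decompose each channel of a channels-by-time matrix to ``levels`` scales."""
    x = np.atleast_2d(np.asarray(signals, dtype=float))
    if x.shape[1] < 2**levels:
        raise ValueError(
            f"signal length {x.shape[1]} too short for a {levels}-level "
            f"decomposition (need >= {2**levels} samples)"
        )
    coeffs = pywt.wavedec(x, wavelet, mode=_DWT_MODE, level=levels, axis=1)
    approx = coeffs[0]
    details = list(reversed(coeffs[1:]))  # index 0 -> level 1 (finest)
    return WaveletDecomposition(
        approx=approx,
        details=details,
        wavelet_name=wavelet,
        levels=levels,
        original_length=x.shape[1],
    )


def wavelet_reconstruct(dec: WaveletDecomposition) -> np.ndarray:
    """Invert :func:`wavelet_decompose`; exact up to numerical round-off."""
    coeffs = [dec.approx] + list(reversed(dec.details))
    rec = pywt.waverec(coeffs, dec.wavelet_name, mode=_DWT_MODE, axis=1)
    return rec[:, : dec.original_length]


def kaiser_retain(eigenvalues) -> list[int]:
    """Indices of components to keep: eigenvalue strictly above the mean.

    ``eigenvalues`` must be non-negative and sorted descending. If no
    eigenvalue strictly exceeds the mean (e.g. all equal), the leading
    component is kept so the retained set is never empty.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size == 0:
        raise ValueError("empty eigenvalue list")
    if (ev < 0).any() or (np.diff(ev) > 0).any():
        raise ValueError("eigenvalues must be non-negative and sorted descending")
    retained = np.flatnonzero(ev > ev.mean())
    if retained.size == 0:
        return [0]
    return retained.tolist()


def pca_denoise_matrix(mat: np.ndarray) -> np.ndarray:
    """Across-channel PCA reconstruction of a channels-by-samples matrix.

    Channels are the variables; each channel row is mean-centred, the
    channel covariance eigendecomposed, and the data projected onto the
    Kaiser-retained components and back, with means restored.
    """
    m = np.asarray(mat, dtype=float)
    mean = m.mean(axis=1, keepdims=True)
    xc = m - mean
    n_obs = m.shape[1]
    cov = xc @ xc.T / max(n_obs - 1, 1)
    ev, vec = np.linalg.eigh(cov)
    order = np.argsort(ev)[::-1]
    ev = np.clip(ev[order], 0.0, None)
    vec = vec[:, order]
    keep = kaiser_retain(ev)
    v = vec[:, keep]
    return v @ (v.T @ xc) + mean


def mspca_denoise(
    signals: np.ndarray,
    wavelet: str = DEFAULT_WAVELET,
    levels: int = DEFAULT_LEVELS,
) -> np.ndarray:
    """Run the full multiscale PCA pipeline on a channels-by-time matrix."""
    x = np.asarray(signals, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError(
            "MSPCA needs at least 2 channels (a channels-by-time matrix); "
            "got shape " + str(x.shape)
        )
    if not np.isfinite(x).all():
        raise ValueError("input contains non-finite values")

    dec = wavelet_decompose(x, wavelet=wavelet, levels=levels)
    dec.approx = pca_denoise_matrix(dec.approx)
    dec.details = [pca_denoise_matrix(d) for d in dec.details]
    rec = wavelet_reconstruct(dec)
    return pca_denoise_matrix(rec)
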