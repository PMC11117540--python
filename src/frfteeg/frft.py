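"""Fast fractional Fourier transform (fast FrFT) graphical representation.

The transform maps a real epoch x(n) of power-of-two length N into N complex
coefficients c_k whose real/imaginary parts form an ordered 2D scatter — the
"graphical" domain on which the geometric features operate.

The algorithm runs log2(N) multiplicative chirp-filter stages and then a
chirp-modulated DFT:

  stage k (k = 1..log2 N):
      f_k(m) = ((m+1)/2) * exp(j*pi*alpha*(m - N/2)^2 / 2^k),   m = 0..N-1
      z      = FFT_N( y * f_k ) * K^(2^(k-1)),                  K = exp(-j*pi*alpha/2)
      y      = IFFT_N(z)

  coefficients:
      c_k = (1/N) * sum_n y(n) * exp(-j*pi*alpha*(n - N/2)^2 / N)
                         * exp(-j*2*pi*n*k/N)

Every step is linear in the signal, so the whole transform is linear; for
alpha = 0 the coefficient chirp kernel degenerates to 1 and c reduces to a
plain (scaled) DFT of the stage-filtered signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrFTScatter", "stage_filter_coeffs", "stage_filter", "fast_frft"]


def _check_power_of_two(n: int) -> None:
    if n < 2 or (n & (n - 1)) != 0:
        lo = 1 << max((n - 1).bit_length() - 1, 1)
        hi = 1 << (n - 1).bit_length() if n > 1 else 2
        raise ValueError(
            f"signal length must be a power of two, got {n} "
            f"(nearest valid lengths: {lo} and {hi})"
        )


@dataclass
class FrFTScatter:
    """Ordered complex fast-FrFT coefficients and their 2D point cloud.

    Attributes
    ----------
    alpha : float
        Fractional order of the transform.
    coefficients : ndarray of complex, shape (N,)
        c_k for k = 0..N-1, in index order (no fftshift).
    y_filtered : ndarray of complex, shape (N,)
        The signal after the stage-filter loop, before the coefficient sum.
    """

    alpha: float
    coefficients: np.ndarray
    y_filtered: np.ndarray
    points: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients)
        self.points = np.column_stack([c.real, c.imag])

    @property
    def n(self) -> int:
        return len(self.coefficients)


def stage_filter_coeffs(k: int, alpha: float, n: int) -> np.ndarray:
    """Chirp filter f_k(m) for stage k of the transform (length n)."""
    m = np.arange(n, dtype=float)
    return (m + 1.0) / 2.0 * np.exp(1j * np.pi * alpha * (m - n / 2.0) ** 2 / 2.0**k)


def stage_filter(y: np.ndarray, k: int, alpha: float) -> np.ndarray:
    """Apply one multiplicative chirp-filter stage to a length-N signal.

    Filters y with f_k, takes an N-point FFT, scales by K^(2^(k-1)) with
    K = exp(-j*pi*alpha/2), and returns the inverse FFT.
    """
    y = np.asarray(y, dtype=complex)
    n = y.shape[-1]
    _check_power_of_two(n)
    n_stages = int(np.log2(n))
    if not 1 <= k <= n_stages:
        raise ValueError(f"stage index k={k} outside 1..log2(N)={n_stages}")
    scale = np.exp(-1j * np.pi * alpha / 2.0) ** (2 ** (k - 1))
    z = np.fft.fft(y * stage_filter_coeffs(k, alpha, n)) * scale
    return np.fft.ifft(z)


def fast_frft(x: np.ndarray, alpha: float = 0.5) -> FrFTScatter:
    """Compute the fast-FrFT scatter of a power-of-two-length signal.

    Parameters
    ----------
    x : array-like, shape (N,)
        Input signal; N must be a power of two.
    alpha : float, default 0.5
        Fractional order.

    Returns
    -------
    FrFTScatter
        Ordered coefficients c_0..c_{N-1} with their (Re, Im) point cloud.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("fast_frft expects a 1-D signal")
    if not np.isfinite(alpha):
        raise ValueError("alpha must be finite")
    n = x.shape[0]
    _check_power_of_two(n)

    y = x.astype(complex)
    for k in range(1, int(np.log2(n)) + 1):
        y = stage_filter(y, k, alpha)

    idx = np.arange(n, dtype=float)
    chirp = np.exp(-1j * np.pi * alpha * (idx - n / 2.0) ** 2 / n)
    # c_k = (1/N) * DFT_k( y * chirp ): the chirp-weighted signal's plain DFT.
    coeffs = np.fft.fft(y * chirp) / n
    return FrFTScatter(alpha=alpha, coefficients=coeffs, y_filtered=y)
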