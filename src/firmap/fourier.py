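"""Centered, unitary 2-D Fourier transforms.

Convention used throughout the package: the DC component of k-space sits at
grid index (N//2, N//2) and both directions of the transform carry the
1/sqrt(N*N) normalisation, so ``ifft2c(fft2c(x)) == x`` and Parseval's
identity holds without extra factors.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as spfft

__all__ = ["fft2c", "ifft2c"]


def fft2c(img: np.ndarray) -> np.ndarray:
    """Unitary centered 2-D FFT over the last two axes."""
    return np.fft.fftshift(
        spfft.fft2(np.fft.ifftshift(img, axes=(-2, -1)), norm="ortho", axes=(-2, -1)),
        axes=(-2, -1),
    )


def ifft2c(ksp: np.ndarray) -> np.ndarray:
    """Unitary centered 2-D inverse FFT over the last two axes."""
    return np.fft.fftshift(
        spfft.ifft2(np.fft.ifftshift(ksp, axes=(-2, -1)), norm="ortho", axes=(-2, -1)),
        axes=(-2, -1),
    )
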