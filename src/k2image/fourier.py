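"""Centered 2D FFT conventions used package-wide.

The image pixel at array index ``i`` has spatial coordinate ``r = i - w/2``
(so the geometric image center maps to r = 0) and the Cartesian k-space grid
point at index ``g`` has frequency ``k = 2*pi*(g - w/2)/w`` radians per pixel.
With these conventions a "centered" transform is an fftshift / ifftshift
sandwich around the standard FFT.

Two normalizations are exposed:

* ``fft2c`` / ``ifft2c`` — orthonormal (unitary) pair; used by the learned
  model so that k-space-domain residuals equal image-domain residuals.
* ``fft2c_unnorm`` / ``ifft2c_unnorm`` — plain DFT sum and its inverse
  (1/N); used by the gridding operators where the transform must match the
  non-uniform DFT sum exactly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fft2c", "ifft2c", "fft2c_unnorm", "ifft2c_unnorm"]


def fft2c(x: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2D FFT (image -> k-space)."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x, axes=(-2, -1)),
                                       norm="ortho"), axes=(-2, -1))


def ifft2c(k: np.ndarray) -> np.ndarray:
    """Centered orthonormal 2D inverse FFT (k-space -> image)."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k, axes=(-2, -1)),
                                        norm="ortho"), axes=(-2, -1))


def fft2c_unnorm(x: np.ndarray) -> np.ndarray:
    """Centered 2D DFT sum (no normalization factor)."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x, axes=(-2, -1))),
                           axes=(-2, -1))


def ifft2c_unnorm(k: np.ndarray) -> np.ndarray:
    """Centered 2D inverse DFT (with the 1/N factor)."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k, axes=(-2, -1))),
                           axes=(-2, -1))
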