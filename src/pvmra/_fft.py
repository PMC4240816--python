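"""Centered, orthonormal Fourier transforms.

All modules share one k-space convention: the DC component sits at the array
center index ``floor(N/2)`` along every transformed axis, and the transform is
unitary (``norm="ortho"``), so image energy equals k-space energy (Parseval).
"""

from __future__ import annotations

import numpy as np
from scipy import fft as _sp_fft


def fftc(x: np.ndarray, axes=None) -> np.ndarray:
    """Centered forward FFT (DC at ``N//2``), unitary scaling."""
    y = _sp_fft.ifftshift(x, axes=axes)
    y = _sp_fft.fftn(y, axes=axes, norm="ortho")
    return _sp_fft.fftshift(y, axes=axes)


def ifftc(k: np.ndarray, axes=None) -> np.ndarray:
    """Centered inverse FFT, adjoint of :func:`fftc`."""
    y = _sp_fft.ifftshift(k, axes=axes)
    y = _sp_fft.ifftn(y, axes=axes, norm="ortho")
    return _sp_fft.fftshift(y, axes=axes)


def dc_index(n: int) -> int:
    """Index of the DC sample on an ``n``-point centered grid."""
    return n // 2
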