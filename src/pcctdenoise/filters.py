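"""Gaussian blur helpers shared by the channel transform and the loss.

The blur used inside the training loss must expose an exact adjoint so the
loss gradient can be computed analytically.  For that purpose the separable
1D blur along each image axis is materialised as a small banded matrix with
half-sample reflect boundary handling (identical to ``scipy.ndimage``'s
``mode='reflect'``); applying the transpose of that matrix is then the exact
adjoint of the blur.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import ndimage

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # sigma = FWHM * this


def gaussian_kernel_1d(fwhm: float, radius: int) -> np.ndarray:
    """Normalized 1D Gaussian taps of length ``2*radius + 1``."""
    sigma = fwhm * FWHM_TO_SIGMA
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _reflect_index(i: np.ndarray, n: int) -> np.ndarray:
    """Half-sample reflection of indices into [0, n): ...dcba|abcd|dcba..."""
    period = 2 * n
    j = np.mod(i, period)
    return np.where(j < n, j, period - 1 - j)


@lru_cache(maxsize=32)
def blur_matrix_1d(n: int, fwhm: float, radius: int) -> np.ndarray:
    """Dense (n, n) matrix applying the reflected-boundary Gaussian blur."""
    k = gaussian_kernel_1d(fwhm, radius)
    mat = np.zeros((n, n), dtype=np.float64)
    rows = np.arange(n)
    for t, w in zip(range(-radius, radius + 1), k):
        cols = _reflect_index(rows + t, n)
        np.add.at(mat, (rows, cols), w)
    return mat


def blur2d(x: np.ndarray, fwhm: float = 5.0, radius: int = 9,
           transpose: bool = False) -> np.ndarray:
    """Separable 2D Gaussian blur over the last two axes of ``x``.

    With ``transpose=True`` applies the exact adjoint operator instead
    (needed for gradients of blurred-image penalties).
    """
    h, w = x.shape[-2], x.shape[-1]
    by = blur_matrix_1d(h, fwhm, radius)
    bx = blur_matrix_1d(w, fwhm, radius)
    if transpose:
        by, bx = by.T, bx.T
    out = np.einsum("ij,...jk->...ik", by, x)
    out = np.einsum("...ij,kj->...ik", out, bx)
    return out.astype(x.dtype, copy=False)


def blur3d(x: np.ndarray, fwhm: float = 10.0, radius: int = 18) -> np.ndarray:
    """3D Gaussian blur (reflect boundaries) used by the high-pass step.

    ``radius=18`` truncates the kernel at 37 taps per axis.
    """
    sigma = fwhm * FWHM_TO_SIGMA
    return ndimage.gaussian_filter(
        x, sigma=sigma, mode="reflect", radius=radius, output=x.dtype
    )
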