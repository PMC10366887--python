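"""Multi-energy non-local means (ME NLM) baseline filter.

For every voxel of the output slice, a weighted average is taken over the
voxels of a 3D search window; the weight of neighbour j combines patch
distances from *all* energy channels,

    w_ij = exp( - sum_e d_e(i, j) / (2 h^2 sigma_e^2 |P|) )

with d_e the squared Euclidean distance between the 3^3 patches around i
and j at energy e, |P| the patch size, sigma_e the per-energy noise std
(measured in a homogeneous water ROI) and h the filtering strength.  The
same weights are applied to every energy channel, which is what couples
the channels and distinguishes ME NLM from filtering each energy
independently.  The filter is applied to a sliding stack of 31 axial
slices, keeping the filtered 16th slice each time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import SpectralVolume
from .spectral_materials import ROISpec

__all__ = ["NLMParams", "noise_std_from_roi", "me_nlm_stack", "me_nlm_volume",
           "MultiEnergyNLM"]


@dataclass
class NLMParams:
    search_edge: int = 11  # search window edge (voxels), cubed
    patch_edge: int = 3  # patch edge (voxels), cubed
    h: float = 1.2  # filtering strength
    noise_std: tuple = ()  # per-energy sigma (1/cm)
    stack_depth: int = 31
    output_index: int = 16  # 1-based index of the kept slice within the stack

    def __post_init__(self) -> None:
        if self.search_edge % 2 == 0 or self.patch_edge % 2 == 0:
            raise ValueError("search window and patch edges must be odd")
        if self.h <= 0:
            raise ValueError("filtering strength h must be positive")
        if not (1 <= self.output_index <= self.stack_depth):
            raise ValueError("output index must lie within the stack")
        if len(self.noise_std) and np.any(np.asarray(self.noise_std) <= 0):
            raise ValueError("noise std must be positive per energy")


def noise_std_from_roi(volume: SpectralVolume, water_roi: ROISpec) -> np.ndarray:
    """Per-energy sample std of a homogeneous (water) ROI, floored at eps."""
    vals = water_roi.extract(volume)  # (E, n)
    std = vals.std(axis=1, ddof=1)
    return np.maximum(std, np.finfo(np.float64).eps)


def me_nlm_stack(stack: np.ndarray, params: NLMParams) -> np.ndarray:
    """Filter one multi-energy slice stack; returns the designated slice.

    ``stack`` is (E, D, H, W) with D == ``params.stack_depth``.  The
    search window is 3D (it extends in z within the stack) and clipped at
    the stack/image boundaries; patches are taken from a reflect-padded
    copy.  Returns the filtered output slice, shape (E, H, W).
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 4:
        raise ValueError("stack must be (E, D, H, W)")
    ne, d, h_, w_ = stack.shape
    if d != params.stack_depth:
        raise ValueError(f"stack depth {d} != configured {params.stack_depth}")
    if len(params.noise_std) != ne:
        raise ValueError("one noise std per energy required")

    sr = params.search_edge // 2
    pr = params.patch_edge // 2
    z0 = params.output_index - 1
    npatch = params.patch_edge**3
    sigma2 = np.asarray(params.noise_std, dtype=np.float64) ** 2
    denom = 2.0 * params.h**2 * npatch

    # reflect padding supplies patch voxels that overhang the image edge;
    # search neighbours themselves are restricted to real image voxels
    padded = np.pad(stack, ((0, 0), (pr, pr), (pr, pr), (pr, pr)), mode="symmetric")

    num = np.zeros((ne, h_, w_))
    den = np.zeros((h_, w_))
    inv_s2 = (1.0 / sigma2)[:, None, None]
    for dz in range(-sr, sr + 1):
        if not (0 <= z0 + dz < d):
            continue
        for dy in range(-sr, sr + 1):
            ys = slice(max(0, -dy), h_ - max(0, dy))  # centers with y+dy inside
            if ys.start >= ys.stop:
                continue
            for dx in range(-sr, sr + 1):
                xs = slice(max(0, -dx), w_ - max(0, dx))
                if xs.start >= xs.stop:
                    continue
                dist = np.zeros((ys.stop - ys.start, xs.stop - xs.start))
                for pz in range(-pr, pr + 1):
                    a = padded[
                        :, z0 + pr + pz,
                        ys.start:ys.stop + 2 * pr, xs.start:xs.stop + 2 * pr,
                    ]
                    b = padded[
                        :, z0 + dz + pr + pz,
                        ys.start + dy:ys.stop + dy + 2 * pr,
                        xs.start + dx:xs.stop + dx + 2 * pr,
                    ]
                    c = (((a - b) ** 2) * inv_s2).sum(axis=0)
                    dist += sliding_window_view(
                        c, (params.patch_edge, params.patch_edge)
                    ).sum(axis=(-1, -2))
                wmap = np.exp(-dist / denom)
                neigh = stack[:, z0 + dz, ys.start + dy:ys.stop + dy,
                              xs.start + dx:xs.stop + dx]
                num[:, ys, xs] += wmap * neigh
                den[ys, xs] += wmap
    return num / den


def me_nlm_volume(volume: SpectralVolume, params: NLMParams) -> SpectralVolume:
    """Slide the stack filter over a whole volume (reflect padding in z)."""
    data = volume.data
    nz = data.shape[1]
    z0 = params.output_index - 1
    before = z0
    after = params.stack_depth - 1 - z0
    padded = np.pad(data, ((0, 0), (before, after), (0, 0), (0, 0)), mode="symmetric")
    out = np.empty_like(data, dtype=np.float64)
    for z in range(nz):
        out[:, z] = me_nlm_stack(padded[:, z:z + params.stack_depth], params)
    return SpectralVolume(
        out.astype(data.dtype, copy=False), list(volume.energies), volume.voxel_size_mm
    )


class MultiEnergyNLM(BaseEstimator, TransformerMixin):
    """Estimator facade over the stack filter.

    ``fit`` measures per-energy noise std from a water ROI when one is
    given (otherwise ``noise_std`` must be set); ``transform`` filters a
    whole volume.
    """

    def __init__(self, search_edge: int = 11, patch_edge: int = 3, h: float = 1.2,
                 noise_std: tuple = (), stack_depth: int = 31, output_index: int = 16):
        self.search_edge = search_edge
        self.patch_edge = patch_edge
        self.h = h
        self.noise_std = noise_std
        self.stack_depth = stack_depth
        self.output_index = output_index

    def fit(self, volume: SpectralVolume | None = None,
            water_roi: ROISpec | None = None):
        if water_roi is not None:
            if volume is None:
                raise ValueError("a volume is required to measure ROI noise")
            std = tuple(noise_std_from_roi(volume, water_roi))
        elif len(self.noise_std):
            std = tuple(self.noise_std)
        else:
            raise ValueError("either a water ROI or explicit noise_std is required")
        self.params_ = NLMParams(
            self.search_edge, self.patch_edge, self.h, std,
            self.stack_depth, self.output_index,
        )
        return self

    def transform(self, volume: SpectralVolume) -> SpectralVolume:
        if not hasattr(self, "params_"):
            raise RuntimeError("MultiEnergyNLM is not fitted")
        return me_nlm_volume(volume, self.params_)
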