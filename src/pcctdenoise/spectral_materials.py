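"""Image-domain K-edge material decomposition.

Each voxel's multi-energy attenuation row ``x`` (length E) is modelled as a
linear combination of basis-material sensitivities,

    x = c @ M,        M : (materials, energies), c : (materials,)

where ``M`` holds attenuation (1/cm) per unit concentration (g/mL for
water, mg/mL for everything else).  Decomposition inverts this system per
voxel, ``c = x @ M^-1`` (pseudo-inverse when more energies than
materials).  A non-negativity-constrained variant solves the per-voxel
non-negative least squares problem by active-set elimination: repeatedly
drop the most-negative material from the basis and re-solve on the
remaining subspace, falling back to a KKT-verified NNLS solve for the rare
voxels where greedy elimination is not optimal.

``M`` itself is calibrated from ROI measurements in vials of known
concentration by fitting the slope of (attenuation - water attenuation)
versus concentration through the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import MaterialMaps, SpectralVolume

__all__ = [
    "SensitivityMatrix",
    "ROISpec",
    "fit_sensitivity",
    "decompose",
    "decompose_nonneg",
    "compose",
    "colorize_maps",
    "MaterialDecomposer",
]


@dataclass
class SensitivityMatrix:
    """Materials x energies sensitivity matrix.

    ``matrix[i, e]`` is the attenuation (1/cm) contributed at energy ``e``
    by one unit of material ``i`` (1 g/mL for water, 1 mg/mL otherwise).
    """

    matrix: np.ndarray
    materials: list
    energies: list = field(default_factory=list)
    vial_concentrations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("sensitivity matrix must be 2D (materials, energies)")
        if len(self.materials) != self.matrix.shape[0]:
            raise ValueError("one material name per row required")
        if len(set(self.materials)) != len(self.materials):
            raise ValueError("duplicate material names")
        if not self.energies:
            self.energies = list(range(self.matrix.shape[1]))
        if len(self.energies) != self.matrix.shape[1]:
            raise ValueError("one energy label per column required")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("sensitivity matrix entries must be finite")

    @property
    def n_materials(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_energies(self) -> int:
        return self.matrix.shape[1]

    def right_inverse(self) -> np.ndarray:
        """(E, M) matrix mapping attenuation rows to concentration rows."""
        m, e = self.matrix.shape
        if e < m:
            raise np.linalg.LinAlgError(
                f"under-determined system: {e} energies < {m} materials"
            )
        if np.linalg.matrix_rank(self.matrix) < m:
            raise np.linalg.LinAlgError("sensitivity matrix is rank deficient")
        if e == m:
            return np.linalg.inv(self.matrix)
        return np.linalg.pinv(self.matrix)

    def row_for(self, material: str) -> np.ndarray:
        return self.matrix[self.materials.index(material)]


@dataclass
class ROISpec:
    """Cylindrical ROI in voxel coordinates with a known vial content.

    ``center`` is (z, y, x); the ROI spans axial slices
    ``zmin..zmax`` (inclusive) and the in-plane disk of given radius.
    """

    center: tuple
    radius: float
    zmin: int
    zmax: int
    material: str = "water"
    concentration: float = 1.0

    def mask(self, grid_shape: tuple) -> np.ndarray:
        nz, ny, nx = grid_shape
        if not (0 <= self.zmin <= self.zmax < nz):
            raise ValueError(f"ROI slice range [{self.zmin}, {self.zmax}] outside volume")
        _, cy, cx = self.center
        yy, xx = np.mgrid[0:ny, 0:nx]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= self.radius**2
        if cy - self.radius < -0.5 or cy + self.radius > ny - 0.5 or \
           cx - self.radius < -0.5 or cx + self.radius > nx - 0.5:
            raise ValueError("ROI disk extends outside the volume")
        mask = np.zeros(grid_shape, dtype=bool)
        mask[self.zmin:self.zmax + 1] = disk
        if mask.sum() < 8:
            raise ValueError("ROI must cover at least 8 voxels")
        return mask

    def extract(self, volume: SpectralVolume) -> np.ndarray:
        """ROI voxel values, shape (E, n_voxels)."""
        mask = self.mask(volume.grid_shape)
        return volume.data[:, mask]


def compose(maps: MaterialMaps, M: SensitivityMatrix) -> SpectralVolume:
    """Forward spectral model: X(e) = sum_i C_i * M[i, e], voxelwise."""
    if maps.data.shape[0] != M.n_materials:
        raise ValueError("material maps do not match sensitivity matrix rows")
    data = np.einsum("mzyx,me->ezyx", maps.data, M.matrix)
    return SpectralVolume(
        data.astype(maps.data.dtype, copy=False),
        list(M.energies),
        maps.voxel_size_mm,
    )


def decompose(volume: SpectralVolume, M: SensitivityMatrix) -> MaterialMaps:
    """Unconstrained matrix-inversion decomposition, C = X @ M^-1.

    The result may contain negative concentrations; see
    :func:`decompose_nonneg` for the constrained variant.
    """
    if volume.n_energies != M.n_energies:
        raise ValueError("volume energies do not match sensitivity matrix columns")
    minv = M.right_inverse()  # (E, M)
    data = np.einsum("ezyx,em->mzyx", volume.data.astype(np.float64), minv)
    return MaterialMaps(data, list(M.materials), volume.voxel_size_mm)


def _nnls_rows(X: np.ndarray, M: np.ndarray, kkt_tol: float = 1e-9) -> np.ndarray:
    """Row-wise non-negative least squares ``min ||c @ M - x||, c >= 0``.

    X : (n, E) attenuation rows; M : (m, E).  Active-set elimination
    vectorised over rows, with a per-row ``scipy.optimize.nnls`` fallback
    whenever the greedy path fails the KKT optimality check.
    """
    n, _ = X.shape
    m = M.shape[0]
    C = np.zeros((n, m))
    active = np.ones((n, m), dtype=bool)

    # group rows by active-set pattern and solve each group with one lstsq
    for _ in range(m):
        patterns = {}
        for key in np.unique(active, axis=0):
            sel = np.nonzero((active == key).all(axis=1))[0]
            patterns[tuple(key)] = sel
        changed = False
        for key, rows in patterns.items():
            idx = np.nonzero(np.asarray(key))[0]
            if idx.size == 0:
                C[rows] = 0.0
                continue
            sol, *_ = np.linalg.lstsq(M[idx].T, X[rows].T, rcond=None)
            sol = sol.T  # (len(rows), len(idx))
            full = np.zeros((len(rows), m))
            full[:, idx] = sol
            C[rows] = full
            neg = sol.min(axis=1) < 0
            if np.any(neg):
                changed = True
                bad = rows[neg]
                worst = idx[np.argmin(sol[neg], axis=1)]
                active[bad, worst] = False
        if not changed:
            break

    C = np.maximum(C, 0.0)

    # KKT check: on the zero set the residual gradient must be >= 0
    resid = C @ M - X  # (n, E)
    grad = resid @ M.T  # (n, m)
    scale = np.maximum(np.abs(X).max(axis=1, keepdims=True), 1.0)
    viol = np.any((C <= 0) & (grad < -kkt_tol * scale), axis=1)
    for i in np.nonzero(viol)[0]:
        C[i], _ = nnls(M.T, X[i])
    return C


def decompose_nonneg(volume: SpectralVolume, M: SensitivityMatrix) -> MaterialMaps:
    """Decomposition with non-negative concentrations.

    Voxels whose unconstrained solution is already non-negative are kept
    unchanged; the rest are re-solved in the subspace of non-violating
    basis materials (orthogonal subspace projection, in active-set form).
    """
    unconstrained = decompose(volume, M)
    C = unconstrained.data.reshape(M.n_materials, -1).T  # (n, m)
    bad = np.any(C < 0, axis=1)
    if np.any(bad):
        X = volume.data.reshape(volume.n_energies, -1).T[bad].astype(np.float64)
        C = C.copy()
        C[bad] = _nnls_rows(X, M.matrix)
    data = C.T.reshape(unconstrained.data.shape)
    return MaterialMaps(data, list(M.materials), volume.voxel_size_mm)


def nnls_subset_oracle(x: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Brute-force NNLS reference for one voxel: enumerate every material
    subset, keep feasible (non-negative) unconstrained solutions, return
    the one with the smallest residual.  Exponential in the number of
    materials — a test oracle, not a production path."""
    m = M.shape[0]
    best, best_r = np.zeros(m), float(np.dot(x, x))
    for size in range(1, m + 1):
        for idx in combinations(range(m), size):
            idx = list(idx)
            sol, *_ = np.linalg.lstsq(M[idx].T, x, rcond=None)
            if np.any(sol < 0):
                continue
            r = float(np.sum((sol @ M[idx] - x) ** 2))
            if r < best_r - 1e-12 * max(best_r, 1.0):
                best_r = r
                best = np.zeros(m)
                best[idx] = sol
    return best


def fit_sensitivity(
    volume: SpectralVolume,
    rois: list,
    water_roi: ROISpec,
    energies: list | None = None,
) -> SensitivityMatrix:
    """Calibrate a sensitivity matrix from vial ROI measurements.

    For every contrast material the per-energy sensitivity is the
    least-squares slope through the origin of (mean vial attenuation -
    mean water attenuation) versus known concentration; the water row is
    the mean water-vial attenuation per energy (density 1 g/mL).  Vials
    are assumed to be aqueous solutions, hence the water subtraction.
    """
    water_mean = water_roi.extract(volume).mean(axis=1)  # (E,)

    by_material: dict[str, list] = {}
    for roi in rois:
        if roi.material == "water":
            continue
        by_material.setdefault(roi.material, []).append(roi)

    materials = ["water"] + list(by_material)
    rows = [water_mean]
    for name, mat_rois in by_material.items():
        conc = np.array([r.concentration for r in mat_rois], dtype=np.float64)
        if np.all(conc == 0):
            raise ValueError(f"all calibration concentrations are zero for {name!r}")
        means = np.stack([r.extract(volume).mean(axis=1) for r in mat_rois])
        delta = means - water_mean  # (n_vials, E)
        slope = (conc[:, None] * delta).sum(axis=0) / np.dot(conc, conc)
        rows.append(slope)

    vials = {"water": water_roi.concentration}
    for name, mat_rois in by_material.items():
        vials[name] = mat_rois[0].concentration
    return SensitivityMatrix(
        np.stack(rows),
        materials,
        list(energies) if energies is not None else list(volume.energies),
        vial_concentrations=vials,
    )


def colorize_maps(maps: MaterialMaps, colors: dict, slice_index: int | None = None,
                  saturation: dict | None = None) -> np.ndarray:
    """Additive RGB composite of material maps for one axial slice.

    ``colors`` maps material name -> RGB triple in [0, 1]; each map is
    scaled by its saturation concentration (default: its own maximum)
    before blending; the blend is clipped to [0, 1].  Returns (Y, X, 3).
    """
    z = maps.data.shape[1] // 2 if slice_index is None else slice_index
    out = np.zeros(maps.grid_shape[1:] + (3,), dtype=np.float64)
    for name, rgb in colors.items():
        img = maps.map_for(name)[z]
        sat = None if saturation is None else saturation.get(name)
        if sat is None:
            sat = img.max() if img.max() > 0 else 1.0
        out += np.clip(img / sat, 0.0, 1.0)[..., None] * np.asarray(rgb, dtype=np.float64)
    return np.clip(out, 0.0, 1.0)


class MaterialDecomposer(BaseEstimator, TransformerMixin):
    """Estimator wrapper around sensitivity calibration and decomposition.

    Parameters
    ----------
    sensitivity : SensitivityMatrix, optional
        Known matrix; when omitted, `fit` calibrates one from ROIs.
    nonneg : bool
        Apply the non-negativity projection in `transform`.
    """

    def __init__(self, sensitivity: SensitivityMatrix | None = None,
                 nonneg: bool = False):
        self.sensitivity = sensitivity
        self.nonneg = nonneg

    def fit(self, volume: SpectralVolume | None = None, rois: list | None = None,
            water_roi: ROISpec | None = None):
        if self.sensitivity is not None:
            self.sensitivity_ = self.sensitivity
        else:
            if volume is None or not rois or water_roi is None:
                raise ValueError(
                    "fit requires a calibration volume, vial ROIs and a water ROI "
                    "when no sensitivity matrix is given"
                )
            self.sensitivity_ = fit_sensitivity(volume, rois, water_roi)
        return self

    def transform(self, volume: SpectralVolume) -> MaterialMaps:
        self._check_fitted()
        if self.nonneg:
            return decompose_nonneg(volume, self.sensitivity_)
        return decompose(volume, self.sensitivity_)

    def inverse_transform(self, maps: MaterialMaps) -> SpectralVolume:
        self._check_fitted()
        return compose(maps, self.sensitivity_)

    def _check_fitted(self) -> None:
        if not hasattr(self, "sensitivity_"):
            raise RuntimeError("MaterialDecomposer is not fitted")
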