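"""In-memory containers for spectral CT data.

Conventions used package-wide:

* Spectral volumes are ``(E, Z, Y, X)`` float arrays of linear attenuation
  in 1/cm, energy first, axial slices along ``Z``.
* Material maps are ``(M, Z, Y, X)`` with water in g/mL and every other
  material in mg/mL.
* All coordinates are voxel-indexed, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpectralVolume", "MaterialMaps"]


@dataclass
class SpectralVolume:
    """A multi-energy attenuation volume.

    Parameters
    ----------
    data : ndarray, shape (E, Z, Y, X)
        Linear attenuation coefficients in 1/cm, one channel per
        detector energy threshold.
    energies : list of float
        Energy threshold labels in keV, one per channel.
    voxel_size_mm : float
        Isotropic voxel edge length in mm.
    """

    data: np.ndarray
    energies: list = field(default_factory=list)
    voxel_size_mm: float = 0.125

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"spectral volume must be 4D (E, Z, Y, X), got {self.data.ndim}D"
            )
        if not self.energies:
            self.energies = list(range(self.data.shape[0]))
        if len(self.energies) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.energies)} energy labels for {self.data.shape[0]} channels"
            )

    @property
    def n_energies(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple:
        """Spatial shape (Z, Y, X)."""
        return self.data.shape[1:]

    def copy(self) -> "SpectralVolume":
        return SpectralVolume(self.data.copy(), list(self.energies), self.voxel_size_mm)


@dataclass
class MaterialMaps:
    """Per-material concentration volumes.

    ``data`` is ``(M, Z, Y, X)``; water is stored as density in g/mL and
    all other materials as concentration in mg/mL.
    """

    data: np.ndarray
    materials: list = field(default_factory=list)
    voxel_size_mm: float = 0.125

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"material maps must be 4D (M, Z, Y, X), got {self.data.ndim}D"
            )
        if not self.materials:
            self.materials = [f"material_{i}" for i in range(self.data.shape[0])]
        if len(self.materials) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.materials)} names for {self.data.shape[0]} maps"
            )

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[1:]

    def map_for(self, material: str) -> np.ndarray:
        try:
            idx = self.materials.index(material)
        except ValueError:
            raise KeyError(f"no map for material {material!r}") from None
        return self.data[idx]
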