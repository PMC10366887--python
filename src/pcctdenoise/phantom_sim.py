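"""Synthetic spectral micro-CT phantoms with paired clean/noisy volumes.

The generator emulates the kind of data a four-threshold photon-counting
scanner produces after reconstruction: vial phantoms and soft-tissue-like
objects composed from a K-edge basis-material model (the clean,
iterative-reconstruction-like volume), plus an additive Gaussian noise
model whose standard deviation grows with threshold energy (the noisy,
filtered-backprojection-like volume).  Everything is seeded and
bit-reproducible so datasets can be regenerated from their manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import MaterialMaps, SpectralVolume
from .spectral_materials import SensitivityMatrix, compose

__all__ = [
    "PhantomSpec",
    "NoiseSpec",
    "PhantomObject",
    "build_sensitivity_matrix",
    "compose_phantom",
    "add_noise",
    "random_phantom_spec",
    "make_paired_dataset",
    "load_manifest_volume",
    "K_EDGES_KEV",
    "DEFAULT_ENERGIES_KEV",
    "DEFAULT_MATERIALS",
    "DEFAULT_NOISE_STD",
]

#: K-shell binding energies (keV) of the usual contrast elements.
K_EDGES_KEV = {
    "iodine": 33.2,
    "barium": 37.4,
    "gadolinium": 50.2,
    "tantalum": 67.4,
    "gold": 80.7,
    "bismuth": 90.5,
}

#: Default study conditions: four thresholds bracketing the iodine and
#: gadolinium K-edges, the basis set used with them, and per-energy noise
#: levels that rise with threshold energy.  Against the synthesized water
#: attenuation these correspond to roughly 75-220 HU of water-region noise,
#: the regime of filtered-backprojection photon-counting reconstructions
#: (above 70 HU at every threshold, worst in the photon-starved high bins).
DEFAULT_ENERGIES_KEV = (25.0, 34.0, 50.0, 60.0)
DEFAULT_MATERIALS = ("water", "iodine", "gadolinium", "calcium")
DEFAULT_NOISE_STD = (0.040, 0.044, 0.048, 0.053)  # 1/cm


@dataclass
class PhantomObject:
    """One geometric primitive: an axial cylinder or an ellipsoid."""

    shape: str  # "cylinder" | "ellipsoid"
    center: tuple  # (z, y, x) voxels
    radii: tuple  # cylinder: (half_height, radius); ellipsoid: (rz, ry, rx)
    material: str
    concentration: float  # g/mL for water, mg/mL otherwise
    aqueous: bool = True  # vial contents dissolved in 1 g/mL water

    def mask(self, grid_shape: tuple) -> np.ndarray:
        nz, ny, nx = grid_shape
        cz, cy, cx = self.center
        zz, yy, xx = np.ogrid[0:nz, 0:ny, 0:nx]
        if self.shape == "cylinder":
            hh, r = self.radii
            return (np.abs(zz - cz) <= hh) & ((yy - cy) ** 2 + (xx - cx) ** 2 <= r**2)
        if self.shape == "ellipsoid":
            rz, ry, rx = self.radii
            return ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + (
                (xx - cx) / rx
            ) ** 2 <= 1.0
        raise ValueError(f"unknown object shape {self.shape!r}")


@dataclass
class PhantomSpec:
    """Geometry + composition of one phantom."""

    grid_shape: tuple = (48, 64, 64)  # (Z, Y, X)
    voxel_size_mm: float = 0.125
    objects: list = field(default_factory=list)
    background_material: str = "water"
    background_concentration: float = 1.0

    def validate(self, M: SensitivityMatrix) -> None:
        if self.background_material not in M.materials:
            raise ValueError(f"unknown background material {self.background_material!r}")
        for obj in self.objects:
            if obj.concentration < 0:
                raise ValueError("concentrations must be non-negative")
            if obj.material not in M.materials:
                raise ValueError(f"unknown material {obj.material!r} in phantom spec")
            if not obj.mask(self.grid_shape).any():
                raise ValueError("phantom object lies outside the grid")


@dataclass
class NoiseSpec:
    """Per-energy additive Gaussian noise (1/cm) with an RNG seed."""

    std: tuple = DEFAULT_NOISE_STD
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.std) < 0):
            raise ValueError("noise std must be non-negative")

    def scaled(self, dose_factor: float) -> "NoiseSpec":
        """Emulate projection undersampling by factor f: noise grows ~sqrt(f)."""
        return NoiseSpec(tuple(np.asarray(self.std) * np.sqrt(dose_factor)), self.seed)


def build_sensitivity_matrix(
    material_names=DEFAULT_MATERIALS,
    energy_labels=DEFAULT_ENERGIES_KEV,
    square: bool = False,
) -> SensitivityMatrix:
    """Synthesize a plausible K-edge sensitivity matrix.

    Water follows a Compton + photoelectric energy dependence; contrast
    elements decay photoelectrically with a step increase above their
    K-edge, which is what makes the energy bins spectrally separable.
    Values are in 1/cm per g/mL (water) or per mg/mL (others), in the
    range measured on preclinical photon-counting systems.
    """
    names = list(material_names)
    if len(set(names)) != len(names):
        raise ValueError("duplicate material names")
    if len(names) < 1:
        raise ValueError("at least one material required")
    energies = np.asarray(energy_labels, dtype=np.float64)
    if square and energies.size != len(names):
        raise ValueError(
            f"square matrix demanded but {energies.size} energies != {len(names)} materials"
        )
    if energies.size < len(names):
        raise ValueError("need at least as many energies as materials")

    # per-mg/mL photoelectric amplitudes at 30 keV (1/cm), loosely element-Z ordered
    amp = {
        "calcium": 0.012,
        "iodine": 0.028,
        "barium": 0.030,
        "gadolinium": 0.034,
        "tantalum": 0.038,
        "gold": 0.040,
        "bismuth": 0.042,
    }
    rows = []
    for name in names:
        if name == "water":
            rows.append(0.18 + 230.0 / energies**2)
            continue
        a = amp.get(name, 0.025)
        spectrum = a * (30.0 / energies) ** 2.5
        kedge = K_EDGES_KEV.get(name)
        if kedge is not None:
            above = energies >= kedge
            spectrum = np.where(above, 5.0 * a * (kedge / energies) ** 2.5, spectrum)
        rows.append(spectrum)
    mat = np.stack(rows)
    if not np.isfinite(np.linalg.cond(mat @ mat.T)):
        raise ValueError("synthesized matrix is singular for these materials/energies")
    return SensitivityMatrix(mat, names, list(energies))


def compose_phantom(
    spec: PhantomSpec, M: SensitivityMatrix
) -> tuple[MaterialMaps, SpectralVolume]:
    """Rasterize a phantom spec into ground-truth maps and its clean volume.

    Voxel membership is by voxel center (no partial volume), so the
    returned maps are the exact ground truth of the composed volume.
    """
    spec.validate(M)
    maps = np.zeros((M.n_materials, *spec.grid_shape), dtype=np.float64)
    bg = M.materials.index(spec.background_material)
    maps[bg] = spec.background_concentration
    water = M.materials.index("water") if "water" in M.materials else None
    for obj in spec.objects:
        mask = obj.mask(spec.grid_shape)
        maps[:, mask] = 0.0
        maps[M.materials.index(obj.material), mask] = obj.concentration
        if obj.aqueous and water is not None and obj.material != "water":
            maps[water, mask] = 1.0
    material_maps = MaterialMaps(maps, list(M.materials), spec.voxel_size_mm)
    return material_maps, compose(material_maps, M)


def add_noise(clean: SpectralVolume, noise: NoiseSpec) -> SpectralVolume:
    """Additive zero-mean Gaussian noise, i.i.d. per voxel and energy."""
    std = np.asarray(noise.std, dtype=np.float64)
    if std.size != clean.n_energies:
        raise ValueError(
            f"{std.size} noise levels for {clean.n_energies} energy channels"
        )
    rng = np.random.default_rng(noise.seed)
    out = clean.data.astype(np.float32) + (
        rng.standard_normal(clean.data.shape).astype(np.float32)
        * std[:, None, None, None].astype(np.float32)
    )
    return SpectralVolume(out, list(clean.energies), clean.voxel_size_mm)


def random_phantom_spec(
    seed: int,
    grid_shape: tuple = (48, 64, 64),
    materials=DEFAULT_MATERIALS,
    n_vials: tuple = (3, 6),
    n_blobs: tuple = (2, 5),
    concentration_range: tuple = (2.0, 15.0),
    voxel_size_mm: float = 0.125,
) -> PhantomSpec:
    """Randomized vial phantom inside a soft-tissue-like body cylinder.

    Vials (axial cylinders of contrast solution) and ellipsoidal density
    blobs are placed at random inside a water body; concentrations are
    drawn uniformly from ``concentration_range`` (mg/mL).
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = grid_shape
    body_r = 0.42 * min(ny, nx)
    cy, cx = ny / 2, nx / 2
    objects = [
        PhantomObject(
            "cylinder", (nz / 2, cy, cx), (nz / 2 + 1, body_r), "water",
            float(rng.uniform(0.95, 1.05)), aqueous=False,
        )
    ]
    contrast = [m for m in materials if m != "water"]
    for _ in range(rng.integers(*n_vials, endpoint=True)):
        material = contrast[rng.integers(len(contrast))]
        r = max(1.0, rng.uniform(0.05, 0.12) * min(ny, nx))
        theta = rng.uniform(0, 2 * np.pi)
        rho = rng.uniform(0, body_r - r - 2)
        objects.append(
            PhantomObject(
                "cylinder",
                (nz / 2, cy + rho * np.sin(theta), cx + rho * np.cos(theta)),
                (rng.uniform(0.3, 0.5) * nz, r),
                material,
                float(rng.uniform(*concentration_range)),
            )
        )
    for _ in range(rng.integers(*n_blobs, endpoint=True)):
        theta = rng.uniform(0, 2 * np.pi)
        rho = rng.uniform(0, 0.6 * body_r)
        objects.append(
            PhantomObject(
                "ellipsoid",
                (
                    rng.uniform(0.25, 0.75) * nz,
                    cy + rho * np.sin(theta),
                    cx + rho * np.cos(theta),
                ),
                tuple(np.maximum(1.0, rng.uniform(0.06, 0.18) * np.array([nz, ny, nx]))),
                "water",
                float(rng.uniform(0.85, 1.15)),
                aqueous=False,
            )
        )
    # air outside the body cylinder
    return PhantomSpec(grid_shape, voxel_size_mm, objects, background_concentration=0.0)


def _volume_pair(volume_seed: int, grid_shape, M, noise_std):
    spec = random_phantom_spec(volume_seed, grid_shape, materials=M.materials)
    maps, clean = compose_phantom(spec, M)
    noisy = add_noise(
        SpectralVolume(clean.data.astype(np.float32), clean.energies, clean.voxel_size_mm),
        NoiseSpec(tuple(noise_std), volume_seed + 1),
    )
    clean32 = SpectralVolume(clean.data.astype(np.float32), clean.energies,
                             clean.voxel_size_mm)
    return spec, maps, clean32, noisy


def generate_paired_volumes(
    n_volumes: int,
    M: SensitivityMatrix | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    grid_shape: tuple = (48, 64, 64),
):
    """In-memory paired dataset: list of (clean, noisy, maps) triples."""
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes (1 train + 1 validation)")
    M = build_sensitivity_matrix() if M is None else M
    noise = NoiseSpec() if noise is None else noise
    root = np.random.default_rng(seed)
    out = []
    for _ in range(n_volumes):
        vseed = int(root.integers(2**31 - 2))
        _, maps, clean, noisy = _volume_pair(vseed, grid_shape, M, noise.std)
        out.append((clean, noisy, maps))
    return out


def make_paired_dataset(
    n_volumes: int,
    out_dir: str | Path,
    M: SensitivityMatrix | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    grid_shape: tuple = (48, 64, 64),
) -> Path:
    """Write paired noisy/clean NIfTI volumes plus a JSON manifest.

    The manifest records the sensitivity matrix, noise levels and the
    per-volume seeds, so the exact dataset can be regenerated from it.
    Returns the manifest path.
    """
    from .cli_io import write_spectral_volume

    if n_volumes < 2:
        raise ValueError("need at least 2 volumes (1 train + 1 validation)")
    M = build_sensitivity_matrix() if M is None else M
    noise = NoiseSpec() if noise is None else noise
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    root = np.random.default_rng(seed)
    entries = []
    for i in range(n_volumes):
        vseed = int(root.integers(2**31 - 2))
        _, _, clean, noisy = _volume_pair(vseed, grid_shape, M, noise.std)
        clean_path = out_dir / f"vol{i:03d}_clean.nii.gz"
        noisy_path = out_dir / f"vol{i:03d}_noisy.nii.gz"
        write_spectral_volume(clean, clean_path)
        write_spectral_volume(noisy, noisy_path)
        entries.append(
            {"index": i, "seed": vseed, "clean": clean_path.name, "noisy": noisy_path.name}
        )
    manifest = {
        "grid_shape": list(grid_shape),
        "seed": seed,
        "noise_std": [float(s) for s in noise.std],
        "sensitivity": {
            "matrix": M.matrix.tolist(),
            "materials": list(M.materials),
            "energies": [float(e) for e in M.energies],
        },
        "volumes": entries,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def load_manifest_volume(manifest_path: str | Path, index: int):
    """Regenerate one dataset volume pair from its manifest entry."""
    manifest = json.loads(Path(manifest_path).read_text())
    entry = manifest["volumes"][index]
    M = SensitivityMatrix(
        np.asarray(manifest["sensitivity"]["matrix"]),
        manifest["sensitivity"]["materials"],
        manifest["sensitivity"]["energies"],
    )
    _, maps, clean, noisy = _volume_pair(
        entry["seed"], tuple(manifest["grid_shape"]), M, manifest["noise_std"]
    )
    return clean, noisy, maps
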