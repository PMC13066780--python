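"""Deterministic synthetic volumes, coil sensitivity maps and masks.

Stands in for clinical coil-combined brain scans: a brain-like phantom of
nested ellipsoids with seeded small "lesions" providing the texture that
rigid registration needs, smooth complex coil maps normalized so the
root-sum-of-squares magnitude is one, and simple registration masks.
Intensities are real and nonnegative; complex phase enters only through
the coil maps.  Default spacing is isotropic 1 mm so mm and voxel units
coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "Volume",
    "CoilMaps",
    "make_phantom",
    "make_coil_maps",
    "svd_compress_coils",
    "make_registration_mask",
]


@dataclass
class Volume:
    """3D image (complex or real magnitude) with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def magnitude(self) -> "Volume":
        return Volume(np.abs(self.data), self.spacing)

    def save_nifti(self, path) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        data = self.data
        if np.iscomplexobj(data):
            data = np.abs(data)
        nib.save(nib.Nifti1Image(np.asarray(data, np.float32), affine), str(path))

    @classmethod
    def load_nifti(cls, path) -> "Volume":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.get_fdata(), np.float64), spacing)


@dataclass
class CoilMaps:
    """Per-coil complex sensitivity volumes on a common grid, shape
    (n_coils, nx, ny, nz)."""

    maps: np.ndarray

    def __post_init__(self):
        self.maps = np.asarray(self.maps, np.complex128)
        if self.maps.ndim != 4:
            raise ValueError("coil maps must have shape (n_coils, nx, ny, nz)")

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.maps.shape[1:]

    def rss(self) -> np.ndarray:
        return np.sqrt((np.abs(self.maps) ** 2).sum(axis=0))

    def normalized(self) -> "CoilMaps":
        """RSS normalization: sum_c |S_c|^2 = 1 wherever any coil is nonzero."""
        rss = self.rss()
        out = np.where(rss > 0, self.maps / np.where(rss > 0, rss, 1.0), 0.0)
        return CoilMaps(out)

    def save_h5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("maps", data=self.maps)

    @classmethod
    def load_h5(cls, path) -> "CoilMaps":
        with h5py.File(path, "r") as f:
            return cls(f["maps"][()])

    @classmethod
    def unit(cls, shape) -> "CoilMaps":
        return cls(np.ones((1, *shape), np.complex128))


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _ellipsoid(grid, center, semiaxes) -> np.ndarray:
    x, y, z = grid
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def make_phantom(n: int, seed: int = 0) -> Volume:
    """Brain-like deterministic phantom of size n^3, values in [0, 1].

    Nested ellipsoids (scalp / brain / off-center ventricle) plus at least
    20 small seeded ellipsoidal lesions of 1-4 voxel scale scattered inside
    the brain.  Structures are deliberately asymmetric so a 180-degree
    rotation does not map the phantom to itself, which makes rigid
    registration identifiable.
    """
    if n < 16:
        raise ValueError("phantom size must be >= 16")
    rng = np.random.default_rng(seed)
    c = (n - 1) / 2.0
    grid = np.meshgrid(*([np.arange(n, dtype=float)] * 3), indexing="ij")

    vol = np.zeros((n, n, n))
    vol[_ellipsoid(grid, (c, c, c), (0.44 * n, 0.40 * n, 0.42 * n))] = 0.35
    # brain, slightly off center to break point symmetry
    vol[_ellipsoid(grid, (c + 0.02 * n, c, c - 0.02 * n),
                   (0.36 * n, 0.32 * n, 0.34 * n))] = 0.7
    # one-sided "ventricle"
    vol[_ellipsoid(grid, (c + 0.10 * n, c + 0.08 * n, c),
                   (0.10 * n, 0.07 * n, 0.12 * n))] = 0.15

    brain_center = np.array([c + 0.02 * n, c, c - 0.02 * n])
    brain_axes = np.array([0.36 * n, 0.32 * n, 0.34 * n])
    n_lesions = max(20, n // 2)
    placed = 0
    while placed < n_lesions:
        u = rng.uniform(-0.8, 0.8, 3)
        if (u ** 2).sum() > 0.64:
            continue
        center = brain_center + u * brain_axes
        semi = rng.uniform(1.0, 4.0, 3) * max(1.0, n / 64.0)
        inten = rng.uniform(0.4, 1.0)
        vol[_ellipsoid(grid, center, semi)] = inten
        placed += 1
    # band-limit: acquired MR images carry no step edges, and sharp digital
    # edges bias interpolation-based resampling and ring under Fourier
    # sampling
    support = vol > 0
    vol = gaussian_filter(vol, sigma=0.9)
    vol[~support & (vol < 0.02)] = 0.0
    return Volume(np.clip(vol, 0.0, 1.0))


def make_coil_maps(n: int, n_coils: int, seed: int = 0) -> CoilMaps:
    """Smooth complex coil maps: Gaussian lobes on a ring around the volume
    with gentle linear phase ramps, RSS-normalized."""
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    rng = np.random.default_rng(seed)
    ax = np.arange(n, dtype=float)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    c = (n - 1) / 2.0
    width = 0.9 * n
    maps = np.empty((n_coils, n, n, n), np.complex128)
    for k in range(n_coils):
        phi = 2 * np.pi * k / n_coils + rng.uniform(-0.2, 0.2)
        zc = c + 0.3 * n * rng.uniform(-1, 1)
        cx = c + 0.75 * n * np.cos(phi)
        cy = c + 0.75 * n * np.sin(phi)
        mag = np.exp(-(((x - cx) ** 2 + (y - cy) ** 2 + (z - zc) ** 2)
                       / (2 * width ** 2)))
        ramp = rng.uniform(-0.5, 0.5, 3) * 2 * np.pi / n
        phase = ramp[0] * (x - c) + ramp[1] * (y - c) + ramp[2] * (z - c) \
            + rng.uniform(0, 2 * np.pi)
        maps[k] = mag * np.exp(1j * phase)
    return CoilMaps(maps).normalized()


def svd_compress_coils(maps: CoilMaps, k: int) -> CoilMaps:
    """Compress the coil dimension onto the top-k left singular vectors of
    the coil-by-voxel matrix, then RSS-renormalize."""
    if not (1 <= k <= maps.n_coils):
        raise ValueError("k must satisfy 1 <= k <= n_coils")
    mat = maps.maps.reshape(maps.n_coils, -1)
    u, _, _ = np.linalg.svd(mat, full_matrices=False)
    comp = (u[:, :k].conj().T @ mat).reshape(k, *maps.grid)
    return CoilMaps(comp).normalized()


def make_registration_mask(vol: Volume, mode: str = "full",
                           threshold: float = 0.0) -> np.ndarray:
    """Binary registration mask.

    ``full`` is the support of the volume; ``head_only`` additionally drops
    the lowest 20% of axial (last-axis) slices, the stand-in for ignoring
    the neck region during registration.
    """
    support = np.abs(vol.data) > threshold
    if mode == "full":
        return support
    if mode == "head_only":
        nz = vol.shape[2]
        cut = int(np.ceil(0.2 * nz))
        out = support.copy()
        out[:, :, :cut] = False
        return out
    raise ValueError(f"unknown mask mode {mode!r}")
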