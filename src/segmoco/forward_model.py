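"""Rigid-motion MRI forward model ``A = M F S C_theta`` and its adjoint.

The encoding chain is: rigid resampling ``C_theta`` (trilinear, rotation
about the volume center then translation), coil sensitivity weighting
``S``, centered orthonormal 3D FFT ``F`` (DC at ``n//2`` via pre/post
shifts), and line selection ``M`` on the ky-kz phase-encode plane (the
readout axis kx is fully sampled).  The adjoint uses the exact transpose of
the trilinear interpolation weights by default, so the operator passes a
dot test to floating-point accuracy and conjugate-gradient theory applies;
the cheaper approximation ``C_{theta^-1}`` is available behind a flag.

Line ordering: wherever a segment's samples are stored as a flat list, the
lines are in row-major (argwhere) order of the segment's binary mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import scipy.fft as spfft
from scipy.ndimage import map_coordinates

from .motion import IDENTITY, MotionTrajectory, RigidTransform
from .phantom import CoilMaps, Volume
from .sampling import SamplingScheme, segment_masks

__all__ = [
    "SegmentedKSpace",
    "apply_rigid",
    "apply_rigid_adjoint",
    "encode_segment",
    "adjoint_segment",
    "simulate_corrupted_acquisition",
    "fft3c",
    "ifft3c",
    "mask_lines",
]

_AXES = (-3, -2, -1)


def fft3c(x: np.ndarray) -> np.ndarray:
    """Centered orthonormal 3D FFT over the last three axes.

    Uses ``scipy.fft``, which preserves single precision (``numpy.fft``
    silently upcasts to double).
    """
    return np.fft.fftshift(
        spfft.fftn(np.fft.ifftshift(x, axes=_AXES), axes=_AXES, norm="ortho"),
        axes=_AXES)


def ifft3c(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(
        spfft.ifftn(np.fft.ifftshift(x, axes=_AXES), axes=_AXES,
                    norm="ortho"),
        axes=_AXES)


def mask_lines(mask: np.ndarray) -> np.ndarray:
    """(n_lines, 2) array of (ky, kz) indices in row-major order."""
    return np.argwhere(np.asarray(mask, bool))


# ---------------------------------------------------------------------------
# Rigid resampling C_theta and its exact transpose
# ---------------------------------------------------------------------------

def _sample_coords(shape, spacing, theta: RigidTransform) -> np.ndarray:
    """Voxel coordinates at which the input is sampled to produce the
    transformed output: ``T^-1(v)`` with ``T(p) = R(p - c) + c + t`` in mm,
    ``c`` the geometric grid center."""
    spacing = np.asarray(spacing, float)
    c = (np.asarray(shape, float) - 1.0) / 2.0 * spacing
    idx = np.indices(shape, dtype=float).reshape(3, -1)
    world = idx * spacing[:, None]
    rinv = theta.matrix().T
    src = rinv @ (world - c[:, None] - np.asarray(theta.t, float)[:, None]) + c[:, None]
    return src / spacing[:, None]


def _corner_data(coords, shape):
    i0 = np.floor(coords).astype(np.int64)
    frac = coords - i0
    for bits in range(8):
        off = np.array([(bits >> 2) & 1, (bits >> 1) & 1, bits & 1])
        idx = i0 + off[:, None]
        w = np.ones(coords.shape[1])
        valid = np.ones(coords.shape[1], bool)
        for ax in range(3):
            w *= frac[ax] if off[ax] else (1.0 - frac[ax])
            valid &= (idx[ax] >= 0) & (idx[ax] < shape[ax])
        yield idx, w, valid


def _trilinear_pull(data: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Sample ``data`` at fractional voxel ``coords``; outside-grid is zero.

    Delegates to ``scipy.ndimage.map_coordinates`` (order 1, constant 0),
    which computes exactly the trilinear weights that
    :func:`_trilinear_push` transposes.
    """
    # grid-constant: boundary samples interpolate partially against zeros,
    # exactly mirroring the corner weights of the transpose
    grid = coords.reshape(3, *data.shape)
    if np.iscomplexobj(data):
        out = map_coordinates(data.real, grid, order=1,
                              mode="grid-constant").astype(data.dtype)
        out += 1j * map_coordinates(data.imag, grid, order=1,
                                    mode="grid-constant")
        return out
    return map_coordinates(data, grid, order=1, mode="grid-constant")


def _trilinear_push(data: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Exact transpose of :func:`_trilinear_pull` (scatter-add of weights)."""
    out = np.zeros(data.size, dtype=data.dtype)
    vals = data.ravel()
    for idx, w, valid in _corner_data(coords, data.shape):
        lin = np.ravel_multi_index(
            [np.clip(idx[a], 0, data.shape[a] - 1) for a in range(3)], data.shape)
        np.add.at(out, lin[valid], (w * vals)[valid])
    return out.reshape(data.shape)


def apply_rigid(vol: Volume, theta: RigidTransform) -> Volume:
    """Resample a volume under a rigid transform with trilinear
    interpolation; samples falling outside the grid are zero."""
    if theta.is_identity():
        return Volume(vol.data.copy(), vol.spacing)
    coords = _sample_coords(vol.shape, vol.spacing, theta)
    return Volume(_trilinear_pull(vol.data, coords), vol.spacing)


def apply_rigid_adjoint(vol: Volume, theta: RigidTransform,
                        exact: bool = True) -> Volume:
    """Adjoint of :func:`apply_rigid` for the same ``theta``.

    ``exact=True`` applies the transpose of the interpolation weights;
    ``exact=False`` uses the approximation ``C_{theta^-1}``.
    """
    if theta.is_identity():
        return Volume(vol.data.copy(), vol.spacing)
    if not exact:
        return apply_rigid(vol, theta.invert())
    coords = _sample_coords(vol.shape, vol.spacing, theta)
    return Volume(_trilinear_push(vol.data, coords), vol.spacing)


# ---------------------------------------------------------------------------
# Segment encoding
# ---------------------------------------------------------------------------

def encode_segment(x: Volume, theta: RigidTransform, S: CoilMaps,
                   mask: np.ndarray) -> np.ndarray:
    """``M F S C_theta x``: per-coil k-space samples of one segment,
    shape (n_coils, nx, n_lines) with lines in row-major mask order."""
    if S.grid != x.shape:
        raise ValueError("coil map grid does not match the volume")
    xt = apply_rigid(x, theta)
    k = fft3c(S.maps * xt.data[None])
    lines = mask_lines(mask)
    return k[:, :, lines[:, 0], lines[:, 1]]


def adjoint_segment(y_seg: np.ndarray, theta: RigidTransform, S: CoilMaps,
                    mask: np.ndarray, spacing=(1.0, 1.0, 1.0),
                    exact_adjoint: bool = True) -> Volume:
    """``C_theta^H S^H F^-1 M^H y``: zero-fill, inverse FFT, conjugate-coil
    combine, then the adjoint of the rigid resampling."""
    lines = mask_lines(mask)
    if y_seg.shape[-1] != len(lines):
        raise ValueError("segment samples do not match the mask")
    n_coils, nx = y_seg.shape[0], y_seg.shape[1]
    k = np.zeros((n_coils, nx, *mask.shape), np.complex128)
    k[:, :, lines[:, 0], lines[:, 1]] = y_seg
    img = ifft3c(k)
    combined = (np.conj(S.maps) * img).sum(axis=0)
    return apply_rigid_adjoint(Volume(combined, spacing), theta, exact=exact_adjoint)


# ---------------------------------------------------------------------------
# Segmented k-space container
# ---------------------------------------------------------------------------

@dataclass
class SegmentedKSpace:
    """Per-segment multicoil k-space samples with their line lists."""

    scheme: SamplingScheme
    segments: list[np.ndarray]          # each (n_coils, nx, n_lines)
    lines: list[np.ndarray]             # each (n_lines, 2)
    noise_std: float = 0.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if len(self.segments) != self.scheme.n_segments:
            raise ValueError("segment count does not match the scheme")
        for seg, ln in zip(self.segments, self.lines):
            if seg.shape[-1] != len(ln):
                raise ValueError("segment data does not match its line list")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_coils(self) -> int:
        return self.segments[0].shape[0]

    @property
    def nx(self) -> int:
        return self.segments[0].shape[1]

    def masks(self) -> list[np.ndarray]:
        return segment_masks(self.scheme)

    def save_h5(self, path) -> None:
        import json
        with h5py.File(path, "w") as f:
            f.attrs["scheme"] = json.dumps(self.scheme.to_dict())
            f.attrs["noise_std"] = self.noise_std
            f.attrs["spacing"] = self.spacing
            for i, (seg, ln) in enumerate(zip(self.segments, self.lines)):
                g = f.create_group(f"segments/{i}")
                g.create_dataset("data", data=seg)
                g.create_dataset("lines", data=ln)

    @classmethod
    def load_h5(cls, path) -> "SegmentedKSpace":
        import json
        with h5py.File(path, "r") as f:
            scheme = SamplingScheme.from_dict(json.loads(f.attrs["scheme"]))
            n = scheme.n_segments
            segs = [f[f"segments/{i}/data"][()] for i in range(n)]
            lines = [f[f"segments/{i}/lines"][()] for i in range(n)]
            return cls(scheme=scheme, segments=segs, lines=lines,
                       noise_std=float(f.attrs["noise_std"]),
                       spacing=tuple(f.attrs["spacing"]))


def simulate_corrupted_acquisition(
    x: Volume,
    traj: MotionTrajectory,
    scheme: SamplingScheme,
    S: CoilMaps,
    noise_std: float = 0.0,
    seed: int = 0,
) -> SegmentedKSpace:
    """Retrospective motion corruption of a still volume.

    For each shot, the volume is moved to the shot's motion state and that
    shot's k-space lines are sampled from the transformed image; i.i.d.
    complex Gaussian noise of standard deviation ``noise_std`` (per complex
    sample) is added, and samples are assembled per segment.  Motion is
    constant within a shot.
    """
    if len(traj.assignment) != scheme.n_shots:
        raise ValueError("trajectory does not cover all shots of the scheme")

    # which state acquired each k-space line
    state_of_line = np.full((scheme.ny, scheme.nz), -1, np.int64)
    for shot, lines in enumerate(scheme.order):
        s = traj.assignment[shot]
        for ky, kz in lines:
            state_of_line[ky, kz] = s

    masks = segment_masks(scheme)
    seg_lines = [mask_lines(m) for m in masks]
    nx = x.shape[0]
    out = [np.zeros((S.n_coils, nx, len(ln)), np.complex128) for ln in seg_lines]

    for state in sorted(set(traj.assignment)):
        xt = apply_rigid(x, traj.states[state])
        k = fft3c(S.maps * xt.data[None])
        for seg, ln in enumerate(seg_lines):
            sel = state_of_line[ln[:, 0], ln[:, 1]] == state
            if np.any(sel):
                out[seg][:, :, sel] = k[:, :, ln[sel, 0], ln[sel, 1]]

    if noise_std > 0:
        rng = np.random.default_rng(seed)
        s = noise_std / np.sqrt(2.0)
        for seg in out:
            seg += rng.normal(0, s, seg.shape) + 1j * rng.normal(0, s, seg.shape)

    return SegmentedKSpace(scheme=scheme, segments=out, lines=seg_lines,
                           noise_std=noise_std, spacing=x.spacing)
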