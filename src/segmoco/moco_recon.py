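"""Motion-corrected CG-SENSE reconstruction.

Solves the least-squares problem ``min_x || M F S C_theta x - y ||^2`` by
conjugate gradients on the normal equations ``A^H A x = A^H y``, where the
forward operator stacks the per-segment encoders with their estimated
rigid transforms.  No explicit regularizer is used by default (basic CG;
early stopping acts as the regularizer — too many iterations amplify
noise); an optional Tikhonov term is available behind ``lam``.

When the trajectory is finer than the segmentation (per-shot states), the
operator splits each segment into per-state line blocks, so a per-shot
ground-truth trajectory can be used as an oracle.
"""

from __future__ import annotations

import numpy as np

from ._cg import CGResult, cg_hermitian
from .forward_model import (SegmentedKSpace, apply_rigid, apply_rigid_adjoint,
                            fft3c, ifft3c)
from .motion import MotionTrajectory
from .phantom import CoilMaps, Volume

__all__ = ["motion_corrected_cgsense", "uncorrected_recon"]


def _blocks(ks: SegmentedKSpace, traj: MotionTrajectory):
    """Split the measured lines into (transform, segment, line-index array)
    blocks of constant motion state; blocks sharing one transform across
    segments are merged into a single FFT pass (state index keyed, so an
    all-identity trajectory costs one block)."""
    scheme = ks.scheme
    state_of_line = np.full((scheme.ny, scheme.nz), -1, np.int64)
    for shot, lines in enumerate(scheme.order):
        s = traj.assignment[shot]
        for ky, kz in lines:
            state_of_line[ky, kz] = s
    per_state: dict[bytes, list] = {}
    thetas: dict[bytes, "RigidTransform"] = {}
    for seg, ln in enumerate(ks.lines):
        states = state_of_line[ln[:, 0], ln[:, 1]]
        if np.any(states < 0):
            raise ValueError("trajectory does not cover all measured lines")
        for state in np.unique(states):
            sel = np.where(states == state)[0]
            key = traj.states[state].params.tobytes()
            thetas[key] = traj.states[state]
            per_state.setdefault(key, []).append((seg, sel))
    return [(thetas[k], parts) for k, parts in per_state.items()]


def motion_corrected_cgsense(
    ks: SegmentedKSpace,
    traj: MotionTrajectory,
    S: CoilMaps,
    n_iters: int = 10,
    tol: float = 0.0,
    lam: float = 0.0,
    exact_adjoint: bool = True,
    x0: np.ndarray | None = None,
) -> Volume:
    """CG-SENSE reconstruction with rigid motion in the forward operator.

    Starts from ``x0 = A^H y`` unless an explicit ``x0`` (warm start) is
    given, and stops at ``n_iters`` iterations or
    relative residual below ``tol``.  Returns a complex volume carrying the
    CG diagnostics as attribute ``cg`` (:class:`CGResult`); take the
    magnitude for metrics.  Divergence or NaNs are flagged on ``cg``.
    """
    if len(traj.assignment) != ks.scheme.n_shots:
        raise ValueError("trajectory does not cover all shots")
    nx, (ny, nz) = ks.nx, (ks.scheme.ny, ks.scheme.nz)
    shape = (nx, ny, nz)
    spacing = ks.spacing
    blocks = _blocks(ks, traj)

    def ah_y() -> np.ndarray:
        acc = np.zeros(shape, np.complex128)
        for theta, parts in blocks:
            k = np.zeros((S.n_coils, nx, ny, nz), np.complex128)
            for seg, sel in parts:
                ln = ks.lines[seg][sel]
                k[:, :, ln[:, 0], ln[:, 1]] = ks.segments[seg][:, :, sel]
            img = (np.conj(S.maps) * ifft3c(k)).sum(axis=0)
            acc += apply_rigid_adjoint(Volume(img, spacing), theta,
                                       exact=exact_adjoint).data
        return acc

    def normal(x: np.ndarray) -> np.ndarray:
        acc = np.zeros(shape, np.complex128)
        for theta, parts in blocks:
            xt = apply_rigid(Volume(x, spacing), theta)
            k = fft3c(S.maps * xt.data[None])
            kz = np.zeros_like(k)
            for seg, sel in parts:
                ln = ks.lines[seg][sel]
                kz[:, :, ln[:, 0], ln[:, 1]] = k[:, :, ln[:, 0], ln[:, 1]]
            img = (np.conj(S.maps) * ifft3c(kz)).sum(axis=0)
            acc += apply_rigid_adjoint(Volume(img, spacing), theta,
                                       exact=exact_adjoint).data
        if lam > 0:
            acc = acc + lam * x
        return acc

    b = ah_y()
    if not b.any():
        out = Volume(b, spacing)
        out.cg = CGResult(x=b, residuals=[0.0], converged=True)
        return out
    start = b.copy() if x0 is None else np.asarray(x0, np.complex128)
    res = cg_hermitian(normal, b, x0=start, n_iters=n_iters, tol=tol)
    out = Volume(res.x, spacing)
    out.cg = res
    return out


def uncorrected_recon(ks: SegmentedKSpace, S: CoilMaps, n_iters: int = 10,
                      tol: float = 0.0, lam: float = 0.0) -> Volume:
    """Baseline reconstruction with a zero-motion estimate (all-identity
    trajectory)."""
    traj = MotionTrajectory.identity(1, ks.scheme.n_shots)
    return motion_corrected_cgsense(ks, traj, S, n_iters=n_iters, tol=tol,
                                    lam=lam)
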