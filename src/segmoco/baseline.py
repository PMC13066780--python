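"""Simplified alternating joint optimization of image and motion.

The comparison baseline interleaves (a) a CG image update with the current
motion estimate held fixed and (b) per-segment 6-parameter motion updates
minimizing that segment's k-space data-consistency residual
``|| M_s F S C_theta x - y_s ||^2`` by coordinate-wise pattern search with
a shrinking step (derivative-free, seeded segment visiting order).  Both
steps can only lower the global data-consistency residual, so it is
non-increasing across outer iterations.  This is a deliberate
simplification of joint image/motion optimizers from the literature:
comparisons to published implementations are qualitative only.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger("segmoco")

from .forward_model import SegmentedKSpace, encode_segment
from .moco_recon import motion_corrected_cgsense
from .motion import IDENTITY, MotionTrajectory, RigidTransform
from .phantom import CoilMaps, Volume

__all__ = ["alternating_moco", "refine_trajectory", "SearchParams",
           "AlternatingResult"]


@dataclass
class SearchParams:
    """Pattern-search settings for the per-segment motion update."""

    init_step_mm: float = 1.0
    init_step_deg: float = 1.0
    min_step: float = 0.05
    max_sweeps: int = 12


@dataclass
class AlternatingResult:
    volume: Volume
    trajectory: MotionTrajectory
    residual_trace: list[float]      # global ||Ax - y|| after each outer iter
    stagnated: bool = False


def _segment_residual(x: Volume, theta: RigidTransform, S: CoilMaps,
                      mask: np.ndarray, y_seg: np.ndarray) -> float:
    pred = encode_segment(x, theta, S, mask)
    return float(np.linalg.norm(pred - y_seg) ** 2)


def _pattern_search(x, theta, S, mask, y_seg, p: SearchParams):
    best = theta.params
    fbest = _segment_residual(x, RigidTransform.from_params(best), S, mask, y_seg)
    step = np.array([p.init_step_mm] * 3 + [p.init_step_deg] * 3)
    for _ in range(p.max_sweeps):
        improved = False
        for k in range(6):
            for sgn in (+1.0, -1.0):
                cand = best.copy()
                cand[k] += sgn * step[k]
                f = _segment_residual(x, RigidTransform.from_params(cand),
                                      S, mask, y_seg)
                if f < fbest:
                    best, fbest = cand, f
                    improved = True
        if not improved:
            step *= 0.5
            if step.max() < p.min_step:
                break
    return RigidTransform.from_params(best), fbest


def alternating_moco(
    ks: SegmentedKSpace,
    S: CoilMaps,
    outer_iters: int = 3,
    cg_iters: int = 5,
    search: SearchParams | None = None,
    seed: int = 0,
    stagnation_tol: float = 1e-6,
    init_traj: MotionTrajectory | None = None,
) -> AlternatingResult:
    """Alternate CG image updates and per-segment rigid motion search.

    ``outer_iters=0`` returns the CG reconstruction under the initial
    trajectory (uncorrected when no ``init_traj`` is given) and that
    trajectory.  ``init_traj`` warm-starts the motion estimate — used to
    polish a groupwise-registration estimate against the measured k-space.
    Stagnation (relative residual decrease below ``stagnation_tol`` over an
    outer iteration) is reported on the result.
    """
    search = search or SearchParams()
    rng = np.random.default_rng(seed)
    n_seg = ks.n_segments
    scheme = ks.scheme
    per = scheme.shots_per_segment
    assignment = [s for s in range(n_seg) for _ in range(per)]
    if init_traj is None:
        transforms = [IDENTITY] * n_seg
    else:
        if init_traj.n_states != n_seg:
            init_traj = init_traj.resample_to(
                MotionTrajectory.identity(n_seg, scheme.n_shots))
        transforms = list(init_traj.states)
    masks = ks.masks()

    def traj():
        return MotionTrajectory(list(transforms), assignment)

    def global_residual(x: Volume) -> float:
        acc = 0.0
        for s in range(n_seg):
            acc += _segment_residual(x, transforms[s], S, masks[s],
                                     ks.segments[s])
        return float(np.sqrt(acc))

    x = motion_corrected_cgsense(ks, traj(), S, n_iters=cg_iters)
    trace = [global_residual(x)]
    stagnated = False

    for _ in range(outer_iters):
        for s in rng.permutation(n_seg):
            transforms[s], _ = _pattern_search(x, transforms[s], S, masks[s],
                                               ks.segments[s], search)
        # warm start keeps the CG data residual monotone across A updates
        x = motion_corrected_cgsense(ks, traj(), S, n_iters=cg_iters,
                                     x0=x.data)
        trace.append(global_residual(x))
        if trace[-2] - trace[-1] < stagnation_tol * max(trace[0], 1e-30):
            stagnated = True

    return AlternatingResult(volume=x, trajectory=traj(),
                             residual_trace=trace, stagnated=stagnated)


# ---------------------------------------------------------------------------
# Data-consistency trajectory refinement
# ---------------------------------------------------------------------------

def _virtual_coil_data(ks: SegmentedKSpace, S: CoilMaps, k: int):
    """Project coil maps and measured data onto the top-k left singular
    vectors of the coil matrix (unnormalized, so the projected residual is
    the dominant part of the true residual)."""
    mat = S.maps.reshape(S.n_coils, -1)
    u, _, _ = np.linalg.svd(mat, full_matrices=False)
    uk = u[:, :k].conj().T
    maps = (uk @ mat).reshape(k, *S.grid).astype(np.complex64)
    segs = [np.einsum("vc,cxl->vxl", uk, seg).astype(np.complex64)
            for seg in ks.segments]
    return maps, segs


def refine_trajectory(
    ks: SegmentedKSpace,
    S: CoilMaps,
    traj0: MotionTrajectory | None = None,
    cg_iters: int = 5,
    loo_iters: int = 4,
    t_passes: int = 2,
    r_passes: int = 6,
    maxfev_trans: int = 40,
    maxfev_full: int = 70,
    maxfev_polish: int = 4,
    bound_mm: float = 8.0,
    bound_deg: float = 8.0,
    rot_trust_deg: float = 1.5,
    over_relax: float = 1.0,
    seed: int = 0,
    n_virtual_coils: int = 4,
) -> AlternatingResult:
    """Leave-one-out data-consistency motion estimation.

    Image-based groupwise registration of heavily undersampled segment
    reconstructions has limited precision (segments whose sampling misses
    the lowest spatial frequencies reconstruct poorly); this stage restores
    it by fitting each segment's six rigid parameters directly to its
    measured k-space lines.  The critical detail is the reference image:
    a reconstruction that includes segment ``s``'s own data reproduces
    those k-space lines at the *current* (wrong) pose, so the residual has
    a trap at the current estimate and plain alternating optimization
    stalls.  Each segment is therefore fitted against a leave-one-out
    reference reconstructed from the other segments only (warm-started CG,
    a few iterations), which removes the self-consistency trap; the full
    reference is refreshed after every sweep and the procedure is repeated
    ``passes`` times.

    The schedule matters because early references are consensus-blurred
    ghosted images whose high-frequency content misleads rotation fits:
    ``t_passes`` translation-only sweeps run first (rotations frozen),
    which deblurs the reference, then ``r_passes`` full 6-parameter sweeps
    move rotations only within a trust region of ``rot_trust_deg`` degrees
    around the current value per sweep, so estimates track the sharpening
    reference instead of latching onto ghosts.  The per-segment search is
    bounded Powell minimization on the residual of the ``n_virtual_coils``
    dominant SVD virtual coils in single precision.  An optional prior
    estimate ``traj0`` (e.g. from groupwise registration) provides initial
    translations and competes as a rotation initializer at the first full
    sweep.  The returned volume is a full-precision CG reconstruction
    under the final trajectory.
    """
    from scipy.optimize import least_squares, minimize
    from ._cg import cg_hermitian
    from .forward_model import apply_rigid, apply_rigid_adjoint, fft3c, ifft3c

    rng = np.random.default_rng(seed)
    n_seg = ks.n_segments
    scheme = ks.scheme
    assignment = [s for s in range(n_seg)
                  for _ in range(scheme.shots_per_segment)]
    if traj0 is not None and traj0.n_states != n_seg:
        traj0 = traj0.resample_to(
            MotionTrajectory.identity(n_seg, scheme.n_shots))
    masks = ks.masks()
    k_virt = min(n_virtual_coils, S.n_coils)
    vmaps, vsegs = _virtual_coil_data(ks, S, k_virt)
    vS = CoilMaps.__new__(CoilMaps)
    vS.maps = vmaps  # speed-only internal object, complex64 on purpose

    lo = np.array([-bound_mm] * 3 + [-bound_deg] * 3)
    hi = -lo
    transforms = [IDENTITY] * n_seg
    if traj0 is not None:
        # adopt the prior estimate; rotations are clipped to a modest range
        # so a wrong prior cannot pin the early frozen-rotation passes far
        # from identity (prior rotations are also re-probed at the first
        # full sweep)
        for s, st in enumerate(traj0.states):
            t = np.clip(np.asarray(st.t), -bound_mm, bound_mm)
            r = np.clip(np.asarray(st.r), -4.0, 4.0)
            transforms[s] = RigidTransform(t=tuple(t), r=tuple(r))

    def traj():
        return MotionTrajectory(list(transforms), assignment)

    def seg_residual(x32, s, theta):
        pred = encode_segment(x32, theta, vS, masks[s])
        return float(np.linalg.norm(pred - vsegs[s]) ** 2)

    # fast residual path for the Powell fits: the centering shifts of the
    # FFT are folded into precomputed permutations of the coil maps and
    # the measured lines, the rigid warp runs as a single native affine
    # resampling, and the reference image is constrained to the reals
    # (the simulated object is real; its reconstructed imaginary part is
    # ~1% numerical residue) — one float32 warp, one raw FFT, one gather
    # per evaluation
    import scipy.fft as _spfft
    from scipy.ndimage import affine_transform as _afft

    _shape3 = (ks.nx, scheme.ny, scheme.nz)
    _spacing = np.asarray(ks.spacing, float)
    _c_mm = (np.asarray(_shape3, float) - 1.0) / 2.0 * _spacing
    _vmaps_raw = np.fft.ifftshift(vS.maps, axes=(-3, -2, -1))
    _perm = [np.fft.fftshift(np.arange(n)) for n in _shape3]
    _raw_lines = [np.stack([_perm[1][ln[:, 0]], _perm[2][ln[:, 1]]], axis=1)
                  for ln in ks.lines]
    _y_raw = [np.fft.ifftshift(y, axes=1) for y in vsegs]

    def _resid_vec(x32, s):
        y = _y_raw[s]
        ln = _raw_lines[s]
        data = np.ascontiguousarray(x32.data.real, dtype=np.float32)

        def fvec(p):
            theta = RigidTransform.from_params(p)
            rinv = theta.matrix().T
            mat = (rinv * _spacing[None, :]) / _spacing[:, None]
            off = (_c_mm - rinv @ (_c_mm + np.asarray(theta.t))) / _spacing
            w = _afft(data, mat, offset=off, order=1, mode="grid-constant")
            w = np.fft.ifftshift(w)
            k = _spfft.fftn(_vmaps_raw * w[None], axes=(-3, -2, -1),
                            norm="ortho")
            r = (k[:, :, ln[:, 0], ln[:, 1]] - y).ravel()
            return np.concatenate([r.real, r.imag]).astype(np.float64)

        return fvec

    def seg_obj(x32, s):
        fvec = _resid_vec(x32, s)
        return lambda p: float(np.sum(fvec(p) ** 2))

    # Per-segment fits: exploratory passes use bounded Powell (large
    # initial direction steps escape the small-scale ruggedness of
    # ghosted early references); polish passes use bounded Gauss-Newton
    # (trust-region-reflective least squares with finite-difference
    # Jacobians), which reaches interpolation-limited precision in a
    # handful of Jacobian evaluations once the landscape is smooth
    def fit_translations(x32, s, p0, maxfev):
        obj = seg_obj(x32, s)
        p0 = np.clip(p0, lo, hi)

        def obj_t(t3):
            q = p0.copy()
            q[:3] = t3
            return obj(q)

        f0 = obj_t(p0[:3])
        r = minimize(obj_t, p0[:3], method="Powell",
                     bounds=[(-bound_mm, bound_mm)] * 3,
                     options={"maxfev": maxfev, "xtol": 0.005,
                              "ftol": 1e-9})
        out = p0.copy()
        if r.fun < f0:
            out[:3] = r.x
        return out

    def fit_full(x32, s, p0, maxfev, polish=False):
        # rotations move within a trust region around the incoming value
        rlo = np.maximum(p0[3:] - rot_trust_deg, -bound_deg)
        rhi = np.minimum(p0[3:] + rot_trust_deg, bound_deg)
        blo = np.concatenate([[-bound_mm] * 3, rlo])
        bhi = np.concatenate([[bound_mm] * 3, rhi])
        p0 = np.clip(p0, blo, bhi)
        if polish:
            fvec = _resid_vec(x32, s)
            f0 = float(np.sum(fvec(p0) ** 2))
            res = least_squares(fvec, p0, method="trf", bounds=(blo, bhi),
                                diff_step=0.05, max_nfev=maxfev,
                                xtol=1e-9, ftol=1e-9)
            fr = 2 * res.cost
            return (res.x, fr) if fr < f0 else (p0, f0)
        obj = seg_obj(x32, s)
        f0 = obj(p0)
        res = minimize(obj, p0, method="Powell",
                       bounds=list(zip(blo, bhi)),
                       options={"maxfev": maxfev, "xtol": 0.005,
                                "ftol": 1e-9})
        return (res.x, float(res.fun)) if res.fun < f0 else (p0, f0)

    # single-precision virtual-coil CG for the evolving reference images
    # (they only steer the fits; the caller gets a full-precision result)
    shape = (ks.nx, scheme.ny, scheme.nz)
    seg_lines = ks.lines

    def _seg_correction(x32, s, theta):
        """Zero-filled adjoint of segment ``s``'s unexplained data under
        ``theta`` — the first-order contribution of ``s`` to the
        reference."""
        pred = encode_segment(x32, theta, vS, masks[s])
        r = vsegs[s] - pred
        k = np.zeros((k_virt, *shape), np.complex64)
        ln = seg_lines[s]          # stored in row-major mask order
        k[:, :, ln[:, 0], ln[:, 1]] = r
        img = (np.conj(vmaps) * ifft3c(k)).sum(axis=0)
        return apply_rigid_adjoint(Volume(img, ks.spacing), theta).data

    def _loo_reference(x32, s):
        """First-order leave-one-out: subtract the zero-filled adjoint of
        segment ``s``'s unexplained data from the full reference.  This is
        the linearization of the exact LOO solve around ``x32`` and removes
        the self-consistency term at a single encode/adjoint's cost."""
        corr = _seg_correction(x32, s, transforms[s])
        return Volume(x32.data - corr, ks.spacing)

    def _reference(x0=None, iters=None, exclude=None):
        active = [s for s in range(n_seg) if s != exclude]

        def normal(z):
            acc = np.zeros(shape, np.complex64)
            for s in active:
                zt = apply_rigid(Volume(z, ks.spacing), transforms[s])
                k = fft3c(vmaps * zt.data[None])
                kz = np.zeros_like(k)
                ln = seg_lines[s]
                kz[:, :, ln[:, 0], ln[:, 1]] = k[:, :, ln[:, 0], ln[:, 1]]
                img = (np.conj(vmaps) * ifft3c(kz)).sum(axis=0)
                acc += apply_rigid_adjoint(Volume(img, ks.spacing),
                                           transforms[s]).data
            return acc

        b = np.zeros(shape, np.complex64)
        for s in active:
            k = np.zeros((k_virt, *shape), np.complex64)
            ln = seg_lines[s]
            k[:, :, ln[:, 0], ln[:, 1]] = vsegs[s]
            img = (np.conj(vmaps) * ifft3c(k)).sum(axis=0)
            b += apply_rigid_adjoint(Volume(img, ks.spacing),
                                     transforms[s]).data
        res = cg_hermitian(normal, b, x0=x0, n_iters=iters or cg_iters)
        return Volume(res.x.astype(np.complex64), ks.spacing)

    trace = []
    x32 = _reference()
    if traj0 is not None:
        # a poor prior can be worse than no prior: probe the total
        # residual of both initializations and keep the better one
        res_prior = sum(seg_residual(x32, s, transforms[s])
                        for s in range(n_seg))
        saved = list(transforms)
        transforms = [IDENTITY] * n_seg
        x32_id = _reference()
        res_id = sum(seg_residual(x32_id, s, transforms[s])
                     for s in range(n_seg))
        if res_prior < res_id:
            transforms = saved
        else:
            x32 = x32_id
        log.info("refine init: prior %.4g vs identity %.4g -> %s",
                 res_prior, res_id,
                 "prior" if res_prior < res_id else "identity")

    def log_pass(tag, t_pass):
        trace.append(float(np.sqrt(sum(
            seg_residual(x32, s, transforms[s]) for s in range(n_seg)))))
        log.info("refine %-8s residual %.4g  %.1fs", tag, trace[-1],
                 time.monotonic() - t_pass)

    for p_i in range(t_passes):
        t_pass = time.monotonic()
        for s in rng.permutation(n_seg):
            x_loo = _loo_reference(x32, int(s))
            p = fit_translations(x_loo, s, transforms[s].params, maxfev_trans)
            transforms[s] = RigidTransform.from_params(p)
            x32 = Volume(x_loo.data + _seg_correction(
                x_loo, int(s), transforms[s]), ks.spacing)
        x32 = _reference(x0=x32.data, iters=loo_iters)
        log_pass(f"t-{p_i + 1}", t_pass)
    for p_i in range(r_passes):
        t_pass = time.monotonic()
        maxfev = maxfev_full if p_i == 0 else maxfev_polish
        for s in rng.permutation(n_seg):
            x_loo = _loo_reference(x32, int(s))
            p0 = transforms[s].params
            if p_i == 0 and traj0 is not None:
                obj = seg_obj(x_loo, s)
                alt = p0.copy()
                alt[3:] = np.clip(traj0.states[s].r, -bound_deg, bound_deg)
                if obj(np.clip(alt, lo, hi)) < obj(np.clip(p0, lo, hi)):
                    p0 = alt
            p_prev = transforms[s].params
            p, f_fit = fit_full(x_loo, s, p0, maxfev, polish=p_i > 0)
            if over_relax > 0 and p_i > 0:
                # sweep errors contract geometrically because each fit is
                # biased by the other segments' residual errors in the
                # reference; extrapolating along the update direction
                # cancels part of that bias (step capped by the trust
                # radius, so a bad extrapolation is undone next sweep)
                step = np.clip(over_relax * (p - p_prev),
                               [-1.0] * 3 + [-rot_trust_deg] * 3,
                               [1.0] * 3 + [rot_trust_deg] * 3)
                p = np.clip(p + step, lo, hi)
            transforms[s] = RigidTransform.from_params(p)
            # re-insert the segment at its new pose so later fits in this
            # sweep see it correctly (first-order Gauss-Seidel update)
            x32 = Volume(x_loo.data + _seg_correction(
                x_loo, int(s), transforms[s]), ks.spacing)
        x32 = _reference(x0=x32.data, iters=loo_iters)
        log_pass(f"r-{p_i + 1}", t_pass)
        # stop when the sweep no longer pays for itself
        if len(trace) >= 2 and trace[-1] > 0.92 * trace[-2]:
            break
    x = motion_corrected_cgsense(ks, traj(), S, n_iters=cg_iters,
                                 x0=x32.data.astype(np.complex128))
    return AlternatingResult(volume=x, trajectory=traj(),
                             residual_trace=trace, stagnated=False)
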