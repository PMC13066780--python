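"""Groupwise rigid registration of segment reconstructions.

All segment volumes are jointly aligned to an evolving mean template: the
objective is the sum of squared differences between each rigidly
transformed segment volume and the template over a registration mask, plus
a quadratic penalty on the distance of each transform from the identity,

    sum_s sum_{v in mask} ( (C_{theta_s} xhat_s)(v) - T(v) )^2
        + w * sum_s ( ||t_s||^2 + (c * rot_s)^2 ),

with ``c`` the mm-per-degree scale.  For fixed transforms the template has
the closed-form minimizer ``T = mean_s C_{theta_s} xhat_s``; transforms are
updated per segment by bounded derivative-free descent on a Gaussian
multiresolution pyramid, coarse to fine, with the whole schedule optionally
repeated.  The mean template leaves a global pose undetermined (gauge
freedom); it is removed by left-composing all transforms with the inverse
of their Fréchet-mean at the end of every pyramid level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, spline_filter
from scipy.optimize import minimize

from .forward_model import _sample_coords
from .motion import (IDENTITY, ROT_SCALE_MM_PER_DEG, MotionTrajectory,
                     RigidTransform, mean_transform)
from .phantom import Volume

__all__ = [
    "GroupwiseResult",
    "groupwise_objective",
    "update_template",
    "groupwise_register",
    "register_pairwise",
]


@dataclass
class GroupwiseResult:
    transforms: list[RigidTransform]
    template: Volume
    objective_trace: list[dict]      # {level, repeat, step, value}
    settings: dict
    diverged: bool = False

    def trajectory(self, n_shots: int | None = None) -> MotionTrajectory:
        """Estimated subject-motion trajectory.

        ``transforms`` align each segment volume to the template, i.e. they
        undo the subject's motion; the motion states are their inverses.
        """
        n = len(self.transforms)
        if n_shots is None:
            n_shots = n
        per = n_shots // n
        return MotionTrajectory([t.invert() for t in self.transforms],
                                [s for s in range(n) for _ in range(per)])


def _warp(raw: np.ndarray, theta: RigidTransform, spacing,
          pref: np.ndarray | None = None) -> np.ndarray:
    """Cubic-spline rigid resampling used internally by the registration.

    Cubic interpolation is used here (unlike the trilinear forward model
    ``C_theta``) because linear interpolation of a warped image biases the
    SSD minimum by a sizeable fraction of a degree; spline resampling keeps
    the groupwise optimum on the true transform.  ``pref`` is an optional
    precomputed ``spline_filter`` of ``raw`` reused across evaluations.
    """
    if theta.is_identity():
        return raw.copy()
    coords = _sample_coords(raw.shape, spacing, theta)
    if pref is None:
        pref = spline_filter(raw, order=3, mode="constant")
    return map_coordinates(pref, coords.reshape(3, *raw.shape), order=3,
                           mode="constant", prefilter=False)


def _penalty(theta: RigidTransform, rot_scale: float) -> float:
    t = np.asarray(theta.t)
    rot = float(np.degrees(theta.rotation.magnitude()))
    return float(t @ t) + (rot_scale * rot) ** 2


def groupwise_objective(transforms, volumes, template: Volume,
                        mask: np.ndarray, reg_weight: float,
                        rot_scale: float = ROT_SCALE_MM_PER_DEG) -> float:
    """Evaluate the groupwise SSD + regularization objective."""
    mask = np.asarray(mask, bool)
    val = 0.0
    for theta, vol in zip(transforms, volumes):
        warped = _warp(np.abs(vol.data).astype(float), theta, vol.spacing)
        diff = warped[mask] - template.data[mask]
        val += float((diff ** 2).sum()) + reg_weight * _penalty(theta, rot_scale)
    return val


def update_template(transforms, volumes, mask: np.ndarray | None = None) -> Volume:
    """Closed-form template update: voxelwise mean of the transformed
    volumes (the exact minimizer of the quadratic data term)."""
    acc = None
    for theta, vol in zip(transforms, volumes):
        warped = _warp(np.abs(vol.data).astype(float), theta, vol.spacing)
        acc = warped if acc is None else acc + warped
    return Volume(acc / len(volumes), volumes[0].spacing)


# ---------------------------------------------------------------------------
# Multiresolution pyramid
# ---------------------------------------------------------------------------

def _downsample(data: np.ndarray, times: int) -> np.ndarray:
    for _ in range(times):
        data = gaussian_filter(data, sigma=1.0)[::2, ::2, ::2]
    return data


def _pyramid_level(volumes, mask, level: int):
    spacing0 = volumes[0].spacing
    spacing = tuple(s * 2 ** level for s in spacing0)
    vols = [Volume(_downsample(v.data.astype(float), level), spacing)
            for v in volumes]
    m = np.asarray(mask, float)
    for _ in range(level):
        m = gaussian_filter(m, sigma=1.0)[::2, ::2, ::2]
    return vols, m > 0.5, spacing


def groupwise_register(
    volumes: list[Volume],
    mask: np.ndarray,
    levels: int = 3,
    iters_per_level: int = 120,
    repeats: int = 1,
    reg_weight: float = 0.0,
    seed: int = 0,
    rot_scale: float = ROT_SCALE_MM_PER_DEG,
    alternations: int = 3,
    normalize: bool = True,
    init: list[RigidTransform] | None = None,
) -> GroupwiseResult:
    """Groupwise rigid registration, coarse to fine.

    ``iters_per_level`` bounds the function evaluations of each per-segment
    transform update; ``alternations`` template/transform rounds are run per
    level and the full coarse-to-fine schedule is repeated ``repeats``
    times.  Inputs are optionally normalized to unit RMS over the mask so
    segments reconstructed with different methods register comparably.
    ``seed`` is reserved for stochastic voxel subsampling and unused by the
    default deterministic optimizer.
    """
    if len(volumes) < 2:
        raise ValueError("groupwise registration needs at least 2 volumes")
    mask = np.asarray(mask, bool)
    if normalize:
        vols = []
        for v in volumes:
            rms = float(np.sqrt(np.mean(np.abs(v.data[mask]) ** 2))) or 1.0
            vols.append(Volume(np.abs(v.data) / rms, v.spacing))
    else:
        vols = [v.magnitude() for v in volumes]

    transforms = list(init) if init is not None else [IDENTITY] * len(vols)
    trace: list[dict] = []
    diverged = False

    for rep in range(repeats):
        for level in range(levels - 1, -1, -1):
            lvols, lmask, lspacing = _pyramid_level(vols, mask, level)
            if not lmask.any():
                continue
            prefs = [spline_filter(v.data, order=3, mode="constant")
                     for v in lvols]
            for alt in range(alternations):
                template = update_template(transforms, lvols, lmask)
                obj = groupwise_objective(transforms, lvols, template,
                                          lmask, reg_weight, rot_scale)
                trace.append({"level": level, "repeat": rep, "step": alt,
                              "value": obj})
                transforms = [
                    _update_one(theta, vol.data, pref, lspacing, template,
                                lmask, reg_weight, rot_scale, iters_per_level)
                    for theta, vol, pref in zip(transforms, lvols, prefs)
                ]
            # gauge fix at the end of the level
            g = mean_transform(transforms).invert()
            transforms = [g.compose(t) for t in transforms]
        # persistent divergence check per repeat, within final level
        lvals = [t["value"] for t in trace if t["repeat"] == rep and t["level"] == 0]
        if len(lvals) >= 2 and lvals[-1] > lvals[0] * (1 + 1e-6):
            diverged = True

    template = update_template(transforms, vols, mask)
    return GroupwiseResult(
        transforms=transforms, template=template, objective_trace=trace,
        settings={"levels": levels, "iters_per_level": iters_per_level,
                  "repeats": repeats, "reg_weight": reg_weight,
                  "rot_scale": rot_scale, "alternations": alternations,
                  "normalize": normalize, "seed": seed},
        diverged=diverged)


def register_pairwise(moving: Volume, fixed: Volume,
                      mask: np.ndarray | None = None, levels: int = 3,
                      iters_per_level: int = 200,
                      init: RigidTransform = IDENTITY) -> RigidTransform:
    """Rigid SSD registration of ``moving`` onto ``fixed``, coarse to fine.

    Used e.g. to register a motion-corrected reconstruction (which lives in
    the gauge-fixed mean pose of the groupwise estimate) to a reference
    volume before image-quality metrics are computed.
    """
    if mask is None:
        mask = np.ones(fixed.shape, bool)
    pair = [moving.magnitude(), fixed.magnitude()]
    theta = init
    for level in range(levels - 1, -1, -1):
        (mv, fx), lmask, lspacing = _pyramid_level(pair, mask, level)
        if not lmask.any():
            continue
        pref = spline_filter(mv.data, order=3, mode="constant")
        theta = _update_one(theta, mv.data, pref, lspacing, fx, lmask, 0.0,
                            ROT_SCALE_MM_PER_DEG, iters_per_level)
    return theta


#: Cap on SSD evaluation points per transform update; masked voxels beyond
#: this are strided deterministically (the optimizer's similarity estimate,
#: not the reported objective, which always uses the full mask).
MAX_EVAL_POINTS = 24_000


def _eval_points(mask: np.ndarray, cap: int = MAX_EVAL_POINTS) -> np.ndarray:
    """(3, M) voxel coordinates of (possibly strided) masked voxels."""
    idx = np.argwhere(mask)
    if len(idx) > cap:
        idx = idx[:: int(np.ceil(len(idx) / cap))]
    return idx.T.astype(float)


def _update_one(theta, raw, pref, spacing, template, mask, reg_weight,
                rot_scale, maxfev):
    pts = _eval_points(np.asarray(mask, bool))
    ipts = tuple(pts.astype(int))
    tvals = template.data[ipts]
    spacing = np.asarray(spacing, float)
    c = (np.asarray(raw.shape, float) - 1.0) / 2.0 * spacing
    world = pts * spacing[:, None]

    def obj(p):
        th = RigidTransform.from_params(p)
        src = (th.matrix().T @ (world - c[:, None]
                                - np.asarray(th.t, float)[:, None])
               + c[:, None]) / spacing[:, None]
        vals = map_coordinates(pref, src, order=3, mode="constant",
                               prefilter=False)
        diff = vals - tvals
        return float((diff ** 2).sum()) + reg_weight * _penalty(th, rot_scale)

    x0 = theta.params
    f0 = obj(x0)
    res = minimize(obj, x0, method="Powell",
                   options={"maxfev": maxfev, "xtol": 1e-4, "ftol": 1e-8})
    # never accept a worse iterate than the incoming transform
    if res.fun <= f0:
        return RigidTransform.from_params(res.x)
    return theta
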