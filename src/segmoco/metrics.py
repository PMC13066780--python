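"""Image-quality and trajectory-error metrics.

SSIM is the mean local structural similarity with Gaussian windows
(sigma 1.5, population covariances, standard constants) computed in 3D;
the data range is fixed to the reference volume's maximum because SSIM is
range-sensitive.  PSNR uses the reference maximum as peak.  The trajectory
error is gauge-invariant: the global rigid offset that best registers the
estimate to the reference is removed before per-state distances are
averaged, mirroring evaluation against a known simulated trajectory.
All metrics accept an optional evaluation mask.
"""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

from .motion import MotionTrajectory, remove_global_offset, transform_distance
from .phantom import Volume

__all__ = ["ssim", "psnr", "nmse", "trajectory_error", "evaluation_report"]


def _mag(v: Volume | np.ndarray) -> np.ndarray:
    data = v.data if isinstance(v, Volume) else v
    return np.abs(np.asarray(data, np.complex128)).astype(float)


def _check(a, b):
    a, b = _mag(a), _mag(b)
    if a.shape != b.shape:
        raise ValueError("volumes are on different grids")
    return a, b


def ssim(a: Volume, b: Volume, mask: np.ndarray | None = None) -> float:
    """3D SSIM of ``a`` against reference ``b`` (data range = max of ``b``)."""
    a, b = _check(a, b)
    data_range = float(b.max())
    if data_range == 0:
        raise ValueError("reference volume is zero")
    mean_s, full = structural_similarity(
        a, b, data_range=data_range, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, full=True)
    if mask is None:
        return float(mean_s)
    mask = np.asarray(mask, bool)
    return float(full[mask].mean())


def psnr(a: Volume, b: Volume, mask: np.ndarray | None = None) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical volumes."""
    a, b = _check(a, b)
    if mask is not None:
        mask = np.asarray(mask, bool)
        a, b = a[mask], b[mask]
    mse = float(np.mean((a - b) ** 2))
    peak = float(b.max())
    if peak == 0:
        raise ValueError("reference volume is zero")
    if mse == 0:
        return float("inf")
    return 10.0 * np.log10(peak ** 2 / mse)


def nmse(a: Volume, b: Volume, mask: np.ndarray | None = None) -> float:
    """Normalized mean squared error ``||a - b||^2 / ||b||^2``."""
    a, b = _check(a, b)
    if mask is not None:
        mask = np.asarray(mask, bool)
        a, b = a[mask], b[mask]
    denom = float(np.sum(b ** 2))
    if denom == 0:
        raise ValueError("reference volume is zero")
    return float(np.sum((a - b) ** 2)) / denom


def trajectory_error(est: MotionTrajectory, gt: MotionTrajectory
                     ) -> tuple[float, float]:
    """Gauge-invariant mean motion error ``(mean_mm, mean_deg)``.

    The estimate is resampled to the reference state grid (nearest shot),
    the best global rigid offset is removed, and translation / rotation
    distances are averaged over states.
    """
    if est.n_states != gt.n_states:
        est = est.resample_to(gt)
    aligned = remove_global_offset(est, gt)
    d = [transform_distance(a, b) for a, b in zip(aligned.states, gt.states)]
    d = np.asarray(d)
    return float(d[:, 0].mean()), float(d[:, 1].mean())


def evaluation_report(corrected: Volume, uncorrected: Volume | None,
                      reference: Volume, mask: np.ndarray | None = None,
                      est_traj: MotionTrajectory | None = None,
                      gt_traj: MotionTrajectory | None = None) -> dict:
    """Bundle the standard metrics into a JSON-serializable dict."""
    rep = {
        "ssim_corrected": ssim(corrected, reference, mask),
        "psnr_corrected": psnr(corrected, reference, mask),
        "nmse_corrected": nmse(corrected, reference, mask),
    }
    if uncorrected is not None:
        rep.update({
            "ssim_uncorrected": ssim(uncorrected, reference, mask),
            "psnr_uncorrected": psnr(uncorrected, reference, mask),
            "nmse_uncorrected": nmse(uncorrected, reference, mask),
        })
    if est_traj is not None and gt_traj is not None:
        mm, deg = trajectory_error(est_traj, gt_traj)
        rep.update({"motion_error_mm": mm, "motion_error_deg": deg})
    return rep
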