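"""End-to-end experiment orchestration and the segment-count sweep.

An experiment is fully described by a YAML-serializable config with
explicit seeds: generate a phantom, coil maps, a sampling scheme and a
motion trajectory; simulate the motion-corrupted segmented acquisition;
reconstruct every segment; groupwise-register the segment volumes to
estimate the motion; run the motion-corrected and uncorrected CG-SENSE
reconstructions; and evaluate SSIM/PSNR/NMSE against the known still
phantom plus the gauge-invariant trajectory error.  Identical configs and
seeds give byte-identical reports.

The default desk-scale experiment uses a 64^3 phantom, 8 coils and
64 shots of 64 lines (full coverage of the 64x64 phase-encode plane) in
16 segments of 4 shots — a scaled-down version of the reference 240^3 /
320-shot / 64-segment protocol that runs in minutes on one CPU.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

log = logging.getLogger("segmoco")

import numpy as np
import yaml

from . import metrics as _metrics
from .forward_model import (SegmentedKSpace, mask_lines,
                            simulate_corrupted_acquisition)
from .moco_recon import motion_corrected_cgsense, uncorrected_recon
from .motion import MotionTrajectory, make_scripted_trajectory, \
    sample_random_trajectory
from .phantom import CoilMaps, Volume, make_coil_maps, make_phantom, \
    make_registration_mask
from .baseline import refine_trajectory
from .motion import IDENTITY, RigidTransform, transform_distance
from .registration import groupwise_register, register_pairwise
from .sampling import SamplingScheme, generate_disorder_scheme, segment_masks
from .segment_recon import reconstruct_all_segments
from .forward_model import apply_rigid

__all__ = ["default_config", "load_config", "run_experiment",
           "segment_count_sweep", "regroup_segments"]


def default_config(seed: int = 0) -> dict:
    """Desk-scale default experiment configuration."""
    return {
        "name": "default",
        "seed": seed,
        "phantom": {"n": 64, "seed": seed + 1},
        "coils": {"n_coils": 8, "seed": seed + 2},
        "scheme": {"ny": 64, "nz": 64, "n_shots": 64, "tfe_factor": 64,
                   "shots_per_segment": 4, "seed": seed + 3},
        "trajectory": {"kind": "random", "trans_std_mm": 2.0,
                       "rot_std_deg": 2.0, "seed": seed + 4},
        "noise_std": 0.0,
        "noise_seed": seed + 5,
        "segment_recon": {"method": "tv_cs",
                          "params": {"tv_weight": 0.01, "n_iters": 30}},
        "registration": {"levels": 2, "iters_per_level": 100, "repeats": 1,
                         "reg_weight": 0.0, "alternations": 2},
        "refine": {"enabled": True, "cg_iters": 5, "t_passes": 2,
                   "r_passes": 6, "max_plausible_trans_mm": 10.0,
                   "max_plausible_rot_deg": 10.0},
        "recon": {"n_iters": 10, "tol": 0.0},
        "mask_mode": "full",
        "align_to_reference": True,
    }


def load_config(path) -> dict:
    with open(path) as f:
        user = yaml.safe_load(f) or {}
    cfg = default_config(int(user.get("seed", 0)))
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    _validate(cfg)
    return cfg


def _validate(cfg: dict) -> None:
    sch = cfg["scheme"]
    if sch["n_shots"] * sch["tfe_factor"] > sch["ny"] * sch["nz"]:
        raise ValueError("config: scheme exceeds phase-encode plane capacity")
    if sch["n_shots"] % sch["shots_per_segment"]:
        raise ValueError("config: n_shots not divisible by shots_per_segment")
    if cfg["segment_recon"]["method"] not in ("zero_filled", "cg_tikhonov",
                                              "tv_cs", "learned"):
        raise ValueError("config: unknown segment_recon method")


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _clamp_outliers(traj: MotionTrajectory, max_trans: float,
                    max_rot: float) -> MotionTrajectory:
    """Reset implausibly large states to identity (registration escapes)."""
    states = []
    for s in traj.states:
        trans, rot = transform_distance(s, IDENTITY)
        states.append(IDENTITY if (trans > max_trans or rot > max_rot) else s)
    return MotionTrajectory(states, list(traj.assignment))


def _make_trajectory(cfg: dict, n_shots: int, n_segments: int
                     ) -> MotionTrajectory:
    t = cfg["trajectory"]
    kind = t.get("kind", "random")
    n_states = t.get("n_states", n_segments)
    if kind == "still":
        return MotionTrajectory.identity(n_states, n_shots)
    if kind == "random":
        return sample_random_trajectory(n_states, t["trans_std_mm"],
                                        t["rot_std_deg"], t["seed"],
                                        n_shots=n_shots)
    if kind == "scripted":
        return make_scripted_trajectory(
            t["pattern"], n_states, amplitude_mm=t.get("amplitude_mm", 0.0),
            amplitude_deg=t.get("amplitude_deg", 5.0),
            jump_period=t.get("jump_period", 8), seed=t["seed"],
            n_shots=n_shots)
    raise ValueError(f"unknown trajectory kind {kind!r}")


def run_experiment(cfg: dict, outdir=None) -> dict:
    """Execute the full simulate / estimate / correct / evaluate flow.

    Returns the JSON report; with ``outdir`` set, all intermediate
    artifacts (phantom, coils, k-space, trajectories, reconstructions,
    report, config) are persisted there.
    """
    cfg = copy.deepcopy(cfg)
    _validate(cfg)
    stage = "setup"
    t_stage = time.monotonic()

    def _tick(done):
        nonlocal t_stage
        log.info("stage %-14s %6.1fs", done, time.monotonic() - t_stage)
        t_stage = time.monotonic()

    try:
        x = make_phantom(cfg["phantom"]["n"], cfg["phantom"]["seed"])
        S = make_coil_maps(cfg["phantom"]["n"], cfg["coils"]["n_coils"],
                           cfg["coils"]["seed"])
        sch = cfg["scheme"]
        scheme = generate_disorder_scheme(
            sch["ny"], sch["nz"], sch["n_shots"], sch["tfe_factor"],
            sch["seed"], shots_per_segment=sch["shots_per_segment"])
        gt_traj = _make_trajectory(cfg, scheme.n_shots, scheme.n_segments)

        _tick(stage)
        stage = "simulate"
        ks = simulate_corrupted_acquisition(x, gt_traj, scheme, S,
                                            noise_std=cfg["noise_std"],
                                            seed=cfg["noise_seed"])

        _tick(stage)
        stage = "segment_recon"
        segs = reconstruct_all_segments(ks, S,
                                        method=cfg["segment_recon"]["method"],
                                        params=cfg["segment_recon"].get("params"))

        _tick(stage)
        stage = "registration"
        mask = make_registration_mask(x, cfg["mask_mode"])
        reg = cfg["registration"]
        gw = groupwise_register(segs.volumes, mask, levels=reg["levels"],
                                iters_per_level=reg["iters_per_level"],
                                repeats=reg["repeats"],
                                reg_weight=reg["reg_weight"],
                                seed=cfg["seed"],
                                alternations=reg.get("alternations", 3))
        est_traj = gw.trajectory(n_shots=scheme.n_shots)

        _tick(stage)
        stage = "refine"
        warm = None
        rf = cfg.get("refine", {"enabled": False})
        if rf.get("enabled", True):
            # image registration of few-percent-sampled segments has limited
            # precision: clamp implausible outliers to identity, then polish
            # all transforms against the measured k-space
            est_traj = _clamp_outliers(
                est_traj, rf.get("max_plausible_trans_mm", 10.0),
                rf.get("max_plausible_rot_deg", 10.0))
            res = refine_trajectory(ks, S, est_traj,
                                    cg_iters=rf.get("cg_iters", 5),
                                    t_passes=rf.get("t_passes", 2),
                                    r_passes=rf.get("r_passes", 6),
                                    seed=cfg["seed"])
            est_traj = res.trajectory
            warm = res.volume.data

        _tick(stage)
        stage = "moco_recon"
        rc = cfg["recon"]
        corrected = motion_corrected_cgsense(ks, est_traj, S,
                                             n_iters=rc["n_iters"],
                                             tol=rc["tol"], x0=warm)
        uncorr = uncorrected_recon(ks, S, n_iters=rc["n_iters"],
                                   tol=rc["tol"])

        _tick(stage)
        stage = "evaluate"
        corrected_eval = corrected.magnitude()
        if cfg["align_to_reference"]:
            g = register_pairwise(corrected_eval, x, mask)
            corrected_eval = apply_rigid(corrected_eval, g)
        report = _metrics.evaluation_report(
            corrected_eval, uncorr.magnitude(), x, mask=None,
            est_traj=est_traj, gt_traj=gt_traj)
        report["ssim_corrected_vs_uncorrected"] = _metrics.ssim(
            corrected.magnitude(), uncorr.magnitude())
        report["config"] = cfg
        report["config_hash"] = config_hash(cfg)
        report["n_segments"] = scheme.n_segments
        report["registration_diverged"] = gw.diverged
        _tick(stage)
    except Exception as err:
        raise RuntimeError(f"experiment failed at stage {stage!r}") from err

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        x.save_nifti(outdir / "phantom.nii.gz")
        S.save_h5(outdir / "coils.h5")
        ks.save_h5(outdir / "kspace.h5")
        scheme.save(outdir / "scheme.json")
        corrected.magnitude().save_nifti(outdir / "corrected.nii.gz")
        uncorr.magnitude().save_nifti(outdir / "uncorrected.nii.gz")
        with open(outdir / "trajectory_est.json", "w") as f:
            json.dump(est_traj.to_dict(), f)
        with open(outdir / "trajectory_gt.json", "w") as f:
            json.dump(gt_traj.to_dict(), f)
        with open(outdir / "config.yaml", "w") as f:
            yaml.safe_dump(cfg, f)
        with open(outdir / "report.json", "w") as f:
            json.dump(report, f, sort_keys=True, indent=2)
    return report


# ---------------------------------------------------------------------------
# Segment-count sweep
# ---------------------------------------------------------------------------

def regroup_segments(ks: SegmentedKSpace, shots_per_segment: int
                     ) -> SegmentedKSpace:
    """Repartition measured k-space into a different number of segments
    (same shots, same samples, different shot grouping)."""
    scheme = ks.scheme
    if scheme.n_shots % shots_per_segment:
        raise ValueError("shots_per_segment must divide n_shots")
    new_scheme = SamplingScheme(
        ny=scheme.ny, nz=scheme.nz, tfe_factor=scheme.tfe_factor,
        n_shots=scheme.n_shots, order=scheme.order,
        shots_per_segment=shots_per_segment, seed=scheme.seed)
    # scatter existing samples onto the plane, then gather per new segment
    full = np.zeros((ks.n_coils, ks.nx, scheme.ny, scheme.nz), np.complex128)
    for seg, ln in zip(ks.segments, ks.lines):
        full[:, :, ln[:, 0], ln[:, 1]] = seg
    masks = segment_masks(new_scheme)
    lines = [mask_lines(m) for m in masks]
    segs = [full[:, :, ln[:, 0], ln[:, 1]] for ln in lines]
    return SegmentedKSpace(scheme=new_scheme, segments=segs, lines=lines,
                           noise_std=ks.noise_std, spacing=ks.spacing)


def segment_count_sweep(cfg: dict, counts: list[int]) -> list[dict]:
    """Trade-off between per-segment image quality and temporal resolution.

    Simulates one corrupted dataset from the config, then repartitions it
    into each requested segment count and runs estimation + correction on
    the shared data.  Returns one result row per count.
    """
    cfg = copy.deepcopy(cfg)
    _validate(cfg)
    sch = cfg["scheme"]
    for c in counts:
        if sch["n_shots"] % c:
            raise ValueError(f"segment count {c} does not divide n_shots")

    x = make_phantom(cfg["phantom"]["n"], cfg["phantom"]["seed"])
    S = make_coil_maps(cfg["phantom"]["n"], cfg["coils"]["n_coils"],
                       cfg["coils"]["seed"])
    scheme = generate_disorder_scheme(
        sch["ny"], sch["nz"], sch["n_shots"], sch["tfe_factor"], sch["seed"],
        shots_per_segment=sch["shots_per_segment"])
    gt_traj = _make_trajectory(cfg, scheme.n_shots, scheme.n_segments)
    ks0 = simulate_corrupted_acquisition(x, gt_traj, scheme, S,
                                         noise_std=cfg["noise_std"],
                                         seed=cfg["noise_seed"])
    mask = make_registration_mask(x, cfg["mask_mode"])
    rc, reg = cfg["recon"], cfg["registration"]

    rows = []
    for count in counts:
        ks = regroup_segments(ks0, scheme.n_shots // count)
        if cfg.get("oracle_trajectory"):
            # ground truth resampled to the count's state grid (upper bound)
            est = gt_traj.resample_to(
                MotionTrajectory.identity(count, scheme.n_shots))
        elif count < 2:
            # a single state cannot express intersegment motion
            est = MotionTrajectory.identity(1, scheme.n_shots)
        else:
            segs = reconstruct_all_segments(
                ks, S, method=cfg["segment_recon"]["method"],
                params=cfg["segment_recon"].get("params"))
            gw = groupwise_register(segs.volumes, mask, levels=reg["levels"],
                                    iters_per_level=reg["iters_per_level"],
                                    repeats=reg["repeats"],
                                    reg_weight=reg["reg_weight"],
                                    seed=cfg["seed"],
                                    alternations=reg.get("alternations", 3))
            est = gw.trajectory(n_shots=scheme.n_shots)
            rf = cfg.get("refine", {"enabled": False})
            if rf.get("enabled", True):
                est = _clamp_outliers(
                    est, rf.get("max_plausible_trans_mm", 10.0),
                    rf.get("max_plausible_rot_deg", 10.0))
                est = refine_trajectory(
                    ks, S, est, cg_iters=rf.get("cg_iters", 5),
                    t_passes=rf.get("t_passes", 2),
                    r_passes=rf.get("r_passes", 6),
                    seed=cfg["seed"]).trajectory
        corrected = motion_corrected_cgsense(ks, est, S, n_iters=rc["n_iters"],
                                             tol=rc["tol"])
        cmag = corrected.magnitude()
        if cfg["align_to_reference"]:
            g = register_pairwise(cmag, x, mask)
            cmag = apply_rigid(cmag, g)
        rows.append({"n_segments": count,
                     "ssim": _metrics.ssim(cmag, x),
                     "psnr": _metrics.psnr(cmag, x)})
    return rows
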