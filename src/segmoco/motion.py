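"""Rigid transforms and motion trajectories.

A rigid transform is parameterized by a translation ``t`` (mm) and Euler
angles ``r`` (degrees).  The rotation convention, fixed package-wide and
echoed in every trajectory JSON, is:

* extrinsic rotations about the volume center, applied in x -> y -> z order
  (rotation matrix ``R = Rz @ Ry @ Rx``);
* rotation is applied before translation.

Transforms act on center-relative coordinates ``q = p - c`` (``c`` the
volume center) as ``q' = R q + t``, so the image of the volume center under
a state's transform is ``c + t`` — rotation about the center contributes
nothing to the center's displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

#: Convention string stored in trajectory JSON files.
CONVENTION = "extrinsic-xyz-deg, rotation about volume center before translation (mm)"

#: Degrees-to-mm scale used when rotation and translation errors are combined
#: into a single scalar (1 mm per degree by default).
ROT_SCALE_MM_PER_DEG = 1.0


# ---------------------------------------------------------------------------
# RigidTransform
# ---------------------------------------------------------------------------

def _canonical_deg(a: float) -> float:
    """Wrap an angle into (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


@dataclass(frozen=True)
class RigidTransform:
    """6-parameter rigid transform: translation (mm) and rotation (deg)."""

    t: tuple[float, float, float] = (0.0, 0.0, 0.0)
    r: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        t = tuple(float(v) for v in self.t)
        r = tuple(_canonical_deg(float(v)) for v in self.r)
        if not all(np.isfinite(t)) or not all(np.isfinite(r)):
            raise ValueError("non-finite rigid parameters")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "r", r)

    # -- conversions --------------------------------------------------------
    @property
    def rotation(self) -> Rotation:
        return Rotation.from_euler("xyz", self.r, degrees=True)

    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix (extrinsic xyz)."""
        return self.rotation.as_matrix()

    @classmethod
    def from_rotation(cls, rot: Rotation, t) -> "RigidTransform":
        r = rot.as_euler("xyz", degrees=True)
        return cls(t=tuple(np.asarray(t, float)), r=tuple(r))

    # -- group operations ----------------------------------------------------
    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform acting as "apply ``other``, then ``self``"."""
        ra, rb = self.rotation, other.rotation
        t = ra.apply(other.t) + np.asarray(self.t)
        return RigidTransform.from_rotation(ra * rb, t)

    def invert(self) -> "RigidTransform":
        rinv = self.rotation.inv()
        return RigidTransform.from_rotation(rinv, -rinv.apply(self.t))

    @property
    def params(self) -> np.ndarray:
        """(tx, ty, tz, rx, ry, rz) as a float vector."""
        return np.asarray(self.t + self.r, float)

    @classmethod
    def from_params(cls, p) -> "RigidTransform":
        p = np.asarray(p, float)
        return cls(t=tuple(p[:3]), r=tuple(p[3:6]))

    def is_identity(self, tol: float = 1e-12) -> bool:
        return bool(np.all(np.abs(self.params) <= tol))


IDENTITY = RigidTransform()


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Composition "apply ``b``, then ``a``"."""
    return a.compose(b)


def invert(a: RigidTransform) -> RigidTransform:
    return a.invert()


def transform_distance(a: RigidTransform, b: RigidTransform) -> tuple[float, float]:
    """Distance between two rigid transforms.

    Returns ``(trans_mm, rot_deg)`` where ``trans_mm`` is the Euclidean norm
    of the translation of ``b^-1 ∘ a`` (equal to the distance between the two
    transformed volume-center positions) and ``rot_deg`` the geodesic angle
    of its rotation part.
    """
    rel = b.invert().compose(a)
    trans = float(np.linalg.norm(rel.t))
    rot = float(np.degrees(rel.rotation.magnitude()))
    return trans, rot


# ---------------------------------------------------------------------------
# MotionTrajectory
# ---------------------------------------------------------------------------

@dataclass
class MotionTrajectory:
    """Ordered motion states plus a shot -> state assignment.

    Shots belonging to one state must be contiguous in acquisition order: a
    state is a contiguous stretch of the scan during which the subject is
    modeled as still.
    """

    states: list[RigidTransform]
    assignment: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.states:
            raise ValueError("trajectory needs at least one state")
        a = list(self.assignment)
        if a:
            if min(a) < 0 or max(a) >= len(self.states):
                raise ValueError("assignment references unknown state")
            if any(a[i + 1] < a[i] for i in range(len(a) - 1)):
                raise ValueError("shots of one state must be contiguous")
        self.assignment = a

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_of_shot(self, shot: int) -> RigidTransform:
        return self.states[self.assignment[shot]]

    @classmethod
    def identity(cls, n_states: int, n_shots: int | None = None) -> "MotionTrajectory":
        states = [IDENTITY] * n_states
        return cls(states, _uniform_assignment(n_states, n_shots))

    def resample_to(self, ref: "MotionTrajectory") -> "MotionTrajectory":
        """Resample onto ``ref``'s state grid by nearest-shot lookup.

        Each reference state is matched with the state of this trajectory
        that covers the same shots (the first shared shot decides).
        """
        if not self.assignment or not ref.assignment:
            raise ValueError("resampling requires shot assignments")
        if len(self.assignment) != len(ref.assignment):
            raise ValueError("trajectories cover different shot counts")
        states = []
        for s in range(ref.n_states):
            shot = ref.assignment.index(s)
            states.append(self.state_of_shot(shot))
        return MotionTrajectory(states, list(ref.assignment))

    def to_dict(self) -> dict:
        return {
            "convention": CONVENTION,
            "states": [{"t": list(s.t), "r": list(s.r)} for s in self.states],
            "assignment": list(self.assignment),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MotionTrajectory":
        states = [RigidTransform(t=tuple(s["t"]), r=tuple(s["r"])) for s in d["states"]]
        return cls(states, list(d.get("assignment", [])))


def _uniform_assignment(n_states: int, n_shots: int | None) -> list[int]:
    if n_shots is None:
        n_shots = n_states
    if n_shots % n_states:
        raise ValueError("n_shots must be a multiple of n_states")
    per = n_shots // n_states
    return [s for s in range(n_states) for _ in range(per)]


# ---------------------------------------------------------------------------
# Trajectory generators
# ---------------------------------------------------------------------------

def sample_random_trajectory(
    n_states: int,
    trans_std_mm: float,
    rot_std_deg: float,
    seed: int,
    n_shots: int | None = None,
) -> MotionTrajectory:
    """Draw i.i.d. zero-mean normal rigid motion per state.

    Each of the six parameters is drawn independently: translations with
    per-axis std ``trans_std_mm``, rotations with per-axis std
    ``rot_std_deg``.  This is the random intersegment motion protocol: stds
    of (2 mm, 1 deg) give "medium" motion and (12 mm, 6 deg) "extreme"
    motion, whose mean pairwise center distances are 4.5 and 27.1 mm.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if trans_std_mm < 0 or rot_std_deg < 0:
        raise ValueError("stds must be >= 0")
    rng = np.random.default_rng(seed)
    t = rng.normal(0.0, trans_std_mm, (n_states, 3))
    r = rng.normal(0.0, rot_std_deg, (n_states, 3))
    states = [RigidTransform(t=tuple(t[i]), r=tuple(r[i])) for i in range(n_states)]
    return MotionTrajectory(states, _uniform_assignment(n_states, n_shots))


def mean_pairwise_center_distance(traj: MotionTrajectory) -> float:
    """Mean Euclidean distance between transformed volume-center positions
    over all unordered state pairs."""
    t = np.array([s.t for s in traj.states])
    d = np.linalg.norm(t[:, None, :] - t[None, :, :], axis=-1)
    iu = np.triu_indices(len(t), k=1)
    return float(d[iu].mean())


def monte_carlo_center_distance(
    trans_std_mm: float, rot_std_deg: float, n_pairs: int, seed: int
) -> float:
    """Monte-Carlo mean pairwise center distance for i.i.d. normal motion.

    Draws ``n_pairs`` independent state pairs with the given per-axis stds
    and averages the distance between the two transformed center positions.
    """
    rng = np.random.default_rng(seed)
    ta = rng.normal(0.0, trans_std_mm, (n_pairs, 3))
    tb = rng.normal(0.0, trans_std_mm, (n_pairs, 3))
    # rotations about the center leave the center fixed; drawn only to
    # mirror the full sampling protocol
    _ = rng.normal(0.0, rot_std_deg, (n_pairs, 6))
    return float(np.linalg.norm(ta - tb, axis=1).mean())


def add_intrasegment_motion(
    traj: MotionTrajectory,
    n_states: int,
    severity_fraction: float,
    seed: int,
    trans_std_mm: float | None = None,
    rot_std_deg: float | None = None,
) -> MotionTrajectory:
    """Refine a trajectory with small within-segment perturbations.

    Each original state is split into ``n_states / len(traj.states)``
    states, each composed with an independent normal perturbation whose
    per-axis stds are ``severity_fraction`` times the original stds.  When
    the original stds are not given they are estimated from the trajectory
    itself (sample std over states, per parameter group).
    """
    n0 = traj.n_states
    if n_states % n0:
        raise ValueError("n_states must be a multiple of the original state count")
    per = n_states // n0
    if trans_std_mm is None:
        trans_std_mm = float(np.std([s.t for s in traj.states]))
    if rot_std_deg is None:
        rot_std_deg = float(np.std([s.r for s in traj.states]))
    rng = np.random.default_rng(seed)
    dt = rng.normal(0.0, severity_fraction * trans_std_mm, (n_states, 3))
    dr = rng.normal(0.0, severity_fraction * rot_std_deg, (n_states, 3))
    states = []
    for i in range(n_states):
        pert = RigidTransform(t=tuple(dt[i]), r=tuple(dr[i]))
        states.append(pert.compose(traj.states[i // per]))
    n_shots = len(traj.assignment) if traj.assignment else n_states
    return MotionTrajectory(states, _uniform_assignment(n_states, n_shots))


def make_scripted_trajectory(
    pattern: str,
    n_states: int,
    amplitude_mm: float = 0.0,
    amplitude_deg: float = 5.0,
    jump_period: int = 8,
    seed: int = 0,
    n_shots: int | None = None,
) -> MotionTrajectory:
    """Scripted head-motion shapes mimicking instructed volunteer motion.

    ``gradual``
        slowly drifting piecewise-linear rotations/translations between a
        few seeded waypoints (a subject slowly relaxing or looking around);
    ``jittery``
        piecewise-constant states with abrupt seeded jumps every
        ``jump_period`` states (a subject abruptly moving every ~15 s);
    ``stepwise_extreme``
        monotone stepwise progression from -A to +A in equal steps (the
        bottom-left to top-right stepwise protocol).
    """
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    rng = np.random.default_rng(seed)
    if pattern == "gradual":
        n_way = max(2, n_states // 16)
        way_t = rng.normal(0.0, amplitude_mm, (n_way, 3))
        way_r = rng.normal(0.0, amplitude_deg, (n_way, 3))
        x = np.linspace(0, n_way - 1, n_states)
        t = np.stack([np.interp(x, np.arange(n_way), way_t[:, k]) for k in range(3)], -1)
        r = np.stack([np.interp(x, np.arange(n_way), way_r[:, k]) for k in range(3)], -1)
    elif pattern == "jittery":
        n_jumps = int(np.ceil(n_states / jump_period))
        jt = rng.normal(0.0, amplitude_mm, (n_jumps, 3))
        jr = rng.normal(0.0, amplitude_deg, (n_jumps, 3))
        idx = np.arange(n_states) // jump_period
        t, r = jt[idx], jr[idx]
    elif pattern == "stepwise_extreme":
        frac = np.linspace(-1.0, 1.0, n_states)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        t = frac[:, None] * amplitude_mm * axis
        r = frac[:, None] * amplitude_deg * axis
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    states = [RigidTransform(t=tuple(t[i]), r=tuple(r[i])) for i in range(n_states)]
    return MotionTrajectory(states, _uniform_assignment(n_states, n_shots))


# ---------------------------------------------------------------------------
# Gauge removal
# ---------------------------------------------------------------------------

def mean_transform(transforms: list[RigidTransform]) -> RigidTransform:
    """Fréchet-style mean: chordal mean rotation (quaternion/Procrustes)
    and arithmetic mean translation."""
    ms = np.stack([tr.matrix() for tr in transforms])
    u, _, vt = np.linalg.svd(ms.sum(axis=0))
    rmean = u @ np.diag([1.0, 1.0, np.sign(np.linalg.det(u @ vt))]) @ vt
    tmean = np.mean([tr.t for tr in transforms], axis=0)
    return RigidTransform.from_rotation(Rotation.from_matrix(rmean), tmean)


def _stack(traj: MotionTrajectory):
    rot = Rotation.from_euler("xyz", [s.r for s in traj.states], degrees=True)
    t = np.array([s.t for s in traj.states])
    return rot, t


def _mean_sq_distance(g: RigidTransform, est: MotionTrajectory, ref: MotionTrajectory,
                      rot_scale: float, stacks=None) -> float:
    if stacks is None:
        stacks = (_stack(est), _stack(ref))
    (re, te), (rr, tr) = stacks
    rg = g.rotation
    # composed = g ∘ est;  rel = ref^-1 ∘ composed
    tc = rg.apply(te) + np.asarray(g.t)
    dt = np.linalg.norm(tc - tr, axis=1)
    dr = np.degrees((rr.inv() * (rg * re)).magnitude())
    return float(np.mean(dt ** 2 + (rot_scale * dr) ** 2))


def remove_global_offset(
    est: MotionTrajectory,
    ref: MotionTrajectory,
    rot_scale: float = ROT_SCALE_MM_PER_DEG,
) -> MotionTrajectory:
    """Left-compose ``est`` with the rigid ``g`` best aligning it to ``ref``.

    Groupwise estimates carry an undetermined global pose (gauge freedom);
    this finds the single transform ``g`` minimizing the mean squared
    combined distance of ``{g ∘ θ_s}`` to ``ref`` and applies it.  The
    rotation part is initialized by chordal rotation averaging of the
    per-state relative rotations and polished by iterative minimization; the
    translation part is the mean residual in closed form.  The result never
    has a larger mean distance than the input.
    """
    if est.n_states != ref.n_states:
        if est.assignment and ref.assignment:
            est = est.resample_to(ref)
        else:
            raise ValueError("state counts differ and no assignments to resample by")

    rels = [r.compose(e.invert()) for e, r in zip(est.states, ref.states)]
    g0 = _closed_form_gauge(rels, est, ref)
    stacks = (_stack(est), _stack(ref))

    def obj(p):
        return _mean_sq_distance(RigidTransform.from_params(p), est, ref,
                                 rot_scale, stacks)

    res = minimize(obj, g0.params, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000})
    g = RigidTransform.from_params(res.x)
    # safeguard: keep the best of {identity, closed form, polished}
    cands = [IDENTITY, g0, g]
    g = min(cands, key=lambda c: _mean_sq_distance(c, est, ref, rot_scale,
                                                   stacks))
    states = [g.compose(e) for e in est.states]
    return MotionTrajectory(states, list(est.assignment))


def _closed_form_gauge(rels, est, ref) -> RigidTransform:
    # rotation: chordal mean of the relative rotations ref_s ∘ est_s^-1
    rg = mean_transform(rels).rotation
    # translation: mean residual for that rotation
    te = np.array([s.t for s in est.states])
    tr = np.array([s.t for s in ref.states])
    tg = (tr - rg.apply(te)).mean(axis=0)
    return RigidTransform.from_rotation(rg, tg)
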