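"""Distributed-incoherent (DISORDER-style) Cartesian sampling orders.

A 3D multishot Cartesian acquisition samples the ky-kz phase-encode plane
line by line; the readout direction kx is always fully sampled and is not
represented here.  The random-checkered variant tiles the phase-encode
plane into ``tfe_factor`` near-equal contiguous rectangles and lets every
shot sample exactly one location in every tile, so each shot (and therefore
each segment, a whole number of shots) spans low and high spatial
frequencies.  Indices are 0-based with the k-space center at
``(ny//2, nz//2)``, matching the centered FFT convention of the forward
model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SamplingScheme",
    "generate_disorder_scheme",
    "segment_masks",
    "accelerate_by_shot_discarding",
    "tile_grid",
]


@dataclass
class SamplingScheme:
    """Ordered k-space line lists per shot plus shot -> segment grouping."""

    ny: int
    nz: int
    tfe_factor: int
    n_shots: int
    order: list[list[tuple[int, int]]]
    shots_per_segment: int = 1
    seed: int = 0

    def __post_init__(self):
        if len(self.order) != self.n_shots:
            raise ValueError("order length != n_shots")
        if self.n_shots % self.shots_per_segment:
            raise ValueError("n_shots not divisible by shots_per_segment")
        if self.n_shots * self.tfe_factor > self.ny * self.nz:
            raise ValueError("scheme capacity exceeds the phase-encode plane")
        seen = set()
        for shot in self.order:
            if len(shot) != self.tfe_factor or len(set(shot)) != self.tfe_factor:
                raise ValueError("each shot must hold tfe_factor distinct lines")
            for ky, kz in shot:
                if not (0 <= ky < self.ny and 0 <= kz < self.nz):
                    raise ValueError(f"line ({ky},{kz}) outside the plane")
                if (ky, kz) in seen:
                    raise ValueError(f"line ({ky},{kz}) sampled twice")
                seen.add((ky, kz))

    @property
    def n_segments(self) -> int:
        return self.n_shots // self.shots_per_segment

    @property
    def lines_per_segment(self) -> int:
        return self.shots_per_segment * self.tfe_factor

    def segment_shots(self, s: int) -> list[int]:
        k = self.shots_per_segment
        return list(range(s * k, (s + 1) * k))

    def shot_mask(self, shot: int) -> np.ndarray:
        m = np.zeros((self.ny, self.nz), dtype=bool)
        idx = np.asarray(self.order[shot])
        m[idx[:, 0], idx[:, 1]] = True
        return m

    def full_mask(self) -> np.ndarray:
        m = np.zeros((self.ny, self.nz), dtype=bool)
        for shot in self.order:
            idx = np.asarray(shot)
            m[idx[:, 0], idx[:, 1]] = True
        return m

    # -- JSON round trip -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "ny": self.ny,
            "nz": self.nz,
            "tfe_factor": self.tfe_factor,
            "n_shots": self.n_shots,
            "shots_per_segment": self.shots_per_segment,
            "seed": self.seed,
            "order": [[list(line) for line in shot] for shot in self.order],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SamplingScheme":
        order = [[(int(ky), int(kz)) for ky, kz in shot] for shot in d["order"]]
        return cls(ny=d["ny"], nz=d["nz"], tfe_factor=d["tfe_factor"],
                   n_shots=d["n_shots"], order=order,
                   shots_per_segment=d.get("shots_per_segment", 1),
                   seed=d.get("seed", 0))

    def save(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f)

    @classmethod
    def load(cls, path) -> "SamplingScheme":
        with open(path) as f:
            return cls.from_dict(json.load(f))


def tile_grid(ny: int, nz: int, tfe_factor: int) -> tuple[int, int]:
    """Factor ``tfe_factor = a_y * a_z`` into a tile grid for the plane.

    Pairs that divide the plane evenly (equal-size tiles) are preferred;
    among candidates the aspect ratio ``a_y/a_z`` closest to ``ny/nz``
    wins.  Uneven factorizations (edge tiles absorb the remainder) are a
    fallback.  Raises if no factorization fits the plane at all.
    """
    best = None
    target = np.log(ny / nz)
    for a_y in range(1, tfe_factor + 1):
        if tfe_factor % a_y:
            continue
        a_z = tfe_factor // a_y
        if a_y > ny or a_z > nz:
            continue
        exact = 0 if (ny % a_y == 0 and nz % a_z == 0) else 1
        score = (exact, abs(np.log(a_y / a_z) - target))
        if best is None or score < best[:2]:
            best = (*score, a_y, a_z)
    if best is None:
        raise ValueError(
            f"cannot tile a {ny}x{nz} plane into {tfe_factor} rectangles")
    return best[2], best[3]


def _tile_cells(ny: int, nz: int, a_y: int, a_z: int):
    """Contiguous rectangular tiles covering the plane; remainder rows and
    columns are absorbed by the edge tiles (np.array_split semantics)."""
    ys = np.array_split(np.arange(ny), a_y)
    zs = np.array_split(np.arange(nz), a_z)
    tiles = []
    for yb in ys:
        for zb in zs:
            yy, zz = np.meshgrid(yb, zb, indexing="ij")
            tiles.append(np.stack([yy.ravel(), zz.ravel()], axis=1))
    return tiles


def generate_disorder_scheme(
    ny: int,
    nz: int,
    n_shots: int,
    tfe_factor: int,
    seed: int,
    shots_per_segment: int = 1,
) -> SamplingScheme:
    """Seeded random-checkered sampling order.

    Each shot samples exactly one location per tile; within each tile the
    shot-to-location assignment is a seeded random draw, and within each
    shot the tile visiting order is a seeded random permutation.  When the
    scheme does not cover the full plane (``n_shots * tfe_factor <
    ny * nz``) each tile contributes ``n_shots`` locations drawn without
    replacement and the rest are never sampled.
    """
    if n_shots * tfe_factor > ny * nz:
        raise ValueError("n_shots * tfe_factor exceeds the phase-encode plane")
    a_y, a_z = tile_grid(ny, nz, tfe_factor)
    tiles = _tile_cells(ny, nz, a_y, a_z)
    rng = np.random.default_rng(seed)

    # per tile: a seeded choice of n_shots cells, shuffled over shots
    per_tile = []
    for cells in tiles:
        if len(cells) < n_shots:
            raise ValueError(
                f"tile of {len(cells)} cells cannot host {n_shots} shots "
                f"(tile grid {a_y}x{a_z})")
        pick = rng.choice(len(cells), size=n_shots, replace=False)
        per_tile.append(cells[pick])

    order = []
    for shot in range(n_shots):
        visit = rng.permutation(tfe_factor)
        order.append([tuple(int(v) for v in per_tile[t][shot]) for t in visit])
    return SamplingScheme(ny=ny, nz=nz, tfe_factor=tfe_factor, n_shots=n_shots,
                          order=order, shots_per_segment=shots_per_segment,
                          seed=seed)


def segment_masks(scheme: SamplingScheme) -> list[np.ndarray]:
    """One binary (ny, nz) mask per segment: the union of its shots' lines.

    Masks are pairwise disjoint and their union is the full sampled set.
    """
    masks = []
    for s in range(scheme.n_segments):
        m = np.zeros((scheme.ny, scheme.nz), dtype=bool)
        for shot in scheme.segment_shots(s):
            idx = np.asarray(scheme.order[shot])
            m[idx[:, 0], idx[:, 1]] = True
        masks.append(m)
    return masks


def accelerate_by_shot_discarding(
    scheme: SamplingScheme, R: float, seed: int
) -> SamplingScheme:
    """Retrospective acceleration by discarding whole shots.

    Keeps ``round(n_shots / R)`` shots — rounded to the nearest multiple of
    ``shots_per_segment`` so segments stay whole — chosen by a seeded
    uniform draw without replacement; retained shots keep their original
    relative order and within-shot line order.
    """
    if R < 1:
        raise ValueError("acceleration factor must be >= 1")
    if R == 1:
        return scheme
    k = scheme.shots_per_segment
    n_keep = int(round(scheme.n_shots / R / k)) * k
    if n_keep < k:
        raise ValueError("R too large: fewer than one segment would remain")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(scheme.n_shots, size=n_keep, replace=False))
    order = [scheme.order[i] for i in keep]
    return SamplingScheme(ny=scheme.ny, nz=scheme.nz, tfe_factor=scheme.tfe_factor,
                          n_shots=n_keep, order=order,
                          shots_per_segment=k, seed=seed)
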