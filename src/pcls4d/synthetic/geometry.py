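"""Cell and nucleus placement inside the tissue slab.

Cells are spheres packed into the slab with a small allowed overlap
(centre distance >= 0.9 * sum of radii), emulating the tight packing of
hepatocytes.  A configurable fraction of cells is binucleate, with the
two nuclei sitting symmetrically about the cell centre as seen in liver
tissue; mononucleate cells carry one slightly jittered central nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .config import SimConfig


class PackingError(RuntimeError):
    """Raised when the requested packing fraction cannot be reached."""

    def __init__(self, target: float, achieved: float):
        self.target = target
        self.achieved = achieved
        super().__init__(
            f"packing failed: achieved fraction {achieved:.3f} of target {target:.3f}")


@dataclass
class CellPopulation:
    """Initial (t=0) tissue geometry; positions in µm, axes (z, y, x)."""

    centers: np.ndarray          # (n_cells, 3)
    radii: np.ndarray            # (n_cells,)
    nucleus_positions: np.ndarray  # (n_nuclei, 3), absolute
    nucleus_cell: np.ndarray     # (n_nuclei,) owning cell index
    nucleus_radius: float

    @property
    def n_cells(self) -> int:
        return len(self.radii)

    def volumes(self) -> np.ndarray:
        return 4.0 / 3.0 * np.pi * self.radii**3

    def nuclei_per_cell(self) -> np.ndarray:
        return np.bincount(self.nucleus_cell, minlength=self.n_cells)


def _candidate_lattice(lo, hi, spacing, rng):
    """Jittered hexagonal-ish lattice of candidate centres covering a box."""
    axes = [np.arange(lo[i] + spacing / 2, hi[i] + 1e-9, spacing * (0.82 if i == 0 else 1.0))
            for i in range(3)]
    if any(len(a) == 0 for a in axes):
        return np.empty((0, 3))
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1)
    # shift alternate z-layers by half a spacing laterally (denser packing)
    pts[1::2, :, :, 1:] += spacing / 2
    pts = pts.reshape(-1, 3)
    pts += rng.uniform(-0.12 * spacing, 0.12 * spacing, size=pts.shape)
    return pts


def build_tissue_geometry(config: SimConfig, *, attempt_budget: int = 200_000,
                          rng: np.random.Generator | None = None) -> CellPopulation:
    """Place cells and nuclei in the slab.

    Deterministic for a fixed ``config.seed``.  Cells lie fully inside the
    slab (margin >= own radius from every slab face, including the lateral
    faces of the simulated window).  Raises :class:`PackingError`, reporting
    the achieved fraction, if the target packing cannot be reached within
    ``attempt_budget`` random insertion attempts.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    _, ly, lx = config.extent
    lz = config.slab_thickness
    r_mu = config.cell_diameter_mean / 2.0
    r_sd = config.cell_diameter_sd / 2.0

    slab_volume = lz * ly * lx
    target_volume = config.packing_fraction * slab_volume

    centers: list[np.ndarray] = []
    radii: list[float] = []
    placed_volume = 0.0

    r_floor = max(r_mu - 2.0 * r_sd, 0.3 * r_mu, config.nucleus_diameter / 2 + 0.5)
    r_cap = r_mu + 2.5 * r_sd

    def radius_sample(n):
        return np.clip(rng.normal(r_mu, r_sd, size=n), r_floor, r_cap)

    if target_volume > 0:
        tree: cKDTree | None = None
        n_at_build = 0

        def rebuild_tree():
            nonlocal tree, n_at_build
            tree = cKDTree(np.asarray(centers))
            n_at_build = len(centers)

        def try_place(p, r):
            """Place at p with radius <= r (trimmed to fit neighbours)."""
            nonlocal placed_volume
            if len(radii):
                if tree is None or len(centers) - n_at_build >= 64:
                    rebuild_tree()
                cand_idx = tree.query_ball_point(p, 0.9 * 2 * r_cap + 1e-9)
                cand_idx.extend(range(n_at_build, len(centers)))
                if cand_idx:
                    arr_c = np.asarray([centers[j] for j in cand_idx])
                    arr_r = np.asarray([radii[j] for j in cand_idx])
                    d = np.linalg.norm(arr_c - p, axis=1)
                    near = d < 0.9 * (arr_r + r_cap)
                    if near.any():
                        allowed = np.min(d[near] / 0.9 - arr_r[near])
                        if allowed < r_floor:
                            return False
                        r = min(r, allowed)
            # margin >= own radius from every slab face
            r = min(r, p[0], lz - p[0], p[1], ly - p[1], p[2], lx - p[2])
            if r < r_floor:
                return False
            centers.append(np.asarray(p, dtype=float))
            radii.append(float(r))
            placed_volume += 4.0 / 3.0 * np.pi * r**3
            return True

        # Phase 1: jittered lattice seeding sized for ~the target count.
        spacing = 2.0 * r_mu * 0.95
        lo = np.array([r_floor, r_floor, r_floor])
        hi = np.array([lz - r_floor, ly - r_floor, lx - r_floor])
        if np.all(hi >= lo):
            cand = _candidate_lattice(lo, hi, spacing, rng)
            rng.shuffle(cand)
            for p, r in zip(cand, radius_sample(len(cand))):
                if placed_volume >= target_volume:
                    break
                try_place(p, r)

        # Phase 2: random dart-throwing top-up.
        attempts = 0
        while placed_volume < target_volume and attempts < attempt_budget:
            attempts += 1
            r = float(radius_sample(1)[0])
            p = rng.uniform([r_floor] * 3, [lz - r_floor, ly - r_floor, lx - r_floor])
            try_place(p, r)

        if placed_volume < 0.98 * target_volume:
            raise PackingError(config.packing_fraction,
                               placed_volume / slab_volume)

    centers_a = np.asarray(centers).reshape(-1, 3)
    radii_a = np.asarray(radii, dtype=float)

    # Nuclei: decide binucleation, then place inside each cell.
    n = len(radii_a)
    r_nuc = config.nucleus_diameter / 2.0
    binuc = rng.random(n) < config.binucleate_fraction
    nuc_pos: list[np.ndarray] = []
    nuc_cell: list[int] = []
    for i in range(n):
        c, r = centers_a[i], radii_a[i]
        jitter = rng.normal(0.0, 0.5, size=3)
        if binuc[i]:
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            # symmetric pair, both fully inside the cell
            off = min(0.45 * r, max(r - r_nuc - 0.5, r_nuc * 0.6))
            nuc_pos.append(c + jitter + u * off)
            nuc_pos.append(c + jitter - u * off)
            nuc_cell += [i, i]
        else:
            nuc_pos.append(c + jitter)
            nuc_cell.append(i)

    return CellPopulation(
        centers=centers_a,
        radii=radii_a,
        nucleus_positions=np.asarray(nuc_pos).reshape(-1, 3),
        nucleus_cell=np.asarray(nuc_cell, dtype=int),
        nucleus_radius=r_nuc,
    )
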