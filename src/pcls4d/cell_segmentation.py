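"""3D cell instance segmentation from membrane and nuclei channels.

Nuclei detected as multiscale Laplacian-of-Gaussian blobs seed a
watershed on the smoothed membrane intensity; seeds closer than a merge
distance are unioned first, so the two nuclei of a binucleate hepatocyte
grow a single cell.  Objects below a voxel-count threshold are removed
afterwards, and per-label morphometrics (volume, exposed-face surface
area, geometric centroid) are tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.segmentation import watershed

from .stack import LabelVolume

DEFAULT_MIN_VOXELS = 10_000   # tied to the original acquisition's voxel geometry


@dataclass
class Spot:
    """One detected nucleus-like blob."""

    position: np.ndarray    # (z, y, x) µm
    scale: float            # best LoG sigma, µm
    intensity: float        # LoG response

    @property
    def radius(self) -> float:
        """Blob radius implied by the LoG scale (r = sqrt(3) * sigma)."""
        return float(np.sqrt(3.0) * self.scale)


def detect_nuclei(volume: np.ndarray, voxel_size, *,
                  diameter_range_um: tuple[float, float] = (6.0, 12.0),
                  threshold: float = 0.05,
                  n_scales: int = 4) -> list[Spot]:
    """Multiscale LoG spot detection on an anisotropy-rescaled volume.

    The volume is resampled to isotropic voxels (the lateral pitch), LoG
    filtered at scales spanning ``diameter_range_um`` (sigma = d / (2*sqrt(3))),
    and local maxima above ``threshold`` (scale-normalized response,
    relative to the volume's maximum intensity) are kept after
    non-maximum suppression at 0.7x the minimum diameter.  Deterministic;
    an empty list is a valid result.
    """
    d_lo, d_hi = diameter_range_um
    if d_lo <= 0 or d_hi < d_lo:
        raise ValueError("diameter range must be positive and ordered")
    vol = np.asarray(volume, dtype=np.float32)
    dz, dy, dx = voxel_size
    iso = float(min(dy, dx))
    zoom = (dz / iso, dy / iso, dx / iso)
    if not np.allclose(zoom, 1.0):
        vol = ndi.zoom(vol, zoom, order=1)

    vmax = float(vol.max())
    if vmax <= 0:
        return []

    sigmas = np.linspace(d_lo, d_hi, n_scales) / (2.0 * np.sqrt(3.0))
    responses = np.empty((n_scales,) + vol.shape, dtype=np.float32)
    for i, s in enumerate(sigmas):
        responses[i] = -(s / iso) ** 2 * ndi.gaussian_laplace(vol, sigma=s / iso)

    best = responses.max(axis=0)
    best_scale = sigmas[responses.argmax(axis=0)]

    # local maxima of the scale-maximum response
    footprint = np.ones((3, 3, 3), dtype=bool)
    is_peak = (best == ndi.maximum_filter(best, footprint=footprint)) \
        & (best > threshold * vmax)
    coords = np.argwhere(is_peak)
    if len(coords) == 0:
        return []
    vals = best[tuple(coords.T)]
    scl = best_scale[tuple(coords.T)]

    # sub-voxel refinement first: intensity-weighted centroid in a small
    # window (axially one acquisition plane each side, since z sampling is
    # much coarser than the blob).  Plateau peaks produced by the axial
    # interpolation collapse onto one position here, so the subsequent
    # suppression sees true blob distances.
    win_lat = max(int(round(0.5 * d_lo / iso)), 1)
    win_z = max(int(round(dz / iso)), win_lat)
    wins = (win_z, win_lat, win_lat)
    refined = np.empty((len(coords), 3))
    for j, c in enumerate(coords):
        sl = tuple(slice(max(ci - win, 0), min(ci + win + 1, dim))
                   for ci, win, dim in zip(c, wins, vol.shape))
        w = np.clip(vol[sl], 0, None)
        if w.sum() > 0:
            off = np.array(np.meshgrid(
                *[np.arange(s.start, s.stop) for s in sl], indexing="ij"))
            refined[j] = (off * w[None]).reshape(3, -1).sum(axis=1) / w.sum()
        else:
            refined[j] = c
    pos_um = refined * iso + iso / 2.0

    # non-maximum suppression on refined positions, strongest first
    order = np.argsort(vals, kind="stable")[::-1]
    min_sep = 0.7 * d_lo
    spots: list[Spot] = []
    kept_pos: list[np.ndarray] = []
    for j in order:
        p = pos_um[j]
        if kept_pos:
            d = np.linalg.norm(np.asarray(kept_pos) - p, axis=1)
            if (d < min_sep).any():
                continue
        kept_pos.append(p)
        spots.append(Spot(position=p, scale=float(scl[j]),
                          intensity=float(vals[j])))
    return spots


def merge_seeds(positions: np.ndarray, merge_um: float) -> np.ndarray:
    """Union-find grouping of seed positions closer than ``merge_um``.

    Returns a group index per seed (binucleate handling: the two nuclei
    of one cell collapse onto one marker).
    """
    n = len(positions)
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if n > 1 and merge_um > 0:
        tree = cKDTree(positions)
        for i, j in tree.query_pairs(merge_um):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    roots = np.array([find(i) for i in range(n)])
    _, groups = np.unique(roots, return_inverse=True)
    return groups


def segment_cells(membrane: np.ndarray, seeds: list[Spot] | np.ndarray,
                  mask: np.ndarray, voxel_size, *,
                  merge_um: float = 14.4,
                  smoothing_um: float = 1.5,
                  compactness: float = 0.0) -> LabelVolume:
    """Seeded watershed on smoothed membrane intensity inside ``mask``.

    Every foreground voxel of ``mask`` is assigned to exactly one label;
    the label count equals the merged-seed count.  Raises ``ValueError``
    when no seed falls inside the mask.
    """
    mem = np.asarray(membrane, dtype=np.float32)
    mask = np.asarray(mask, dtype=bool)
    if len(seeds) and isinstance(seeds[0], Spot):
        pos = np.asarray([s.position for s in seeds])
    else:
        pos = np.asarray(seeds, dtype=float).reshape(-1, 3)
    if len(pos) == 0:
        raise ValueError("no seeds supplied")

    groups = merge_seeds(pos, merge_um)
    # marker voxel per group: mean position of its seeds
    markers = np.zeros(mem.shape, dtype=np.int32)
    voxel = np.asarray(voxel_size)
    n_groups = groups.max() + 1
    placed = 0
    for g in range(n_groups):
        p = pos[groups == g].mean(axis=0)
        idx = np.minimum(np.maximum((p / voxel).astype(int), 0),
                         np.asarray(mem.shape) - 1)
        if mask[tuple(idx)]:
            markers[tuple(idx)] = g + 1
            placed += 1
        else:
            # nudge the marker to the nearest in-mask voxel within one radius
            markers_set = False
            for r_vox in range(1, 4):
                lo = np.maximum(idx - r_vox, 0)
                hi = np.minimum(idx + r_vox + 1, np.asarray(mem.shape))
                sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
                if sub.any():
                    local = np.argwhere(sub)[0] + lo
                    markers[tuple(local)] = g + 1
                    placed += 1
                    markers_set = True
                    break
            if not markers_set:
                pass   # seed outside the mask: it simply grows nothing
    if placed == 0:
        raise ValueError("no seeds inside the mask")

    sigma = tuple(smoothing_um / v for v in voxel)
    relief = ndi.gaussian_filter(mem, sigma=sigma)
    labels = watershed(relief, markers=markers, mask=mask,
                       connectivity=1, compactness=compactness)
    return LabelVolume(labels.astype(np.int32), tuple(voxel_size))


def size_filter(labels: LabelVolume, min_voxels: int = DEFAULT_MIN_VOXELS) -> LabelVolume:
    """Remove objects containing fewer than ``min_voxels`` voxels.

    Strict "less than": an object of exactly ``min_voxels`` voxels is
    retained.  Other labels are left untouched (idempotent).
    """
    if min_voxels < 0:
        raise ValueError("min_voxels must be >= 0")
    arr = labels.labels
    if arr.max() == 0 or min_voxels == 0:
        return LabelVolume(arr.copy(), labels.voxel_size)
    counts = np.bincount(arr.ravel())
    lut = np.arange(len(counts), dtype=arr.dtype)
    lut[counts < min_voxels] = 0
    lut[0] = 0
    return LabelVolume(lut[arr], labels.voxel_size)


def measure_cells(labels: LabelVolume, *, frame: int = 0, time_s: float = 0.0,
                  nucleus_positions: np.ndarray | None = None) -> pd.DataFrame:
    """One row per label: volume, surface area, centroid, voxel count.

    Centroids are geometric (voxel-centre means), in µm.  When
    ``nucleus_positions`` (µm) is given, a ``nucleus_count`` per cell is
    included (nuclei assigned by the label at their voxel).
    """
    arr = labels.labels
    dz, dy, dx = labels.voxel_size
    vv = labels.voxel_volume()
    ids = np.unique(arr)
    ids = ids[ids != 0]
    rows = []
    if len(ids):
        counts = np.bincount(arr.ravel(), minlength=arr.max() + 1)
        centroids = ndi.center_of_mass(np.ones_like(arr, dtype=np.uint8), arr, ids)
        areas = _label_surface_areas(arr, labels.voxel_size, ids)
        nuc_counts = {}
        if nucleus_positions is not None and len(nucleus_positions):
            vox = (np.asarray(nucleus_positions) /
                   np.array([dz, dy, dx])).astype(int)
            vox = np.clip(vox, 0, np.asarray(arr.shape) - 1)
            owner = arr[tuple(vox.T)]
            for o in owner:
                nuc_counts[o] = nuc_counts.get(o, 0) + 1
        for lab, (cz, cy, cx) in zip(ids, centroids):
            rows.append({
                "label": int(lab), "frame": frame, "time_s": time_s,
                "volume_um3": counts[lab] * vv,
                "surface_um2": areas[lab],
                "x_um": (cx + 0.5) * dx, "y_um": (cy + 0.5) * dy,
                "z_um": (cz + 0.5) * dz,
                "voxel_count": int(counts[lab]),
                "nucleus_count": int(nuc_counts.get(lab, 0)),
            })
    return pd.DataFrame(rows, columns=["label", "frame", "time_s", "volume_um3",
                                       "surface_um2", "x_um", "y_um", "z_um",
                                       "voxel_count", "nucleus_count"])


def _label_surface_areas(arr: np.ndarray, voxel_size, ids) -> dict[int, float]:
    """Exposed-face area per label (faces against background or other labels)."""
    dz, dy, dx = voxel_size
    face = {0: dy * dx, 1: dz * dx, 2: dz * dy}
    areas = np.zeros(arr.max() + 1)
    for axis in range(3):
        pad = [(1, 1) if a == axis else (0, 0) for a in range(3)]
        p = np.pad(arr, pad)
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(0, -1)
        hi[axis] = slice(1, None)
        a, b = p[tuple(lo)], p[tuple(hi)]
        diffm = a != b
        for side in (a[diffm], b[diffm]):
            np.add.at(areas, side, face[axis])
    areas[0] = 0.0
    return {int(i): float(areas[i]) for i in ids}


def assign_cell_track_ids(cell_tables: list[pd.DataFrame], *,
                          gate_um: float = 20.0) -> pd.DataFrame:
    """Link per-frame cell tables into tracks by centroid assignment.

    Uses the same gated optimal assignment as nuclei tracking (shared
    implementation).  Returns the concatenated table with a ``track_id``
    column; a cell absent in one frame ends its track (no gap closing).
    """
    from .nuclei_tracking import link_point_sets

    frames = [t[["z_um", "y_um", "x_um"]].to_numpy(dtype=float) for t in cell_tables]
    track_ids = link_point_sets(frames, gate_um=gate_um)
    out = []
    for tbl, ids in zip(cell_tables, track_ids):
        t = tbl.copy()
        t["track_id"] = ids
        out.append(t)
    return pd.concat(out, ignore_index=True)
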