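"""Nuclei tracking: frame-to-frame linking, kinematics, regional statistics.

Detections in consecutive frames are linked by optimal bipartite
assignment on squared displacement, gated at a maximum per-frame
displacement.  Unmatched detections start new tracks; unmatched track
heads terminate; there is no gap closing, merging or splitting (nuclei
neither divide nor vanish at these timescales).

Tracks are stratified into *periphery* and *core* by an anisotropy-aware
distance transform of the tissue mask in which the lateral and top faces
count as boundary but the bottom face (chamber glass) does not, because
no solute exchange happens through the glass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import linear_sum_assignment

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegionLabel:
    region: str          # "periphery" | "core"
    cutoff_um: float

    def __post_init__(self):
        if self.region not in ("periphery", "core"):
            raise ValueError("region must be 'periphery' or 'core'")
        if self.cutoff_um <= 0:
            raise ValueError("cutoff must be > 0")


def pair_assignment(prev: np.ndarray, new: np.ndarray, gate_um: float):
    """Gated optimal assignment between two point sets.

    Minimizes total squared displacement over matched pairs, with an
    unmatched cost of ``gate_um**2`` per endpoint, so no matched pair can
    exceed the gate.  Returns a list of (i_prev, j_new) matches.
    """
    n, m = len(prev), len(new)
    if n == 0 or m == 0:
        return []
    d2 = ((prev[:, None, :] - new[None, :, :]) ** 2).sum(-1)
    big = 4.0 * gate_um ** 2 + 1.0   # finite stand-in for a forbidden link
    size = n + m
    cost = np.full((size, size), big)
    gated = np.where(d2 <= gate_um ** 2, d2, big)
    cost[:n, :m] = gated
    cost[np.arange(n), m + np.arange(n)] = gate_um ** 2   # track termination
    cost[n + np.arange(m), np.arange(m)] = gate_um ** 2   # new track birth
    cost[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols)
            if r < n and c < m and d2[r, c] <= gate_um ** 2]


def link_point_sets(frames: list[np.ndarray], *, gate_um: float = 15.0):
    """Assign a track id to every point of every frame.

    Returns one integer array per frame.  Deterministic.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to link")
    next_id = 0
    ids_per_frame: list[np.ndarray] = []
    ids0 = np.arange(len(frames[0]))
    next_id = len(frames[0])
    ids_per_frame.append(ids0)
    for k in range(1, len(frames)):
        prev_pts = frames[k - 1]
        new_pts = frames[k]
        ids = np.full(len(new_pts), -1, dtype=int)
        for i, j in pair_assignment(prev_pts, new_pts, gate_um):
            ids[j] = ids_per_frame[k - 1][i]
        for j in np.nonzero(ids < 0)[0]:
            ids[j] = next_id
            next_id += 1
        ids_per_frame.append(ids)
    return ids_per_frame


def link_tracks(spot_frames, *, gate_um: float = 15.0,
                frame_interval: float = 1.0) -> pd.DataFrame:
    """Link per-frame spot lists into a track table.

    ``spot_frames`` is a sequence of per-frame lists of
    :class:`~pcls4d.cell_segmentation.Spot` (or (z, y, x) arrays).
    Returns the documented track table with per-spot volume estimated
    from the LoG scale (sphere of radius sqrt(3)*sigma).
    """
    def as_points(frame):
        if len(frame) == 0:
            return np.empty((0, 3)), np.empty((0,))
        if hasattr(frame[0], "position"):
            return (np.asarray([s.position for s in frame]),
                    np.asarray([s.radius for s in frame]))
        return np.asarray(frame, dtype=float).reshape(-1, 3), \
            np.full(len(frame), np.nan)

    pts, radii = zip(*(as_points(f) for f in spot_frames))
    ids_per_frame = link_point_sets(list(pts), gate_um=gate_um)
    rows = []
    for k, (p, r, ids) in enumerate(zip(pts, radii, ids_per_frame)):
        for (z, y, x), rad, tid in zip(p, r, ids):
            rows.append({
                "track_id": int(tid), "frame": k, "time_s": k * frame_interval,
                "x_um": x, "y_um": y, "z_um": z,
                "volume_um3": 4.0 / 3.0 * np.pi * rad ** 3 if np.isfinite(rad) else np.nan,
            })
    return pd.DataFrame(rows, columns=["track_id", "frame", "time_s",
                                       "x_um", "y_um", "z_um", "volume_um3"])


def compute_kinematics(tracks: pd.DataFrame, frame_interval: float | None = None) -> pd.DataFrame:
    """Add velocity (central differences), speed and acceleration per row.

    Velocity uses central differences at interior points and one-sided
    differences at track ends; acceleration is the second difference.
    """
    out = tracks.sort_values(["track_id", "frame"]).copy()
    for col in ("vx_um_s", "vy_um_s", "vz_um_s", "speed_um_s", "accel_um_s2"):
        out[col] = np.nan
    for tid, grp in out.groupby("track_id"):
        idx = grp.index
        t = grp["time_s"].to_numpy(dtype=float)
        if len(t) < 2:
            continue
        p = grp[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        v = np.gradient(p, t, axis=0)
        out.loc[idx, ["vx_um_s", "vy_um_s", "vz_um_s"]] = v
        out.loc[idx, "speed_um_s"] = np.linalg.norm(v, axis=1)
        if len(t) >= 3:
            a = np.gradient(v, t, axis=0)
            out.loc[idx, "accel_um_s2"] = np.linalg.norm(a, axis=1)
    return out


def stratify_periphery_core(positions: np.ndarray, tissue_mask: np.ndarray,
                            voxel_size, *, cutoff_um: float = 50.0) -> np.ndarray:
    """Label positions (µm) as "periphery" or "core".

    Distance-to-boundary is the Euclidean distance transform of the
    tissue mask with physical sampling; the mask is padded with
    background on the lateral and top faces (they count as boundary even
    when the mask touches the array edge) and extended at the bottom
    face so the chamber glass never counts as boundary.
    """
    if cutoff_um <= 0:
        raise ValueError("cutoff must be > 0")
    mask = np.asarray(tissue_mask, dtype=bool)
    padded = np.pad(mask, ((0, 1), (1, 1), (1, 1)))
    padded = np.concatenate([padded[:1], padded], axis=0)   # extend bottom slice
    dist = ndi.distance_transform_edt(padded, sampling=voxel_size)
    dist = dist[1:-1, 1:-1, 1:-1]

    voxel = np.asarray(voxel_size)
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    idx = (pos / voxel).astype(int)
    inside = np.all((idx >= 0) & (idx < np.asarray(mask.shape)), axis=1)
    labels = np.full(len(pos), "periphery", dtype=object)
    n_out = 0
    for i, (ok, iv) in enumerate(zip(inside, idx)):
        if not ok or not mask[tuple(iv)]:
            n_out += 1
            continue   # outside the mask: labelled periphery
        labels[i] = "periphery" if dist[tuple(iv)] < cutoff_um else "core"
    if n_out:
        log.warning("%d positions outside the tissue mask labelled periphery", n_out)
    return labels.astype(str)


def edge_distances(positions: np.ndarray, tissue_mask: np.ndarray,
                   voxel_size) -> np.ndarray:
    """Distance (µm) of each position to the exposed tissue boundary."""
    mask = np.asarray(tissue_mask, dtype=bool)
    padded = np.pad(mask, ((0, 1), (1, 1), (1, 1)))
    padded = np.concatenate([padded[:1], padded], axis=0)
    dist = ndi.distance_transform_edt(padded, sampling=voxel_size)[1:-1, 1:-1, 1:-1]
    voxel = np.asarray(voxel_size)
    idx = np.clip((np.atleast_2d(positions) / voxel).astype(int), 0,
                  np.asarray(mask.shape) - 1)
    return dist[tuple(idx.T)]


def displacement_summary(tracks: pd.DataFrame, *, region_col: str = "region",
                         n_edge_bins: int = 4) -> dict:
    """Directional displacement statistics of complete tracks.

    Axial sign convention: positive = toward the exposed top face
    (increasing z).  For each track the *net displacement* is
    position(last) - position(first); the *path length* is the summed
    frame-to-frame displacement (both are reported, as they answer
    different questions about drift).
    """
    if tracks.empty:
        raise ValueError("no tracks to summarize")
    per_track = []
    for tid, grp in tracks.sort_values("frame").groupby("track_id"):
        p = grp[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        net = p[-1] - p[0]
        steps = np.diff(p, axis=0)
        rec = {
            "track_id": tid,
            "net_dx": net[0], "net_dy": net[1], "net_dz": net[2],
            "net_magnitude": float(np.linalg.norm(net)),
            "path_length": float(np.linalg.norm(steps, axis=1).sum()) if len(steps) else 0.0,
            "n_frames": len(grp),
        }
        if region_col in grp.columns:
            rec["region"] = grp[region_col].iloc[0]
        if "edge_um" in grp.columns:
            rec["edge_um"] = float(grp["edge_um"].iloc[0])
        per_track.append(rec)
    df = pd.DataFrame(per_track)

    summary = {
        "n_tracks": int(len(df)),
        "mean_axial_um": float(df["net_dz"].mean()),
        "axial_sign": int(np.sign(df["net_dz"].mean())),
        "upward_fraction": float((df["net_dz"] > 0).mean()),
        "mean_net_magnitude_um": float(df["net_magnitude"].mean()),
        "mean_path_length_um": float(df["path_length"].mean()),
    }
    if "region" in df.columns:
        summary["by_region"] = {
            str(region): {
                "n": int(len(g)),
                "mean_axial_um": float(g["net_dz"].mean()),
                "mean_net_magnitude_um": float(g["net_magnitude"].mean()),
                "mean_path_length_um": float(g["path_length"].mean()),
            }
            for region, g in df.groupby("region")
        }
    if "edge_um" in df.columns and df["edge_um"].notna().any():
        bins = np.linspace(0.0, float(df["edge_um"].max()) + 1e-9, n_edge_bins + 1)
        tbl = []
        which = np.digitize(df["edge_um"], bins) - 1
        for b in range(n_edge_bins):
            g = df[which == b]
            if len(g):
                tbl.append({"edge_lo_um": float(bins[b]), "edge_hi_um": float(bins[b + 1]),
                            "n": int(len(g)),
                            "mean_net_magnitude_um": float(g["net_magnitude"].mean())})
        summary["drift_vs_edge"] = tbl
    return summary
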