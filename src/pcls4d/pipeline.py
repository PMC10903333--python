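"""End-to-end orchestration: simulate -> segment -> track -> quantify.

``run_benchmark`` generates one named synthetic condition, runs every
analysis stage on the rendered stack, compares the measurements against
the generator's ground truth and returns a JSON-serializable summary.
``analyze_stack`` runs the measurement stages on any Stack4D (real or
synthetic); ``run_analysis`` is its file-based wrapper.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .cell_segmentation import (assign_cell_track_ids, detect_nuclei,
                                measure_cells, segment_cells, size_filter)
from .kinetics import (aggregate_mean_sem, equilibration_time, normalize_tracks,
                       shrink_swell_metrics, smooth_series)
from .nuclei_tracking import (compute_kinematics, displacement_summary,
                              edge_distances, link_tracks,
                              stratify_periphery_core)
from .stack import Stack4D
from .synthetic import (GroundTruth, TransportParams, make_benchmark,
                        render_stack)
from .synthetic.benchmark import CONDITIONS
from .tissue_volume import measure_tissue, relative_change, segment_tissue

log = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """All analysis-stage knobs in one place (units in names)."""

    tissue_channel: str = "cytoplasm"
    tissue_threshold: float | None = None     # None = Otsu
    closing_um: float = 10.0
    nucleus_diam_um: tuple[float, float] = (6.0, 12.0)
    spot_threshold: float = 0.05
    merge_um: float = 14.4                    # binucleate merge distance
    min_volume_um3: float | None = 1000.0     # cell size filter (µm³ route)
    min_voxels: int | None = None             # overrides the µm³ route if set
    gate_um: float = 15.0                     # nuclei linking gate per frame
    cell_gate_um: float = 20.0
    edge_um: float = 50.0                     # periphery cutoff
    span: float = 0.5                         # LOESS span
    epsilon: float = 0.05                     # equilibration band
    min_track_coverage: float = 0.8


@dataclass
class AnalysisResult:
    tissue: pd.DataFrame
    tracks: pd.DataFrame
    cells: pd.DataFrame
    aggregate: pd.DataFrame
    displacement: dict
    equilibration_s: float
    shrink_swell: dict | None
    smoothed: dict


def analyze_stack(stack: Stack4D, *, params: PipelineParams | None = None,
                  perturbation_time: float = 0.0) -> AnalysisResult:
    """Run all measurement stages on a three-channel stack."""
    p = params or PipelineParams()
    times = stack.frame_times
    n_frames = stack.n_frames

    # --- whole-tissue volumetry -------------------------------------------
    t0 = time.perf_counter()
    tissue_rows = []
    masks = []
    for k in range(n_frames):
        m = segment_tissue(stack, p.tissue_channel,
                           absolute_threshold=p.tissue_threshold,
                           closing_um=p.closing_um, timepoint=k)
        vol, area, radius = measure_tissue(m)
        masks.append(m.mask)
        tissue_rows.append({"frame": k, "time_s": times[k], "volume_um3": vol,
                            "surface_um2": area, "radius_um": radius})
    tissue = pd.DataFrame(tissue_rows)
    tissue["dv_v0"] = relative_change(tissue["volume_um3"].to_numpy())
    log.info("tissue stage: %.1f s", time.perf_counter() - t0)

    # --- nuclei detection and tracking ------------------------------------
    t0 = time.perf_counter()
    nuc = stack.channel("nuclei")
    spot_frames = [detect_nuclei(nuc[k], stack.voxel_size,
                                 diameter_range_um=p.nucleus_diam_um,
                                 threshold=p.spot_threshold)
                   for k in range(n_frames)]
    tracks = link_tracks(spot_frames, gate_um=p.gate_um,
                         frame_interval=stack.frame_interval)
    tracks = compute_kinematics(tracks)
    pos0 = tracks.loc[tracks["frame"] == 0, ["z_um", "y_um", "x_um"]].to_numpy()
    region0 = stratify_periphery_core(pos0, masks[0], stack.voxel_size,
                                      cutoff_um=p.edge_um)
    edge0 = edge_distances(pos0, masks[0], stack.voxel_size)
    region_map = dict(zip(tracks.loc[tracks["frame"] == 0, "track_id"], region0))
    edge_map = dict(zip(tracks.loc[tracks["frame"] == 0, "track_id"], edge0))
    tracks["region"] = tracks["track_id"].map(region_map).fillna("periphery")
    tracks["edge_um"] = tracks["track_id"].map(edge_map)
    complete = tracks.groupby("track_id")["frame"].transform("count") >= \
        p.min_track_coverage * n_frames
    displacement = displacement_summary(tracks[complete])
    log.info("tracking stage: %.1f s (%d tracks)", time.perf_counter() - t0,
             displacement["n_tracks"])

    # --- cell instance segmentation ---------------------------------------
    t0 = time.perf_counter()
    mem = stack.channel("membrane")
    cyt = stack.channel("cytoplasm")
    from skimage.filters import threshold_otsu

    # the binucleate merge distance follows the measured bulk strain, so
    # neighbouring mononucleate cells are not merged once the tissue shrinks
    tissue_scale = np.cbrt(np.clip(
        tissue["volume_um3"].to_numpy() / tissue["volume_um3"].iloc[0],
        1e-6, None))
    cell_tables = []
    for k in range(n_frames):
        cell_mask = (cyt[k] >= threshold_otsu(cyt[k])) & masks[k]
        labels = segment_cells(mem[k], spot_frames[k], cell_mask,
                               stack.voxel_size,
                               merge_um=p.merge_um * min(tissue_scale[k], 1.0))
        if p.min_voxels is not None:
            labels = size_filter(labels, p.min_voxels)
        elif p.min_volume_um3 is not None:
            labels = size_filter(
                labels, int(np.ceil(p.min_volume_um3 / labels.voxel_volume())))
        spots_pos = np.asarray([s.position for s in spot_frames[k]]) \
            if spot_frames[k] else np.empty((0, 3))
        tbl = measure_cells(labels, frame=k, time_s=times[k],
                            nucleus_positions=spots_pos)
        cell_tables.append(tbl)
    cells = assign_cell_track_ids(cell_tables, gate_um=p.cell_gate_um)
    log.info("cell stage: %.1f s (%d cells at t0)", time.perf_counter() - t0,
             len(cell_tables[0]))

    # --- kinetics ----------------------------------------------------------
    series = normalize_tracks(cells, perturbation_time=perturbation_time,
                              min_coverage=p.min_track_coverage)
    smoothed: dict = {}
    shrink = None
    t_eq = float("nan")
    if not series.empty:
        agg = aggregate_mean_sem(series)
        fit = smooth_series(agg["time_s"].to_numpy(), agg["mean"].to_numpy(),
                            span=p.span)
        t_eq = equilibration_time(fit.grid, fit.fitted, epsilon=p.epsilon,
                                  perturbation_time=perturbation_time)
        ss = shrink_swell_metrics(fit.grid, fit.fitted,
                                  perturbation_time=perturbation_time, v0=1.0)
        shrink = {"v_min": ss.v_min, "t_min_s": ss.t_min,
                  "recovery_fraction": ss.recovery_fraction}
        smoothed = {"grid_s": fit.grid.tolist(), "fitted": fit.fitted.tolist()}
    else:
        agg = pd.DataFrame(columns=["time_s", "mean", "sem", "n"])

    return AnalysisResult(tissue=tissue, tracks=tracks, cells=cells,
                          aggregate=agg, displacement=displacement,
                          equilibration_s=t_eq, shrink_swell=shrink,
                          smoothed=smoothed)


# ---------------------------------------------------------------------------
# ground-truth comparison

def _match_cells_to_truth(cells: pd.DataFrame, truth: GroundTruth,
                          frame: int) -> pd.DataFrame:
    """Match measured cells to ground-truth cells by nearest centre."""
    from scipy.spatial import cKDTree

    sub = cells[cells["frame"] == frame]
    if sub.empty:
        return pd.DataFrame()
    meas = sub[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)
    gt_centers = truth.cell_centers[frame]
    tree = cKDTree(meas)
    dist, idx = tree.query(gt_centers)
    radii = truth.cell_radii(frame)
    ok = dist <= radii            # measured centroid inside the true cell
    rows = []
    for gt_i in np.nonzero(ok)[0]:
        m = sub.iloc[idx[gt_i]]
        rows.append({"gt_cell": int(gt_i), "label": int(m["label"]),
                     "track_id": int(m.get("track_id", -1)),
                     "meas_volume_um3": float(m["volume_um3"]),
                     "true_volume_um3": float(
                         truth.cell_v[frame, gt_i]
                         * truth.population.volumes()[gt_i]),
                     "dist_um": float(dist[gt_i])})
    return pd.DataFrame(rows)


def _link_accuracy(tracks: pd.DataFrame, truth: GroundTruth,
                   match_um: float = 6.0) -> float:
    """Fraction of frame-to-frame links joining detections of one true nucleus.

    Each detection is attributed to its nearest true nucleus (within
    ``match_um``); a link is correct when both endpoints belong to the
    same nucleus.  Links with an unattributable endpoint are excluded —
    detection recall is reported separately.
    """
    from scipy.spatial import cKDTree

    owner = {}
    for k in range(len(truth.times)):
        sub = tracks[tracks["frame"] == k]
        if sub.empty:
            continue
        pts = sub[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)
        tree = cKDTree(truth.nuclei_positions[k])
        dist, idx = tree.query(pts)
        for (row_id, d, i) in zip(sub.index, dist, idx):
            owner[row_id] = int(i) if d <= match_um else -1

    good = bad = 0
    for tid, grp in tracks.sort_values("frame").groupby("track_id"):
        rows = list(grp.index)
        for a, b in zip(rows[:-1], rows[1:]):
            oa, ob = owner.get(a, -1), owner.get(b, -1)
            if oa < 0 or ob < 0:
                continue
            if oa == ob:
                good += 1
            else:
                bad += 1
    total = good + bad
    return good / total if total else float("nan")


def compare_to_truth(result: AnalysisResult, truth: GroundTruth) -> dict:
    """Recovery metrics of the analysis against the generator's truth."""
    out: dict = {}
    # per-cell volume recovery at mid-movie and last frame
    errs = []
    recovered = 0
    frames = [0, len(truth.times) // 2, len(truth.times) - 1]
    for k in frames:
        m = _match_cells_to_truth(result.cells, truth, k)
        if m.empty:
            continue
        errs.append(np.abs(m["meas_volume_um3"] / m["true_volume_um3"] - 1.0))
        if k == 0:
            # recovered = true cells matched one-to-one by a measured label
            uniq = m.drop_duplicates(subset="label", keep=False)
            recovered = len(uniq)
    if errs:
        allerr = pd.concat(errs)
        out["median_volume_error"] = float(allerr.median())
        out["n_matched"] = int(len(allerr))
    out["recovered_fraction"] = recovered / truth.population.n_cells \
        if truth.population.n_cells else float("nan")
    out["link_accuracy"] = _link_accuracy(result.tracks, truth)

    gt_mean_v = truth.cell_v.mean(axis=1)
    out["gt_final_mean_v"] = float(gt_mean_v[-1])
    out["tissue_dv_final"] = float(result.tissue["dv_v0"].iloc[-1])
    out["tissue_direction_ok"] = bool(
        np.sign(result.tissue["dv_v0"].iloc[-1]) == np.sign(gt_mean_v[-1] - 1.0)
    ) if abs(gt_mean_v[-1] - 1.0) > 1e-3 else True
    return out


# ---------------------------------------------------------------------------
# benchmark entry point

def run_benchmark(condition: str, seed: int = 0, *, scale: str = "default",
                  params: PipelineParams | None = None,
                  transport: TransportParams | None = None,
                  outdir: str | Path | None = None) -> dict:
    """Generate a named benchmark, analyze it and report recovery metrics."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; know {CONDITIONS}")
    t_start = time.perf_counter()
    truth = make_benchmark(condition, seed=seed, scale=scale, params=transport)
    rendered = render_stack(truth)
    result = analyze_stack(rendered.stack, params=params,
                           perturbation_time=truth.protocol.perturbation_time)
    recovery = compare_to_truth(result, truth)

    summary = {
        "condition": condition,
        "seed": seed,
        "scale": scale,
        "n_cells_truth": truth.population.n_cells,
        "n_frames": len(truth.times),
        "clipped_cell_draws": rendered.clipped_cells,
        "equilibration_s": result.equilibration_s,
        "displacement": result.displacement,
        "shrink_swell": result.shrink_swell,
        "tissue_dv_final": float(result.tissue["dv_v0"].iloc[-1]),
        "recovery": recovery,
        "wall_time_s": round(time.perf_counter() - t_start, 1),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_outputs(outdir, summary, result, rendered.stack)
    return summary


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_outputs(outdir: Path, summary: dict, result: AnalysisResult,
                   stack: Stack4D | None = None, write_stack_file: bool = False) -> None:
    pio.write_table(result.tissue, outdir / "tissue.csv")
    tr = result.tracks[[c for c in pio.TRACK_TABLE_COLUMNS
                        if c in result.tracks.columns]]
    pio.write_table(tr, outdir / "tracks.csv")
    pio.write_table(result.cells[[c for c in pio.CELL_TABLE_COLUMNS
                                  if c in result.cells.columns]],
                    outdir / "cells.csv")
    result.aggregate.to_csv(outdir / "aggregate.csv", index=False)
    if not result.aggregate.empty:
        _plot_aggregate(result, outdir / "aggregate.png")
    if stack is not None and write_stack_file:
        pio.write_stack(stack, outdir / "stack.tiff")
    manifest = {}
    for pattern in ("*.csv", "*.png", "*.tiff"):
        for f in sorted(outdir.glob(pattern)):
            manifest[f.name] = _file_checksum(f)
    (outdir / "summary.json").write_text(json.dumps(
        {**summary, "manifest": manifest}, indent=2, default=float))


def run_direction_benchmark(condition: str, seed: int = 0, *,
                            scale: str = "small",
                            params: PipelineParams | None = None) -> dict:
    """Light benchmark for directional checks: tissue + nuclei stages only.

    Skips cell instance segmentation, so many seeds can be screened
    quickly.  Reports the measured whole-tissue volume change, the
    full-window displacement summary and an early-window (t < L²/(4·D_eff),
    the diffusion penetration time of the slab) summary stratified into
    periphery and core.
    """
    p = params or PipelineParams()
    truth = make_benchmark(condition, seed=seed, scale=scale)
    stack = render_stack(truth).stack
    times = stack.frame_times

    mask0 = segment_tissue(stack, p.tissue_channel, closing_um=p.closing_um,
                           timepoint=0).mask
    vol0, *_ = measure_tissue(mask0, stack.voxel_size)
    mask_end = segment_tissue(stack, p.tissue_channel, closing_um=p.closing_um,
                              timepoint=stack.n_frames - 1).mask
    vol_end, *_ = measure_tissue(mask_end, stack.voxel_size)

    nuc = stack.channel("nuclei")
    spot_frames = [detect_nuclei(nuc[k], stack.voxel_size,
                                 diameter_range_um=p.nucleus_diam_um,
                                 threshold=p.spot_threshold)
                   for k in range(stack.n_frames)]
    tracks = link_tracks(spot_frames, gate_um=p.gate_um,
                         frame_interval=stack.frame_interval)
    first = tracks[tracks["frame"] == 0]
    region0 = stratify_periphery_core(
        first[["z_um", "y_um", "x_um"]].to_numpy(), mask0, stack.voxel_size,
        cutoff_um=p.edge_um)
    region_map = dict(zip(first["track_id"], region0))
    tracks["region"] = tracks["track_id"].map(region_map).fillna("periphery")
    complete = tracks.groupby("track_id")["frame"].transform("count") \
        >= p.min_track_coverage * stack.n_frames
    summary = displacement_summary(tracks[complete])

    l_slab = truth.config.slab_thickness
    t_early = l_slab ** 2 / (4.0 * truth.params.D_eff)
    early = tracks[complete & (tracks["time_s"] <= t_early)]
    early_summary = displacement_summary(early) if not early.empty else {}

    return {
        "condition": condition,
        "seed": seed,
        "tissue_dv": float(vol_end / vol0 - 1.0),
        "displacement": summary,
        "early_window_s": t_early,
        "early_displacement": early_summary,
    }


def _plot_aggregate(result: AnalysisResult, path: Path) -> None:
    """Mean ± SEM volume curve with the LOESS fit (headless-safe)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    agg = result.aggregate
    ax.errorbar(agg["time_s"], agg["mean"], yerr=agg["sem"], fmt="o",
                ms=3, lw=1, color="0.3", label="mean ± SEM")
    if result.smoothed:
        ax.plot(result.smoothed["grid_s"], result.smoothed["fitted"],
                color="k", label="local regression")
    if np.isfinite(result.equilibration_s):
        ax.axvline(result.equilibration_s, color="tab:red", ls="--", lw=1,
                   label=f"equilibration {result.equilibration_s:.0f} s")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("V / V0")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_analysis(stack_path, *, params: PipelineParams | None = None,
                 perturbation_time: float = 0.0,
                 outdir: str | Path | None = None) -> AnalysisResult:
    """File-based analysis: read a stack, run all stages, write outputs."""
    stack = pio.read_stack(stack_path)
    if stack.data.shape[1] < 3:
        raise ValueError(
            f"stack has {stack.data.shape[1]} channels; need membrane, "
            "cytoplasm and nuclei for the full pipeline")
    result = analyze_stack(stack, params=params,
                           perturbation_time=perturbation_time)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summary = {
            "source": str(stack_path),
            "equilibration_s": result.equilibration_s,
            "displacement": result.displacement,
            "shrink_swell": result.shrink_swell,
        }
        _write_outputs(outdir, summary, result)
    return result
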