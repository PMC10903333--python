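"""Per-cell volume time-series analytics.

Normalized volume series (V/V0, with V0 taken at the last pre-switch
frame) are aggregated into mean +/- SEM curves, smoothed with a tricube
local linear regression (LOESS), and reduced to scalar kinetics: the
equilibration time under a plateau criterion and shrink-swell metrics
for permeating-solute exposures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def aggregate_mean_sem(series: pd.DataFrame, value_col: str = "v_norm",
                       time_col: str = "time_s") -> pd.DataFrame:
    """Per-timepoint mean, SEM (sample sd / sqrt(n), ddof=1) and n.

    ``series`` is long-format with one row per (cell, timepoint).  Every
    timepoint must be covered by at least two series.
    """
    if series.empty:
        raise ValueError("no series to aggregate")
    g = series.groupby(time_col)[value_col]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    if (out["n"] < 2).any():
        bad = out.loc[out["n"] < 2, time_col].iloc[0]
        raise ValueError(f"timepoint {bad} covered by fewer than 2 series")
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out[[time_col, "mean", "sem", "n"]]


@dataclass
class LoessFit:
    grid: np.ndarray      # uniform time grid
    fitted: np.ndarray
    ci_low: np.ndarray    # 95% pointwise (normal approximation)
    ci_high: np.ndarray


def smooth_series(t, y, span: float = 0.5, *, n_grid: int = 200) -> LoessFit:
    """Tricube-weighted local linear regression on a uniform time grid.

    ``span`` is the fraction of points in each local window.  The 95%
    pointwise interval uses the local-linear smoother variance
    ``sigma^2 * sum(l_i^2)`` with ``sigma^2`` estimated from the
    residuals at the data points.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(t)
    t, y = t[order], y[order]
    n = len(t)
    if n < 5:
        raise ValueError("need at least 5 points to smooth")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    k = max(int(np.ceil(span * n)), 3)
    if k > n:
        raise ValueError("window larger than the series")

    grid = np.linspace(t[0], t[-1], n_grid)

    def fit_at(t0):
        d = np.abs(t - t0)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            h = max(d.max(), 1.0)
        w = np.clip(1.0 - (d / (h * 1.0000001)) ** 3, 0.0, None) ** 3
        used = w > 0
        w_, t_, y_ = w[used], t[used], y[used]
        sw = w_.sum()
        tb = (w_ * t_).sum() / sw
        yb = (w_ * y_).sum() / sw
        stt = (w_ * (t_ - tb) ** 2).sum()
        slope = (w_ * (t_ - tb) * (y_ - yb)).sum() / stt if stt > 0 else 0.0
        yhat = yb + slope * (t0 - tb)
        # equivalent-kernel weights l_i at t0
        li = w_ / sw + (w_ * (t_ - tb)) * (t0 - tb) / stt if stt > 0 else w_ / sw
        return yhat, float((li ** 2).sum())

    fitted = np.empty(n_grid)
    l2 = np.empty(n_grid)
    for i, t0 in enumerate(grid):
        fitted[i], l2[i] = fit_at(t0)

    resid = np.array([fit_at(tt)[0] for tt in t]) - y
    dof = max(n - 2, 1)
    sigma2 = float((resid ** 2).sum()) / dof
    half = 1.959964 * np.sqrt(sigma2 * l2)
    return LoessFit(grid=grid, fitted=fitted, ci_low=fitted - half,
                    ci_high=fitted + half)


def equilibration_time(t, y, *, epsilon: float = 0.05,
                       perturbation_time: float = 0.0,
                       plateau_fraction: float = 0.1) -> float:
    """Earliest time after the perturbation from which the series stays
    within ``+/- epsilon * |plateau|`` of the plateau.

    The plateau is the mean of the final ``plateau_fraction`` of points.
    Returns NaN when the series never settles into the band.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 0.0 < epsilon < 0.5:
        raise ValueError("epsilon must lie in (0, 0.5)")
    if len(t) == 0:
        raise ValueError("empty series")
    n_tail = max(int(np.ceil(plateau_fraction * len(y))), 1)
    plateau = float(y[-n_tail:].mean())
    band = epsilon * abs(plateau)
    dev = np.abs(y - plateau)
    # suffix maximum: settled[i] iff all points from i on are inside the band
    suffix_max = np.maximum.accumulate(dev[::-1])[::-1]
    ok = (suffix_max <= band) & (t >= perturbation_time - 1e-12)
    idx = np.nonzero(ok)[0]
    return float(t[idx[0]]) if len(idx) else float("nan")


@dataclass
class ShrinkSwellMetrics:
    v_min: float
    t_min: float
    recovery_fraction: float   # (V_end - V_min) / (V0 - V_min)


def shrink_swell_metrics(t, v, *, perturbation_time: float = 0.0,
                         v0: float | None = None) -> ShrinkSwellMetrics:
    """Minimum normalized volume, its time, and the final recovery fraction."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    pre = t < perturbation_time
    if v0 is None:
        v0 = float(v[pre][-1]) if pre.any() else 1.0
    post = t >= perturbation_time
    tp, vp = t[post], v[post]
    if len(vp) == 0:
        raise ValueError("series does not span the perturbation")
    i = int(np.argmin(vp))
    v_min, t_min = float(vp[i]), float(tp[i])
    denom = v0 - v_min
    rec = float((vp[-1] - v_min) / denom) if denom != 0 else 0.0
    return ShrinkSwellMetrics(v_min=v_min, t_min=t_min, recovery_fraction=rec)


def normalize_tracks(cells: pd.DataFrame, *, perturbation_time: float = 0.0,
                     min_coverage: float = 0.8,
                     require_constant_nuclei: bool = True,
                     max_step_ratio: float = 1.8,
                     track_col: str = "track_id",
                     time_col: str = "time_s",
                     volume_col: str = "volume_um3") -> pd.DataFrame:
    """Turn per-cell volume tracks into normalized series (V/V0).

    V0 is the volume at the last frame at or before the perturbation.
    Tracks covering fewer than ``min_coverage`` of all frames, or missing
    the V0 frame, are dropped (partial tracks bias the aggregate).  When
    a ``nucleus_count`` column is present and ``require_constant_nuclei``
    is set, tracks whose nucleus count changes over time are dropped as
    well: a cell cannot gain or lose nuclei, so such changes flag
    segmentation merges/splits whose volume ratios would otherwise
    inflate the aggregate.

    ``max_step_ratio`` bounds the frame-to-frame volume ratio a track may
    show (default 1.8, symmetric: drops below ``1/max_step_ratio`` also
    disqualify).  Osmotic water transport cannot change a cell's volume
    by more than about +-50% per 15 s frame even directly after a bath
    switch, so larger steps flag a segmentation label annexing or losing
    a neighbour mid-track.  Constant segmentation errors cancel in the
    V/V0 normalization; only such mid-track changes bias the mean.
    """
    n_frames = cells[time_col].nunique()
    pre_times = cells.loc[cells[time_col] <= perturbation_time + 1e-9, time_col]
    if pre_times.empty:
        raise ValueError("no frame at or before the perturbation to define V0")
    t0 = pre_times.max()
    check_nuclei = require_constant_nuclei and "nucleus_count" in cells.columns

    out = []
    for tid, grp in cells.groupby(track_col):
        if len(grp) < min_coverage * n_frames:
            continue
        at0 = grp.loc[np.isclose(grp[time_col], t0)]
        if at0.empty:
            continue
        if check_nuclei and grp["nucleus_count"].nunique() > 1:
            continue
        if max_step_ratio is not None:
            vv = grp.sort_values(time_col)[volume_col].to_numpy(dtype=float)
            ratio = vv[1:] / vv[:-1]
            if len(ratio) and ((ratio > max_step_ratio)
                               | (ratio < 1.0 / max_step_ratio)).any():
                continue
        v0 = float(at0[volume_col].iloc[0])
        if not np.isfinite(v0) or v0 <= 0:
            continue
        g = grp[[track_col, time_col, volume_col]].copy()
        g["v_norm"] = g[volume_col] / v0
        out.append(g)
    if not out:
        return pd.DataFrame(columns=[track_col, time_col, volume_col, "v_norm"])
    return pd.concat(out, ignore_index=True)
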