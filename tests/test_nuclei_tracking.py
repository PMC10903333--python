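import itertools

import numpy as np
import pandas as pd
import pytest

from pcls4d.nuclei_tracking import (RegionLabel, compute_kinematics,
                                    displacement_summary, link_point_sets,
                                    link_tracks, pair_assignment,
                                    stratify_periphery_core)


def brute_force_assignment(prev, new, gate):
    """Exhaustive minimum-cost matching with gate^2 unmatched cost."""
    n, m = len(prev), len(new)
    d2 = ((prev[:, None, :] - new[None, :, :]) ** 2).sum(-1)
    best, best_cost = [], np.inf
    for k in range(min(n, m) + 1):
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(range(m), k):
                pairs = list(zip(rows, cols))
                if any(d2[i, j] > gate**2 for i, j in pairs):
                    continue
                cost = sum(d2[i, j] for i, j in pairs) \
                    + gate**2 * (n - k) + gate**2 * (m - k)
                if cost < best_cost - 1e-12:
                    best_cost, best = cost, pairs
    return sorted(best), best_cost


def test_stationary_spots_link_to_themselves():
    rng = np.random.default_rng(0)
    pts = rng.uniform(0, 100, (7, 3))
    ids = link_point_sets([pts, pts.copy(), pts.copy()], gate_um=15.0)
    for frame_ids in ids:
        np.testing.assert_array_equal(frame_ids, np.arange(7))


def test_assignment_equals_brute_force_on_small_instances():
    rng = np.random.default_rng(42)
    gate = 10.0
    for _ in range(200):
        n = rng.integers(1, 7)
        prev = rng.uniform(0, 60, (n, 3))
        new = prev + rng.uniform(-gate / 2, gate / 2, (n, 3)) / np.sqrt(3)
        got = sorted(pair_assignment(prev, new, gate))
        want, _ = brute_force_assignment(prev, new, gate)
        assert got == want


def test_unequal_counts_against_brute_force():
    rng = np.random.default_rng(7)
    gate = 12.0
    for _ in range(60):
        n, m = rng.integers(1, 6), rng.integers(1, 6)
        prev = rng.uniform(0, 40, (n, 3))
        new = rng.uniform(0, 40, (m, 3))
        got = sorted(pair_assignment(prev, new, gate))
        want, want_cost = brute_force_assignment(prev, new, gate)
        d2 = ((prev[:, None, :] - new[None, :, :]) ** 2).sum(-1)
        got_cost = sum(d2[i, j] for i, j in got) \
            + gate**2 * (n - len(got)) + gate**2 * (m - len(got))
        assert got_cost == pytest.approx(want_cost)


def test_vanishing_spot_track_length():
    rng = np.random.default_rng(1)
    pts = rng.uniform(0, 100, (5, 3))
    frames = [pts, pts[:4], pts[:4], pts[:4]]
    ids = link_point_sets(frames, gate_um=15.0)
    all_ids = np.concatenate(ids)
    lengths = pd.Series(all_ids).value_counts()
    vanished = ids[0][4]
    assert lengths[vanished] == 1
    assert (lengths.drop(vanished) == 4).all()


def test_kinematics_linear_and_quadratic_motion():
    t = np.arange(6) * 1.0
    tracks = pd.DataFrame({
        "track_id": [1] * 6 + [2] * 6 + [3] * 6,
        "frame": list(range(6)) * 3,
        "time_s": list(t) * 3,
        "x_um": list(2 * t) + [5.0] * 6 + list(t**2),
        "y_um": 0.0, "z_um": 0.0,
    })
    out = compute_kinematics(tracks)
    lin = out[out.track_id == 1].iloc[1:-1]
    assert np.allclose(lin["vx_um_s"], 2.0)
    assert np.allclose(lin["accel_um_s2"], 0.0)
    still = out[out.track_id == 2]
    assert np.allclose(still["speed_um_s"], 0.0)
    assert np.allclose(still["accel_um_s2"].dropna(), 0.0)
    quad = out[out.track_id == 3].iloc[1:-1]
    assert np.allclose(quad["accel_um_s2"].iloc[1:-1], 2.0)


def test_stratification_examples():
    mask = np.ones((30, 50, 50), dtype=bool)   # 300 µm tall, 500 µm wide slab
    voxel = (10.0, 10.0, 10.0)
    pos = np.array([
        [150.0, 5.0, 250.0],      # on the lateral boundary
        [150.0, 250.0, 250.0],    # centre of the slab
        [5.0, 250.0, 250.0],      # on the glass: bottom face excluded
    ])
    lab = stratify_periphery_core(pos, mask, voxel, cutoff_um=50.0)
    assert list(lab) == ["periphery", "core", "core"]
    lab_all = stratify_periphery_core(pos, mask, voxel, cutoff_um=500.0)
    assert list(lab_all) == ["periphery"] * 3


def test_region_label_validation():
    with pytest.raises(ValueError):
        RegionLabel("middle", 50.0)
    with pytest.raises(ValueError):
        RegionLabel("core", -1.0)


def summary_from_tracks(disp):
    rows = []
    for tid, d in enumerate(disp):
        for k in range(3):
            rows.append({"track_id": tid, "frame": k,
                         "x_um": 10.0, "y_um": 10.0,
                         "z_um": 10.0 + d * k / 2.0})
    return pd.DataFrame(rows)


def test_uniform_upward_displacement_summary():
    tracks = summary_from_tracks([5.0] * 6)
    s = displacement_summary(tracks)
    assert s["mean_axial_um"] == pytest.approx(5.0)
    assert s["upward_fraction"] == 1.0


def test_symmetric_displacement_averages_to_zero():
    tracks = summary_from_tracks([4.0, -4.0, 4.0, -4.0])
    s = displacement_summary(tracks)
    assert s["mean_axial_um"] == pytest.approx(0.0)
    assert s["upward_fraction"] == pytest.approx(0.5)


def test_link_tracks_spot_volume_from_scale():
    from pcls4d.cell_segmentation import Spot

    s = Spot(position=np.array([10.0, 10.0, 10.0]), scale=2.0, intensity=1.0)
    frames = [[s], [Spot(position=np.array([10.0, 11.0, 10.0]),
                         scale=2.0, intensity=1.0)]]
    df = link_tracks(frames, gate_um=5.0, frame_interval=15.0)
    r = np.sqrt(3) * 2.0
    assert df["volume_um3"].iloc[0] == pytest.approx(4 / 3 * np.pi * r**3)
    assert df["track_id"].nunique() == 1
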