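import numpy as np
import pandas as pd
import pytest

from pcls4d.cell_segmentation import (assign_cell_track_ids, detect_nuclei,
                                      measure_cells, segment_cells,
                                      size_filter)
from pcls4d.stack import LabelVolume

VOXEL = (10.0, 2.0, 2.0)


def gaussian_blob(shape, center_um, sigma_um, voxel=VOXEL):
    zc = (np.arange(shape[0]) + 0.5) * voxel[0]
    yc = (np.arange(shape[1]) + 0.5) * voxel[1]
    xc = (np.arange(shape[2]) + 0.5) * voxel[2]
    d2 = ((zc[:, None, None] - center_um[0]) ** 2
          + (yc[None, :, None] - center_um[1]) ** 2
          + (xc[None, None, :] - center_um[2]) ** 2)
    return np.exp(-0.5 * d2 / sigma_um**2)


class TestDetectNuclei:
    def test_blank_image_gives_no_spots(self):
        assert detect_nuclei(np.zeros((6, 20, 20)), VOXEL) == []

    def test_two_well_separated_blobs_localized_within_one_voxel(self):
        shape = (10, 40, 40)
        c1, c2 = np.array([50.0, 20.0, 20.0]), np.array([50.0, 60.0, 20.0])
        vol = gaussian_blob(shape, c1, 2.4) + gaussian_blob(shape, c2, 2.4)
        spots = detect_nuclei(vol, VOXEL)
        assert len(spots) == 2
        found = sorted(s.position.tolist() for s in spots)
        for f, c in zip(found, sorted([c1.tolist(), c2.tolist()])):
            # within one (coarsest) voxel dimension of the truth
            assert np.linalg.norm(np.array(f) - np.array(c)) < 10.0
            assert abs(f[1] - c[1]) < 2.0 and abs(f[2] - c[2]) < 2.0

    def test_blobs_closer_than_min_separation_suppressed_to_one(self):
        shape = (10, 40, 40)
        vol = (gaussian_blob(shape, [50, 40, 40], 2.4)
               + gaussian_blob(shape, [50, 40, 43], 2.4))
        spots = detect_nuclei(vol, VOXEL)   # min separation 0.7*6 = 4.2 µm
        assert len(spots) == 1


class TestSegmentCells:
    def test_bright_plane_separates_two_compartments(self):
        shape = (8, 20, 40)
        mem = np.zeros(shape, dtype=np.float32)
        mem[:, :, 19:21] = 10.0             # bright membrane plane at x ~ 40 µm
        mask = np.ones(shape, dtype=bool)
        seeds = np.array([[40.0, 20.0, 20.0], [40.0, 20.0, 60.0]])
        lv = segment_cells(mem, seeds, mask, VOXEL, merge_um=10.0)
        assert set(np.unique(lv.labels)) == {1, 2}
        # boundary within one voxel of the plane centre (x index 20)
        lab = lv.labels
        boundary_x = np.array([np.max(np.nonzero(lab[z, y] == lab[4, 10, 0])[0])
                               for z in range(8) for y in range(20)])
        assert np.all(np.abs(boundary_x - 19.5) <= 1.5)

    def test_single_seed_floods_whole_mask(self):
        mem = np.zeros((6, 12, 12), dtype=np.float32)
        mask = np.zeros((6, 12, 12), dtype=bool)
        mask[1:5, 2:10, 2:10] = True
        lv = segment_cells(mem, np.array([[30.0, 10.0, 10.0]]), mask, VOXEL)
        assert (lv.labels[mask] == 1).all()
        assert (lv.labels[~mask] == 0).all()

    def test_seeds_within_merge_distance_union(self):
        mem = np.zeros((6, 20, 20), dtype=np.float32)
        mask = np.ones((6, 20, 20), dtype=bool)
        seeds = np.array([[30.0, 20.0, 17.5], [30.0, 20.0, 22.5]])  # 5 µm apart
        lv = segment_cells(mem, seeds, mask, VOXEL, merge_um=14.4)
        assert lv.labels.max() == 1

    def test_no_seed_in_mask_raises(self):
        mem = np.zeros((4, 8, 8), dtype=np.float32)
        mask = np.zeros((4, 8, 8), dtype=bool)
        with pytest.raises(ValueError, match="seed"):
            segment_cells(mem, np.array([[10.0, 8.0, 8.0]]), mask, VOXEL)

    def test_watershed_partitions_mask(self):
        rng = np.random.default_rng(4)
        mem = rng.random((8, 24, 24)).astype(np.float32)
        mask = rng.random((8, 24, 24)) > 0.3
        seeds = np.column_stack([rng.uniform(5, 75, 5), rng.uniform(4, 44, 5),
                                 rng.uniform(4, 44, 5)])
        lv = segment_cells(mem, seeds, mask, VOXEL, merge_um=5.0)
        # every reachable foreground voxel assigned, background untouched
        assert (lv.labels[~mask] == 0).all()
        from scipy import ndimage as ndi
        reach = ndi.label(mask, structure=ndi.generate_binary_structure(3, 1))[0]
        seeded_components = set(np.unique(reach[lv.labels > 0])) - {0}
        for comp in seeded_components:
            assert (lv.labels[(reach == comp)] > 0).all()


class TestSizeFilter:
    def _labels_with_sizes(self, sizes):
        total = sum(sizes)
        side = int(np.ceil(total ** (1 / 3))) + 2
        arr = np.zeros(side**3, dtype=np.int32)
        start = 0
        for lab, s in enumerate(sizes, start=1):
            arr[start:start + s] = lab
            start += s
        return LabelVolume(arr.reshape(side, side, side), (1.0, 1.0, 1.0))

    def test_strictly_less_than_semantics_at_default_threshold(self):
        lv = self._labels_with_sizes([9_999, 10_000])
        out = size_filter(lv)
        counts = np.bincount(out.labels.ravel())
        assert len(counts) > 2 and counts[1] == 0        # 9,999 removed
        assert counts[2] == 10_000                       # 10,000 retained

    def test_zero_threshold_is_identity(self):
        lv = self._labels_with_sizes([3, 17])
        out = size_filter(lv, 0)
        np.testing.assert_array_equal(out.labels, lv.labels)

    def test_idempotent(self):
        lv = self._labels_with_sizes([50, 800, 2000])
        once = size_filter(lv, 500)
        twice = size_filter(once, 500)
        np.testing.assert_array_equal(once.labels, twice.labels)


class TestMeasureCells:
    def test_cube_volume_and_centroid(self):
        arr = np.zeros((12, 12, 12), dtype=np.int32)
        arr[1:11, 1:11, 1:11] = 1
        df = measure_cells(LabelVolume(arr, (1.0, 1.0, 1.0)))
        assert df.loc[0, "volume_um3"] == pytest.approx(1000.0)
        assert df.loc[0, "surface_um2"] == pytest.approx(600.0)
        for c in ("x_um", "y_um", "z_um"):
            assert df.loc[0, c] == pytest.approx(6.0)

    def test_centroid_at_center_of_symmetry(self):
        arr = np.zeros((9, 9, 9), dtype=np.int32)
        arr[4, 4, :] = 1        # a symmetric rod
        arr[4, :, 4] = 1
        df = measure_cells(LabelVolume(arr, (2.0, 2.0, 2.0)))
        assert df.loc[0, "x_um"] == pytest.approx(9.0)
        assert df.loc[0, "y_um"] == pytest.approx(9.0)

    def test_digital_sphere_volume(self):
        r = 12.0
        n = 32
        zc = (np.arange(n) + 0.5)[:, None, None]
        yc = (np.arange(n) + 0.5)[None, :, None]
        xc = (np.arange(n) + 0.5)[None, None, :]
        arr = (((zc - 16) ** 2 + (yc - 16) ** 2 + (xc - 16) ** 2) <= r * r)
        df = measure_cells(LabelVolume(arr.astype(np.int32), (1.0, 1.0, 1.0)))
        assert df.loc[0, "volume_um3"] == pytest.approx(4 / 3 * np.pi * r**3,
                                                        rel=0.05)


class TestCellTrackIds:
    def _table(self, centers, frame):
        return pd.DataFrame({
            "label": np.arange(1, len(centers) + 1), "frame": frame,
            "time_s": frame * 15.0,
            "z_um": centers[:, 0], "y_um": centers[:, 1], "x_um": centers[:, 2],
            "volume_um3": 1000.0, "surface_um2": 500.0,
            "voxel_count": 25, "nucleus_count": 1,
        })

    def test_static_scene_keeps_ids_and_count(self):
        rng = np.random.default_rng(1)
        centers = rng.uniform(10, 90, (8, 3))
        tables = [self._table(centers, k) for k in range(4)]
        out = assign_cell_track_ids(tables, gate_um=20.0)
        assert out.groupby("track_id").size().eq(4).all()
        assert out["track_id"].nunique() == 8

    def test_drifting_cells_fully_linked(self):
        rng = np.random.default_rng(2)
        centers = rng.uniform(20, 80, (10, 3))
        tables = []
        for k in range(5):
            tables.append(self._table(centers + 2.0 * k, k))
        out = assign_cell_track_ids(tables, gate_um=20.0)
        assert out["track_id"].nunique() == 10
        # correspondence is exact: same row order every frame
        for k in range(5):
            ids = out[out.frame == k].sort_values("label")["track_id"].to_numpy()
            np.testing.assert_array_equal(ids, out[out.frame == 0]
                                          .sort_values("label")["track_id"].to_numpy())

    def test_cell_absent_one_frame_ends_its_track(self):
        rng = np.random.default_rng(3)
        centers = rng.uniform(20, 80, (5, 3))
        t0 = self._table(centers, 0)
        t1 = self._table(centers[:4], 1)        # cell 5 vanishes
        t2 = self._table(centers, 2)            # reappears
        out = assign_cell_track_ids([t0, t1, t2], gate_um=20.0)
        lost = t0.iloc[4]
        tid0 = out[(out.frame == 0) & (out.label == 5)]["track_id"].iloc[0]
        frames_of_track = out[out.track_id == tid0]["frame"].tolist()
        assert frames_of_track == [0]           # no gap closing
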