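import numpy as np
import pytest

from pcls4d.stack import Stack4D
from pcls4d.tissue_volume import (SegmentationError, measure_tissue,
                                  relative_change, segment_tissue)


def stack_from_volume(vol, voxel=(1.0, 1.0, 1.0)):
    return Stack4D(vol[None, None].astype(np.float32), voxel_size=voxel,
                   channel_names=("cytoplasm",))


def test_bright_cuboid_is_recovered_exactly():
    vol = np.zeros((12, 20, 20))
    vol[2:8, 5:15, 4:16] = 100.0
    stack = stack_from_volume(vol)
    m = segment_tissue(stack, "cytoplasm", absolute_threshold=50.0,
                       closing_um=0.0)
    expected = vol >= 50.0
    np.testing.assert_array_equal(m.mask, expected)


def test_largest_component_rule():
    vol = np.zeros((12, 20, 20))
    vol[1:11, 1:11, 1:11] = 100.0          # 1000 voxels
    vol[2:5, 15:18, 15:18] = 100.0         # 27 voxels, far away
    stack = stack_from_volume(vol)
    m = segment_tissue(stack, "cytoplasm", absolute_threshold=50.0,
                       closing_um=0.0)
    assert m.mask[2:5, 15:18, 15:18].sum() == 0
    assert m.mask[1:11, 1:11, 1:11].all()


def test_threshold_outside_intensity_range_raises():
    vol = np.zeros((4, 8, 8))
    vol[1, 1, 1] = 10.0
    stack = stack_from_volume(vol)
    with pytest.raises(ValueError, match="range"):
        segment_tissue(stack, "cytoplasm", absolute_threshold=99.0,
                       closing_um=0.0)


def test_cube_measurements_analytic():
    mask = np.zeros((14, 14, 14), dtype=bool)
    mask[2:12, 2:12, 2:12] = True
    vol, area, radius = measure_tissue(mask, (1.0, 1.0, 1.0))
    assert vol == pytest.approx(1000.0)
    assert area == pytest.approx(600.0)
    assert radius == pytest.approx(np.sqrt(3) * 9 / 2, rel=1e-9)


def test_cube_volume_scales_with_voxel_size():
    mask = np.zeros((14, 14, 14), dtype=bool)
    mask[2:12, 2:12, 2:12] = True
    vol, _, _ = measure_tissue(mask, (2.0, 1.0, 1.0))
    assert vol == pytest.approx(2000.0)


def test_digital_sphere_volume_close_to_analytic():
    r = 20.0
    n = 50
    zc = (np.arange(n) + 0.5)[:, None, None]
    yc = (np.arange(n) + 0.5)[None, :, None]
    xc = (np.arange(n) + 0.5)[None, None, :]
    mask = ((zc - 25) ** 2 + (yc - 25) ** 2 + (xc - 25) ** 2) <= r * r
    vol, _, radius = measure_tissue(mask, (1.0, 1.0, 1.0))
    assert vol == pytest.approx(4 / 3 * np.pi * r**3, rel=0.05)
    assert radius == pytest.approx(r, rel=0.05)


def test_volume_invariant_under_axis_permutation():
    rng = np.random.default_rng(0)
    mask = rng.random((6, 10, 14)) > 0.6
    voxel = (5.0, 2.0, 1.0)
    v1, a1, r1 = measure_tissue(mask, voxel)
    v2, a2, r2 = measure_tissue(mask.transpose(2, 0, 1), (1.0, 5.0, 2.0))
    assert v2 == pytest.approx(v1)
    assert a2 == pytest.approx(a1)
    assert r2 == pytest.approx(r1)


def test_noise_free_render_recovers_ground_truth_tissue_volume():
    """Segmenting a noise-free synthetic slab recovers the generator's mask."""
    from pcls4d.synthetic import (SimConfig, SolutionProtocol, TransportParams,
                                  render_stack, simulate_ground_truth)

    cfg = SimConfig(shape=(16, 64, 64), voxel_size=(10.0, 2.0, 2.0),
                    slab_thickness=140.0, packing_fraction=0.4,
                    photon_scale=0.0, read_noise_sd=0.0, seed=2)
    prot = SolutionProtocol(duration=15.0, frame_interval=15.0)
    truth = simulate_ground_truth(cfg, prot, TransportParams())
    stack = render_stack(truth).stack
    mask = segment_tissue(stack, "cytoplasm", closing_um=10.0)
    v_meas, *_ = measure_tissue(mask)
    v_gt = truth.tissue_mask0.sum() * cfg.voxel_volume()
    assert v_meas == pytest.approx(v_gt, rel=0.05)


def test_relative_change_examples():
    np.testing.assert_allclose(relative_change([100.0, 50.0]), [0.0, -0.5])
    np.testing.assert_allclose(relative_change([7.0] * 5), np.zeros(5))
    with pytest.raises(ValueError):
        relative_change([])


def test_empty_mask_raises():
    with pytest.raises(ValueError, match="empty"):
        measure_tissue(np.zeros((3, 3, 3), dtype=bool), (1, 1, 1))
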