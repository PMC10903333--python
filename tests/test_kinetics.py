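import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pcls4d.kinetics import (aggregate_mean_sem, equilibration_time,
                             normalize_tracks, shrink_swell_metrics,
                             smooth_series)


def long_series(values_by_cell, times=None):
    rows = []
    for cid, vals in enumerate(values_by_cell):
        t = times if times is not None else np.arange(len(vals)) * 15.0
        for ti, v in zip(t, vals):
            rows.append({"track_id": cid, "time_s": ti, "v_norm": v})
    return pd.DataFrame(rows)


class TestAggregate:
    def test_identical_series_have_zero_sem(self):
        df = long_series([[1.0, 1.2, 0.9]] * 4)
        agg = aggregate_mean_sem(df)
        np.testing.assert_allclose(agg["sem"], 0.0)
        np.testing.assert_allclose(agg["mean"], [1.0, 1.2, 0.9])
        assert (agg["n"] == 4).all()

    def test_two_cells_hand_computed(self):
        df = long_series([[0.9], [1.1]])
        agg = aggregate_mean_sem(df)
        assert agg.loc[0, "mean"] == pytest.approx(1.0)
        assert agg.loc[0, "sem"] == pytest.approx(0.1)

    def test_sem_scales_as_inverse_sqrt_n(self, rng):
        n = 1000
        df = long_series(rng.normal(0.0, 1.0, (n, 1)))
        agg = aggregate_mean_sem(df)
        assert agg.loc[0, "sem"] == pytest.approx(1 / np.sqrt(n), rel=0.10)

    def test_single_coverage_timepoint_rejected(self):
        df = long_series([[1.0, 1.0], [1.0]])
        with pytest.raises(ValueError, match="fewer than 2"):
            aggregate_mean_sem(df)


class TestSmooth:
    def test_collinear_points_reproduced_exactly(self):
        t = np.linspace(0, 100, 20)
        y = 0.3 * t + 2.0
        fit = smooth_series(t, y, span=0.5)
        expected = 0.3 * fit.grid + 2.0
        assert np.abs(fit.fitted - expected).max() < 1e-10

    def test_constant_series_constant_fit(self):
        t = np.linspace(0, 10, 12)
        fit = smooth_series(t, np.full(12, 3.3), span=0.6)
        assert np.abs(fit.fitted - 3.3).max() < 1e-12
        assert np.all(fit.ci_low <= fit.fitted) and np.all(fit.fitted <= fit.ci_high)

    def test_noisy_exponential_recovered(self, rng):
        t = np.linspace(0, 300, 60)
        truth = 1 + 0.5 * np.exp(-t / 80.0)
        y = truth + rng.normal(0, 0.02, len(t))
        fit = smooth_series(t, y, span=0.3)
        interior = (fit.grid > 30) & (fit.grid < 270)
        truth_g = 1 + 0.5 * np.exp(-fit.grid / 80.0)
        assert np.abs(fit.fitted - truth_g)[interior].max() < 0.02

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            smooth_series([0, 1, 2], [1, 2, 3], span=0.5)


class TestEquilibration:
    def test_constant_series_equilibrates_at_perturbation(self):
        t = np.arange(20) * 15.0
        assert equilibration_time(t, np.ones(20)) == 0.0
        assert equilibration_time(t, np.ones(20), perturbation_time=30.0) == 30.0

    def test_exponential_analytic_time(self):
        tau = 60.0
        t = np.linspace(0, 600, 2000)
        v = 1 + 0.5 * np.exp(-t / tau)
        t_eq = equilibration_time(t, v, epsilon=0.05)
        # plateau ~1 ; t_eq solves 0.5 exp(-t/tau) = 0.05 -> tau ln 10
        assert t_eq == pytest.approx(tau * np.log(10.0), rel=0.02)

    def test_never_settling_series_returns_nan(self):
        t = np.arange(30) * 1.0
        v = np.concatenate([np.ones(29), [50.0]])
        assert np.isnan(equilibration_time(t, v, epsilon=0.05))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_matches_exhaustive_suffix_scan(self, data):
        n = data.draw(st.integers(10, 40))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        t = np.arange(n) * 7.5
        v = 1 + rng.normal(0, 0.3, n) * np.exp(-t / 50.0)   # noisy settling
        eps = data.draw(st.sampled_from([0.02, 0.05, 0.1]))
        got = equilibration_time(t, v, epsilon=eps)
        # oracle: scan all suffixes
        n_tail = max(int(np.ceil(0.1 * n)), 1)
        plateau = v[-n_tail:].mean()
        band = eps * abs(plateau)
        expected = float("nan")
        for i in range(n):
            if np.all(np.abs(v[i:] - plateau) <= band):
                expected = t[i]
                break
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == expected

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(shift=st.floats(-500.0, 500.0), scale=st.floats(0.1, 40.0),
           seed=st.integers(0, 2**31 - 1))
    def test_invariance_time_translation_and_volume_rescaling(self, shift, scale, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(25) * 15.0
        v = 1 + rng.normal(0, 0.2, 25) * np.exp(-t / 60.0)
        base = equilibration_time(t, v, epsilon=0.05)
        shifted = equilibration_time(t + shift, v, epsilon=0.05,
                                     perturbation_time=shift)
        scaled = equilibration_time(t, v * scale, epsilon=0.05)
        if np.isnan(base):
            assert np.isnan(shifted) and np.isnan(scaled)
        else:
            assert shifted == pytest.approx(base + shift)
            assert scaled == pytest.approx(base)


class TestShrinkSwell:
    def test_monotone_decay_has_zero_recovery(self):
        t = np.arange(10) * 10.0
        v = np.linspace(1.0, 0.5, 10)
        m = shrink_swell_metrics(t, v, v0=1.0)
        assert m.recovery_fraction == pytest.approx(0.0)
        assert m.v_min == pytest.approx(0.5)

    def test_full_return_recovery_is_one(self):
        t = np.arange(11) * 10.0
        v = np.concatenate([np.linspace(1, 0.6, 6), np.linspace(0.7, 1.0, 5)])
        m = shrink_swell_metrics(t, v, v0=1.0)
        assert m.recovery_fraction == pytest.approx(1.0)
        assert m.t_min == 50.0


@pytest.fixture(scope="module")
def gt_curves():
    from pcls4d.synthetic import (SimConfig, TransportParams,
                                  benchmark_protocol, simulate_ground_truth)

    column = SimConfig(shape=(40, 3, 3), voxel_size=(10.0, 64.0, 64.0),
                       slab_thickness=300.0, packing_fraction=0.0)
    curves = {}
    for cond in ("hypo80", "hyper1215", "dmso1molal"):
        truth = simulate_ground_truth(column, benchmark_protocol(cond),
                                      TransportParams(), lateral_bc="neumann",
                                      with_tissue_mask=False)
        z = truth.field.z
        band = (z >= 12) & (z <= 288)
        curves[cond] = (truth.times,
                        truth.v_field[:, band, 1, 1].mean(axis=1))
    return curves


class TestBenchmarkShapes:
    """Shapes of the aggregate volume curves under the three exposures."""

    def test_hyposmotic_rises_then_returns_toward_initial(self, gt_curves):
        t, v = gt_curves["hypo80"]
        peak = int(np.argmax(v))
        assert v[peak] > 1.05
        assert 0 < peak < len(v) - 1            # interior maximum
        assert v[-1] < v[peak] - 1e-3           # regulatory return

    def test_hyperosmotic_falls_then_returns(self, gt_curves):
        t, v = gt_curves["hyper1215"]
        low = int(np.argmin(v))
        assert v[low] < 0.95
        assert low < len(v) - 1
        assert v[-1] > v[low] + 1e-4

    def test_dmso_single_interior_minimum_on_smoothed_mean(self, gt_curves):
        t, v = gt_curves["dmso1molal"]
        fit = smooth_series(t, v, span=0.5)
        low = int(np.argmin(fit.fitted))
        assert 0 < low < len(fit.fitted) - 1
        # single minimum: decreasing before, increasing after (smoothed)
        assert np.all(np.diff(fit.fitted[:low + 1]) <= 1e-9)
        assert np.all(np.diff(fit.fitted[low:]) >= -1e-9)


class TestNormalizeTracks:
    def _cells(self, vols_by_track, n_frames=5):
        rows = []
        for tid, vols in vols_by_track.items():
            for k, v in enumerate(vols):
                rows.append({"track_id": tid, "frame": k, "time_s": k * 15.0,
                             "volume_um3": v, "nucleus_count": 1})
        return pd.DataFrame(rows)

    def test_normalization_and_coverage_rule(self):
        cells = self._cells({1: [100, 110, 120, 130, 140],
                             2: [200, 210],               # < 80% coverage
                             3: [50, 55, 60, 65, 70]})
        out = normalize_tracks(cells)
        assert set(out["track_id"]) == {1, 3}
        v1 = out[out.track_id == 1].sort_values("time_s")["v_norm"].to_numpy()
        np.testing.assert_allclose(v1, [1.0, 1.1, 1.2, 1.3, 1.4])

    def test_changing_nucleus_count_disqualifies(self):
        cells = self._cells({1: [100] * 5})
        cells.loc[cells.index[-1], "nucleus_count"] = 2
        assert normalize_tracks(cells).empty

    def test_large_volume_jump_disqualifies(self):
        cells = self._cells({1: [100, 100, 250, 250, 250],
                             2: [100, 101, 102, 103, 104]})
        out = normalize_tracks(cells)
        assert set(out["track_id"]) == {2}
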