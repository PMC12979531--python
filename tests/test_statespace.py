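"""Sliding-window binning, smoothing, z-scoring, PCA trajectories and
divergence measures."""

import numpy as np
import pytest

from pigeonpop import (build_activity_matrix, build_stimulus_set,
                       condition_average_and_smooth, make_population,
                       pca_trajectories, schedule_session, sliding_bin,
                       simulate_spike_counts, top_divergences,
                       trajectory_distance, zscore_to_baseline)
from pigeonpop.statespace import BaselineStats, gaussian_sigma_steps


class TestSlidingBin:
    def test_window_count_convention(self):
        # 4000 ms trial -> floor((4000-200)/40)+1 = 96 windows
        counts = np.ones(20)
        assert sliding_bin(counts).size == 96

    def test_constant_rate_gives_constant_series(self):
        out = sliding_bin(np.full(10, 3.0))
        assert np.allclose(out, 3.0)

    def test_too_short_duration_is_empty(self):
        assert sliding_bin([], kind="times", duration_ms=100).size == 0

    def test_spike_times_match_bruteforce_loop(self, rng):
        times = np.sort(rng.uniform(0, 2000, 150))
        out = sliding_bin(times, kind="times", duration_ms=2000)
        starts = np.arange(out.size) * 40
        oracle = [np.sum((times >= t) & (times < t + 200)) for t in starts]
        assert np.array_equal(out, oracle)

    def test_count_resampling_interpolates_adjacent_bins(self):
        counts = np.array([0.0, 10.0, 0.0])
        out = sliding_bin(counts)
        # window starting at 40 ms overlaps bins 0 and 1 by 160/40 ms
        assert out[1] == pytest.approx(0.0 * 0.8 + 10.0 * 0.2)
        assert out[5] == pytest.approx(10.0)


class TestSmoothing:
    def test_identical_trials_average_to_single_trial(self, rng):
        trial = rng.poisson(3.0, 50).astype(float)
        avg = condition_average_and_smooth([trial, trial, trial])
        assert np.allclose(avg, condition_average_and_smooth([trial]))

    def test_constant_series_unchanged(self):
        out = condition_average_and_smooth([np.full(40, 2.5)])
        assert np.allclose(out, 2.5)

    def test_impulse_becomes_kernel(self):
        x = np.zeros(101)
        x[50] = 1.0
        out = condition_average_and_smooth([x])
        sigma = gaussian_sigma_steps()
        i = np.arange(101.0)
        kern = np.exp(-0.5 * ((i - 50) / sigma) ** 2)
        kern /= kern.sum()
        assert np.argmax(out) == 50
        assert np.allclose(out, kern, atol=1e-3)

    def test_fwhm_interpretation_narrower(self):
        assert gaussian_sigma_steps(interpretation="fwhm") < \
            gaussian_sigma_steps(interpretation="sd")


class TestZScore:
    def test_baseline_itself_standardizes(self, rng):
        x = rng.normal(4.0, 2.0, 2000)
        z = zscore_to_baseline(x, x.mean(), x.std())
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_constant_at_mean_gives_zeros(self):
        z = zscore_to_baseline(np.full(10, 3.0), 3.0, 1.5)
        assert np.all(z == 0.0)

    def test_affine_relation(self, rng):
        x = rng.normal(size=50)
        z = zscore_to_baseline(x, 1.0, 2.0)
        assert np.allclose(z, (x - 1.0) / 2.0)

    def test_sd_floor_enforced(self):
        with pytest.raises(ValueError):
            zscore_to_baseline(np.ones(5), 0.0, 0.0)


class TestPca:
    def test_matches_eigendecomposition_oracle(self, rng):
        m = rng.normal(size=(5, 20))
        index = [("v", "pigeon", 0.04 * i) for i in range(20)]
        ts = pca_trajectories(m, index, [f"n{i}" for i in range(5)], k=3)
        centered = m - m.mean(axis=1, keepdims=True)
        cov = centered @ centered.T / (20 - 1)
        evals, evecs = np.linalg.eigh(cov)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        assert np.allclose(ts.variance_explained,
                           (evals / evals.sum())[:3], atol=1e-8)
        for j in range(3):   # loadings equal up to sign
            dot = np.abs(evecs[:, j] @ ts.loadings[:, j])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_planar_data_has_vanishing_third_component(self, rng):
        basis = rng.normal(size=(2, 30))
        weights = rng.normal(size=(6, 2))
        m = weights @ basis
        index = [("v", "pigeon", 0.04 * i) for i in range(30)]
        ts = pca_trajectories(m, index, [f"n{i}" for i in range(6)])
        assert ts.variance_explained[2] < 1e-12
        assert ts.variance_explained.sum() <= 1.0 + 1e-9
        assert np.all(np.diff(ts.variance_explained) <= 1e-12)

    def test_loadings_orthonormal(self, rng):
        m = rng.normal(size=(8, 40))
        index = [("v", "pigeon", 0.04 * i) for i in range(40)]
        ts = pca_trajectories(m, index, [f"n{i}" for i in range(8)])
        assert np.allclose(ts.loadings.T @ ts.loadings, np.eye(3), atol=1e-10)


class TestDistances:
    def test_identical_trajectories_zero(self, rng):
        t = rng.normal(size=(30, 3))
        assert np.all(trajectory_distance(t, t) == 0.0)

    def test_pythagorean_offset(self, rng):
        t = rng.normal(size=(30, 3))
        assert np.allclose(trajectory_distance(t, t + [3.0, 4.0, 0.0]), 5.0)

    def test_rotation_invariance(self, rng):
        from scipy.stats import ortho_group
        a, b = rng.normal(size=(2, 25, 3))
        R = ortho_group.rvs(3, random_state=1)
        assert np.allclose(trajectory_distance(a, b),
                           trajectory_distance(a @ R, b @ R))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            trajectory_distance(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_top_divergences_order_and_ties(self):
        assert np.array_equal(top_divergences(np.arange(10.0)), [9, 8])
        assert np.array_equal(top_divergences(np.ones(5)), [0, 1])
        assert np.array_equal(top_divergences(np.array([1.0]), k=2), [0])


@pytest.fixture(scope="module")
def small_table():
    stim = build_stimulus_set(2, 1, include_two_pigeon=False, seed=0)
    sched = schedule_session(stim, seed=1)
    pop = make_population(3, {"non_selective": 1.0}, seed=2,
                          regions=("MVL",), baseline_mean_log=np.log(3.0))
    return stim, simulate_spike_counts(sched, stim, pop, seed=3)


class TestActivityMatrix:
    def test_matrix_shape_and_index(self, small_table):
        stim, table = small_table
        matrix, index, neurons = build_activity_matrix(table)
        assert matrix.shape[0] == 3
        assert matrix.shape[1] == len(index)
        # per condition: 15 baseline-trim windows + video windows
        conds = sorted({(p, a) for p, a, _t in index})
        assert len(conds) == 4   # 2 pairs x 2 actors
        for pair, actor in conds:
            times = [t for p, a, t in index if (p, a) == (pair, actor)]
            assert sum(t < 0 for t in times) == 15
            dur = next(v.duration for v in stim.videos if v.pair == pair)
            n_bins = int(dur / 0.2 + 1e-9)   # partial last bin dropped
            n_vid = (n_bins * 200 - 200) // 40 + 1
            assert sum(t >= 0 for t in times) == n_vid

    def test_index_roundtrip_bijective(self, small_table):
        _stim, table = small_table
        _m, index, _n = build_activity_matrix(table)
        assert len(set(index)) == len(index)

    def test_baseline_stats_match_manual(self, small_table):
        _stim, table = small_table
        stats = BaselineStats.from_table(table)
        base = table[table["phase"] == "baseline"]
        for n_id, grp in base.groupby("neuron_id"):
            assert stats.mean[n_id] == pytest.approx(grp["count"].mean())
            assert stats.sd[n_id] == pytest.approx(grp["count"].std(ddof=0))
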