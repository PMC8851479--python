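"""Tuning-map and score checks against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from mectopo import synthio, tuning
from mectopo._util import pearson_pairwise
from mectopo.synthio import ArenaSpec, GroundTruthCell, Trajectory, simulate_trajectory
from mectopo.tuning import (
    Autocorrelogram, HDTuning, border_score, compute_occupancy, compute_ratemap,
    filter_by_snr, grid_score, hd_tuning, mvl, object_vector_map, ov_score,
    spatial_autocorrelogram, spatial_information,
)


def _stationary_traj(n=100, x=40.0, y=40.0, fps=7.52):
    t = np.arange(n) / fps
    return Trajectory(t, np.full(n, x), np.full(n, y), np.zeros(n), fps)


class TestOccupancy:
    def test_stationary_trajectory_fills_one_bin(self, arena):
        occ = compute_occupancy(_stationary_traj(), arena, speed_min_cms=0.0)
        assert occ.visited.sum() == 1
        assert occ.exploration_ratio == pytest.approx(1 / 1024)

    def test_uniform_visit_gives_full_ratio_zero_sd(self, arena):
        # one frame in every bin center, zero speed filter
        nb = arena.n_bins
        centers = (np.arange(nb) + 0.5) * arena.bin_cm
        xx, yy = np.meshgrid(centers, centers)
        n = nb * nb
        traj = Trajectory(np.arange(n) / 7.52, xx.ravel(), yy.ravel(),
                          np.zeros(n), 7.52)
        occ = compute_occupancy(traj, arena, speed_min_cms=0.0)
        assert occ.exploration_ratio == 1.0
        assert occ.exploration_sd == pytest.approx(0.0)

    def test_occupancy_sums_to_filtered_duration(self, traj600, arena):
        occ = compute_occupancy(traj600, arena, speed_min_cms=2.5)
        kept = (traj600.speed_cms() >= 2.5).sum()
        assert occ.total_s == pytest.approx(kept * traj600.dt, abs=traj600.dt)

    def test_good_coverage_quadrant_for_default_session(self, traj1200, arena):
        occ = compute_occupancy(traj1200, arena)
        assert occ.exploration_ratio > 0.9
        assert occ.exploration_sd < 1.0

    def test_all_frames_filtered_is_error(self, arena):
        with pytest.raises(tuning.EmptyOccupancyError):
            compute_occupancy(_stationary_traj(), arena, speed_min_cms=2.5)


class TestRateMap:
    def test_zero_events_give_zero_map_on_visited_bins(self, traj600, arena):
        rm = compute_ratemap(np.zeros(traj600.n_frames), traj600, arena)
        vals = rm.rate[np.isfinite(rm.rate)]
        assert len(vals) > 0 and np.all(vals == 0.0)

    def test_single_bin_rate_is_amplitude_over_dwell(self, arena):
        traj = _stationary_traj(n=75)  # ~10 s in one bin
        events = np.zeros(75)
        events[10] = 3.0
        events[20] = 1.5
        rm = compute_ratemap(events, traj, arena, smoothing_sigma_bins=0.0,
                             speed_min_cms=0.0)
        expected = 4.5 / (75 / 7.52)
        finite = rm.rate[np.isfinite(rm.rate)]
        assert finite.size == 1 and finite[0] == pytest.approx(expected)

    def test_rate_is_linear_in_amplitude(self, traj600, arena):
        rng = np.random.default_rng(0)
        events = rng.exponential(1.0, traj600.n_frames) * (rng.random(traj600.n_frames) < 0.1)
        r1 = compute_ratemap(events, traj600, arena).rate
        r2 = compute_ratemap(2 * events, traj600, arena).rate
        m = np.isfinite(r1)
        assert np.allclose(r2[m], 2 * r1[m], rtol=1e-9)

    def test_rate_invariant_to_uniform_time_rescaling(self, traj600, arena):
        rng = np.random.default_rng(1)
        events = rng.exponential(1.0, traj600.n_frames) * (rng.random(traj600.n_frames) < 0.1)
        slow = Trajectory(traj600.t_s * 2, traj600.x_cm, traj600.y_cm,
                          traj600.hd_deg, traj600.fps / 2)
        r1 = compute_ratemap(events, traj600, arena, speed_min_cms=0.0).rate
        r2 = compute_ratemap(events, slow, arena, speed_min_cms=0.0).rate
        m = np.isfinite(r1)
        assert np.allclose(r2[m], r1[m] / 2, rtol=1e-9)

    def test_length_mismatch_rejected(self, traj600, arena):
        with pytest.raises(ValueError):
            compute_ratemap(np.zeros(10), traj600, arena)


def _autocorr_oracle(m, min_overlap):
    """Brute-force pairwise-complete Pearson at every integer offset."""
    ny, nx = m.shape
    out = np.full((2 * ny - 1, 2 * nx - 1), np.nan)
    for dy in range(-ny + 1, ny):
        for dx in range(-nx + 1, nx):
            pairs = []
            for y in range(ny):
                for x in range(nx):
                    y2, x2 = y + dy, x + dx
                    if 0 <= y2 < ny and 0 <= x2 < nx:
                        a, b = m[y, x], m[y2, x2]
                        if np.isfinite(a) and np.isfinite(b):
                            pairs.append((a, b))
            if len(pairs) >= min_overlap:
                a, b = np.array(pairs).T
                if a.std() > 1e-9 and b.std() > 1e-9:
                    out[dy + ny - 1, dx + nx - 1] = np.corrcoef(a, b)[0, 1]
    return out


class TestAutocorrelogram:
    def test_center_is_one_and_point_symmetric(self, traj600, grid_cell, arena):
        act = synthio.generate_activity(grid_cell, traj600, arena, seed=41)
        ac = spatial_autocorrelogram(compute_ratemap(act.events, traj600, arena))
        cy, cx = (np.array(ac.values.shape) - 1) // 2
        assert ac.values[cy, cx] == 1.0
        flipped = ac.values[::-1, ::-1]
        m = np.isfinite(ac.values) & np.isfinite(flipped)
        assert np.allclose(ac.values[m], flipped[m], atol=1e-6)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        m = rng.normal(size=(9, 9))
        m[rng.random((9, 9)) < 0.15] = np.nan
        ac = spatial_autocorrelogram(m, min_overlap=5)
        oracle = _autocorr_oracle(m, min_overlap=5)
        both = np.isfinite(ac.values) & np.isfinite(oracle)
        assert both.sum() > 50
        assert np.allclose(ac.values[both], oracle[both], atol=1e-6)

    def test_white_noise_decorrelates_beyond_three_bins(self):
        rng = np.random.default_rng(6)
        ac = spatial_autocorrelogram(rng.normal(size=(40, 40)))
        cy, cx = (np.array(ac.values.shape) - 1) // 2
        yy, xx = np.mgrid[0:ac.values.shape[0], 0:ac.values.shape[1]]
        far = (np.hypot(yy - cy, xx - cx) >= 3) & (np.hypot(yy - cy, xx - cx) <= 12)
        vals = ac.values[far & np.isfinite(ac.values)]
        assert np.all(np.abs(vals) < 0.2)

    def test_constant_map_has_no_defined_correlations(self):
        ac = spatial_autocorrelogram(np.ones((10, 10)))
        assert not np.isfinite(np.delete(ac.values.ravel(),
                                         np.argmax(np.isfinite(ac.values.ravel())))).any() \
            or np.isnan(ac.values).sum() >= ac.values.size - 1


def _analytic_grid_map(arena, spacing=40.0, orientation=15.0):
    nb = arena.n_bins
    centers = (np.arange(nb) + 0.5) * arena.bin_cm
    xx, yy = np.meshgrid(centers, centers)
    return synthio._grid_rate(xx, yy, {"spacing_cm": spacing,
                                       "orientation_deg": orientation,
                                       "phase_x_cm": 3.0, "phase_y_cm": 7.0})


def _rotation_oracle_gs(ac_values):
    """Independent grid score: full-map rotation via scipy, fixed annulus."""
    h, w = ac_values.shape
    cy, cx = (h - 1) // 2, (w - 1) // 2
    yy, xx = np.mgrid[0:h, 0:w]
    rr = np.hypot(yy - cy, xx - cx)
    valid = np.isfinite(ac_values)
    filled = np.nan_to_num(ac_values)
    corrs = {}
    for ang in (30, 60, 90, 120, 150):
        rot = ndimage.rotate(filled, ang, reshape=False, order=1)
        rot_ok = ndimage.rotate(valid.astype(float), ang, reshape=False, order=1) > 0.99
        ring = (rr > 3) & (rr <= min(cy, cx)) & valid & rot_ok
        corrs[ang] = np.corrcoef(filled[ring], rot[ring])[0, 1]
    return min(corrs[60], corrs[120]) - max(corrs[30], corrs[90], corrs[150])


class TestGridScore:
    def test_analytic_hexagonal_map_scores_high(self, arena):
        ac = tuning.grid_autocorrelogram(_analytic_grid_map(arena))
        assert grid_score(ac) > 0.8
        assert _rotation_oracle_gs(ac.values) > 0.8

    def test_isotropic_bump_scores_near_zero(self, arena):
        nb = arena.n_bins
        yy, xx = np.mgrid[0:nb, 0:nb]
        bump = np.exp(-((xx - nb / 2) ** 2 + (yy - nb / 2) ** 2) / (2 * 6.0**2))
        gs = grid_score(tuning.grid_autocorrelogram(bump))
        assert abs(gs) < 0.05

    def test_parallel_stripes_score_negative(self, arena):
        nb = arena.n_bins
        xx = np.arange(nb)[None, :] * np.ones((nb, 1))
        stripes = 0.5 + 0.5 * np.cos(2 * np.pi * xx / 8.0)
        assert grid_score(tuning.grid_autocorrelogram(stripes)) < 0

    def test_sixty_degree_rotation_consistency(self, arena):
        ac = tuning.grid_autocorrelogram(_analytic_grid_map(arena)).values
        rot = tuning._rotate_nan(ac, 60.0)
        assert abs(grid_score(ac) - grid_score(rot)) < 0.05


class TestBorderScore:
    def test_one_wall_strip_is_perfect(self, arena):
        nb = arena.n_bins
        m = np.zeros((nb, nb))
        m[:, 0] = 1.0
        assert border_score(m, min_field_bins=10) == pytest.approx(1.0)

    def test_central_field_scores_negative(self, arena):
        nb = arena.n_bins
        yy, xx = np.mgrid[0:nb, 0:nb]
        m = (np.hypot(xx - nb / 2, yy - nb / 2) < 5).astype(float)
        assert border_score(m) < 0

    def test_uniform_field_matches_discrete_oracle(self, arena):
        nb = arena.n_bins
        m = np.ones((nb, nb))
        # oracle: cM = 1; dm = mean min-distance-to-wall in bins over half side
        yy, xx = np.mgrid[0:nb, 0:nb]
        dist = np.minimum.reduce([xx, nb - 1 - xx, yy, nb - 1 - yy])
        dm = dist.mean() / (nb / 2)
        expected = (1 - dm) / (1 + dm)
        assert border_score(m) == pytest.approx(expected, abs=1e-9)

    def test_no_field_is_missing(self, arena):
        assert np.isnan(border_score(np.zeros((32, 32))))


class TestHDTuning:
    def _uniform_hd_traj(self, n=3600):
        t = np.arange(n) / 7.52
        hd = np.mod(np.arange(n) * 7.0, 360.0)
        return Trajectory(t, np.linspace(1, 79, n), np.linspace(1, 79, n), hd, 7.52)

    def test_single_bin_activity_has_unit_mvl(self):
        traj = self._uniform_hd_traj()
        events = np.where(np.abs(traj.hd_deg - 93.0) < 3.0, 1.0, 0.0)
        h = hd_tuning(events, traj, speed_min_cms=0.0, smoothing_sigma_bins=0.0)
        assert mvl(h) == pytest.approx(1.0)

    def test_uniform_rate_has_zero_mvl(self):
        traj = self._uniform_hd_traj()
        h = hd_tuning(np.ones(traj.n_frames), traj, speed_min_cms=0.0,
                      smoothing_sigma_bins=0.0)
        assert mvl(h) == pytest.approx(0.0, abs=1e-9)

    def test_two_orthogonal_bins_give_root_half(self):
        h = HDTuning(np.array([3.0, 93.0]), np.ones(2), np.array([1.0, 1.0]))
        assert mvl(h) == pytest.approx(np.sqrt(2) / 2, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 10.0), min_size=4, max_size=60))
    def test_mvl_matches_complex_sum_oracle(self, rates):
        rates = np.array(rates)
        n = len(rates)
        centers = (np.arange(n) + 0.5) * 360.0 / n
        h = HDTuning(centers, np.ones(n), rates)
        got = mvl(h)
        if rates.sum() == 0:
            assert np.isnan(got)
        else:
            z = np.sum(rates * np.exp(1j * np.deg2rad(centers)))
            assert got == pytest.approx(abs(z) / rates.sum(), abs=1e-12)


class TestObjectVector:
    def test_identical_maps_correlate_perfectly(self, traj600, arena):
        c = GroundTruthCell("o", "ov", {"r_cm": 18.0, "theta_deg": 45.0, "width_cm": 8.0},
                            peak_rate=3.0, anat_x_um=0, anat_y_um=0)
        ar = ArenaSpec(objects=((25.0, 25.0),))
        act = synthio.generate_activity(c, traj600, ar, seed=51)
        m = object_vector_map(act.events, traj600, (25.0, 25.0), ar)
        assert ov_score(m, m) == pytest.approx(1.0)

    def test_synthetic_ov_cell_reproduces_across_object_moves(self, arena):
        c = GroundTruthCell("o", "ov", {"r_cm": 18.0, "theta_deg": 45.0, "width_cm": 8.0},
                            peak_rate=4.0, anat_x_um=0, anat_y_um=0)
        maps = []
        for seed, obj in ((61, (25.0, 25.0)), (62, (55.0, 50.0))):
            ar = ArenaSpec(objects=(obj,))
            traj = simulate_trajectory(900.0, ar, seed=seed)
            act = synthio.generate_activity(c, traj, ar, seed=seed)
            maps.append(object_vector_map(act.events, traj, obj, ar))
        assert ov_score(*maps) > 0.5

    def test_white_noise_maps_decorrelate(self):
        rng = np.random.default_rng(7)
        shape = (46, 60)
        m1 = tuning.ObjectVectorMap(rng.normal(size=shape), 2.5, 60)
        m2 = tuning.ObjectVectorMap(rng.normal(size=shape), 2.5, 60)
        assert abs(ov_score(m1, m2)) < 0.1

    def test_too_few_joint_bins_is_missing(self):
        m = tuning.ObjectVectorMap(np.full((46, 60), np.nan), 2.5, 60)
        assert np.isnan(ov_score(m, m))


class TestSpatialInformation:
    def test_uniform_rate_carries_no_information(self):
        assert spatial_information(np.ones((4, 4)), np.ones((4, 4))) == pytest.approx(0.0)

    @pytest.mark.parametrize("n,expected", [(4, 2.0), (16, 4.0)])
    def test_single_active_bin_of_n(self, n, expected):
        side = int(np.sqrt(n))
        rate = np.zeros((side, side))
        rate[0, 0] = 1.0
        occ = np.ones((side, side))
        assert spatial_information(rate, occ) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(2, 6), st.integers(0, 1000))
    def test_nonnegative_and_matches_closed_form(self, side, seed):
        rng = np.random.default_rng(seed)
        rate = rng.exponential(1.0, (side, side))
        occ = rng.uniform(0.5, 2.0, (side, side))
        got = spatial_information(rate, occ)
        p = occ / occ.sum()
        lam_bar = (p * rate).sum()
        expected = np.sum(p * (rate / lam_bar) * np.log2(rate / lam_bar,
                          where=rate > 0, out=np.zeros_like(rate)))
        assert got >= -1e-12
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_rate_is_missing(self):
        assert np.isnan(spatial_information(np.zeros((4, 4)), np.ones((4, 4))))


class TestSNR:
    def test_noiseless_transient_is_kept_with_capped_snr(self):
        events = np.zeros(500)
        events[250] = 1.0
        dff = np.zeros(500)
        dff[250] = 1.0
        keep, snr = filter_by_snr(dff, events)
        assert keep and snr == tuning.SNR_CAP

    def test_pure_noise_without_events_is_dropped(self):
        rng = np.random.default_rng(8)
        keep, snr = filter_by_snr(rng.normal(size=500), np.zeros(500))
        assert not keep and snr == 0.0

    def test_noise_level_separates_cutoffs(self, traj600, untuned_cell, arena):
        c = GroundTruthCell("u", "untuned", {}, peak_rate=0.5, anat_x_um=0, anat_y_um=0)
        act = synthio.generate_activity(c, traj600, arena, noise_level=0.2, seed=71)
        _, snr = filter_by_snr(act.dff, act.events)
        assert 2.0 < snr < 50.0
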