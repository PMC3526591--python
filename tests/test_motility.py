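"""Trajectory statistics: path length, chemotactic index, motile fraction,
velocity binning, speed distributions and the biased-cell t-test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from conftest import straight_trajectory
from gradchamber.motility import (
    Trajectory,
    TrackSet,
    biased_fraction_ttest,
    build_motility_report,
    chemotactic_index_cell,
    chemotactic_index_population,
    chemotactic_index_series,
    curvilinear_length,
    motile_fraction,
    per_cell_mean_speed,
    velocity_series,
)

GRAD = (0.0, -1.0, 0.0)


def random_trajectory_strategy():
    n = st.integers(min_value=2, max_value=20)
    return n.flatmap(lambda k: arrays(
        float, (k, 2),
        elements=st.floats(-100, 100, allow_nan=False, width=32),
    ).map(lambda xy: Trajectory("h", np.arange(len(xy), dtype=float), xy)))


class TestCurvilinearLength:
    def test_hand_computed_three_four_five(self, three_point_trajectory):
        assert curvilinear_length(three_point_trajectory, 0, 2) == pytest.approx(8.0)

    def test_stationary_cell_zero(self):
        tr = Trajectory("s", [0, 1, 2], np.zeros((3, 3)))
        assert curvilinear_length(tr, 0, 2) == 0.0

    def test_window_with_single_sample_is_zero(self, three_point_trajectory):
        assert curvilinear_length(three_point_trajectory, 0.5, 0.9) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(traj=random_trajectory_strategy())
    def test_length_bounds_net_displacement(self, traj):
        L = curvilinear_length(traj, 0, len(traj))
        net = np.linalg.norm(traj.xyz[-1, :2] - traj.xyz[0, :2])
        assert L >= net - 1e-6

    def test_coarser_sampling_shortens_paths(self, unbiased_walk_experiment):
        """Documented caveat: halving the frame rate can only shorten the
        measured curvilinear length of a jagged path."""
        for traj in list(unbiased_walk_experiment.tracks)[:20]:
            sub = Trajectory(traj.cell_id, traj.t_min[::2], traj.xyz[::2],
                             traj.diameter_um)
            L_full = curvilinear_length(traj, 0, traj.t_min[-1])
            L_sub = curvilinear_length(sub, 0, traj.t_min[-1])
            assert L_sub <= L_full + 1e-9


class TestChemotacticIndex:
    def test_straight_toward_source_is_plus_one(self):
        tr = straight_trajectory(GRAD)
        I, L = chemotactic_index_cell(tr, 0, 110, GRAD)
        assert I == pytest.approx(1.0)
        assert L > 0

    def test_straight_away_is_minus_one(self):
        tr = straight_trajectory((0.0, 1.0, 0.0))
        I, _ = chemotactic_index_cell(tr, 0, 110, GRAD)
        assert I == pytest.approx(-1.0)

    def test_hand_computed_three_point_example(self, three_point_trajectory):
        I, L = chemotactic_index_cell(three_point_trajectory, 0, 2, GRAD)
        assert I == pytest.approx(0.75)
        assert L == pytest.approx(8.0)

    def test_zero_path_cell_excluded_via_weight(self):
        tr = Trajectory("s", [0, 1], np.zeros((2, 3)))
        I, L = chemotactic_index_cell(tr, 0, 1, GRAD)
        assert np.isnan(I) and L == 0.0

    def test_population_weighted_mean_example(self):
        """(I, L) = (1, 10) and (0, 30) combine to 0.25."""
        toward = straight_trajectory(GRAD, speed_um_min=1.0, n_frames=11,
                                     cell_id="toward")  # I=1, L=10
        xs = np.cumsum(np.r_[0.0, np.tile([3.0, -3.0], 5)])
        zigzag = Trajectory("zigzag", np.arange(11.0),
                            np.column_stack([xs, np.zeros(11), np.zeros(11)]))
        tracks = TrackSet([toward, zigzag])
        assert chemotactic_index_population(tracks, 10.0) == pytest.approx(0.25)

    def test_identical_straight_population_is_one(self):
        tracks = TrackSet([straight_trajectory(GRAD, cell_id=f"c{i}")
                           for i in range(5)])
        assert chemotactic_index_population(tracks, 110.0) == pytest.approx(1.0)

    def test_all_stationary_population_is_nan(self):
        tracks = TrackSet([Trajectory("s", [0, 1, 2], np.zeros((3, 3)))])
        assert np.isnan(chemotactic_index_population(tracks, 2.0))

    def test_reversing_gradient_negates_index(self, unbiased_walk_experiment):
        tracks = unbiased_walk_experiment.tracks
        I_fwd = chemotactic_index_population(tracks, 110.0)
        flipped = TrackSet(list(tracks), gradient_dir=(0.0, 1.0, 0.0),
                           t_stimulus_min=tracks.t_stimulus_min)
        I_rev = chemotactic_index_population(flipped, 110.0)
        assert I_rev == pytest.approx(-I_fwd)

    def test_population_index_bounded(self, unbiased_walk_experiment):
        ci = chemotactic_index_series(unbiased_walk_experiment.tracks)
        vals = ci.chemotactic_index.dropna()
        assert np.all((vals >= -1) & (vals <= 1))

    def test_rigid_translation_invariance(self, unbiased_walk_experiment):
        tracks = unbiased_walk_experiment.tracks
        shifted = TrackSet(
            [Trajectory(t.cell_id, t.t_min, t.xyz + np.array([50.0, -30.0, 10.0]),
                        t.diameter_um) for t in tracks],
            t_stimulus_min=tracks.t_stimulus_min)
        assert chemotactic_index_population(shifted, 110.0) == pytest.approx(
            chemotactic_index_population(tracks, 110.0))
        v0 = velocity_series(tracks)
        v1 = velocity_series(shifted)
        assert np.allclose(v0[["v_x_um_min", "v_y_um_min", "v_mod_um_min"]],
                           v1[["v_x_um_min", "v_y_um_min", "v_mod_um_min"]])


class TestMotileFraction:
    def test_strict_diameter_criterion(self):
        mover = Trajectory("m", [0.0, 9.0], [[0, 0, 0], [12, 0, 0]], 10.0)
        boundary = Trajectory("b", [0.0, 9.0], [[0, 0, 0], [10, 0, 0]], 10.0)
        still = Trajectory("s", [0.0, 9.0], [[0, 0, 0], [1, 0, 0]], 10.0)
        mf = motile_fraction(TrackSet([mover, boundary, still]))
        assert mf.motile_fraction.iloc[0] == pytest.approx(1 / 3)

    def test_absent_cell_excluded_from_denominator(self):
        present = Trajectory("p", [0.0, 9.0], [[0, 0, 0], [20, 0, 0]], 10.0)
        late = Trajectory("l", [12.0, 19.0], [[0, 0, 0], [20, 0, 0]], 10.0)
        mf = motile_fraction(TrackSet([present, late]))
        assert mf.n_cells.tolist() == [1, 1]
        assert mf.motile_fraction.tolist() == [1.0, 1.0]

    def test_recovers_known_mover_fraction(self):
        """40% fast movers vs jittering non-movers."""
        rng = np.random.default_rng(2)
        t = np.arange(0.0, 31.0)
        cells = []
        for i in range(100):
            if i < 40:  # ballistic movers, 5 µm/min >> diameter per window
                xyz = np.column_stack([np.zeros_like(t), -5.0 * t, np.zeros_like(t)])
            else:
                xyz = rng.normal(0.0, 0.3, (t.size, 3))
            cells.append(Trajectory(f"c{i}", t, xyz, diameter_um=10.0))
        mf = motile_fraction(TrackSet(cells))
        assert np.allclose(mf.motile_fraction, 0.40, atol=0.05)


class TestVelocity:
    def test_constant_velocity_cell(self):
        tr = straight_trajectory((0.0, -1.0, 0.0), speed_um_min=2.0, n_frames=11)
        vs = velocity_series(TrackSet([tr]))
        assert np.allclose(vs.v_y_um_min, -2.0)
        assert np.allclose(vs.v_x_um_min, 0.0)
        assert np.allclose(vs.v_mod_um_min, 2.0)

    def test_isotropic_population_zero_mean_positive_modulus(
            self, unbiased_walk_experiment):
        vs = velocity_series(unbiased_walk_experiment.tracks)
        # stationary AR(1) component sd: s*sqrt((1-a)/(1+a)); within-bin
        # serial correlation inflates the variance of the bin mean by
        # (1/m)*sum_{j,k} a^|j-k| relative to sigma^2/m
        a, s, m = 0.5, 2.0, 5
        sigma = s * np.sqrt((1 - a) / (1 + a))
        j = np.arange(m)
        infl = np.sum(a ** np.abs(j[:, None] - j[None, :])) / m
        se = sigma * np.sqrt(infl / vs.n_samples.to_numpy())
        assert np.all(np.abs(vs.v_x_um_min) < 4 * se)
        assert np.all(np.abs(vs.v_y_um_min) < 4 * se)
        assert np.all(vs.v_mod_um_min > 0)

    def test_drifted_population_recovers_drift(self):
        from gradchamber.synth import WalkParams, simulate_tracks

        b = 1.5
        wp = WalkParams(n_cells=200, persistence=0.0, chemotactic_coupling=0.0,
                        baseline_drift_um_min=b, motile_fraction_pre=1.0,
                        motile_fraction_post=1.0, speed_scale_pre_um_min=2.0,
                        speed_scale_post_um_min=2.0, seed=23)
        exp = simulate_tracks(wp)
        vs = velocity_series(exp.tracks)
        pooled = np.average(vs.v_y_um_min, weights=vs.n_samples)
        se = 2.0 / np.sqrt(vs.n_samples.sum())  # sd≈2 per sample
        assert pooled == pytest.approx(-b, abs=2 * se)

    def test_modulus_is_mean_of_norms_not_norm_of_means(self):
        up = straight_trajectory((0.0, 1.0, 0.0), 2.0, 11, "up")
        down = straight_trajectory((0.0, -1.0, 0.0), 2.0, 11, "down")
        vs = velocity_series(TrackSet([up, down]))
        assert np.allclose(vs.v_y_um_min, 0.0)
        assert np.allclose(vs.v_mod_um_min, 2.0)


class TestPerCellSpeed:
    def test_constant_speed_cell_same_in_both_periods(self):
        tr = straight_trajectory((1.0, 0.0, 0.0), speed_um_min=3.0, n_frames=111)
        tracks = TrackSet([tr], t_stimulus_min=30.0)
        for period in ("pre", "post"):
            dist = per_cell_mean_speed(tracks, period)
            assert dist.per_cell.iloc[0] == pytest.approx(3.0)

    def test_histogram_mass_matches_slow_population(self):
        """80% of cells below 1 µm/min lands 80% of histogram mass in [0,1)."""
        cells = []
        for i in range(50):
            speed = 0.5 if i < 40 else 3.0
            cells.append(straight_trajectory((1.0, 0.0, 0.0), speed, 31, f"c{i}"))
        dist = per_cell_mean_speed(TrackSet(cells, t_stimulus_min=15.0), "pre")
        assert dist.hist_counts[0] / dist.hist_counts.sum() == pytest.approx(0.8)

    def test_cell_in_single_period_reported_once(self):
        late = Trajectory("late", np.arange(40.0, 60.0),
                          np.column_stack([np.arange(20.0) * 2,
                                           np.zeros(20), np.zeros(20)]))
        tracks = TrackSet([late], t_stimulus_min=30.0)
        assert len(per_cell_mean_speed(tracks, "pre").per_cell) == 0
        assert len(per_cell_mean_speed(tracks, "post").per_cell) == 1

    def test_post_stimulus_speedup_detected(self):
        from scipy import stats

        from gradchamber.synth import WalkParams, simulate_tracks

        wp = WalkParams(n_cells=70, persistence=0.0, chemotactic_coupling=0.0,
                        motile_fraction_pre=1.0, motile_fraction_post=1.0,
                        speed_scale_pre_um_min=1.0, speed_scale_post_um_min=3.0,
                        seed=4)
        tracks = simulate_tracks(wp).tracks
        pre = per_cell_mean_speed(tracks, "pre").per_cell
        post = per_cell_mean_speed(tracks, "post").per_cell
        common = pre.index.intersection(post.index)
        assert post[common].mean() > pre[common].mean()
        assert stats.ttest_rel(post[common], pre[common]).pvalue < 0.05


class TestBiasedFraction:
    def test_alpha_level_calibration_on_iid_gaussian(self):
        """Zero-mean iid velocities reject at about the test's alpha."""
        rng = np.random.default_rng(8)
        t = np.arange(0.0, 56.0)
        cells = [Trajectory(f"c{i}", t,
                            np.cumsum(rng.normal(0, 2.0, (t.size, 3)), axis=0))
                 for i in range(300)]
        bf = biased_fraction_ttest(TrackSet(cells))
        for col in ("pct_biased_vx", "pct_biased_vy"):
            assert bf[col].mean() == pytest.approx(5.0, abs=2.0)

    def test_constant_drift_rejects_everywhere(self):
        rng = np.random.default_rng(9)
        t = np.arange(0.0, 26.0)
        steps = np.zeros((t.size, 3))
        cells = []
        for i in range(30):
            steps = rng.normal(0, 1e-4, (t.size, 3))
            steps[:, 1] -= 3.0  # strong drift, negligible noise
            cells.append(Trajectory(f"c{i}", t, np.cumsum(steps, axis=0)))
        bf = biased_fraction_ttest(TrackSet(cells))
        assert np.allclose(bf.pct_biased_vy, 100.0)
        assert np.all(bf.pct_biased_vx < 20.0)

    def test_transient_y_drift_peaks_only_in_y_component(self):
        """A drift pulse shows in v_y rejections while v_x stays at alpha."""
        rng = np.random.default_rng(10)
        t = np.arange(0.0, 111.0)
        drift = np.where((t >= 55) & (t < 80), 2.0, 0.0)
        cells = []
        for i in range(150):
            steps = rng.normal(0, 1.0, (t.size, 3))
            steps[:, 1] -= drift
            cells.append(Trajectory(f"c{i}", t, np.cumsum(steps, axis=0)))
        bf = biased_fraction_ttest(TrackSet(cells))
        pulse = (bf.t_start_min >= 55) & (bf.t_start_min < 80)
        quiet = ~pulse
        assert bf.pct_biased_vy[pulse].mean() > 5 * bf.pct_biased_vy[quiet].mean()
        assert bf.pct_biased_vx[pulse].mean() < 15.0

    def test_short_bins_skipped(self):
        tr = Trajectory("c", [0.0, 1.0, 5.0, 6.0, 7.0, 8.0, 9.0],
                        np.cumsum(np.ones((7, 3)), axis=0))
        bf = biased_fraction_ttest(TrackSet([tr]), min_samples=3)
        # bin [0,5) has 2 velocity samples -> no row for it
        assert bf.t_start_min.tolist() == [5.0]


class TestReport:
    def test_report_assembles_all_metrics(self, unbiased_walk_experiment):
        report = build_motility_report(unbiased_walk_experiment.tracks)
        tidy = report.to_tidy()
        expected = {"motile_fraction", "v_x_um_min", "v_y_um_min",
                    "v_mod_um_min", "chemotactic_index", "pct_biased_vx",
                    "pct_biased_vy", "pct_biased_mod", "mean_speed_pre",
                    "mean_speed_post", "sd_speed_pre", "sd_speed_post"}
        assert expected <= set(tidy.metric)
        mf = tidy[tidy.metric == "motile_fraction"].value.dropna()
        assert np.all((mf >= 0) & (mf <= 1))
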