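"""Rips Betti curves, the boundary-rank oracle, and crocker operations."""

import numpy as np
import pytest

from swarmtda import (
    ArenaConfig,
    average_crocker,
    betti_oracle,
    build_point_clouds,
    compute_crocker,
    concatenate_crockers,
    connectivity_scale,
    crocker_contour_plot,
    crocker_distance,
    generate_initial_conditions,
    rips_betti_curve,
    simulate,
    vr_intervals,
)
from swarmtda.topology import Crocker
from .conftest import make_trajectory

UNIT_SQUARE = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)


class TestBettiCurves:
    def test_discrete_complex_below_min_distance(self):
        rng = np.random.default_rng(0)
        pts = rng.random((9, 2))
        from scipy.spatial.distance import pdist

        eps = 0.9 * pdist(pts).min()
        curve = rips_betti_curve(pts, np.array([eps]), max_dim=1)
        assert curve[0, 0] == 9 and curve[1, 0] == 0

    def test_unit_square_cycle(self):
        grid = np.array([0.5, 1.0, 1.3, np.sqrt(2), 2.0])
        curve = rips_betti_curve(UNIT_SQUARE, grid, max_dim=1)
        assert list(curve[0]) == [4, 1, 1, 1, 1]
        # cycle alive exactly on 1 <= eps < sqrt(2)
        assert list(curve[1]) == [0, 1, 1, 0, 0]

    def test_b0_at_zero_counts_distinct_points(self):
        pts = np.array([[0, 0], [0, 0], [0.1, 0], [0.2, 0.2]])
        curve = rips_betti_curve(pts, np.array([0.0]), max_dim=0)
        assert curve[0, 0] == 3

    def test_b0_monotone_and_terminal(self):
        rng = np.random.default_rng(1)
        pts = rng.random((15, 2))
        from scipy.spatial.distance import pdist

        grid = np.linspace(0, 1.01 * pdist(pts).max(), 40)
        b0 = rips_betti_curve(pts, grid, max_dim=0)[0]
        assert np.all(np.diff(b0) <= 0)
        assert b0[-1] == 1
        assert b0[0] == 15

    def test_empty_and_singleton_clouds(self):
        grid = np.array([0.0, 0.5])
        assert np.array_equal(rips_betti_curve(np.empty((0, 2)), grid, 1), np.zeros((2, 2)))
        single = rips_betti_curve(np.array([[0.3, 0.3]]), grid, 1)
        assert list(single[0]) == [1, 1] and list(single[1]) == [0, 0]

    def test_descending_grid_rejected(self):
        with pytest.raises(ValueError):
            rips_betti_curve(UNIT_SQUARE, np.array([1.0, 0.5]), 1)


class TestBettiOracle:
    def test_filled_triangle(self):
        pts = np.array([[0, 0], [1, 0], [0.5, 0.9]])
        assert betti_oracle(pts, 1.2, 0) == 1
        assert betti_oracle(pts, 1.2, 1) == 0

    def test_unit_square_at_one(self):
        assert betti_oracle(UNIT_SQUARE, 1.0, 1) == 1
        assert betti_oracle(UNIT_SQUARE, 1.0, 0) == 1

    def test_five_pairs_at_two_cm(self):
        pts = np.concatenate([[[0.1 * i, 0], [0.1 * i, 0.02]] for i in range(5)])
        assert betti_oracle(pts, 0.02, 0) == 5

    def test_oversize_cloud_rejected(self):
        with pytest.raises(ValueError):
            betti_oracle(np.zeros((26, 2)), 0.1, 0)

    def test_persistence_agrees_with_oracle_on_random_clouds(self):
        # smaller companion of the acceptance-level sweep
        rng = np.random.default_rng(2)
        for _ in range(40):
            n = int(rng.integers(2, 16))
            dim = int(rng.choice([2, 4]))
            pts = rng.random((n, dim))
            grid = np.sort(rng.random(4)) * 1.5
            curve = rips_betti_curve(pts, grid, max_dim=1)
            for i, eps in enumerate(grid):
                assert curve[0, i] == betti_oracle(pts, eps, 0)
                assert curve[1, i] == betti_oracle(pts, eps, 1)


class TestIntervals:
    def test_h0_intervals_one_per_point(self):
        rng = np.random.default_rng(3)
        pts = rng.random((7, 2))
        ivals = vr_intervals(pts, max_dim=0)
        assert len(ivals[0]) == 7
        assert sum(1 for b, d in ivals[0] if np.isinf(d)) == 1
        assert all(b == 0 for b, _ in ivals[0])

    def test_truncation_keeps_betti_exact_within_range(self):
        rng = np.random.default_rng(4)
        pts = rng.random((12, 2))
        full = rips_betti_curve(pts, np.linspace(0, 0.6, 10), max_dim=1)
        for i, eps in enumerate(np.linspace(0, 0.6, 10)):
            assert full[1, i] == betti_oracle(pts, eps, 1)


class TestPointClouds:
    def test_stride_counts_frames(self):
        traj = make_trajectory(np.zeros((16, 3, 2)))
        seq = build_point_clouds(traj, "pos", time_stride=4)
        assert len(seq.clouds) == 4
        assert list(seq.times) == [0, 4, 8, 12]

    def test_posvel_normalisation(self):
        pos = np.tile([[0.2, 0.0]], (4, 1, 1))
        traj = make_trajectory(pos)
        seq = build_point_clouds(traj, "posvel", time_stride=1)
        assert seq.times[0] == 1
        assert np.allclose(seq.clouds[0][0], [1.0, 0.0, 0.0, 0.0])

    def test_pos_mode_ignores_velocities(self):
        rng = np.random.default_rng(5)
        pos = np.cumsum(rng.normal(0, 1e-3, (6, 4, 2)), axis=0)
        traj = make_trajectory(pos, arena=ArenaConfig(radius=1.0))
        seq = build_point_clouds(traj, "pos", time_stride=1)
        assert np.allclose(seq.clouds[2], pos[2])

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            build_point_clouds(make_trajectory(np.zeros((4, 2, 2))), "velocity")


class TestCrocker:
    def test_static_cloud_columns_identical(self):
        pos = np.tile(np.array([[[0.0, 0.0], [0.05, 0.0], [0.0, 0.07]]]), (12, 1, 1))
        c = compute_crocker(make_trajectory(pos), "pos", k=0)
        assert np.all(c.betti == c.betti[:, :1])

    def test_coincident_agents_single_component(self):
        pos = np.zeros((8, 5, 2))
        c = compute_crocker(make_trajectory(pos), "pos", k=0)
        assert np.all(c.betti[1:] == 1)
        assert c.betti.shape == (50, 2)

    def test_defaults_follow_study_grid(self, short_run):
        c = compute_crocker(short_run, "pos", k=0)
        assert c.eps_grid[0] == 0.0 and c.eps_grid[-1] == pytest.approx(0.2)
        assert len(c.eps_grid) == 50
        assert np.all(np.diff(c.times) == 4)
        cpv = compute_crocker(short_run, "posvel", k=1)
        assert cpv.eps_grid[-1] == pytest.approx(1.5)

    def test_dropped_agent_column_uses_reduced_cloud(self, short_run):
        present = short_run.present.copy()
        present[8, :3] = False
        traj = make_trajectory(short_run.positions, states=short_run.states, present=present)
        c = compute_crocker(traj, "pos", k=0, time_stride=8)
        col = list(c.times).index(8)
        cloud = short_run.positions[8][present[8]]
        for i in (0, 10, 30):
            assert c.betti[i, col] == betti_oracle(cloud, c.eps_grid[i], 0)

    def test_rigid_motion_and_relabel_invariance(self):
        rng = np.random.default_rng(6)
        pos = rng.uniform(-0.08, 0.08, (9, 7, 2))
        base = compute_crocker(make_trajectory(pos), "pos", k=0, time_stride=2)
        ang = 0.7
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        moved = pos @ rot.T + [0.01, -0.02]
        perm = rng.permutation(7)
        other = compute_crocker(
            make_trajectory(moved[:, perm], arena=ArenaConfig(radius=0.5)),
            "pos", k=0, time_stride=2,
        )
        assert np.array_equal(base.betti, other.betti)

    def test_invalid_k_rejected(self, short_run):
        with pytest.raises(ValueError):
            compute_crocker(short_run, "pos", k=2)


class TestCrockerAlgebra:
    def _crocker(self, matrix):
        matrix = np.asarray(matrix)
        return Crocker(
            matrix,
            np.linspace(0, 1, matrix.shape[0]),
            np.arange(matrix.shape[1]),
            0,
            "pos",
        )

    def test_average_identity_and_midpoint(self):
        a = self._crocker(np.zeros((4, 3), int))
        b = self._crocker(2 * np.ones((4, 3), int))
        assert np.array_equal(average_crocker([b, b]).betti, b.betti)
        assert np.allclose(average_crocker([a, b]).betti, 1.0)

    def test_average_grid_mismatch_rejected(self):
        a = self._crocker(np.zeros((4, 3), int))
        b = self._crocker(np.zeros((5, 3), int))
        with pytest.raises(ValueError):
            average_crocker([a, b])

    def test_averaging_reduces_column_variance(self, params):
        ic = generate_initial_conditions(8, "clustered", seed=20)
        crockers = [
            compute_crocker(simulate(ic, params, 40, seed=s), "pos", 0, time_stride=8)
            for s in range(8)
        ]
        mean_c = average_crocker(crockers)
        var_single = np.mean([np.var(c.betti, axis=1).mean() for c in crockers])
        assert np.var(mean_c.betti, axis=1).mean() <= var_single + 1e-12

    def test_concatenation_rows_and_norm_additivity(self, short_run):
        c0 = compute_crocker(short_run, "pos", 0, time_stride=8)
        c1 = compute_crocker(short_run, "pos", 1, time_stride=8)
        cat = concatenate_crockers(c0, c1)
        assert cat.shape[0] == c0.betti.shape[0] + c1.betti.shape[0]
        other0 = Crocker(c0.betti + 1, c0.eps_grid, c0.times, 0, "pos")
        other1 = Crocker(c1.betti + 2, c1.eps_grid, c1.times, 1, "pos")
        d_cat = crocker_distance(cat, concatenate_crockers(other0, other1))
        d0 = crocker_distance(c0, other0)
        d1 = crocker_distance(c1, other1)
        assert d_cat == pytest.approx(np.sqrt(d0**2 + d1**2))

    def test_concatenation_time_grid_mismatch_rejected(self, short_run):
        c0 = compute_crocker(short_run, "pos", 0, time_stride=8)
        c1 = compute_crocker(short_run, "pos", 1, time_stride=16)
        with pytest.raises(ValueError):
            concatenate_crockers(c0, c1)

    def test_connectivity_scale_monotone_meaning(self):
        m = np.array([[3, 2], [2, 1], [1, 1], [1, 1]])
        c = self._crocker(m)
        scale = connectivity_scale(c)
        assert scale[0] == c.eps_grid[2] and scale[1] == c.eps_grid[1]


class TestContourPlot:
    def test_smoke_render_and_cap(self, tmp_path, short_run):
        c = compute_crocker(short_run, "pos", k=0)
        out = tmp_path / "crocker.png"
        ax = crocker_contour_plot(c, max_contour=11, path=str(out))
        assert out.exists() and out.stat().st_size > 0

    def test_levels_respect_cap(self, short_run):
        import matplotlib

        matplotlib.use("Agg", force=True)
        import matplotlib.pyplot as plt

        c = compute_crocker(short_run, "pos", k=0)
        fig, ax = plt.subplots()
        crocker_contour_plot(c, max_contour=5, ax=ax)
        levels = [coll for coll in ax.collections]
        assert len(levels) > 0
        plt.close(fig)
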