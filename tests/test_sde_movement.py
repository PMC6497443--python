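import numpy as np
import pytest

from colonystate.errors import FitError
from colonystate.preprocess import IN_NEST, OUTSIDE, AntTrack
from colonystate.sde_movement import (
    SurfaceGrid,
    build_regression,
    fit_sde,
    regression_loglik,
    simulate_positions,
    surface_report,
)

from conftest import stationary_track


def _tracks_from(pos):
    return [
        AntTrack(f"a{i}", pos[i], np.full(pos.shape[1], IN_NEST, dtype=np.int8))
        for i in range(len(pos))
    ]


class TestBuildRegression:
    def test_stationary_ant_zero_targets(self, nest1):
        rec = build_regression([stationary_track("a", (30.0, 0.0), 20)])
        assert np.allclose(rec.target, 0.0)
        assert np.allclose(rec.vel, 0.0)

    def test_constant_velocity_zero_second_difference(self, nest1):
        t = np.arange(31)
        xy = np.column_stack([5.0 + 0.5 * t, np.full(31, -5.0)])
        rec = build_regression([AntTrack("a", xy, np.full(31, IN_NEST, dtype=np.int8))])
        assert np.allclose(rec.target, 0.0, atol=1e-12)
        assert np.allclose(rec.vel[:, 0], 0.5)

    def test_outside_spells_break_windows(self, nest1):
        xy = np.tile([30.0, 0.0], (10, 1))
        presence = np.full(10, IN_NEST, dtype=np.int8)
        presence[4] = OUTSIDE
        rec = build_regression([AntTrack("a", xy, presence)])
        # windows 2..4, 3..5, 4..6 are unusable
        assert rec.n == 10 - 2 - 3

    def test_short_track_warns(self, nest1):
        with pytest.warns(UserWarning):
            with pytest.raises(FitError):
                build_regression([stationary_track("a", (5.0, 0.0), 1)])

    def test_likelihood_peaks_near_truth(self, nest1):
        pos = simulate_positions(
            nest1, 5, 2000, beta=0.5, mu=None, c=1.0, x0=np.array([32.0, 0.0]), seed=0
        )
        rec = build_regression(_tracks_from(pos))
        ll_true = regression_loglik(rec, 0.5, 0.0, 1.0)
        assert ll_true > regression_loglik(rec, 1.2, 0.0, 1.0)
        assert ll_true > regression_loglik(rec, 0.5, 0.0, 2.5)


class TestSimulate:
    def test_zero_noise_zero_drift_is_stationary(self, nest1):
        pos = simulate_positions(
            nest1, 3, 100, beta=0.5, mu=None, c=0.0, x0=np.array([30.0, 5.0]), seed=1
        )
        assert np.allclose(pos, pos[:, :1, :])

    def test_bit_reproducible(self, nest1):
        kw = dict(beta=0.5, mu=None, c=1.0, x0=np.array([30.0, 0.0]), seed=9)
        a = simulate_positions(nest1, 4, 500, **kw)
        b = simulate_positions(nest1, 4, 500, **kw)
        assert np.array_equal(a, b)

    def test_velocity_matches_ou_stationary_variance(self):
        # wide open arena so wall projection cannot clip the noise
        from colonystate.geometry import build_nest

        nest = build_nest(
            {
                "chambers": [(0, -300, 600, 600)],
                "openings": [{"a": 0, "b": "outside", "center": (0, 0)}],
            }
        )
        beta, c, h = 0.5, 1.0, 1.0
        pos = simulate_positions(
            nest, 30, 4000, beta=beta, mu=None, c=c, x0=np.array([300.0, 0.0]), seed=3
        )
        v = np.diff(pos[:, 1000:, :], axis=1)
        want = h**3 * c**2 / h**2 / (1 - (1 - beta * h) ** 2)
        assert np.var(v) == pytest.approx(want, rel=0.05)

    def test_deep_well_occupancy(self, nest4):
        well = np.asarray(nest4.chambers[3].center)
        pos = simulate_positions(
            nest4,
            5,
            4000,
            beta=0.5,
            mu=lambda x: -0.05 * (x - well),
            c=1.0,
            x0=well,
            seed=5,
        )
        in_queen = pos[:, :, 0] >= nest4.chambers[3].x0
        assert in_queen.mean() >= 0.90

    def test_mean_position_near_well_centre(self, nest1):
        well = np.array([40.0, 5.0])
        pos = simulate_positions(
            nest1,
            10,
            3000,
            beta=0.5,
            mu=lambda x: -0.05 * (x - well),
            c=1.0,
            x0=well,
            seed=6,
        )
        mean = pos[:, 500:, :].reshape(-1, 2).mean(axis=0)
        assert np.linalg.norm(mean - well) < 2.0


class TestFitSDE:
    def test_flat_surface_recovery(self, nest1):
        pos = simulate_positions(
            nest1, 10, 6000, beta=0.5, mu=None, c=1.0, x0=np.array([32.0, 0.0]), seed=7
        )
        fit = fit_sde(build_regression(_tracks_from(pos)), nest1, grid_mm=10.0)
        assert fit.beta == pytest.approx(0.5, rel=0.10)
        assert np.median(fit.motility) == pytest.approx(1.0, rel=0.15)

    def test_well_centre_recovered(self, nest1):
        well = np.array([40.0, 5.0])
        pos = simulate_positions(
            nest1,
            10,
            6000,
            beta=0.5,
            mu=lambda x: -0.05 * (x - well),
            c=1.0,
            x0=well,
            seed=8,
        )
        fit = fit_sde(build_regression(_tracks_from(pos)), nest1, grid_mm=5.0)
        argmin = fit.grid.centers[np.argmin(fit.potential)]
        assert np.linalg.norm(argmin - well) <= 2 * 5.0

    def test_zero_noise_gives_vanishing_residual_variance(self, nest1):
        # deterministic gliding motion (initial velocity, no noise): the fit
        # explains it exactly and the motility estimate collapses to zero
        rng = np.random.default_rng(0)
        v0 = rng.normal(0, 0.5, size=(5, 2))
        pos = simulate_positions(
            nest1, 5, 200, beta=0.1, mu=None, c=0.0,
            x0=np.array([32.0, 0.0]), v0=v0, seed=0,
        )
        fit = fit_sde(build_regression(_tracks_from(pos)), nest1, grid_mm=20.0)
        assert np.all(fit.motility < 1e-3)

    def test_penalty_monotonically_smooths_potential(self, nest1):
        well = np.array([40.0, 5.0])
        pos = simulate_positions(
            nest1, 5, 3000, beta=0.5,
            mu=lambda x: -0.05 * (x - well), c=1.0, x0=well, seed=2,
        )
        rec = build_regression(_tracks_from(pos))
        grid = SurfaceGrid(nest1, cell_mm=10.0)
        d2 = grid.second_difference()
        rough = []
        for lam in (1e0, 1e3, 1e6):
            fit = fit_sde(rec, nest1, grid_mm=10.0, penalty_drift=lam)
            rough.append(float(((d2 @ fit.potential) ** 2).sum()))
        assert rough[0] >= rough[1] >= rough[2]

    def test_downhill_force_alignment(self, nest1):
        # average fitted drift points downhill: cosine similarity with the
        # true inward force of the well
        well = np.array([40.0, 0.0])
        pos = simulate_positions(
            nest1, 10, 6000, beta=0.5,
            mu=lambda x: -0.05 * (x - well), c=1.0, x0=well, seed=4,
        )
        fit = fit_sde(build_regression(_tracks_from(pos)), nest1, grid_mm=5.0)
        visited = np.zeros(fit.grid.n_cells, dtype=bool)
        visited[np.unique(fit.grid.cell_of(pos.reshape(-1, 2)))] = True
        truth = -0.05 * (fit.grid.centers - well)
        num = (fit.drift_field[visited] * truth[visited]).sum()
        den = np.linalg.norm(fit.drift_field[visited]) * np.linalg.norm(truth[visited])
        assert num / den > 0.9


class TestSurfaceReport:
    def test_uniform_fit_equal_chamber_means(self, nest4):
        pos = simulate_positions(
            nest4, 12, 4000, beta=0.5, mu=None, c=1.0,
            x0=np.array([nest4.chambers[i % 4].center for i in range(12)]), seed=11,
        )
        fit = fit_sde(build_regression(_tracks_from(pos)), nest4, grid_mm=10.0)
        _, means = surface_report(fit)
        vals = np.array(list(means.values()))
        assert vals.max() - vals.min() < 0.25 * vals.mean()

    def test_grid_export_covers_walkable_cells(self, nest4):
        grid = SurfaceGrid(nest4, cell_mm=5.0)
        from colonystate.sde_movement import SDEFit

        fit = SDEFit(
            beta=0.5,
            potential=np.zeros(grid.n_cells),
            motility=np.ones(grid.n_cells),
            grid=grid,
            h=1.0,
            penalty_drift=1.0,
            penalty_motility=1.0,
            drift_field=np.zeros((grid.n_cells, 2)),
        )
        df, _ = surface_report(fit)
        assert len(df) == grid.n_cells
        # every exported cell centre is inside or within half a cell of the nest
        from colonystate.geometry import project_into_nest_many

        pts = df[["x_mm", "y_mm"]].to_numpy()
        proj = project_into_nest_many(pts, nest4)
        assert np.all(np.abs(proj - pts).max(axis=1) <= 2.5 + 1e-9)

    def test_highway_scenario_middle_chambers_faster(self, nest4):
        # 3x motility in the two middle chambers, wells keeping ants near the
        # ends: fitted middle-chamber motility clearly exceeds the occupied end
        # chambers
        ends = np.array([nest4.chambers[0].center, nest4.chambers[3].center])
        homes = ends[np.arange(16) % 2]

        def c_of(x):
            mid = (x[:, 0] > nest4.chambers[1].x0) & (x[:, 0] < nest4.chambers[2].x1)
            return np.where(mid, 3.0, 1.0)

        def mu(x):
            return -0.02 * (x - homes)

        pos = simulate_positions(
            nest4, 16, 8000, beta=0.5, mu=mu, c=c_of, x0=homes, seed=13
        )
        fit = fit_sde(build_regression(_tracks_from(pos)), nest4, grid_mm=10.0)
        _, means = surface_report(fit)
        middle = np.mean([means[1], means[2]])
        occupied = np.mean([means[0], means[3]])
        assert middle > 2.0 * occupied
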