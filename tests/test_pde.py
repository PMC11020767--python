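import numpy as np
import pytest

from abtau import (
    Grid2D,
    InflammationField,
    chemotaxis_divergence,
    integrate_ode,
    integrate_pde,
    laplacian_noflux,
    make_pixel_map,
    map_to_field,
    spatial_average,
)
from abtau.pde import FieldSnapshot, _DiffusionSolvers
from tests.conftest import rel_err


@pytest.fixture()
def grid():
    return Grid2D(n_x=12, n_y=10, h=0.05)


class TestLaplacian:
    def test_constant_field_annihilated(self, grid):
        assert np.allclose(laplacian_noflux(np.full(grid.shape, 3.7), grid), 0.0)

    def test_interior_spike_conserves_mass(self, grid):
        f = np.zeros(grid.shape)
        f[4, 6] = 1.0
        lap = laplacian_noflux(f, grid)
        assert abs(lap.sum()) < 1e-12 / grid.h**2

    def test_cosine_mode_eigenvalue(self):
        # cos(pi x / L) is a Neumann eigenmode with eigenvalue -(pi/L)^2
        n = 200
        g = Grid2D(n_x=n, n_y=2, h=1.0 / n)
        x = (np.arange(n) + 0.5) * g.h
        f = np.tile(np.cos(np.pi * x), (2, 1))
        lap = laplacian_noflux(f, g)
        lam = lap[0, 50:150] / f[0, 50:150]  # away from tiny denominators
        assert np.allclose(lam, -np.pi**2, rtol=1e-3)

    def test_shape_mismatch_rejected(self, grid):
        with pytest.raises(ValueError, match="shape"):
            laplacian_noflux(np.zeros((3, 3)), grid)

    def test_mask_boundary_is_reflecting(self):
        mask = np.ones((6, 6), dtype=bool)
        mask[:, 3:] = False
        g = Grid2D(6, 6, 0.1, mask=mask)
        f = np.where(mask, 2.0, 99.0)  # inactive values must not leak in
        lap = laplacian_noflux(f, g)
        assert np.allclose(lap[mask], 0.0)


class TestChemotaxis:
    def test_uniform_attractant_no_flux(self, grid):
        M = np.random.default_rng(0).uniform(1, 2, grid.shape)
        div = chemotaxis_divergence(M, np.full(grid.shape, 5.0), 1e-3, 1e-5, grid)
        assert np.allclose(div, 0.0)

    def test_divergence_sums_to_zero(self, grid):
        rng = np.random.default_rng(1)
        M = rng.uniform(0.5, 1.5, grid.shape)
        abo = rng.uniform(0.0, 1.0, grid.shape)
        div = chemotaxis_divergence(M, abo, 1e-3, 1e-5, grid)
        assert abs(div.sum()) < 1e-14 * np.abs(div).max() * div.size

    def test_face_speed_saturates_at_delta(self, grid):
        # arbitrarily steep gradients: transport speed approaches delta
        delta = 2.5e-4
        abo = np.zeros(grid.shape)
        abo[:, 6:] = 1.0  # huge jump relative to K_grad
        M = np.ones(grid.shape)
        div = chemotaxis_divergence(M, abo, delta, 1e-9, grid)
        # outflow from the donor column equals speed/h * M, bounded by delta/h
        assert div.max() <= delta / grid.h * (1 + 1e-12)
        assert div.max() == pytest.approx(delta / grid.h, rel=1e-3)

    def test_microglia_move_up_gradient(self, grid):
        abo = np.tile(np.linspace(0, 1, grid.n_x), (grid.n_y, 1))
        M = np.ones(grid.shape)
        div = chemotaxis_divergence(M, abo, 1e-3, 1e-5, grid)
        # net loss on the low side, net gain on the high side
        assert div[:, 0].mean() > 0
        assert div[:, -1].mean() < 0

    def test_bad_saturation_constant_rejected(self, grid):
        with pytest.raises(ValueError):
            chemotaxis_divergence(
                np.ones(grid.shape), np.ones(grid.shape), 1e-3, 0.0, grid
            )


class TestDiffusionSolver:
    def test_backward_euler_conserves_mass(self, grid):
        solvers = _DiffusionSolvers(grid)
        rng = np.random.default_rng(2)
        f = rng.uniform(0, 1, grid.shape)
        g = solvers.solve(f, dt=5.0, D=1e-3)
        assert g.sum() == pytest.approx(f.sum(), rel=1e-10)

    def test_masked_mass_conservation(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:7, 1:6] = True
        g = Grid2D(8, 8, 0.1, mask=mask)
        solvers = _DiffusionSolvers(g)
        f = np.where(mask, np.random.default_rng(3).uniform(0, 1, (8, 8)), 0.0)
        out = solvers.solve(f, dt=2.0, D=1e-2)
        assert out[mask].sum() == pytest.approx(f[mask].sum(), rel=1e-10)
        assert np.allclose(out[~mask], 0.0)


class TestIntegratePde:
    def test_zero_inflammation_stays_at_health(self, params, ref):
        grid = Grid2D(8, 8, 0.125)
        pm = make_pixel_map(4, 4, (0, 0, 0, 1), seed=0)
        field = map_to_field(pm, block=2)
        snaps = integrate_pde(grid, params, ref, field, 50.0, [25.0, 50.0], dt=0.5)
        for snap in snaps:
            for var, val in zip(
                ("abi", "abo", "tau", "M", "A", "N"), ref.as_state_vector()
            ):
                assert np.allclose(snap[var], val, rtol=1e-9)

    def test_uniform_field_matches_ode(self, params, ref):
        # spatially uniform drivers: every cell follows the well-mixed
        # trajectory (the spatial operators are inert)
        grid = Grid2D(10, 10, 0.1)
        field = InflammationField.uniform()
        times = [100.0, 300.0]
        snaps = integrate_pde(grid, params, ref, field, 300.0, times, dt=0.25)
        traj = integrate_ode(params, ref, field, 300.0, sample_interval=100.0)
        for snap in snaps:
            ode_state = traj.states[np.searchsorted(traj.t, snap.t)]
            for i, var in enumerate(("abi", "abo", "tau", "M", "A", "N")):
                assert np.all(rel_err(snap[var], ode_state[i]) < 5e-3), (snap.t, var)

    def test_mixed_map_brackets_pure_class_endpoints(self, params, ref):
        # per-cell values at late time lie between the tau-biased and
        # amyloid-biased well-mixed solutions (up to diffusive smoothing)
        grid = Grid2D(10, 10, 0.1)
        pm = make_pixel_map(5, 5, (0.4, 0.4, 0.15, 0.05), seed=11)
        field = map_to_field(pm, block=2)
        snap = integrate_pde(grid, params, ref, field, 200.0, [200.0], dt=0.25)[-1]
        lo = integrate_ode(
            params, ref, InflammationField.uniform(0.5 * 1.85e-6, 1.5 * 4.13e-10),
            200.0, sample_interval=100.0,
        )
        hi = integrate_ode(
            params, ref, InflammationField.uniform(1.5 * 1.85e-6, 0.5 * 4.13e-10),
            200.0, sample_interval=100.0,
        )
        tol = 0.02
        assert snap["abo"].max() <= hi["abo"][-1] * (1 + tol)
        assert snap["abo"].min() >= ref.abo_ss * (1 - tol)
        assert snap["tau"].max() <= lo["tau"][-1] * (1 + tol)

    def test_snapshot_times_validated(self, params, ref):
        grid = Grid2D(6, 6, 0.1)
        with pytest.raises(ValueError):
            integrate_pde(
                grid, params, ref, InflammationField.uniform(), 100.0, [150.0]
            )

    def test_all_densities_nonnegative(self, params, ref):
        grid = Grid2D(10, 10, 0.1)
        pm = make_pixel_map(5, 5, (0.5, 0.3, 0.15, 0.05), seed=2)
        field = map_to_field(pm, block=2)
        snap = integrate_pde(grid, params, ref, field, 100.0, [100.0], dt=0.5)[-1]
        for var in ("abi", "abo", "tau", "M", "A", "N"):
            assert np.all(snap[var] >= 0)


class TestSpatialAverage:
    def test_constant_field(self):
        grid = Grid2D(5, 4, 0.1)
        snap = FieldSnapshot(
            t=1.0,
            state={v: np.full(grid.shape, 2.5) for v in ("abi", "abo", "tau", "M", "A", "N")},
            fi=np.full(grid.shape, 0.5),
        )
        avg = spatial_average(snap, grid)
        assert avg["abo"] == pytest.approx(2.5)
        assert avg["fi"] == pytest.approx(0.5)

    def test_checkerboard(self):
        grid = Grid2D(4, 4, 0.1)
        f = np.indices(grid.shape).sum(axis=0) % 2
        board = np.where(f == 0, 1.0, 3.0)
        snap = FieldSnapshot(
            t=0.0,
            state={v: board for v in ("abi", "abo", "tau", "M", "A", "N")},
            fi=board,
        )
        assert spatial_average(snap, grid)["tau"] == pytest.approx(2.0)

    def test_masked_average_uses_active_cells_only(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, :2] = True
        grid = Grid2D(4, 4, 0.1, mask=mask)
        arr = np.zeros((4, 4))
        arr[0, 0], arr[0, 1] = 2.0, 4.0
        snap = FieldSnapshot(
            t=0.0, state={v: arr for v in ("abi", "abo", "tau", "M", "A", "N")}, fi=arr
        )
        assert spatial_average(snap, grid)["M"] == pytest.approx(3.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="active"):
            Grid2D(4, 4, 0.1, mask=np.zeros((4, 4), dtype=bool))
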