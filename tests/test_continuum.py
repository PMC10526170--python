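"""Continuum solver oracles: analytic diffusion, closed forms, balances."""

import numpy as np
import pytest

from hdctumor.config import (BoundaryConditions, GridSpec, InitialConditions,
                             ModelParameters)
from hdctumor import continuum
from hdctumor.continuum import (AxisymStepper, ContinuumState, advance,
                                cell_mass, compute_cell_fluxes, initial_state,
                                run_continuum, step_cells, step_collagen,
                                step_collagenase, step_nutrient)


def make_state(grid, Cp=0.0, n=4.5, M=0.0, f=1e-9):
    shape = (grid.n_r,) if grid.axisymmetric else (grid.n_r, grid.n_theta)
    return ContinuumState(
        Cp=np.full(shape, float(Cp)), n=np.full(shape, float(n)),
        M=np.full(shape, float(M)), f=np.full(shape, float(f)), t=0.0)


@pytest.fixture
def grid():
    return GridSpec(R=0.2, n_r=64, n_theta=16)


@pytest.fixture
def params():
    return ModelParameters()


class TestCellFluxes:
    def test_uniform_fields_give_zero_fluxes(self, grid, params):
        state = make_state(grid, Cp=3.0, n=2.0)
        fx = compute_cell_fluxes(state, params, grid)
        assert np.all(fx.jf_r == 0.0)
        assert np.all(fx.jd_r == 0.0)

    def test_zero_chemotaxis_coefficient_kills_chemotactic_flux(self, grid):
        params = ModelParameters(chi_chem=0.0)
        state = make_state(grid, Cp=1.0)
        state.n = np.linspace(1.0, 4.0, grid.n_r)  # strong gradient
        fx = compute_cell_fluxes(state, params, grid)
        assert np.all(fx.jd_r == 0.0)

    def test_linear_profile_flux_matches_one_sided_oracle(self, params):
        grid = GridSpec(R=0.2, n_r=256)
        r = np.arange(grid.n_r) * grid.dr
        slope = 7.5
        state = make_state(grid)
        state.Cp = 1.0 + slope * r
        fx = compute_cell_fluxes(state, params, grid)
        # independent one-sided difference oracle at a few faces
        for j in (3, 100, 250):
            oracle = (state.Cp[j + 1] - state.Cp[j]) / grid.dr
            assert fx.jf_r[j] == pytest.approx(-params.D_i * oracle,
                                               rel=1e-12)
            assert abs(fx.jf_r[j]) == pytest.approx(params.D_i * slope,
                                                    rel=1e-9)

    def test_nonconvex_mode_finite_and_vanishes_without_cells(self, grid,
                                                              params):
        empty = make_state(grid, Cp=0.0)
        fx0 = compute_cell_fluxes(empty, params, grid, nonconvex=True)
        assert np.all(fx0.jf_r == 0.0)
        state = make_state(grid)
        r = np.arange(grid.n_r) * grid.dr
        state.Cp = params.cp_packing * np.exp(-(r / 0.05) ** 2)
        fx = compute_cell_fluxes(state, params, grid, nonconvex=True)
        assert np.all(np.isfinite(fx.jf_r))
        assert np.any(fx.jf_r != 0.0)

    def test_nonfinite_field_rejected(self, grid, params):
        state = make_state(grid, Cp=1.0)
        state.Cp[3] = np.nan
        with pytest.raises(FloatingPointError):
            compute_cell_fluxes(state, params, grid)


def heat_kernel_2d(r, t_eff, D):
    """Closed-form axisymmetric heat kernel (unit mass)."""
    return np.exp(-r**2 / (4.0 * D * t_eff)) / (4.0 * np.pi * D * t_eff)


def diffuse_gaussian_error(n_r, D, steps_scale=1.0):
    """Relative L2 error of the solver vs the analytic Gaussian spread."""
    grid = GridSpec(R=0.5, n_r=n_r)
    params = ModelParameters(D_n=D)
    bc = BoundaryConditions(n0=0.0)
    r = np.arange(grid.n_r) * grid.dr
    t0 = 0.0064 / (4.0 * D)      # initial width sigma = 80 um
    state = make_state(grid, Cp=0.0)
    state.n = heat_kernel_2d(r, t0, D)
    dt = grid.stability_bound(params)
    n_steps = int(round(t0 * steps_scale / dt))
    for _ in range(n_steps):
        state.n = step_nutrient(state, params, bc, grid, dt)
    exact = heat_kernel_2d(r, t0 + n_steps * dt, D)
    w = r.copy()
    w[0] = grid.dr / 8.0
    num = np.sqrt(np.sum(w * (state.n - exact) ** 2))
    den = np.sqrt(np.sum(w * exact**2))
    return num / den


class TestNutrient:
    def test_equilibrium_without_cells(self, grid, params):
        bc = BoundaryConditions(n0=4.5)
        state = make_state(grid, Cp=0.0, n=4.5)
        out = step_nutrient(state, params, bc, grid, dt=0.1)
        np.testing.assert_allclose(out, 4.5, rtol=1e-14)

    def test_gaussian_matches_heat_kernel(self):
        err = diffuse_gaussian_error(n_r=128, D=4.2e-6)
        assert err < 0.02

    def test_grid_refinement_reduces_error(self):
        e64 = diffuse_gaussian_error(64, 4.2e-6)
        e128 = diffuse_gaussian_error(128, 4.2e-6)
        assert e128 < e64

    def test_no_negative_nutrient_from_consumption(self, grid, params):
        bc = BoundaryConditions(n0=0.0)
        state = make_state(grid, Cp=1e6, n=0.0)
        out = step_nutrient(state, params, bc, grid, dt=1.0)
        assert np.all(out == 0.0)


class TestCollagenase:
    def test_saturated_enzyme_with_no_collagen_is_steady(self, grid, params):
        bc = BoundaryConditions(M0=1e-7)
        state = make_state(grid, M=1e-7, f=0.0)
        out = step_collagenase(state, params, bc, grid, dt=1.0)
        np.testing.assert_allclose(out, 1e-7, rtol=1e-14)

    def test_inward_diffusion_is_monotone_without_binding(self):
        """Comparison principle: supplied enzyme only accumulates."""
        grid = GridSpec(R=0.1, n_r=24)
        params = ModelParameters(zeta=0.0)
        bc = BoundaryConditions(M0=1e-7)
        state = make_state(grid, M=0.0)
        state.M[-1] = bc.M0
        dt = grid.stability_bound(params)
        prev = state.M.copy()
        for i in range(2000):
            state.M = step_collagenase(state, params, bc, grid, dt)
            assert np.all(state.M >= prev - 1e-25)
            prev = state.M.copy()
        assert np.all(state.M[1:] > 0)

    def test_no_source_no_enzyme(self, grid, params):
        bc = BoundaryConditions(M0=0.0)
        state = make_state(grid, M=0.0)
        for _ in range(50):
            state.M = step_collagenase(state, params, bc, grid, dt=1.0)
        assert np.all(state.M == 0.0)


class TestCollagen:
    def test_no_enzyme_no_degradation(self, grid, params):
        state = make_state(grid, M=0.0, f=1e-9)
        out = step_collagen(state, params, dt=100.0)
        np.testing.assert_array_equal(out, state.f)

    def test_constant_enzyme_matches_closed_form(self, grid, params):
        M = 1.8e-7
        f0 = 1e-9
        dt = 50.0
        k = 400
        state = make_state(grid, M=M, f=f0)
        for _ in range(k):
            state.f = step_collagen(state, params, dt)
        expected = f0 * np.exp(-params.delta * M * k * dt)
        np.testing.assert_allclose(state.f, expected, rtol=1e-12)

    def test_degradation_keeps_collagen_positive_below_f0(self, grid, params):
        state = make_state(grid, M=1e-6, f=1e-9)
        out = step_collagen(state, params, dt=1e4)
        assert np.all(out > 0.0)
        assert np.all(out < 1e-9)


class TestCells:
    def test_mass_conserved_with_no_reactions_and_no_flux_bc(self):
        grid = GridSpec(R=0.2, n_r=48)
        params = ModelParameters(eta_max=0.0, lambda_max=0.0)
        bc = BoundaryConditions(cell_bc="noflux")
        state = make_state(grid, n=4.5)
        r = np.arange(grid.n_r) * grid.dr
        state.Cp = np.exp(-(r / 0.05) ** 2) * 100.0
        m0 = cell_mass(state.Cp, grid)
        dt = grid.stability_bound(params)
        for _ in range(1000):
            fx = compute_cell_fluxes(state, params, grid)
            state.Cp = step_cells(state, fx, params, bc, grid, dt)
        m1 = cell_mass(state.Cp, grid)
        assert abs(m1 - m0) / m0 < 1e-3

    def test_no_nutrient_no_proliferation(self, grid, params):
        bc = BoundaryConditions(cell_bc="noflux")
        state = make_state(grid, Cp=10.0, n=0.0)
        fx = compute_cell_fluxes(state, params, grid)
        out = step_cells(state, fx, params, bc, grid, dt=10.0)
        np.testing.assert_allclose(out, 10.0, rtol=1e-14)

    def test_uniform_subcritical_density_grows_at_monod_rate(self):
        grid = GridSpec(R=0.2, n_r=32)
        params = ModelParameters()
        bc = BoundaryConditions(cell_bc="noflux")
        n_level = 4.5
        state = make_state(grid, Cp=100.0, n=n_level)
        rate = params.eta_max * n_level / (params.n_half + n_level)
        dt = 30.0
        steps = 200
        for _ in range(steps):
            fx = compute_cell_fluxes(state, params, grid)
            state.Cp = step_cells(state, fx, params, bc, grid, dt)
        expected = 100.0 * np.exp(rate * dt * steps)
        # forward Euler of a scalar exponential over a short horizon
        assert state.Cp[5] == pytest.approx(expected, rel=0.01)


class TestRunContinuum:
    def test_all_rates_zero_uniform_initial_state_is_steady(self):
        grid = GridSpec(R=0.1, n_r=24, t_end=500.0)
        params = ModelParameters(eta_max=0.0, lambda_max=0.0, zeta=0.0,
                                 delta=0.0)
        bc = BoundaryConditions(n0=2.0, M0=5e-8, C_bc=7.0)
        ic = InitialConditions(C_i=7.0, n_i=2.0, f0=1e-9, r_tumoroid=0.15)
        # uniform cells require the tumoroid to fill the domain; bypass the
        # radius < R check by building the state directly
        state = make_state(grid, Cp=7.0, n=2.0, M=5e-8, f=1e-9)
        dt = grid.stability_bound(params)
        final = state.copy()
        for _ in range(200):
            final = advance(final, params, bc, grid, dt)
        for name in ("Cp", "n", "M", "f"):
            np.testing.assert_allclose(getattr(final, name),
                                       getattr(state, name), rtol=1e-12)

    def test_more_enzyme_strictly_lowers_minimum_collagen(self):
        grid = GridSpec(R=0.1, n_r=24, t_end=3 * 3600.0)
        params = ModelParameters()
        ic = InitialConditions(r_tumoroid=0.03)
        mins = []
        for m0 in (0.0, 1.8e-8, 1.8e-7):
            bc = BoundaryConditions(M0=m0)
            snaps = run_continuum(params, bc, ic, grid, n_snapshots=2)
            mins.append(snaps[-1].f.min())
        assert mins[0] > mins[1] > mins[2]

    def test_axisymmetric_run_matches_full_2d_run(self):
        params = ModelParameters()
        ic = InitialConditions(r_tumoroid=0.03)
        bc = BoundaryConditions(M0=1.8e-7)
        g1 = GridSpec(R=0.1, n_r=24, n_theta=8, t_end=200.0,
                      axisymmetric=True)
        g2 = GridSpec(R=0.1, n_r=24, n_theta=8, t_end=200.0,
                      axisymmetric=False)
        dt = g2.stability_bound(params)
        g1.dt = g2.dt = dt
        s1 = run_continuum(params, bc, ic, g1, n_snapshots=1)[-1]
        s2 = run_continuum(params, bc, ic, g2, n_snapshots=1)[-1]
        for name in ("Cp", "n", "M", "f"):
            profile_2d = getattr(s2, name)
            assert np.ptp(profile_2d, axis=1).max() == 0.0  # stays symmetric
            np.testing.assert_allclose(profile_2d[:, 0], getattr(s1, name),
                                       rtol=1e-8, atol=1e-30)

    def test_nonnegativity_and_collagen_monotonicity(self):
        grid = GridSpec(R=0.1, n_r=24, t_end=2 * 3600.0)
        params = ModelParameters()
        bc = BoundaryConditions(M0=1.8e-7)
        ic = InitialConditions(r_tumoroid=0.03)
        snaps = run_continuum(params, bc, ic, grid, n_snapshots=6)
        prev_f = None
        for s in snaps:
            for name in ("Cp", "n", "M", "f"):
                assert np.all(getattr(s, name) >= 0.0), name
            assert np.all(s.f <= ic.f0 * (1 + 1e-12))
            assert np.all(s.n <= max(ic.n_i, bc.n0) * (1 + 1e-12))
            if prev_f is not None:
                assert np.all(s.f <= prev_f * (1 + 1e-12))
            prev_f = s.f.copy()

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_divergence_is_detected_and_reported(self):
        grid = GridSpec(R=0.1, n_r=24, t_end=3600.0)
        params = ModelParameters()
        # unstable dt: bypass validation and step directly
        bad_dt = grid.stability_bound(params) * 50.0
        bc = BoundaryConditions()
        state = initial_state(InitialConditions(), grid)
        with pytest.raises(FloatingPointError):
            for _ in range(2000):
                state = advance(state, params, bc, grid, bad_dt)
                state.check_finite()


class TestAxisymStepper:
    def test_matches_generic_advance_to_rounding(self):
        grid = GridSpec(R=0.2, n_r=48)
        params = ModelParameters()
        bc = BoundaryConditions(M0=1.8e-7)
        ic = InitialConditions()
        dt = grid.stability_bound(params)
        s_fast = initial_state(ic, grid)
        s_ref = initial_state(ic, grid)
        stepper = AxisymStepper(params, bc, grid, dt)
        for _ in range(500):
            stepper.step(s_fast)
            s_ref = advance(s_ref, params, bc, grid, dt)
        for name in ("Cp", "n", "M", "f"):
            np.testing.assert_allclose(getattr(s_fast, name),
                                       getattr(s_ref, name), rtol=1e-12,
                                       atol=1e-300)

    def test_rejects_unsupported_physics(self):
        grid = GridSpec()
        params = ModelParameters(chi_chem=1.0)
        with pytest.raises(ValueError):
            AxisymStepper(params, BoundaryConditions(), grid, 0.1)
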