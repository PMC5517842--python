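"""Velocity construction, implicit stepping, boundary closures, averaging."""

import numpy as np
import pytest
from scipy.linalg import solve_banded

from melsim import baseline_parameters, SolverOptions, simulate
from melsim.model import FIELD_NAMES, IDX, N_FIELDS
from melsim._grid import GridOps
from melsim.solver import (
    RadialGrid, average_density, velocity_from_source, assemble_field_system,
    initial_state, step, _solve_fields, _kinetics, diffusion_coefficients,
)


def _banded_solve(ab, rhs):
    return solve_banded((1, 1), ab, rhs)


def _dense_from_banded(ab):
    n = ab.shape[1]
    a = np.zeros((n, n))
    for i in range(n):
        a[i, i] = ab[1, i]
        if i + 1 < n:
            a[i, i + 1] = ab[0, i + 1]
            a[i + 1, i] = ab[2, i]
    return a


class TestGrid:
    def test_uniform_constructor(self):
        g = RadialGrid.uniform(0.01, 32)
        assert g.R == 0.01 and g.nodes[0] == 0.0

    @pytest.mark.parametrize("nodes", [
        np.linspace(0.0, 1.0, 8),                  # too few
        np.linspace(0.1, 1.0, 32),                 # does not start at 0
        np.concatenate([[0.0, 0.5, 0.4], np.linspace(0.6, 1.0, 20)]),  # not increasing
    ])
    def test_invalid_grids_rejected(self, nodes):
        with pytest.raises(ValueError):
            RadialGrid(nodes)


class TestVelocity:
    def test_zero_source(self, params):
        r = np.linspace(0.0, 1.0, 101)
        assert np.all(velocity_from_source(np.zeros_like(r), r, params.theta) == 0.0)

    def test_constant_source_closed_form(self, params):
        # u(r) = s0*r/(3*theta) for S = s0
        r = np.linspace(0.0, 1.0, 201)
        s0 = 0.7
        u = velocity_from_source(np.full_like(r, s0), r, params.theta)
        assert np.allclose(u, s0 * r / (3.0 * params.theta), rtol=1e-10)

    def test_linear_source_analytic_integral(self):
        # S(r) = r on [0,1], theta = 0.6039: u(1) = 1/(4*theta) ~ 0.4139
        r = np.linspace(0.0, 1.0, 2001)
        u = velocity_from_source(r, r, 0.6039)
        assert u[-1] == pytest.approx(1.0 / (4.0 * 0.6039), rel=1e-6)
        assert u[-1] == pytest.approx(0.4139, rel=1e-3)


class TestAverageDensity:
    def test_constant_field(self):
        r = np.linspace(0.0, 0.01, 51)
        assert average_density(np.full_like(r, 3.3), r) == pytest.approx(3.3)

    def test_quadratic_field(self):
        r = np.linspace(0.0, 1.0, 2001)
        assert average_density(r ** 2, r) == pytest.approx(0.6, rel=1e-5)

    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError):
            average_density(np.zeros(3), np.array([0.0, 0.0, 0.0]))

    def test_initial_control_state_cancer_average(self, params):
        st = initial_state(params, SolverOptions(n_nodes=61))
        assert average_density(st.fields[IDX["C"]], st.r) == pytest.approx(0.3747, rel=1e-6)
        st_printed = initial_state(params, SolverOptions(n_nodes=61,
                                                         rescale_initial_c=False))
        assert average_density(st_printed.fields[IDX["C"]], st_printed.r) == \
            pytest.approx(0.3774, rel=1e-9)


class TestImplicitUpdate:
    def test_constant_field_invariant_under_diffusion(self):
        """Pure diffusion of a constant field under no-flux conditions."""
        r = np.linspace(0.0, 0.01, 61)
        x = np.full_like(r, 0.4)
        for _ in range(20):
            ab, rhs = assemble_field_system(x, r, 0.01, 1e-2, np.zeros_like(r),
                                            np.zeros_like(r), None, None)
            x = _banded_solve(ab, rhs)
        assert np.allclose(x, 0.4, rtol=1e-12)

    def test_robin_boundary_fixed_point(self, params):
        """A field already at the influx density satisfies the Robin closure."""
        r = np.linspace(0.0, 0.01, 61)
        x = np.full_like(r, params.That_1)
        ab, rhs = assemble_field_system(x, r, 0.01, params.delta_T,
                                        np.zeros_like(r), np.zeros_like(r),
                                        None, None, bc="robin",
                                        sigma_t=0.5, x_hat=params.That_1)
        x_new = _banded_solve(ab, rhs)
        assert np.allclose(x_new, params.That_1, rtol=1e-12)

    def test_robin_rate_saturates_in_il12(self, params):
        """sigma_T = sigma_0*I12/(I12+K_I12): half-max at I12 = K_I12, 0 at 0."""
        sigma = lambda i12: params.sigma_0 * i12 / (i12 + params.K_I12)
        assert sigma(params.K_I12) == pytest.approx(params.sigma_0 / 2)
        assert sigma(0.0) == 0.0

    def test_mass_conservation_under_pure_diffusion(self):
        """No reactions, u = 0: total mass 4*pi*int r^2 X dr is conserved."""
        r = np.linspace(0.0, 0.01, 101)
        x = 1.0 + 0.3 * np.cos(np.pi * r / 0.01)
        mass0 = np.trapezoid(r * r * x, r)
        for _ in range(600):  # 60 days at 0.1-day steps, cell-scale diffusivity
            ab, rhs = assemble_field_system(x, r, 0.1, 8.64e-7, np.zeros_like(r),
                                            np.zeros_like(r), None, None)
            x = _banded_solve(ab, rhs)
        mass = np.trapezoid(r * r * x, r)
        assert mass == pytest.approx(mass0, rel=1e-3)

    def test_manufactured_linear_in_time_solution(self):
        """X(r, t) = a + b*t with source F = b is reproduced exactly."""
        r = np.linspace(0.0, 0.01, 41)
        a, b, tau = 0.2, 0.05, 0.01
        x = np.full_like(r, a)
        for k in range(10):
            ab, rhs = assemble_field_system(x, r, tau, 3e-3,
                                            np.full_like(r, b), np.zeros_like(r),
                                            None, None)
            x = _banded_solve(ab, rhs)
        exact = a + b * 10 * tau
        assert np.max(np.abs(x - exact)) < 1e-6

    def test_tridiagonal_agrees_with_dense_direct_solve(self, params):
        """One implicit step equals a dense-matrix solve of the same system."""
        rng = np.random.default_rng(7)
        r = np.sort(np.concatenate([[0.0], np.cumsum(rng.uniform(0.5, 1.5, 60))]))
        r = 0.01 * r / r[-1]
        x = 0.3 + 0.1 * np.sin(40 * r) ** 2
        src = rng.uniform(0.0, 0.1, r.size)
        loss = rng.uniform(0.0, 0.5, r.size)
        u = 0.02 * r
        u_r = np.full_like(r, 0.02)
        ab, rhs = assemble_field_system(x, r, 0.01, 1e-3, src, loss, u, u_r,
                                        bc="robin", sigma_t=0.4, x_hat=0.25)
        banded = _banded_solve(ab, rhs)
        dense = np.linalg.solve(_dense_from_banded(ab), rhs)
        assert np.allclose(banded, dense, rtol=1e-12, atol=1e-15)

    def test_vectorised_sweep_matches_reference_assembly(self, params):
        """The production solver path equals the per-field reference assembly."""
        opts = SolverOptions(n_nodes=41)
        st = initial_state(params, opts)
        # perturb to exercise gradients
        st.fields[:6] *= 1.0 + 0.05 * np.sin(300 * st.r)
        ops = GridOps(st.r)
        deltas = diffusion_coefficients(params)
        src, loss, _, u = _kinetics(st.fields, st.r, params, 0.1, None, None,
                                    0.0, ops)
        fast = _solve_fields(st.fields, st.fields, ops, 0.005, deltas, src,
                             loss, u, params)
        u_r = ops.deriv(u)
        u_r[0] = u[1] / st.r[1]
        i12_b = st.fields[IDX["I12"], -1]
        sigma_t = params.sigma_0 * i12_b / (i12_b + params.K_I12)
        from melsim.model import ADVECTED_FIELDS
        for k in range(N_FIELDS):
            bc, x_hat = "neumann", 0.0
            if k == IDX["T1"]:
                bc, x_hat = "robin", params.That_1
            if k == IDX["T8"]:
                bc, x_hat = "robin", params.That_8
            adv = k in ADVECTED_FIELDS
            ab, rhs = assemble_field_system(
                st.fields[k], st.r, 0.005, deltas[k], src[k], loss[k],
                u if adv else None, u_r if adv else None, bc, sigma_t, x_hat)
            ref = _banded_solve(ab, rhs)
            assert np.allclose(fast[k], ref, rtol=1e-12, atol=1e-300), FIELD_NAMES[k]


class TestSimulate:
    def test_zero_horizon_returns_initial_state(self, params):
        res = simulate(params, t_end=0.0, options=SolverOptions(n_nodes=31))
        assert res.R[-1] == pytest.approx(0.01)
        assert res.averages["C"].iloc[0] == pytest.approx(0.3747, rel=1e-6)
        assert res.averages["M"].iloc[0] == pytest.approx(0.22, rel=1e-9)

    def test_short_run_grows_all_fields_finite(self, params, coarse_opts):
        res = simulate(params, t_end=2.0, options=coarse_opts)
        assert np.all(np.isfinite(res.final_state.fields))
        assert np.all(res.final_state.fields >= 0.0)
        assert res.metadata["clipped_mass"] < 1e-12

    def test_negative_horizon_rejected(self, params):
        with pytest.raises(ValueError):
            simulate(params, t_end=-1.0)
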