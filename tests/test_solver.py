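import dataclasses
import math

import numpy as np
import pytest

from nanobead import (
    AnalyticInput,
    ConvergenceError,
    ModelParameters,
    SolverConfig,
    bead_radius_analytic,
    boundary_residuals,
    continuation,
    equilibrium_tube_radius,
    ode_rhs,
    single_domain_profiles,
    solve_shape,
    verify_stationarity,
)


class TestOdeRhs:
    def test_cylinder_is_a_fixed_point(self, params):
        """The homogeneous equilibrium cylinder annihilates every
        mechanical derivative — the primary algebra oracle."""
        R = equilibrium_tube_radius(params.kappa, params.lambda0)
        fields = single_domain_profiles(params, sigma0=0.0)
        state = (R, 0.0, np.pi / 2, 1 / (2 * R), 0.0, params.lambda0)
        dr, dz, dpsi, dH, dflux, dlam = ode_rhs(state, 5000.0, fields, params)
        assert dr == pytest.approx(0.0, abs=1e-12)
        assert dz == pytest.approx(1.0)
        assert dpsi == pytest.approx(0.0, abs=1e-12)
        assert dH == pytest.approx(0.0, abs=1e-15)
        assert dflux == pytest.approx(0.0, abs=1e-12)
        assert dlam == pytest.approx(0.0, abs=1e-15)

    def test_uniform_gaussian_modulus_drops_out(self, params):
        fields_a = single_domain_profiles(params, sigma0=1e-4, kappaG_lipid=-288.0)
        fields_b = single_domain_profiles(params, sigma0=1e-4, kappaG_lipid=+500.0)
        state = (40.0, 0.0, 1.4, 0.01, 0.5, 0.05)
        a = ode_rhs(state, 6500.0, fields_a, params)
        b = ode_rhs(state, 6500.0, fields_b, params)
        assert np.allclose(a, b)

    def test_constant_composition_gives_uniform_tension(self, params):
        fields = single_domain_profiles(params, sigma0=1e-4, uniform_sigma=True)
        state = (40.0, 0.0, 1.4, 0.01, 0.5, 0.05)
        *_, dlam = ode_rhs(state, 6500.0, fields, params)
        assert dlam == pytest.approx(0.0, abs=1e-15)

    def test_pinchoff_rejected(self, params):
        fields = single_domain_profiles(params, sigma0=0.0)
        with pytest.raises(ValueError, match="pinch"):
            ode_rhs((0.0, 0.0, 1.0, 0.01, 0.0, 0.05), 100.0, fields, params)


class TestBoundaryResiduals:
    def setup_method(self):
        self.p = ModelParameters()
        R, lam = self.p.Rc, self.p.lambda0
        self.edge = (R, 0.0, np.pi / 2, 1 / (2 * R), 0.0, lam)

    def test_cylinder_satisfies_all_conditions(self):
        res = boundary_residuals(self.edge, self.edge, self.p)
        assert np.allclose(res, 0.0)

    def test_perturbed_radius_only_moves_first_residual(self):
        left = (self.p.Rc + 1.0, *self.edge[1:])
        res = boundary_residuals(left, self.edge, self.p)
        assert res[0] == pytest.approx(1.0)
        assert np.allclose(res[1:], 0.0)

    def test_tension_mismatch_isolated(self):
        right = (*self.edge[:5], self.p.lambda0 + 0.01)
        res = boundary_residuals(self.edge, right, self.p)
        assert res[5] == pytest.approx(0.01)
        assert np.allclose(res[:5], 0.0)

    def test_half_domain_mode(self):
        res = boundary_residuals(self.edge, self.edge, self.p, mode="half")
        assert np.allclose(res, 0.0)
        with pytest.raises(ValueError):
            boundary_residuals(self.edge, self.edge, self.p, mode="bogus")


class TestHomogeneousOracle:
    @pytest.mark.parametrize("lam", np.linspace(0.004, 0.064, 5).tolist())
    def test_solver_reproduces_closed_form_radius(self, params, lam):
        pp = params.replace(lambda0=float(lam))
        sh = solve_shape(single_domain_profiles(pp, sigma0=0.0), pp)
        R = equilibrium_tube_radius(params.kappa, float(lam))
        mid = np.argmin(np.abs(sh.s - params.Lc / 2))
        assert abs(sh.r[mid] - R) / R < 0.005

    def test_uniform_state_fields(self, homogeneous_shape, params):
        mid = len(homogeneous_shape.s) // 2
        R = equilibrium_tube_radius(params.kappa, params.lambda0)
        assert homogeneous_shape.H[mid] == pytest.approx(1 / (2 * R), rel=1e-8)
        assert homogeneous_shape.lam[mid] == pytest.approx(params.lambda0, rel=1e-8)
        assert homogeneous_shape.psi[mid] == pytest.approx(np.pi / 2, abs=1e-8)


class TestShapeInvariants:
    def test_geometric_compatibility(self, protein_bead):
        """dr/ds = cos psi, dz/ds = sin psi, 2H = psi' + sin(psi)/r on
        the collocation mesh."""
        x = protein_bead._x
        interior = x[(x > x[0]) & (x < x[-1])]
        deriv = protein_bead._sol.derivative()(interior)
        y = protein_bead._sol(interior)
        assert np.max(np.abs(deriv[0] - np.cos(y[2]))) < 1e-6
        assert np.max(np.abs(deriv[1] - np.sin(y[2]))) < 1e-6
        assert np.max(np.abs(2 * y[3] - (deriv[2] + np.sin(y[2]) / y[0]))) < 1e-6

    def test_radius_stays_positive(self, protein_bead):
        assert np.all(protein_bead.r > 0)

    def test_mirror_symmetry_full_domain(self, params):
        cfg = SolverConfig(symmetry_mode="full")
        fields = single_domain_profiles(params, sigma0=1e-5)
        pre = solve_shape(single_domain_profiles(params, sigma0=0.0), params, config=cfg)
        sh = solve_shape(fields, params, guess=pre, config=cfg)
        dense = sh.resample(2001)
        assert np.max(np.abs(dense.r - dense.r[::-1])) < 1e-3 * params.Rc

    def test_half_and_full_domain_agree(self, params):
        cfg_full = SolverConfig(symmetry_mode="full")
        pre = solve_shape(single_domain_profiles(params, sigma0=0.0), params, config=cfg_full)
        full = solve_shape(single_domain_profiles(params, sigma0=1e-5), params,
                           guess=pre, config=cfg_full)
        half = continuation(
            [0.0, 1e-5],
            lambda v: single_domain_profiles(params, sigma0=float(v)),
            params,
            config=SolverConfig(symmetry_mode="half"),
        ).shapes[-1]
        assert full.r_max == pytest.approx(half.r_max, rel=1e-3)

    def test_tension_field_consistent_with_line_integral(self, protein_bead, params):
        """Λ(s) from the ODE equals λ₀ plus the a-posteriori integral of
        the tangential balance computed from the solved shape."""
        from scipy.integrate import cumulative_trapezoid

        dense = protein_bead.resample(4001)
        fields = protein_bead.fields
        m = dense.m
        stretch = dense.r / params.Rc
        C = params.mu * params.phi * fields.sigma_fn(m)
        dC = params.mu * params.phi * fields.sigma_fn(m, 1) * stretch
        dkap = fields.kappa_fn(m, 1) * stretch
        dkG = fields.kappaG_fn(m, 1) * stretch
        kap = fields.kappa_fn(m)
        Hc = dense.H - C
        dlam = 2 * kap * Hc * dC - dkap * Hc**2 - dkG * dense.K
        # integrate the tangential balance inward from the edge:
        # lam(s) = lam(S) + \int_S^s dlam ds'
        lam_rec = dense.lam[-1] + (
            cumulative_trapezoid(dlam[::-1], dense.s[::-1], initial=0.0)[::-1]
        )
        assert np.max(np.abs(lam_rec - dense.lam)) < 1e-3 * params.lambda0


class TestBeadSolutions:
    def test_small_density_matches_cylindrical_bead_formula(self, params):
        branch = continuation(
            np.linspace(0.0, 2e-5, 9),
            lambda v: single_domain_profiles(params, sigma0=float(v)),
            params,
        )
        for sigma in (1e-5, 2e-5):
            i = branch.values.index(pytest.approx(sigma))
            rb = branch.shapes[i].r_max
            an = bead_radius_analytic(AnalyticInput(sigma=sigma, params=params))
            assert abs(rb - an) / an < 0.10

    def test_bead_radius_monotone_in_density(self, protein_branch):
        assert np.all(np.diff(protein_branch.r_b) > 0)

    def test_bead_radius_monotone_in_rigidity(self, rigidity_branch):
        assert np.all(np.diff(rigidity_branch.r_b) > 0)

    def test_local_tension_drop_grows_with_bead(self, protein_branch):
        min_lam = np.array([float(np.min(sh.lam)) for sh in protein_branch.shapes])
        assert np.all(np.diff(min_lam)[1:] < 0)

    def test_mesh_convergence_of_bead_radius(self, params, protein_branch):
        fine = continuation(
            np.linspace(0.0, 2e-5, 9),
            lambda v: single_domain_profiles(params, sigma0=float(v)),
            params,
            config=SolverConfig(mesh_size=1201),
        )
        coarse = continuation(
            np.linspace(0.0, 2e-5, 9),
            lambda v: single_domain_profiles(params, sigma0=float(v)),
            params,
            config=SolverConfig(mesh_size=601),
        )
        assert fine.shapes[-1].r_max == pytest.approx(coarse.shapes[-1].r_max, rel=2e-3)


class TestStationarity:
    def test_cylinder(self, homogeneous_shape):
        assert verify_stationarity(homogeneous_shape) < 1e-4

    def test_protein_bead(self, protein_bead):
        assert verify_stationarity(protein_bead) < 1e-4

    def test_heterogeneous_gaussian_modulus(self, params):
        branch = continuation(
            np.linspace(0.0, 1e-4, 9),
            lambda v: single_domain_profiles(params, sigma0=float(v), delta_kappaG=5.0),
            params,
        )
        assert verify_stationarity(branch.shapes[-1]) < 1e-4

    def test_detects_non_equilibrium(self, protein_bead):
        """Test of the test: a perturbed shape must score far above an
        equilibrium."""
        dense = protein_bead.resample(4001)
        bump = 10.0 * np.exp(-((dense.s - 9000.0) ** 2) / (2 * 400.0**2))
        bad = dataclasses.replace(dense, r=dense.r + bump, _sol=None)
        assert verify_stationarity(bad) > 10 * verify_stationarity(protein_bead)


class TestContinuation:
    def test_trivial_sweep(self, params, homogeneous_shape):
        branch = continuation(
            [0.0],
            lambda v: single_domain_profiles(params, sigma0=float(v)),
            params,
        )
        assert len(branch.shapes) == 1
        assert branch.shapes[0].r_max == pytest.approx(homogeneous_shape.r_max, rel=1e-6)

    def test_direction_recorded(self, params):
        br = continuation(
            [1e-5, 5e-6, 0.0],
            lambda v: single_domain_profiles(params, sigma0=float(v)),
            params,
            guess=None,
        )
        assert br.direction == "backward"

    def test_branch_truncates_with_diagnostic_on_hard_failure(self, params):
        # an unreachable state: huge density jump in one step with no
        # halving allowed
        cfg = SolverConfig(step_halving_limit=0, max_nodes=2000)
        br = continuation(
            [0.0, 3.5e-4],
            lambda v: single_domain_profiles(params, sigma0=float(v)),
            params,
            config=cfg,
        )
        assert br.values == [0.0]
        assert 3.5e-4 in br.failures

    def test_solver_config_validation(self):
        with pytest.raises(ValueError):
            SolverConfig(mesh_size=100)
        with pytest.raises(ValueError):
            SolverConfig(tolerance=1e-4)
        with pytest.raises(ValueError):
            SolverConfig(symmetry_mode="diagonal")
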