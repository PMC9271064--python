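"""Coupled reaction-diffusion-elasticity solver correctness."""

import numpy as np
import pytest

from prolifmap.forward_model import (
    FemOperators,
    ModelParams,
    damped_diffusion,
    logistic_flow,
    run_forward,
    von_mises_plane_strain,
)


def logistic_exact(n0, k, t):
    a = np.exp(k * t)
    return n0 * a / (1.0 + n0 * (a - 1.0))


class TestVonMises:
    def test_zero_stress(self):
        assert von_mises_plane_strain(0.0, 0.0, 0.0, 0.45) == 0.0

    def test_uniaxial_with_plane_strain_sigma_zz(self):
        # sigma_zz = nu * sxx = 0.45 -> svm = sqrt(0.5*(0.55^2+0.45^2+1)+0)
        svm = von_mises_plane_strain(1.0, 0.0, 0.0, 0.45)
        assert svm == pytest.approx(np.sqrt(0.7525), rel=1e-12)

    def test_pure_shear(self):
        s = 0.37
        assert von_mises_plane_strain(0.0, 0.0, s, 0.45) == pytest.approx(
            s * np.sqrt(3.0), rel=1e-12
        )

    def test_nonnegative_on_random_states(self):
        rng = np.random.default_rng(0)
        sxx, syy, sxy = rng.normal(size=(3, 100))
        assert np.all(von_mises_plane_strain(sxx, syy, sxy, 0.45) >= 0)


class TestDampedDiffusion:
    def test_no_coupling(self):
        assert np.allclose(damped_diffusion(1e-2, 0.0, np.ones(5)), 1e-2)

    def test_half_decay_at_ln2_over_gamma(self):
        gamma = 1.7
        D = damped_diffusion(1e-2, gamma, np.log(2.0) / gamma)
        assert D == pytest.approx(5e-3, rel=1e-12)

    def test_monotone_decay_to_zero(self):
        svm = np.linspace(0, 50, 20)
        D = damped_diffusion(1e-2, 1.0, svm)
        assert np.all(np.diff(D) < 0) and D[-1] < 1e-12 and np.all(D > 0)


class TestElasticity:
    def test_uniform_cell_field_no_force(self, phantom_mesh, coupled_params):
        ops = FemOperators(phantom_mesh, coupled_params)
        mech = ops.solve_elasticity(np.full(phantom_mesh.n_nodes, 0.4))
        assert np.abs(mech.displacement).max() == 0.0
        assert np.abs(mech.von_mises).max() == 0.0

    def test_lambda_zero_decouples(self, phantom_mesh, n0_nodal):
        params = ModelParams(lam=0.0, theta=1.0)
        ops = FemOperators(phantom_mesh, params)
        mech = ops.solve_elasticity(n0_nodal)
        assert np.abs(mech.displacement).max() == 0.0

    def test_boundary_nodes_fixed(self, phantom_mesh, n0_nodal, coupled_params):
        ops = FemOperators(phantom_mesh, coupled_params)
        mech = ops.solve_elasticity(n0_nodal)
        assert np.abs(mech.displacement[phantom_mesh.boundary_nodes]).max() == 0.0
        assert np.abs(mech.displacement).max() > 0.0  # blob does push

    def test_radial_blob_symmetric_displacement(self):
        # square domain, centered radial blob: displacement must mirror in x
        from prolifmap.mesh import build_mesh

        mask = np.zeros((33, 33), bool)
        mask[2:31, 2:31] = True
        mesh = build_mesh(mask, (1.0, 1.0), 1.5)
        params = ModelParams(gamma=1.0, lam=1.0, theta=1.0)
        ops = FemOperators(mesh, params)
        c = (mesh.nodes.min(0) + mesh.nodes.max(0)) / 2
        r2 = np.sum((mesh.nodes - c) ** 2, axis=1)
        n = np.exp(-r2 / 20.0)
        mech = ops.solve_elasticity(n)
        # mirror each node across the vertical midline and compare u_x
        mirrored = mesh.nodes.copy()
        mirrored[:, 0] = 2 * c[0] - mirrored[:, 0]
        from scipy.interpolate import LinearNDInterpolator

        ux = LinearNDInterpolator(mesh.nodes, mech.displacement[:, 0])
        ux_m = ux(mirrored)
        ok = np.isfinite(ux_m)
        scale = np.abs(mech.displacement[:, 0]).max()
        assert np.abs(mech.displacement[ok, 0] + ux_m[ok]).max() < 0.05 * scale


class TestStep:
    def test_identity_without_dynamics(self, ops_decoupled, n0_nodal):
        from prolifmap.forward_model import step

        zero_D = np.zeros(ops_decoupled.mesh.n_triangles)
        n1, _ = step(n0_nodal, np.zeros_like(n0_nodal), zero_D, ops_decoupled)
        assert np.allclose(n1, n0_nodal, atol=1e-13)

    def test_diffusion_conserves_total_cell_number(self, phantom_mesh, n0_nodal):
        params = ModelParams(D0=1e-2, gamma=0.0, lam=0.0, theta=1.0)
        ops = FemOperators(phantom_mesh, params)
        series = run_forward(
            n0_nodal, 0.0, params, 29.0, ops=ops, input_is_fraction=True
        )
        tot0 = ops.lumped_mass @ series.n_frac[0]
        tot1 = ops.lumped_mass @ series.n_frac[-1]
        assert abs(tot1 - tot0) / tot0 < 1e-8

    def test_logistic_closed_form_growth(self, phantom_mesh):
        # D = 0: every node follows the logistic ODE exactly
        params = ModelParams(D0=0.0, gamma=0.0, lam=0.0, theta=1.0)
        n0 = np.full(phantom_mesh.n_nodes, 0.5)
        series = run_forward(
            n0, 0.1, params, 29.0, mesh=phantom_mesh, input_is_fraction=True
        )
        exact = logistic_exact(0.5, 0.1, 29.0)
        rel = np.abs(series.n_frac[-1] - exact) / exact
        assert rel.max() < 0.01

    def test_logistic_flow_is_exact_decay(self):
        n = np.linspace(0.05, 0.95, 9)
        out = logistic_flow(n, np.full_like(n, -0.1), 29.0)
        assert np.allclose(out, logistic_exact(n, -0.1, 29.0), rtol=1e-14)


class TestRunForward:
    def test_gamma_zero_matches_pure_reaction_diffusion(self, phantom_mesh, n0_nodal):
        k = -0.05
        pa = ModelParams(D0=1e-2, gamma=0.0, lam=1.0, theta=1.0)
        pb = ModelParams(D0=1e-2, gamma=0.0, lam=0.0, theta=1.0)
        sa = run_forward(n0_nodal, k, pa, 10.0, mesh=phantom_mesh, input_is_fraction=True)
        sb = run_forward(n0_nodal, k, pb, 10.0, mesh=phantom_mesh, input_is_fraction=True)
        assert np.allclose(sa.n_frac[-1], sb.n_frac[-1], atol=1e-13)

    def test_negative_k_total_count_non_increasing(self, phantom_mesh, n0_nodal):
        params = ModelParams(D0=5e-3, gamma=1.0, lam=1.0, theta=1.0)
        ops = FemOperators(phantom_mesh, params)
        series = run_forward(
            n0_nodal, -0.08, params, 20.0, ops=ops,
            record_days=np.arange(0, 21, 5.0), input_is_fraction=True,
        )
        totals = [ops.lumped_mass @ n for n in series.n_frac]
        assert np.all(np.diff(totals) < 0)
        # cross-check the 20-day decay against a dt = 0.1 reference run
        fine = ModelParams(D0=5e-3, gamma=1.0, lam=1.0, theta=1.0, dt=0.1)
        sf = run_forward(n0_nodal, -0.08, fine, 20.0, mesh=phantom_mesh,
                         input_is_fraction=True)
        ref = FemOperators(phantom_mesh, fine).lumped_mass @ sf.n_frac[-1]
        assert totals[-1] == pytest.approx(ref, rel=0.01)

    def test_t_end_zero_returns_initial_state(self, phantom_mesh, n0_nodal, decoupled_params):
        series = run_forward(
            n0_nodal, 0.0, decoupled_params, 0.0, mesh=phantom_mesh, input_is_fraction=True
        )
        assert len(series.n_frac) == 1
        assert np.array_equal(series.n_frac[0], n0_nodal)

    def test_fractional_t_end_rejected(self, phantom_mesh, n0_nodal, decoupled_params):
        with pytest.raises(ValueError, match="multiple"):
            run_forward(n0_nodal, 0.0, decoupled_params, 5.5, mesh=phantom_mesh,
                        input_is_fraction=True)

    def test_bounds_preserved(self, phantom_mesh, n0_nodal):
        params = ModelParams(D0=2e-2, gamma=1.0, lam=1.0, theta=1.0)
        series = run_forward(
            n0_nodal, 0.5, params, 29.0, mesh=phantom_mesh,
            record_days=np.arange(30.0), input_is_fraction=True,
        )
        for n in series.n_frac:
            assert n.min() >= 0.0 and n.max() <= 1.0 + 1e-9

    def test_temporal_convergence(self, phantom_mesh, n0_nodal):
        p1 = ModelParams(D0=5e-3, gamma=1.0, lam=1.0, theta=1.0, dt=1.0)
        p2 = ModelParams(D0=5e-3, gamma=1.0, lam=1.0, theta=1.0, dt=0.5)
        s1 = run_forward(n0_nodal, -0.08, p1, 29.0, mesh=phantom_mesh, input_is_fraction=True)
        s2 = run_forward(n0_nodal, -0.08, p2, 29.0, mesh=phantom_mesh, input_is_fraction=True)
        a, b = s1.n_frac[-1], s2.n_frac[-1]
        assert np.linalg.norm(a - b) / np.linalg.norm(b) < 0.01

    def test_stress_damping_only_slows_spread(self, phantom_mesh, n0_nodal):
        # same reaction, gamma > 0 must keep more mass in the initial core
        core = n0_nodal > 0.5
        pg0 = ModelParams(D0=2e-2, gamma=0.0, lam=1.0, theta=1.0)
        pg1 = ModelParams(D0=2e-2, gamma=5.0, lam=1.0, theta=1.0)
        ops = FemOperators(phantom_mesh, pg0)
        s0 = run_forward(n0_nodal, 0.0, pg0, 20.0, mesh=phantom_mesh, input_is_fraction=True)
        s1 = run_forward(n0_nodal, 0.0, pg1, 20.0, mesh=phantom_mesh, input_is_fraction=True)
        out0 = ops.lumped_mass[~core] @ s0.n_frac[-1][~core]
        out1 = ops.lumped_mass[~core] @ s1.n_frac[-1][~core]
        assert out1 <= out0


class TestSpatialConvergence:
    def test_halved_edge_changes_solution_under_2pct(self):
        from prolifmap.mesh import build_mesh, nodal_to_raster, raster_to_nodal

        mask = np.zeros((33, 33), bool)
        mask[2:31, 2:31] = True
        yy, xx = np.mgrid[0:33, 0:33].astype(float)
        # wide Gaussian: feature scale >> edge length, so P1 error is small
        n_img = 0.8 * np.exp(-((xx - 16) ** 2 + (yy - 16) ** 2) / 72.0)
        params = ModelParams(D0=1e-2, gamma=0.0, lam=0.0, theta=1.0)
        fields = {}
        for edge in (1.5, 0.75):
            m = build_mesh(mask, (1.0, 1.0), edge)
            n0 = np.clip(raster_to_nodal(n_img, m, (1, 1)), 0, 1)
            s = run_forward(n0, -0.05, params, 29.0, mesh=m, input_is_fraction=True)
            fields[edge] = nodal_to_raster(s.n_frac[-1], m, (33, 33), (1, 1), np.nan)
        both = np.isfinite(fields[1.5]) & np.isfinite(fields[0.75])
        diff = np.linalg.norm((fields[1.5] - fields[0.75])[both])
        ref = np.linalg.norm(fields[0.75][both])
        assert diff / ref < 0.02
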