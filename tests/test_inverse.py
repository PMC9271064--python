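"""Misfit, adjoint/finite-difference gradients, and parameter recovery."""

import numpy as np
import pytest

from prolifmap.forward_model import ModelParams
from prolifmap.inverse import (
    ObservationPair,
    adjoint_gradient_k,
    estimate,
    fd_gradient_D0,
    misfit,
)

from conftest import D0_TRUE, K_TRUE_8


def central_fd_gradient(k, D0, pair, mesh, params, part, h=1e-6):
    g = np.zeros(part.n_regions)
    for r in range(part.n_regions):
        kp, km = k.copy(), k.copy()
        kp[r] += h
        km[r] -= h
        g[r] = (
            misfit(kp, D0, pair, mesh, params, part)
            - misfit(km, D0, pair, mesh, params, part)
        ) / (2 * h)
    return g


class TestMisfit:
    def test_zero_at_generating_parameters(
        self, pair_decoupled, phantom_mesh, partition8, decoupled_params
    ):
        J = misfit(K_TRUE_8, D0_TRUE, pair_decoupled, phantom_mesh,
                   decoupled_params, partition8)
        assert J < 1e-12

    def test_zero_for_static_data_at_zero_parameters(
        self, phantom_mesh, partition8, n0_nodal, decoupled_params
    ):
        pair = ObservationPair("T01", n0_nodal, n0_nodal.copy(), 29.0,
                               phantom_mesh.node_in_roi)
        params = ModelParams(D0=0.0, gamma=0.0, lam=0.0, theta=1.0)
        assert misfit(np.zeros(8), 0.0, pair, phantom_mesh, params, partition8) < 1e-12

    def test_locally_quadratic_near_optimum(
        self, pair_decoupled, phantom_mesh, partition8, decoupled_params
    ):
        deltas = np.array([-0.008, -0.004, 0.004, 0.008])
        js = []
        for d in deltas:
            k = K_TRUE_8.copy()
            k[3] += d
            js.append(misfit(k, D0_TRUE, pair_decoupled, phantom_mesh,
                             decoupled_params, partition8))
        coeff = np.polyfit(deltas, js, 2)
        fit_resid = np.abs(np.polyval(coeff, deltas) - js).max()
        assert coeff[0] > 0 and fit_resid < 0.02 * max(js)


class TestAdjointGradient:
    def test_matches_central_differences_decoupled(
        self, pair_decoupled, phantom_mesh, partition8, decoupled_params
    ):
        k = K_TRUE_8 + 0.03
        g_adj, _ = adjoint_gradient_k(k, D0_TRUE, pair_decoupled, phantom_mesh,
                                      decoupled_params, partition8)
        g_fd = central_fd_gradient(k, D0_TRUE, pair_decoupled, phantom_mesh,
                                   decoupled_params, partition8)
        rel = np.abs(g_adj - g_fd) / np.abs(g_fd)
        assert rel.max() < 1e-5

    def test_stationary_at_exact_fit(
        self, pair_decoupled, phantom_mesh, partition8, decoupled_params
    ):
        g, J = adjoint_gradient_k(K_TRUE_8, D0_TRUE, pair_decoupled, phantom_mesh,
                                  decoupled_params, partition8)
        assert J < 1e-12 and np.abs(g).max() < 1e-10

    def test_linear_in_residual(
        self, pair_decoupled, phantom_mesh, partition8, decoupled_params
    ):
        # doubling the data residual doubles every gradient component
        from prolifmap.inverse import _forward, _as_ops

        ops = _as_ops(phantom_mesh, decoupled_params)
        k = K_TRUE_8 + 0.05
        series = _forward(k, D0_TRUE, pair_decoupled, ops, partition8)
        n_model = series.n_frac[-1]
        doubled = ObservationPair(
            "T01",
            pair_decoupled.n_start,
            n_model - 2.0 * (n_model - pair_decoupled.n_end),
            pair_decoupled.interval_days,
            pair_decoupled.roi_nodes,
        )
        g1, _ = adjoint_gradient_k(k, D0_TRUE, pair_decoupled, phantom_mesh,
                                   decoupled_params, partition8)
        g2, _ = adjoint_gradient_k(k, D0_TRUE, doubled, phantom_mesh,
                                   decoupled_params, partition8)
        assert np.allclose(g2, 2.0 * g1, rtol=1e-9)

    def test_coupled_approximation_within_5pct(
        self, pair_coupled, phantom_mesh, partition8, coupled_params
    ):
        # frozen-D backward pass: bounded error once mechanics feeds back
        k = K_TRUE_8 + 0.03
        g_adj, _ = adjoint_gradient_k(k, D0_TRUE, pair_coupled, phantom_mesh,
                                      coupled_params, partition8)
        g_fd = central_fd_gradient(k, D0_TRUE, pair_coupled, phantom_mesh,
                                   coupled_params, partition8)
        rel = np.abs(g_adj - g_fd) / np.abs(g_fd)
        assert rel.max() < 0.05


class TestFdGradientD0:
    def test_zero_for_diffusion_insensitive_data(
        self, phantom_mesh, partition8, decoupled_params
    ):
        # spatially uniform field: diffusion does nothing at any D0
        n = np.full(phantom_mesh.n_nodes, 0.3)
        pair = ObservationPair("T01", n, n.copy(), 29.0, phantom_mesh.node_in_roi)
        g = fd_gradient_D0(np.zeros(8), D0_TRUE, pair, phantom_mesh,
                           decoupled_params, partition8)
        assert abs(g) < 1e-8

    def test_positive_when_data_has_no_spread(
        self, phantom_mesh, partition8, n0_nodal, decoupled_params
    ):
        pair = ObservationPair("T01", n0_nodal, n0_nodal.copy(), 29.0,
                               phantom_mesh.node_in_roi)
        g = fd_gradient_D0(np.zeros(8), 1e-2, pair, phantom_mesh,
                           decoupled_params, partition8)
        assert g > 0

    def test_matches_local_slope(
        self, pair_decoupled, phantom_mesh, partition8, decoupled_params
    ):
        k = K_TRUE_8 + 0.02
        D0 = 8e-3
        g = fd_gradient_D0(k, D0, pair_decoupled, phantom_mesh,
                           decoupled_params, partition8)
        h = 0.01 * D0
        j0 = misfit(k, D0, pair_decoupled, phantom_mesh, decoupled_params, partition8)
        j1 = misfit(k, D0 + h, pair_decoupled, phantom_mesh, decoupled_params, partition8)
        assert g == pytest.approx((j1 - j0) / h, rel=1e-12)

    def test_zero_D0_uses_absolute_fallback(
        self, pair_decoupled, phantom_mesh, partition8, decoupled_params
    ):
        g = fd_gradient_D0(K_TRUE_8, 0.0, pair_decoupled, phantom_mesh,
                           decoupled_params, partition8)
        assert np.isfinite(g)


class TestEstimate:
    def test_recovers_known_parameters(
        self, pair_decoupled, phantom_mesh, partition8, decoupled_params
    ):
        fit = estimate(pair_decoupled, phantom_mesh, partition8, decoupled_params)
        assert np.corrcoef(fit.k_regions, K_TRUE_8)[0, 1] > 0.95
        assert np.abs(fit.k_regions - K_TRUE_8).max() < 0.02

    def test_static_pair_yields_zero_rates(
        self, phantom_mesh, partition8, n0_nodal, decoupled_params
    ):
        pair = ObservationPair("T01", n0_nodal, n0_nodal.copy(), 29.0,
                               phantom_mesh.node_in_roi)
        fit = estimate(pair, phantom_mesh, partition8, decoupled_params)
        assert np.abs(fit.k_regions).max() < 1e-3

    def test_uniform_decay_recovered_everywhere(
        self, phantom_mesh, partition8, n0_nodal
    ):
        from prolifmap.forward_model import logistic_flow

        params = ModelParams(D0=0.0, gamma=0.0, lam=0.0, theta=1.0)
        n_end = logistic_flow(n0_nodal, np.full_like(n0_nodal, -0.05), 29.0)
        pair = ObservationPair("T01", n0_nodal, n_end, 29.0, phantom_mesh.node_in_roi)
        fit = estimate(pair, phantom_mesh, partition8, params,
                       init=(np.zeros(8), 0.0), bounds=((-1.0, 1.0), (0.0, 0.0)))
        assert np.abs(fit.k_regions + 0.05).max() < 0.005

    def test_objective_trace_non_increasing(
        self, pair_decoupled, phantom_mesh, partition8, decoupled_params
    ):
        fit = estimate(pair_decoupled, phantom_mesh, partition8, decoupled_params)
        assert np.all(np.diff(fit.objective_trace) <= 1e-12)

    def test_invariant_to_region_relabeling(
        self, pair_decoupled, phantom_mesh, partition8, decoupled_params
    ):
        from dataclasses import replace

        perm = np.array([3, 1, 4, 0, 7, 5, 2, 6])
        inv = np.argsort(perm)
        shuffled = replace(
            partition8,
            region_of_element=inv[partition8.region_of_element],
            region_areas=partition8.region_areas[perm],
        )
        f1 = estimate(pair_decoupled, phantom_mesh, partition8, decoupled_params)
        f2 = estimate(pair_decoupled, phantom_mesh, shuffled, decoupled_params)
        # equal up to the optimizer's own convergence tolerance
        assert np.allclose(f2.k_regions[inv], f1.k_regions, atol=1e-3)

    def test_init_outside_bounds_rejected(
        self, pair_decoupled, phantom_mesh, partition8, decoupled_params
    ):
        with pytest.raises(ValueError, match="bounds"):
            estimate(pair_decoupled, phantom_mesh, partition8, decoupled_params,
                     init=(np.full(8, 2.0), 1e-2))
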