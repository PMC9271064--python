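"""Regional proliferation-rate and global diffusion estimation.

For each pair of observed time points the model is run forward from the
first cellularity map and the misfit to the second map is minimized over a
piecewise-constant regional proliferation field k (day^-1, signed: negative
means net cell death under therapy) and the global stress-free diffusion
D0 (mm^2/day).

The gradient with respect to the regional k values is computed with the
discrete adjoint of the operator-split scheme — one backward sweep through
the stored forward trajectory, independent of the number of regions.  The
per-step diffusion field is held fixed in the backward pass: the sensitivity
of the mechanics (D depending on N through the von Mises stress) is
neglected, which is exact when the coupling is off (gamma = 0) and a small,
test-bounded approximation otherwise.  The D0 gradient uses a forward finite
difference with a 1% relative perturbation.  Optimization is bound-
constrained quasi-Newton (L-BFGS-B).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .forward_model import FemOperators, ModelParams, run_forward
from .mesh import RegionPartition, TriMesh


@dataclass
class ObservationPair:
    """Two co-registered nodal cellularity observations on one mesh.

    ``n_start``/``n_end`` are cell fractions (N/theta) per node;
    ``roi_nodes`` marks the nodes entering the misfit (union of the start
    and end tumor extents, so residual predicted mass outside a shrinking
    tumor is penalized).
    """

    pair_label: str
    n_start: np.ndarray
    n_end: np.ndarray
    interval_days: float
    roi_nodes: np.ndarray

    def __post_init__(self):
        if self.interval_days <= 0:
            raise ValueError("interval_days must be > 0")
        if self.n_start.shape != self.n_end.shape:
            raise ValueError("start/end maps must share the mesh")


@dataclass
class ProliferationFit:
    k_regions: np.ndarray  # day^-1 per region
    D0_hat: float  # mm^2/day
    objective_trace: np.ndarray
    converged: bool
    n_iterations: int
    pair_label: str = ""


def k_elem_from_regions(
    k_regions: np.ndarray, partition: RegionPartition, n_triangles: int
) -> np.ndarray:
    """Expand regional rates to a per-element field (0 outside the tumor)."""
    k_elem = np.zeros(n_triangles)
    k_elem[partition.element_ids] = np.asarray(k_regions, float)[
        partition.region_of_element
    ]
    return k_elem


def _forward(k_regions, D0, pair, ops, partition, store=False):
    params = ops.params
    p = ModelParams(
        D0=float(D0),
        gamma=params.gamma,
        lam=params.lam,
        E=params.E,
        nu=params.nu,
        theta=params.theta,
        dt=params.dt,
    )
    if params.gamma != 0.0 and params.lam != 0.0 and ops._elasticity_lu is None:
        ops._assemble_elasticity()  # share the factorization across D0 values
    ops_local = FemOperators.__new__(FemOperators)
    ops_local.__dict__ = dict(ops.__dict__)
    ops_local.params = p
    k_elem = k_elem_from_regions(k_regions, partition, ops.mesh.n_triangles)
    return run_forward(
        pair.n_start,
        k_elem,
        p,
        pair.interval_days,
        ops=ops_local,
        store_trajectory=store,
        input_is_fraction=True,
    )


def misfit(
    k_regions,
    D0: float,
    pair: ObservationPair,
    mesh_or_ops,
    params: ModelParams,
    partition: RegionPartition,
) -> float:
    """Sum-of-squares data misfit 0.5 * sum_{roi nodes} (n_model - n_obs)^2."""
    ops = _as_ops(mesh_or_ops, params)
    series = _forward(k_regions, D0, pair, ops, partition)
    resid = (series.n_frac[-1] - pair.n_end)[pair.roi_nodes]
    return 0.5 * float(resid @ resid)


def _as_ops(mesh_or_ops, params) -> FemOperators:
    if isinstance(mesh_or_ops, FemOperators):
        return mesh_or_ops
    return FemOperators(mesh_or_ops, params)


def adjoint_gradient_k(
    k_regions,
    D0: float,
    pair: ObservationPair,
    mesh_or_ops,
    params: ModelParams,
    partition: RegionPartition,
):
    """Gradient of the misfit w.r.t. each regional k via the discrete adjoint.

    One stored forward run plus one backward sweep, regardless of the number
    of regions.  Returns ``(gradient, misfit_value)``.
    """
    ops = _as_ops(mesh_or_ops, params)
    series, traj = _forward(k_regions, D0, pair, ops, partition, store=True)
    return _adjoint_from_trajectory(traj, pair, ops, partition, k_regions)


def _adjoint_from_trajectory(traj, pair, ops, partition, k_regions):
    dt = ops.params.dt
    k_elem = k_elem_from_regions(k_regions, partition, ops.mesh.n_triangles)
    k_nodal = np.asarray(ops.W_elem_to_node @ k_elem).ravel()

    resid = np.zeros_like(traj.n_final)
    resid[pair.roi_nodes] = (traj.n_final - pair.n_end)[pair.roi_nodes]
    J = 0.5 * float(resid @ resid)

    from .forward_model import logistic_flow_jacobians

    p = resid
    grad_k_nodal = np.zeros_like(k_nodal)
    for s in range(len(traj.n_steps) - 1, -1, -1):
        ns = traj.n_steps[s]
        z = ops.lumped_mass * traj.lus[s].solve(p)  # M A^{-1} p  (A, M symmetric)
        dn, dk = logistic_flow_jacobians(ns, k_nodal, dt)
        grad_k_nodal += dk * z
        p = dn * z

    grad_elem = np.asarray(ops.W_elem_to_node.T @ grad_k_nodal).ravel()
    grad_regions = np.zeros(partition.n_regions)
    np.add.at(grad_regions, partition.region_of_element, grad_elem[partition.element_ids])
    return grad_regions, J


def fd_gradient_D0(
    k_regions,
    D0: float,
    pair: ObservationPair,
    mesh_or_ops,
    params: ModelParams,
    partition: RegionPartition,
    base_misfit: float | None = None,
) -> float:
    """Forward finite-difference misfit gradient in D0, 1% relative step.

    Falls back to an absolute perturbation of 1e-6 mm^2/day at D0 = 0.
    """
    ops = _as_ops(mesh_or_ops, params)
    h = 0.01 * D0 if D0 > 0 else 1e-6
    if base_misfit is None:
        base_misfit = misfit(k_regions, D0, pair, ops, params, partition)
    j_pert = misfit(k_regions, D0 + h, pair, ops, params, partition)
    return (j_pert - base_misfit) / h


def estimate(
    pair: ObservationPair,
    mesh: TriMesh,
    partition: RegionPartition,
    params: ModelParams,
    init: tuple | None = None,
    bounds: tuple | None = None,
    maxiter: int = 500,
    seed: int = 0,
) -> ProliferationFit:
    """Fit regional k and global D0 to one observation pair with L-BFGS-B.

    ``init`` is ``(k0_regions, D0_0)`` (default: k = 0 everywhere,
    D0 = 1e-2 mm^2/day); ``bounds`` is ``((k_lo, k_hi), (D0_lo, D0_hi))``
    (default k in [-1, 1] day^-1, D0 in [0, 1] mm^2/day).  Deterministic for
    fixed inputs; ``seed`` is accepted for interface uniformity.
    """
    nr = partition.n_regions
    if init is None:
        k0, D0_0 = np.zeros(nr), 1e-2
    else:
        k0, D0_0 = np.asarray(init[0], float), float(init[1])
    if bounds is None:
        (k_lo, k_hi), (d_lo, d_hi) = (-1.0, 1.0), (0.0, 1.0)
    else:
        (k_lo, k_hi), (d_lo, d_hi) = bounds
    if not (np.all(k0 >= k_lo) and np.all(k0 <= k_hi) and d_lo <= D0_0 <= d_hi):
        raise ValueError("init outside bounds")

    ops = FemOperators(mesh, params)
    cache: dict[bytes, tuple[float, np.ndarray]] = {}

    def fun_and_grad(x):
        key = x.tobytes()
        if key in cache:
            return cache[key]
        k_regions, D0 = x[:nr], x[nr]
        grad_k, J = adjoint_gradient_k(k_regions, D0, pair, ops, params, partition)
        gD = fd_gradient_D0(k_regions, D0, pair, ops, params, partition, base_misfit=J)
        g = np.concatenate([grad_k, [gD]])
        if len(cache) > 8:
            cache.clear()
        cache[key] = (J, g)
        return J, g

    trace: list[float] = []

    def callback(xk):
        trace.append(fun_and_grad(np.asarray(xk))[0])

    x0 = np.concatenate([k0, [D0_0]])
    trace.append(fun_and_grad(x0)[0])
    res = minimize(
        fun_and_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(k_lo, k_hi)] * nr + [(d_lo, d_hi)],
        callback=callback,
        options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-10},
    )
    return ProliferationFit(
        k_regions=res.x[:nr].copy(),
        D0_hat=float(res.x[nr]),
        objective_trace=np.asarray(trace),
        converged=bool(res.status == 0),
        n_iterations=int(res.nit),
        pair_label=pair.pair_label,
    )
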