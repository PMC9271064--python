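"""Mechanically coupled reaction-diffusion tumor growth on a P1 FEM mesh.

The model couples three pieces:

* logistic reaction-diffusion of the tumor cell fraction n = N/theta,
  dn/dt = div(D grad n) + k(x) n (1 - n);
* stress damping of cell motility, D = D0 * exp(-gamma * sigma_VM);
* quasi-static linear elasticity (plane strain) driven by the cell-density
  gradient, div(G grad u) + grad(G/(1-2 nu) div u) = lambda grad N, with
  u = 0 on the outer boundary — expanding tumor regions push on host tissue
  and the resulting distortional (von Mises) stress slows cell spread.

Time stepping is operator-split at dt = 1 day: the logistic reaction is
advanced by its exact closed-form flow, then diffusion implicitly (backward
Euler), which is unconditionally stable, bound-preserving, and conserves
total cell number exactly under the no-flux boundary condition.  Mechanics is re-solved every step from the
current cell field (quasi-static).  The cell field is stored internally as
the dimensionless fraction n in [0, 1]; the carrying capacity theta is
applied only at I/O boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csc_matrix
from scipy.sparse.linalg import splu

from .mesh import TriMesh, element_field_to_nodal_weights


@dataclass
class ModelParams:
    """Global biophysical parameters.

    D0 : stress-free cell diffusion, mm^2/day.
    gamma : stress-coupling constant, 1/kPa (damps diffusion).
    lam : force coupling, kPa per unit cell fraction (drives elasticity).
    E : Young's modulus, kPa (scalar or per-element array).
    nu : Poisson's ratio (near-incompressible soft tissue, 0.45).
    theta : carrying capacity, cells/voxel.
    dt : time step, days.
    """

    D0: float = 1e-2
    gamma: float = 1.0
    lam: float = 1.0
    E: float | np.ndarray = 2.0
    nu: float = 0.45
    theta: float = 1.0
    dt: float = 1.0

    def __post_init__(self):
        if self.D0 < 0:
            raise ValueError("D0 must be >= 0")
        if not (0.0 < self.nu < 0.5):
            raise ValueError("nu must lie in (0, 0.5)")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if np.any(np.asarray(self.E) <= 0):
            raise ValueError("E must be > 0")


@dataclass
class MechanicalState:
    displacement: np.ndarray  # (n_nodes, 2), mm
    stress: np.ndarray  # (n_tri, 3): sigma_xx, sigma_yy, sigma_xy
    von_mises: np.ndarray  # (n_tri,)


@dataclass
class CellStateSeries:
    """Recorded trajectory of the cell fraction field."""

    times: np.ndarray  # days
    n_frac: list  # nodal cell fraction per recorded day
    D_field: list  # per-element diffusion per recorded day, mm^2/day
    theta: float = 1.0

    def cellularity(self, i: int) -> np.ndarray:
        return self.n_frac[i] * self.theta


class FemOperators:
    """Cached P1 operators for one mesh: gradients, mass, elasticity factor."""

    def __init__(self, mesh: TriMesh, params: ModelParams):
        self.mesh = mesh
        self.params = params
        self._setup_geometry()
        self._assemble_mass()
        self._elasticity_lu = None
        self.W_elem_to_node = element_field_to_nodal_weights(mesh)

    def _setup_geometry(self):
        mesh = self.mesh
        p = mesh.nodes[mesh.triangles]  # (m, 3, 2)
        x, y = p[..., 0], p[..., 1]
        # P1 shape-function gradients: grad phi_i = (b_i, c_i) / (2A)
        b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
        c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
        area = 0.5 * (b[:, 0] * c[:, 1] - b[:, 1] * c[:, 0])
        # build_mesh guarantees CCW orientation, area > 0
        self.area = area
        self.dphi_x = b / (2.0 * area[:, None])  # (m, 3)
        self.dphi_y = c / (2.0 * area[:, None])

    def _assemble_mass(self):
        # lumped (row-sum) mass: with the non-obtuse triangles produced by
        # build_mesh this makes backward-Euler diffusion an M-matrix scheme,
        # hence monotone and bound-preserving, while total cell number
        # sum_i m_i n_i is conserved exactly under no-flux conditions
        mesh = self.mesh
        lumped = np.zeros(mesh.n_nodes)
        np.add.at(lumped, mesh.triangles.ravel(), np.repeat(self.area / 3.0, 3))
        self.lumped_mass = lumped

    def stiffness(self, D_elem: np.ndarray) -> csc_matrix:
        """Assemble the diffusion stiffness for a per-element D field."""
        mesh = self.mesh
        D_elem = np.broadcast_to(np.asarray(D_elem, float), (mesh.n_triangles,))
        gx, gy = self.dphi_x, self.dphi_y
        ke = (
            gx[:, :, None] * gx[:, None, :] + gy[:, :, None] * gy[:, None, :]
        ) * (D_elem * self.area)[:, None, None]
        rows = np.repeat(mesh.triangles, 3, axis=1).ravel()
        cols = np.tile(mesh.triangles, (1, 3)).ravel()
        n = mesh.n_nodes
        return coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsc()

    # -- elasticity ---------------------------------------------------------

    def _assemble_elasticity(self):
        mesh, params = self.mesh, self.params
        G = np.broadcast_to(
            np.asarray(params.E, float) / (2.0 * (1.0 + params.nu)),
            (mesh.n_triangles,),
        )
        bulk = G / (1.0 - 2.0 * params.nu)
        gx, gy = self.dphi_x, self.dphi_y
        A = self.area
        m = mesh.n_triangles
        # dof layout: [u_x at node, u_y at node] interleaved as 2*node+axis
        g = np.zeros((m, 3, 2))
        g[:, :, 0] = gx
        g[:, :, 1] = gy
        # K[(i,a),(j,b)] = A * [ G * delta_ab * (grad phi_i . grad phi_j)
        #                        + bulk * g_ia * g_jb ]
        lap = gx[:, :, None] * gx[:, None, :] + gy[:, :, None] * gy[:, None, :]
        ke = np.zeros((m, 6, 6))
        for a in range(2):
            for b_ax in range(2):
                blk = bulk[:, None, None] * g[:, :, a][:, :, None] * g[:, :, b_ax][:, None, :]
                if a == b_ax:
                    blk = blk + G[:, None, None] * lap
                ke[:, a::2, b_ax::2] = blk
        ke *= A[:, None, None]
        dofs = np.empty((m, 6), dtype=int)
        dofs[:, 0::2] = 2 * mesh.triangles
        dofs[:, 1::2] = 2 * mesh.triangles + 1
        rows = np.repeat(dofs, 6, axis=1).ravel()
        cols = np.tile(dofs, (1, 6)).ravel()
        ndof = 2 * mesh.n_nodes
        K = coo_matrix((ke.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsr()

        fixed = np.zeros(ndof, dtype=bool)
        fixed[2 * mesh.boundary_nodes] = True
        fixed[2 * mesh.boundary_nodes + 1] = True
        self._free = np.nonzero(~fixed)[0]
        Kff = K[self._free][:, self._free].tocsc()
        self._elasticity_lu = splu(Kff)
        self._G = G
        self._bulk = bulk

    def solve_elasticity(self, n_frac: np.ndarray) -> MechanicalState:
        """Displacement, element stress and von Mises stress for a cell field."""
        mesh, params = self.mesh, self.params
        if self._elasticity_lu is None:
            self._assemble_elasticity()
        # rhs: a(u, v) = -lam * int grad(n) . v  (n in fraction units)
        gn_x = np.sum(self.dphi_x * n_frac[mesh.triangles], axis=1)
        gn_y = np.sum(self.dphi_y * n_frac[mesh.triangles], axis=1)
        f = np.zeros(2 * mesh.n_nodes)
        wx = -params.lam * gn_x * self.area / 3.0
        wy = -params.lam * gn_y * self.area / 3.0
        for loc in range(3):
            np.add.at(f, 2 * mesh.triangles[:, loc], wx)
            np.add.at(f, 2 * mesh.triangles[:, loc] + 1, wy)
        u = np.zeros(2 * mesh.n_nodes)
        u[self._free] = self._elasticity_lu.solve(f[self._free])
        disp = u.reshape(-1, 2)

        ux = disp[mesh.triangles, 0]
        uy = disp[mesh.triangles, 1]
        exx = np.sum(self.dphi_x * ux, axis=1)
        eyy = np.sum(self.dphi_y * uy, axis=1)
        exy = 0.5 * (np.sum(self.dphi_y * ux, axis=1) + np.sum(self.dphi_x * uy, axis=1))
        G = self._G
        lam_lame = 2.0 * G * params.nu / (1.0 - 2.0 * params.nu)
        tr = exx + eyy
        sxx = 2.0 * G * exx + lam_lame * tr
        syy = 2.0 * G * eyy + lam_lame * tr
        sxy = 2.0 * G * exy
        svm = von_mises_plane_strain(sxx, syy, sxy, params.nu)
        return MechanicalState(
            displacement=disp, stress=np.column_stack([sxx, syy, sxy]), von_mises=svm
        )


def von_mises_plane_strain(sigma_xx, sigma_yy, sigma_xy, nu: float):
    """Von Mises stress under plane strain, with sigma_zz = nu*(sxx + syy)."""
    sxx = np.asarray(sigma_xx, float)
    syy = np.asarray(sigma_yy, float)
    sxy = np.asarray(sigma_xy, float)
    szz = nu * (sxx + syy)
    return np.sqrt(
        0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2) + 3.0 * sxy**2
    )


def damped_diffusion(D0: float, gamma: float, von_mises_field) -> np.ndarray:
    """Stress-damped diffusion D = D0 * exp(-gamma * sigma_VM), per element."""
    if D0 < 0:
        raise ValueError("D0 must be >= 0")
    return D0 * np.exp(-gamma * np.asarray(von_mises_field, float))


def solve_elasticity(mesh: TriMesh, N_field: np.ndarray, params: ModelParams) -> MechanicalState:
    """One-off elasticity solve (see :class:`FemOperators` for the cached path)."""
    ops = FemOperators(mesh, params)
    return ops.solve_elasticity(np.asarray(N_field, float) / params.theta)


_CLAMP_TOL = 1e-9


def logistic_flow(n: np.ndarray, k: np.ndarray, dt: float) -> np.ndarray:
    """Exact flow of dn/dt = k n (1 - n) over dt (n in fraction units).

    n(t+dt) = n e^{k dt} / (1 + n (e^{k dt} - 1)); maps [0, 1] to [0, 1]
    for any k, so the reaction substep is unconditionally bound-preserving
    and carries no time-discretization error of its own.
    """
    a = np.exp(np.asarray(k, float) * dt)
    return n * a / (1.0 + n * (a - 1.0))


def logistic_flow_jacobians(n: np.ndarray, k: np.ndarray, dt: float):
    """(d n_out / d n, d n_out / d k) of :func:`logistic_flow`, elementwise."""
    a = np.exp(np.asarray(k, float) * dt)
    denom = (1.0 + n * (a - 1.0)) ** 2
    return a / denom, dt * a * n * (1.0 - n) / denom


def step(
    n_frac: np.ndarray,
    k_nodal: np.ndarray,
    D_elem: np.ndarray,
    ops: FemOperators,
    lu=None,
):
    """Advance the cell fraction one dt: exact logistic flow, implicit diffusion.

    Returns ``(n_next, lu)`` where ``lu`` is the factorization of
    ``M + dt*K(D)`` (reusable while D is unchanged).
    """
    dt = ops.params.dt
    reacted = logistic_flow(n_frac, k_nodal, dt)
    if lu is None:
        from scipy.sparse import diags

        A = (diags(ops.lumped_mass) + dt * ops.stiffness(D_elem)).tocsc()
        lu = splu(A)
    n_next = lu.solve(ops.lumped_mass * reacted)
    lo, hi = n_next.min(), n_next.max()
    if lo < -_CLAMP_TOL or hi > 1.0 + _CLAMP_TOL:
        warnings.warn(
            f"cell fraction left [0,1] by more than {_CLAMP_TOL:g} "
            f"(min={lo:.3e}, max={hi:.3e}); clamping",
            RuntimeWarning,
            stacklevel=2,
        )
        n_next = np.clip(n_next, 0.0, 1.0)
    return n_next, lu


@dataclass
class Trajectory:
    """Per-step forward states needed by the adjoint backward sweep."""

    n_steps: list = field(default_factory=list)  # nodal fraction BEFORE each step
    lus: list = field(default_factory=list)  # factorization used at each step
    D_steps: list = field(default_factory=list)  # per-element D at each step
    n_final: np.ndarray | None = None


def run_forward(
    N0,
    k_field,
    params: ModelParams,
    t_end: float,
    mesh: TriMesh | None = None,
    ops: FemOperators | None = None,
    record_days=None,
    mechanics_update: bool = True,
    store_trajectory: bool = False,
    input_is_fraction: bool = False,
):
    """Run the coupled model from day 0 to ``t_end``.

    Parameters
    ----------
    N0
        Initial nodal cellularity (cells/voxel), or cell fraction when
        ``input_is_fraction``.
    k_field
        Per-element proliferation rate (day^-1), piecewise constant; averaged
        onto nodes (area-weighted) for the reaction term.
    t_end
        End day; must be an integer multiple of ``params.dt``.
    record_days
        Days at which to record the state (default: 0 and t_end).
    mechanics_update
        If False (or gamma == 0 and lam == 0), skip the elasticity solve and
        use D = D0 everywhere.

    Returns
    -------
    CellStateSeries, and the :class:`Trajectory` when ``store_trajectory``.
    """
    if ops is None:
        if mesh is None:
            raise ValueError("provide either ops or mesh")
        ops = FemOperators(mesh, params)
    params = ops.params
    n_steps_f = t_end / params.dt
    n_steps = int(round(n_steps_f))
    if abs(n_steps_f - n_steps) > 1e-9:
        raise ValueError(f"t_end={t_end} is not a multiple of dt={params.dt}")
    if record_days is None:
        record_days = [0.0, float(t_end)]
    record_days = list(record_days)

    n = np.asarray(N0, float).copy()
    if not input_is_fraction:
        n = n / params.theta
    if n.min() < -1e-12 or n.max() > 1.0 + 1e-9:
        raise ValueError("initial cellularity outside [0, theta]")
    n = np.clip(n, 0.0, 1.0)

    k_elem = np.broadcast_to(np.asarray(k_field, float), (ops.mesh.n_triangles,))
    k_nodal = np.asarray(ops.W_elem_to_node @ k_elem).ravel()

    coupled = mechanics_update and (params.gamma != 0.0) and (params.lam != 0.0)
    D0_elem = np.full(ops.mesh.n_triangles, params.D0)
    static_lu = None

    traj = Trajectory() if store_trajectory else None
    series_t, series_n, series_D = [], [], []

    def record(day, n_now, D_now):
        series_t.append(float(day))
        series_n.append(n_now.copy())
        series_D.append(np.array(D_now, float))

    D_now = D0_elem
    if 0.0 in record_days:
        record(0.0, n, D_now)

    for s in range(n_steps):
        if coupled:
            mech = ops.solve_elasticity(n)
            D_now = damped_diffusion(params.D0, params.gamma, mech.von_mises)
            lu_in = None
        else:
            D_now = D0_elem
            lu_in = static_lu
        if traj is not None:
            traj.n_steps.append(n.copy())
            traj.D_steps.append(D_now)
        n, lu = step(n, k_nodal, D_now, ops, lu=lu_in)
        if not coupled:
            static_lu = lu
        if traj is not None:
            traj.lus.append(lu)
        day = (s + 1) * params.dt
        if any(abs(day - rd) < 1e-9 for rd in record_days):
            record(day, n, D_now)

    if traj is not None:
        traj.n_final = n
    series = CellStateSeries(
        times=np.asarray(series_t), n_frac=series_n, D_field=series_D, theta=params.theta
    )
    return (series, traj) if store_trajectory else series
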