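"""Nonlinear membrane finite-element solver for shell inflation.

Total-Lagrangian constant-strain triangles carrying only in-plane stress
(plane stress), with the incompressible HGO material condensed through the
thickness. The inflation pressure is a follower load acting along the current
element normal; its (unsymmetric) load stiffness is included in the Newton
tangent. Displacements can be prescribed node-wise per pressure step (subdomain
boundary conditions, clamped rim); the pressure protocol is applied
sequentially with sub-increments and a backtracking line search.

Units: lengths mm, moduli/pressures kPa, forces mN (kPa * mm^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .constitutive import energy_stress_tangent
from .errors import (
    EnergyOverflowError,
    ParameterError,
    SingularElementError,
    SolverFailureError,
)
from .kinematics import DisplacementField, local_edge_matrix
from .mesh import TriSurfaceMesh

__all__ = [
    "MMHG_TO_KPA",
    "mmhg_to_kpa",
    "PressureProtocol",
    "SolverConfig",
    "InflationProblem",
    "SolveResult",
    "assemble_system",
    "solve_inflation",
]

MMHG_TO_KPA = 0.133322


def mmhg_to_kpa(p_mmhg: float) -> float:
    """Convert pressure from mmHg to kPa (1 mmHg = 0.133322 kPa)."""
    if np.any(np.asarray(p_mmhg) < 0):
        raise ParameterError("pressure must be non-negative")
    return np.multiply(p_mmhg, MMHG_TO_KPA)


@dataclass
class PressureProtocol:
    """Inflation protocol: reference pressure and increasing loading steps (mmHg)."""

    reference_mmhg: float = 5.0
    steps_mmhg: tuple = (15.0, 30.0, 45.0)

    def __post_init__(self):
        steps = np.asarray(self.steps_mmhg, dtype=float)
        if len(steps) == 0 or (np.diff(steps) <= 0).any():
            raise ParameterError("loading steps must be non-empty and strictly increasing")
        if self.reference_mmhg >= steps[0]:
            raise ParameterError("reference pressure must be below the first loading step")
        self.steps_mmhg = tuple(float(s) for s in steps)

    @property
    def all_pressures(self) -> np.ndarray:
        return np.array([self.reference_mmhg, *self.steps_mmhg])

    def load_kpa(self, step_index: int) -> float:
        """Applied load for a step: pressure difference from the reference state."""
        return mmhg_to_kpa(self.steps_mmhg[step_index] - self.reference_mmhg)


@dataclass
class SolverConfig:
    rtol: float = 1e-8
    atol: float = 1e-10            # mN
    max_iterations: int = 50
    sub_increments: int = 5
    max_line_search: int = 10
    max_retries: int = 2           # sub-increment doublings on failure
    include_load_stiffness: bool = True
    pin_rigid_body: bool = False   # Lagrange-constrain the 6 rigid modes (closed shells)


@dataclass
class SolveResult:
    displacements: DisplacementField | None
    log: list = field(default_factory=list)
    success: bool = False
    message: str = ""


class InflationProblem:
    """Mesh + thickness + per-element HGO parameters + protocol + BCs.

    ``prescribed_nodes`` lists the displacement-controlled nodes;
    ``prescribed_u`` has shape (n_loading_steps, len(prescribed_nodes), 3) and
    holds their target displacements at each loading step (zeros = clamped).
    ``fibers`` are 3D mean fiber directions per element; they are projected
    onto each element's tangent plane at setup.
    """

    def __init__(
        self,
        mesh: TriSurfaceMesh,
        thickness: np.ndarray,
        c10,
        k1,
        k2,
        kappa,
        fibers: np.ndarray,
        protocol: PressureProtocol,
        prescribed_nodes: np.ndarray,
        prescribed_u: np.ndarray,
        initial_guess: np.ndarray | None = None,
    ):
        m = mesh.n_triangles
        self.mesh = mesh
        self.thickness = np.broadcast_to(np.asarray(thickness, float), (m,)).copy()
        if (self.thickness <= 0).any():
            raise ParameterError("thickness must be positive everywhere")
        self.c10 = np.broadcast_to(np.asarray(c10, float), (m,)).copy()
        self.k1 = np.broadcast_to(np.asarray(k1, float), (m,)).copy()
        self.k2 = np.broadcast_to(np.asarray(k2, float), (m,)).copy()
        self.kappa = np.broadcast_to(np.asarray(kappa, float), (m,)).copy()
        self.protocol = protocol
        self.prescribed_nodes = np.asarray(prescribed_nodes, dtype=int)
        self.prescribed_u = np.asarray(prescribed_u, dtype=float)
        nsteps = len(protocol.steps_mmhg)
        if self.prescribed_u.shape != (nsteps, len(self.prescribed_nodes), 3):
            raise ParameterError(
                "prescribed_u must have shape (n_loading_steps, n_prescribed, 3)"
            )
        # optional Newton predictor per loading step (e.g. measured fields)
        self.initial_guess = None
        if initial_guess is not None:
            self.initial_guess = np.asarray(initial_guess, dtype=float)
            if self.initial_guess.shape != (nsteps, mesh.n_nodes, 3):
                raise ParameterError("initial_guess must be (n_loading_steps, n_nodes, 3)")

        # reference local frames and edge matrices
        G, e1, e2 = local_edge_matrix(mesh)
        self.Ginv = np.linalg.inv(G)
        self.area0 = 0.5 * np.abs(np.linalg.det(G))
        self.volume0 = self.area0 * self.thickness

        fibers = np.broadcast_to(np.asarray(fibers, float), (m, 3))
        normals, _ = mesh.normals_area()
        tang = fibers - np.einsum("mi,mi->m", fibers, normals)[:, None] * normals
        nt = np.linalg.norm(tang, axis=1)
        degenerate = nt < 1e-10
        if degenerate.any():
            tang = tang.copy()
            tang[degenerate] = e1[degenerate]
            nt = np.linalg.norm(tang, axis=1)
        tang /= nt[:, None]
        self.fiber_local = np.stack(
            [np.einsum("mi,mi->m", tang, e1), np.einsum("mi,mi->m", tang, e2)], axis=1
        )
        self.fiber_local /= np.linalg.norm(self.fiber_local, axis=1)[:, None]

        # dof bookkeeping
        n = mesh.n_nodes
        self.n_dof = 3 * n
        presc_dofs = (3 * self.prescribed_nodes[:, None] + np.arange(3)).ravel()
        self.free_mask = np.ones(self.n_dof, dtype=bool)
        self.free_mask[presc_dofs] = False
        self.presc_dofs = presc_dofs

        # global sparse indices of the per-element 9x9 blocks
        t = mesh.triangles
        dofs = (3 * t[:, :, None] + np.arange(3)).reshape(m, 9)
        self._rows = np.repeat(dofs, 9, axis=1).ravel()
        self._cols = np.tile(dofs, (1, 9)).ravel()
        self._dofs9 = dofs

    def prescribed_target(self, step_index: int) -> np.ndarray:
        return self.prescribed_u[step_index]


_B = np.array([[-1.0, 1.0, 0.0], [-1.0, 0.0, 1.0]])  # edge p <- node n


def _skew(v):
    out = np.zeros(v.shape[:-1] + (3, 3))
    out[..., 0, 1] = -v[..., 2]
    out[..., 0, 2] = v[..., 1]
    out[..., 1, 0] = v[..., 2]
    out[..., 1, 2] = -v[..., 0]
    out[..., 2, 0] = -v[..., 1]
    out[..., 2, 1] = v[..., 0]
    return out


def assemble_system(
    problem: InflationProblem,
    positions: np.ndarray,
    pressure_kpa: float,
    want_tangent: bool = True,
    include_load_stiffness: bool = True,
):
    """Residual R = f_int - f_ext, external force, and tangent at ``positions``.

    Returns ``(R, f_ext, K)`` with K None when ``want_tangent`` is False.
    Raises :class:`SingularElementError` on degenerate/inverted elements and
    :class:`EnergyOverflowError` on fiber-energy overflow.
    """
    mesh = problem.mesh
    if not np.isfinite(positions).all():
        raise SolverFailureError("non-finite nodal positions")
    D = mesh.edge_vectors(positions)  # (m, 2, 3)
    mmat = np.einsum("mpc,mqc->mpq", D, D)
    detm = mmat[:, 0, 0] * mmat[:, 1, 1] - mmat[:, 0, 1] ** 2
    if (detm <= 1e-20).any():
        idx = int(np.argmax(detm <= 1e-20))
        raise SingularElementError(f"element {idx} degenerate in deformed state", idx)
    Gi = problem.Ginv
    C = np.einsum("mpa,mpq,mqb->mab", Gi, mmat, Gi)

    want = ("S", "CC") if want_tangent else ("S",)
    res = energy_stress_tangent(
        C, problem.fiber_local, problem.c10, problem.k1, problem.k2, problem.kappa, want=want
    )
    S = res["S"]
    V0 = problem.volume0

    Sbar = np.einsum("mia,mab,mjb->mij", Gi, S, Gi)
    f_edge = V0[:, None, None] * np.einsum("mij,mjc->mic", Sbar, D)  # (m, 2, 3)

    # follower pressure: each node receives p/6 * (d1 x d2)
    cr = np.cross(D[:, 0], D[:, 1])
    f_press = (pressure_kpa / 6.0) * cr  # (m, 3) per node

    n_dof = problem.n_dof
    flat = problem._dofs9.ravel()
    f_nodes = np.einsum("pn,mpc->mnc", _B, f_edge)  # (m, 3 nodes, 3)
    f_int = np.bincount(flat, weights=f_nodes.reshape(-1), minlength=n_dof)
    ext_nodes = np.repeat(f_press[:, None, :], 3, axis=1)
    f_ext = np.bincount(flat, weights=ext_nodes.reshape(-1), minlength=n_dof)

    R = f_int - f_ext

    K = None
    if want_tangent:
        CC = res["CC"]
        mq = CC.shape[0]
        # Cbar_ijpq = 0.5 Gi_ia Gi_jb CC_abcd Gi_pc Gi_qd, via 4 small matmuls
        t1 = np.einsum("mia,mabcd->mibcd", Gi, CC)
        t1 = np.einsum("mjb,mibcd->mijcd", Gi, t1)
        t1 = np.einsum("mpc,mijcd->mijpd", Gi, t1)
        Cbar = 0.5 * np.einsum("mqd,mijpd->mijpq", Gi, t1)
        # Kmat_ikab = 2 Cbar_ijkq D_ja D_qb
        CbD = np.einsum("mijkq,mqb->mijkb", Cbar, D)
        Kmat = 2.0 * np.einsum("mja,mijkb->mikab", D, CbD)
        K_edge = Kmat
        K_edge[:, 0, 0] += Sbar[:, 0, 0, None, None] * np.eye(3)
        K_edge[:, 0, 1] += Sbar[:, 0, 1, None, None] * np.eye(3)
        K_edge[:, 1, 0] += Sbar[:, 1, 0, None, None] * np.eye(3)
        K_edge[:, 1, 1] += Sbar[:, 1, 1, None, None] * np.eye(3)
        K_edge *= V0[:, None, None, None, None]  # (m, 2, 2, 3, 3)
        # edge dofs -> node dofs
        K_el = np.einsum("pn,qr,mpqab->mnarb", _B, _B, K_edge, optimize=True).reshape(-1, 9, 9)

        if include_load_stiffness and pressure_kpa != 0.0:
            s1 = _skew(D[:, 0])
            s2 = _skew(D[:, 1])
            # d f_press / d d1 = -p/6 [d2]x ; d f_press / d d2 = p/6 [d1]x
            dfd = np.stack([-s2, s1], axis=1) * (pressure_kpa / 6.0)  # (m, 2, 3, 3)
            dfn = np.einsum("pn,mpab->mnab", _B, dfd)  # (m, node_col, 3, 3)
            K_load = np.repeat(dfn[:, None, :, :, :], 3, axis=1)  # same for each row node
            K_el = K_el - K_load.transpose(0, 1, 3, 2, 4).reshape(-1, 9, 9)

        K = sparse.coo_matrix(
            (K_el.ravel(), (problem._rows, problem._cols)), shape=(n_dof, n_dof)
        ).tocsr()
    return R, f_ext, K


def _rigid_constraints(mesh: TriSurfaceMesh) -> sparse.csr_matrix:
    """Six rows constraining mean translation and rotation (closed shells)."""
    n = mesh.n_nodes
    X = mesh.nodes - mesh.nodes.mean(axis=0)
    rows, cols, vals = [], [], []
    for k in range(3):
        rows.extend([k] * n)
        cols.extend((3 * np.arange(n) + k).tolist())
        vals.extend([1.0] * n)
    sk = _skew(X)  # (n, 3, 3): (X x u)_k = sk[n, k, :] . u_n ... sign immaterial
    for k in range(3):
        for c in range(3):
            rows.extend([3 + k] * n)
            cols.extend((3 * np.arange(n) + c).tolist())
            vals.extend(sk[:, k, c].tolist())
    return sparse.csr_matrix((vals, (rows, cols)), shape=(6, 3 * n))


def _newton(problem, u, pressure_kpa, presc_u, config, log, label, candidates=()):
    """Newton iteration at fixed load; updates ``u`` in place. Returns residual.

    ``candidates`` are optional alternative starting displacements (predictor
    states); the start with the smallest initial residual is used.
    """
    mesh = problem.mesh
    u = u.reshape(-1, 3)
    if len(problem.prescribed_nodes):
        u[problem.prescribed_nodes] = presc_u
    free = problem.free_mask

    Cmat = _rigid_constraints(mesh) if config.pin_rigid_body else None
    if Cmat is not None:
        Cf = Cmat[:, free]

    def residual_norm(uu):
        with np.errstate(over="ignore", invalid="ignore"):
            R, f_ext, _ = assemble_system(problem, mesh.nodes + uu, pressure_kpa, want_tangent=False)
            r = float(np.linalg.norm(R[free]))
        return (r if np.isfinite(r) else np.inf), float(np.linalg.norm(f_ext))

    divergence_cap = 1e8  # mN; converged membrane forces are O(1..100) mN
    res, ext = residual_norm(u)
    for cand in candidates:
        trial = np.array(cand, dtype=float)
        if len(problem.prescribed_nodes):
            trial[problem.prescribed_nodes] = presc_u
        try:
            r_c, _ = residual_norm(trial)
        except (SingularElementError, EnergyOverflowError):
            continue
        if r_c < res:
            res = r_c
            u[:] = trial
    tol = config.rtol * max(ext, 1.0) + config.atol
    it = 0
    while res > tol:
        if it >= config.max_iterations:
            raise SolverFailureError(
                f"{label}: no convergence after {it} iterations (residual {res:.3e}, tol {tol:.3e})"
            )
        R, f_ext, K = assemble_system(
            problem, mesh.nodes + u, pressure_kpa,
            include_load_stiffness=config.include_load_stiffness,
        )
        Kff = K[free][:, free]
        rhs = -R[free]
        if Cmat is None:
            du_f = spsolve(Kff, rhs)
        else:
            nfree = Kff.shape[0]
            A = sparse.bmat([[Kff, Cf.T], [Cf, None]], format="csc")
            b = np.concatenate([rhs, -Cf @ u.ravel()[free]])
            du_f = spsolve(A, b)[:nfree]
        if not np.isfinite(du_f).all():
            raise SolverFailureError(f"{label}: singular tangent (non-finite Newton step)")

        # backtracking line search on the residual norm
        step = 1.0
        best = None
        for _ in range(config.max_line_search):
            trial = u.copy()
            trial.reshape(-1)[np.where(free)[0]] += step * du_f
            try:
                cand, _ = residual_norm(trial)
            except (SingularElementError, EnergyOverflowError):
                cand = np.inf
            if best is None or cand < best[0]:
                best = (cand, step, trial)
            if cand < res:
                break
            step *= 0.5
        if best is None or not np.isfinite(best[0]):
            raise SolverFailureError(f"{label}: line search failed")
        res, _, u_new = best
        u[:] = u_new
        it += 1
        if res > divergence_cap:
            raise SolverFailureError(
                f"{label}: divergence (residual {res:.3e} mN)", diverged=True
            )
    log.append({"increment": label, "iterations": it, "residual": res, "tolerance": tol})
    return u


def solve_inflation(problem: InflationProblem, config: SolverConfig | None = None) -> SolveResult:
    """Sequentially pressurize through the protocol; Newton per sub-increment.

    Pressure and prescribed displacements are ramped proportionally inside each
    step. On non-convergence the step is retried with doubled sub-increments
    (up to ``config.max_retries`` doublings); persistent failure yields an
    unsuccessful :class:`SolveResult` with the log attached, never silence.
    """
    config = config or SolverConfig()
    protocol = problem.protocol
    nsteps = len(protocol.steps_mmhg)
    n = problem.mesh.n_nodes
    u = np.zeros((n, 3))
    fields = [np.zeros((n, 3))]
    log: list = []

    p_prev = 0.0
    presc_prev = np.zeros((len(problem.prescribed_nodes), 3))
    for s in range(nsteps):
        p_target = protocol.load_kpa(s)
        presc_target = problem.prescribed_target(s)
        n_inc = config.sub_increments
        attempt = 0
        u_start = u.copy()
        guess = problem.initial_guess[s] if problem.initial_guess is not None else None
        while True:
            try:
                for inc in range(1, n_inc + 1):
                    frac = inc / n_inc
                    p = p_prev + frac * (p_target - p_prev)
                    presc = presc_prev + frac * (presc_target - presc_prev)
                    label = f"step {s + 1}/{nsteps} inc {inc}/{n_inc}"
                    candidates = []
                    if guess is not None:
                        candidates.append(u_start + frac * (guess - u_start))
                    u = _newton(problem, u, p, presc, config, log, label, candidates)
                break
            except (SolverFailureError, SingularElementError, EnergyOverflowError) as exc:
                attempt += 1
                log.append({"increment": f"step {s + 1} attempt {attempt}", "error": str(exc)})
                if getattr(exc, "diverged", False) or attempt > config.max_retries:
                    return SolveResult(None, log, False, f"step {s + 1} failed: {exc}")
                n_inc *= 2
                u = u_start.copy()
        p_prev = p_target
        presc_prev = presc_target
        fields.append(u.copy())

    disp = DisplacementField(protocol.all_pressures, np.stack(fields))
    return SolveResult(disp, log, True, "converged")
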