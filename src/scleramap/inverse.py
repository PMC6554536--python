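"""Inverse estimation of (C10, k1, k2) per subdomain.

A coarse log-spaced design-of-experiments sweep first brackets each
subdomain's optimum inside the wide physical ranges; particle-swarm
optimization then minimizes the displacement sum-of-squares residual inside
the tightened bounds. All three parameters are searched in log10 space since
the admissible ranges span several decades. Per-subdomain results are merged
into a per-element parameter map, smoothed across subdomain boundaries, and
verified by a full-shell forward simulation against the experimental fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import OptimizationFailureError, ParameterError
from .forward import InflationProblem, PressureProtocol, SolverConfig, solve_inflation
from .kinematics import DisplacementField
from .mesh import TriSurfaceMesh
from .subdomains import SubdomainLabeling, SubdomainProblem

logger = logging.getLogger(__name__)

__all__ = [
    "DOEGrid",
    "PSOConfig",
    "OptimizationResult",
    "ParameterMap",
    "run_doe",
    "displacement_sse",
    "mean_displacement_error",
    "optimize_subdomain",
    "merge_and_smooth_parameters",
    "global_check",
    "DEFAULT_RANGES",
]

# wide physical parameter ranges (kPa for moduli): C10 5 kPa - 40 MPa,
# k1 1 Pa - 40 MPa, k2 0.1 - 300 (dimensionless)
DEFAULT_RANGES = {
    "c10": (5.0, 4.0e4),
    "k1": (1.0e-3, 4.0e4),
    "k2": (0.1, 300.0),
}

_PARAMS = ("c10", "k1", "k2")


@dataclass
class DOEGrid:
    """Log-spaced coarse grid over the three unknown parameters."""

    ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))
    resolution: dict = field(default_factory=lambda: {"c10": 6, "k1": 6, "k2": 4})

    def __post_init__(self):
        for p in _PARAMS:
            lo, hi = self.ranges[p]
            if not (0 < lo < hi):
                raise ParameterError(f"invalid range for {p}: ({lo}, {hi})")
            if self.resolution[p] < 2:
                raise ParameterError(f"resolution for {p} must be >= 2")

    def axes(self) -> dict:
        return {
            p: np.geomspace(self.ranges[p][0], self.ranges[p][1], self.resolution[p])
            for p in _PARAMS
        }


@dataclass
class PSOConfig:
    swarm_size: int = 30
    max_iterations: int = 100
    inertia: float = 0.9
    inertia_end: float | None = 0.4  # linearly damped inertia; None = constant
    cognitive: float = 1.4962
    social: float = 1.4962
    ftol: float = 1e-10
    stall_iterations: int = 15
    seed: int = 0
    hybrid_polish: bool = True     # derivative-free simplex polish of the swarm best
    polish_max_evals: int = 400

    def __post_init__(self):
        if self.swarm_size < 2:
            raise ParameterError("swarm size must be >= 2")
        if min(self.inertia, self.cognitive, self.social) <= 0:
            raise ParameterError("PSO coefficients must be positive")


@dataclass
class OptimizationResult:
    subdomain_id: int
    c10: float
    k1: float
    k2: float
    residual: float                # mm^2
    history: list                  # best-so-far residual per iteration
    bounds: dict
    seed: int
    n_evaluations: int = 0

    def as_row(self) -> dict:
        return {
            "subdomain_id": self.subdomain_id,
            "C10_kPa": self.c10,
            "k1_kPa": self.k1,
            "k2": self.k2,
            "residual_mm2": self.residual,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# residual metrics
# ---------------------------------------------------------------------------

def _loading_u(f: DisplacementField | np.ndarray) -> np.ndarray:
    if isinstance(f, DisplacementField):
        return f.u[1:]
    return np.asarray(f, dtype=float)


def displacement_sse(simulated, experimental, interior_nodes, steps=None) -> float:
    """Sum over steps, interior nodes and components of squared differences (mm^2)."""
    us, ue = _loading_u(simulated), _loading_u(experimental)
    if us.shape != ue.shape:
        raise ParameterError(f"field shape mismatch: {us.shape} vs {ue.shape}")
    if steps is None:
        steps = np.arange(us.shape[0])
    idx = np.asarray(interior_nodes, dtype=int)
    d = us[np.asarray(steps)][:, idx, :] - ue[np.asarray(steps)][:, idx, :]
    return float(np.sum(d * d))


def mean_displacement_error(simulated, experimental, interior_nodes, steps=None) -> dict:
    """Displacement mismatch metrics over the interior nodes.

    Returns a dict with two distinctly labeled quantities:

    - ``mean_norm_mm``: mean over interior nodes of the Euclidean norm of the
      displacement difference, averaged over pressure steps (the primary
      error metric, in mm);
    - ``sse_per_node_mm2``: the literal sum-of-squares residual divided by the
      interior node count (mm^2).
    """
    us, ue = _loading_u(simulated), _loading_u(experimental)
    if us.shape != ue.shape:
        raise ParameterError(f"field shape mismatch: {us.shape} vs {ue.shape}")
    idx = np.asarray(interior_nodes, dtype=int)
    if len(idx) == 0:
        raise ParameterError("no interior nodes")
    if steps is None:
        steps = np.arange(us.shape[0])
    d = us[np.asarray(steps)][:, idx, :] - ue[np.asarray(steps)][:, idx, :]
    norms = np.linalg.norm(d, axis=2)          # (steps, nodes)
    return {
        "mean_norm_mm": float(norms.mean()),
        "max_norm_mm": float(norms.max()),
        "sse_per_node_mm2": float(np.sum(d * d) / len(idx)),
    }


# ---------------------------------------------------------------------------
# DOE
# ---------------------------------------------------------------------------

def _objective_factory(problem: SubdomainProblem, solver_config: SolverConfig):
    """Stateless objective: forward solve at (c10, k1, k2), SSE at interior nodes."""

    def objective(c10, k1, k2):
        try:
            fwd = problem.problem_for(c10, k1, k2)
            result = solve_inflation(fwd, solver_config)
        except ParameterError:
            return np.inf, None
        if not result.success:
            return np.inf, result
        idx = problem.interior_nodes
        sim = result.displacements.u[1:][:, idx, :]
        sse = displacement_sse(sim, problem.target_u, np.arange(len(idx)))
        return sse, result

    return objective


def run_doe(
    problem: SubdomainProblem,
    grid: DOEGrid | None = None,
    solver_config: SolverConfig | None = None,
    keep_factor: float = 10.0,
):
    """Forward-solve every grid combination; bracket the near-best ones.

    Returns ``(bounds, records)``. Bounds for each parameter are the union of
    the +/-1 grid-step neighborhoods of every combination whose residual is
    within ``keep_factor`` of the best, clipped to the full range. This keeps
    the swarm's search box honest when the coarse grid is ambiguous along
    weakly identified directions (compensating (C10, k1) combinations, the
    shallow k2 axis): where a single combination dominates the box is one
    cell wide, where several residuals are comparable it widens to cover the
    ambiguity. ``records`` lists every combination with its residual.
    """
    grid = grid or DOEGrid()
    solver_config = solver_config or SolverConfig(sub_increments=1, max_iterations=25, max_retries=1)
    axes = grid.axes()
    for p in _PARAMS:
        if len(axes[p]) < 2:
            raise ParameterError(f"degenerate DOE grid for {p}")
    objective = _objective_factory(problem, solver_config)

    records = []
    combos = []
    for i, c10 in enumerate(axes["c10"]):
        for j, k1 in enumerate(axes["k1"]):
            for k, k2 in enumerate(axes["k2"]):
                sse, _ = objective(c10, k1, k2)
                records.append({"c10": c10, "k1": k1, "k2": k2, "sse": sse})
                combos.append((sse, (i, j, k)))
    feasible = [c for c in combos if np.isfinite(c[0])]
    if not feasible:
        raise OptimizationFailureError(
            f"DOE: all {len(records)} forward solves failed for subdomain {problem.subdomain_id}"
        )
    feasible.sort(key=lambda c: c[0])
    cutoff = feasible[0][0] * max(keep_factor, 1.0)
    top = [c for c in feasible if c[0] <= cutoff] or feasible[:1]
    bounds = {}
    for d, p in enumerate(_PARAMS):
        ax = axes[p]
        lo = min(ax[max(c[1][d] - 1, 0)] for c in top)
        hi = max(ax[min(c[1][d] + 1, len(ax) - 1)] for c in top)
        bounds[p] = (float(lo), float(hi))
    return bounds, records


# ---------------------------------------------------------------------------
# particle swarm
# ---------------------------------------------------------------------------

def optimize_subdomain(
    problem: SubdomainProblem,
    bounds: dict,
    pso: PSOConfig | None = None,
    solver_config: SolverConfig | None = None,
) -> OptimizationResult:
    """Particle-swarm search of (log C10, log k1, log k2) within bounds.

    Reflective bound handling; non-convergent forward solves receive a large
    penalty (1e6 x the best feasible residual so far) instead of aborting.
    Deterministic for a fixed seed. Terminates early when the best residual
    improves by less than ``ftol`` (relatively) over ``stall_iterations``.
    """
    pso = pso or PSOConfig()
    # one sub-increment retry: noisy boundary data occasionally stalls the
    # single-increment Newton at isolated parameter points, and a spurious
    # infeasible there would poison the search
    solver_config = solver_config or SolverConfig(sub_increments=1, max_iterations=25, max_retries=1)
    if solver_config.max_retries < 1:
        solver_config = SolverConfig(**{**solver_config.__dict__, "max_retries": 1})
    if len(problem.interior_nodes) == 0:
        raise ParameterError("subdomain has no interior nodes")
    for p in _PARAMS:
        lo, hi = bounds[p]
        if not (0 < lo < hi):
            raise ParameterError(f"invalid bounds for {p}: ({lo}, {hi})")

    lo = np.log10([bounds[p][0] for p in _PARAMS])
    hi = np.log10([bounds[p][1] for p in _PARAMS])
    objective = _objective_factory(problem, solver_config)
    rng = np.random.default_rng(pso.seed)

    n = pso.swarm_size
    x = lo + (hi - lo) * rng.random((n, 3))
    v = 0.25 * (hi - lo) * (2 * rng.random((n, 3)) - 1)

    n_eval = 0
    penalty_scale = 1e6

    def evaluate(xx):
        nonlocal n_eval
        vals = np.empty(len(xx))
        feasible_best = np.inf
        raw = []
        for i, xi in enumerate(xx):
            sse, _ = objective(*np.power(10.0, xi))
            n_eval += 1
            raw.append(sse)
            if np.isfinite(sse):
                feasible_best = min(feasible_best, sse)
        fail_pen = penalty_scale * (feasible_best if np.isfinite(feasible_best) else 1.0)
        for i, sse in enumerate(raw):
            vals[i] = sse if np.isfinite(sse) else max(fail_pen, 1.0)
        return vals, np.isfinite(raw).any()

    fvals, any_feasible = evaluate(x)
    pbest_x, pbest_f = x.copy(), fvals.copy()
    g = int(np.argmin(pbest_f))
    gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])
    history = [gbest_f]
    ever_feasible = any_feasible

    stall = 0
    for it in range(pso.max_iterations):
        if pso.inertia_end is None or pso.max_iterations <= 1:
            w = pso.inertia
        else:
            w = pso.inertia + (pso.inertia_end - pso.inertia) * it / (pso.max_iterations - 1)
        r1 = rng.random((n, 3))
        r2 = rng.random((n, 3))
        v = (
            w * v
            + pso.cognitive * r1 * (pbest_x - x)
            + pso.social * r2 * (gbest_x[None, :] - x)
        )
        x = x + v
        # reflective bounds
        for d in range(3):
            low, high = lo[d], hi[d]
            over = x[:, d] > high
            under = x[:, d] < low
            x[over, d] = 2 * high - x[over, d]
            x[under, d] = 2 * low - x[under, d]
            v[over | under, d] *= -1.0
            x[:, d] = np.clip(x[:, d], low, high)

        fvals, any_feasible = evaluate(x)
        ever_feasible = ever_feasible or any_feasible
        improved = fvals < pbest_f
        pbest_x[improved] = x[improved]
        pbest_f[improved] = fvals[improved]
        g = int(np.argmin(pbest_f))
        prev = gbest_f
        if pbest_f[g] < gbest_f:
            gbest_f = float(pbest_f[g])
            gbest_x = pbest_x[g].copy()
        history.append(gbest_f)
        rel_impr = (prev - gbest_f) / max(abs(prev), 1e-30)
        stall = 0 if rel_impr > pso.ftol else stall + 1
        if stall >= pso.stall_iterations:
            break

    if not ever_feasible:
        raise OptimizationFailureError(
            f"subdomain {problem.subdomain_id}: every particle infeasible in every iteration"
        )

    if pso.hybrid_polish and np.isfinite(gbest_f):
        # simplex descent from the swarm optimum: the swarm localizes the
        # basin, the polish resolves the shallow (k1, k2) ridge
        from scipy.optimize import minimize

        def fobj(z):
            nonlocal n_eval
            zz = np.clip(z, lo, hi)
            pen = float(np.sum((z - zz) ** 2))
            sse, _ = objective(*np.power(10.0, zz))
            n_eval += 1
            if not np.isfinite(sse):
                sse = max(penalty_scale * gbest_f, 1.0)
            return sse * (1.0 + 100.0 * pen) + pen
        r = minimize(
            fobj,
            gbest_x,
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 0.0, "maxfev": pso.polish_max_evals},
        )
        if np.isfinite(r.fun) and r.fun < gbest_f:
            gbest_f = float(r.fun)
            gbest_x = np.clip(r.x, lo, hi)
        history.append(gbest_f)

    c10, k1, k2 = np.power(10.0, gbest_x)
    return OptimizationResult(
        subdomain_id=problem.subdomain_id,
        c10=float(c10),
        k1=float(k1),
        k2=float(k2),
        residual=gbest_f,
        history=history,
        bounds={p: tuple(bounds[p]) for p in _PARAMS},
        seed=pso.seed,
        n_evaluations=n_eval,
    )


# ---------------------------------------------------------------------------
# parameter-map merging and smoothing
# ---------------------------------------------------------------------------

@dataclass
class ParameterMap:
    """Per-element (C10, k1, k2) over the whole shell."""

    c10: np.ndarray
    k1: np.ndarray
    k2: np.ndarray
    provenance: str = "piecewise"

    def __post_init__(self):
        for name in _PARAMS:
            v = getattr(self, name)
            if (np.asarray(v) <= 0).any():
                raise ParameterError(f"parameter map {name} must be positive everywhere")


def merge_and_smooth_parameters(
    labeling: SubdomainLabeling,
    results: dict[int, OptimizationResult],
    adjacency: list[np.ndarray],
    band_width: int = 3,
    iterations: int = 10,
    factor: float = 0.5,
) -> ParameterMap:
    """Piecewise-constant map from per-subdomain results, relaxed at boundaries.

    Elements within ``band_width`` graph steps of an inter-subdomain boundary
    are smoothed by neighbor averaging in log-parameter space; all other
    elements keep their subdomain value, so smoothed values stay inside the
    convex hull (per parameter) of the subdomain constants.
    """
    for sid in range(1, labeling.K + 1):
        if sid not in results and len(labeling.elements_of(sid)):
            raise ParameterError(f"missing optimization result for subdomain {sid}")
    m = len(labeling.labels)
    maps = {}
    for p in _PARAMS:
        vals = np.empty(m)
        for sid, res in results.items():
            vals[labeling.labels == sid] = getattr(res, p)
        maps[p] = vals

    if band_width <= 0 or iterations <= 0:
        return ParameterMap(provenance="piecewise", **maps)

    labels = labeling.labels
    boundary = np.zeros(m, dtype=bool)
    for i, nb in enumerate(adjacency):
        if len(nb) and (labels[nb] != labels[i]).any():
            boundary[i] = True
    band = boundary.copy()
    frontier = boundary.copy()
    for _ in range(band_width - 1):
        new = np.zeros(m, dtype=bool)
        for i in np.where(frontier)[0]:
            new[adjacency[i]] = True
        frontier = new & ~band
        band |= new

    for p in _PARAMS:
        logv = np.log(maps[p])
        for _ in range(iterations):
            avg = logv.copy()
            for i in np.where(band)[0]:
                nb = adjacency[i]
                if len(nb):
                    avg[i] = (1 - factor) * logv[i] + factor * logv[nb].mean()
            logv = avg
        maps[p] = np.exp(logv)
    return ParameterMap(provenance=f"smoothed(band={band_width},iters={iterations})", **maps)


# ---------------------------------------------------------------------------
# full-shell global check
# ---------------------------------------------------------------------------

def global_check(
    mesh: TriSurfaceMesh,
    parameter_map: ParameterMap,
    thickness,
    fibers,
    kappa,
    protocol: PressureProtocol,
    experimental: DisplacementField,
    solver_config: SolverConfig | None = None,
    hole_margin: str = "prescribed",
):
    """Full-shell forward simulation with the merged map vs experimental fields.

    The rim is clamped; the hole margin is either displacement-prescribed from
    the experimental data (default) or free. Returns ``(report, result)`` where
    the report holds the mean / max / per-node displacement errors over the
    non-prescribed nodes.
    """
    solver_config = solver_config or SolverConfig(sub_increments=2)
    nsteps = len(protocol.steps_mmhg)
    loading = experimental.u[1:]
    if hole_margin == "prescribed":
        presc_nodes = np.unique(np.concatenate([mesh.rim_nodes, mesh.hole_nodes]))
    elif hole_margin == "free":
        presc_nodes = mesh.rim_nodes
    else:
        raise ParameterError("hole_margin must be 'prescribed' or 'free'")
    presc_u = loading[:, presc_nodes, :]
    if hole_margin == "prescribed" and len(mesh.rim_nodes):
        rim_local = np.isin(presc_nodes, mesh.rim_nodes)
        presc_u = presc_u.copy()
        presc_u[:, rim_local, :] = 0.0  # clamped base
    else:
        presc_u = np.zeros_like(presc_u)  # rim clamped

    problem = InflationProblem(
        mesh,
        thickness,
        parameter_map.c10,
        parameter_map.k1,
        parameter_map.k2,
        kappa,
        fibers,
        protocol,
        presc_nodes,
        presc_u,
    )
    result = solve_inflation(problem, solver_config)
    if not result.success:
        raise OptimizationFailureError(f"global check solver failure: {result.message}")

    free_nodes = np.setdiff1d(np.arange(mesh.n_nodes), presc_nodes)
    metrics = mean_displacement_error(result.displacements, experimental, free_nodes)
    d = result.displacements.u[1:][:, free_nodes, :] - loading[:, free_nodes, :]
    per_node = np.zeros(mesh.n_nodes)
    per_node[free_nodes] = np.linalg.norm(d, axis=2).mean(axis=0)
    report = {
        "mean_error_mm": metrics["mean_norm_mm"],
        "max_error_mm": metrics["max_norm_mm"],
        "sse_per_node_mm2": metrics["sse_per_node_mm2"],
        "per_node_error_mm": per_node,
        "n_free_nodes": int(len(free_nodes)),
    }
    return report, result
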