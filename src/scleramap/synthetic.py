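"""Synthetic ground truth and simulated inflation "experiments".

Stands in for the donor-eye data: a hemispherical shell with an apical hole,
a region-wise constant heterogeneous HGO parameter map, circumferential
fibers around the hole, forward-simulated displacement fields through the
pressure protocol, and isotropic Gaussian measurement noise emulating the
speckle-correlation output. Everything is generated through the public
forward pipeline (no hidden physics) and is reproducible from a seed.

Default parameter ranges are chosen so synthetic shells deform on the scale
of measured posterior-sclera inflation fields (nodal displacement components
up to roughly half a millimeter at 45 mmHg): C10 in [30, 150] kPa, k1 in
[150, 1500] kPa, k2 in [20, 200], drawn log-uniformly per region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constitutive import PAPER_KAPPAS
from .errors import InvalidGeometryError, ParameterError
from .forward import InflationProblem, PressureProtocol, SolverConfig, solve_inflation
from .kinematics import DisplacementField
from .mesh import PointCloud3D, TriSurfaceMesh

__all__ = [
    "GroundTruth",
    "make_ground_truth",
    "simulate_inflation_experiment",
    "make_concentric_point_clouds",
    "DEFAULT_TRUTH_RANGES",
]

DEFAULT_TRUTH_RANGES = {
    "c10": (30.0, 150.0),
    "k1": (150.0, 1500.0),
    "k2": (20.0, 200.0),
}


@dataclass
class GroundTruth:
    """A known heterogeneous shell: the target of recovery experiments."""

    mesh: TriSurfaceMesh
    thickness: np.ndarray          # per element, mm
    region_labels: np.ndarray      # per element, 1..n_regions
    c10: np.ndarray                # per region values, index r-1
    k1: np.ndarray
    k2: np.ndarray
    kappa: np.ndarray              # per region
    fibers: np.ndarray             # per element 3D mean fiber directions
    seed: int

    @property
    def n_regions(self) -> int:
        return len(self.c10)

    def element_param(self, name: str) -> np.ndarray:
        return getattr(self, name)[self.region_labels - 1]

    def inflation_problem(self, protocol: PressureProtocol) -> InflationProblem:
        """Full-shell problem: rim clamped, hole margin free."""
        nsteps = len(protocol.steps_mmhg)
        rim = self.mesh.rim_nodes
        return InflationProblem(
            self.mesh,
            self.thickness,
            self.element_param("c10"),
            self.element_param("k1"),
            self.element_param("k2"),
            self.element_param("kappa"),
            self.fibers,
            protocol,
            rim,
            np.zeros((nsteps, len(rim), 3)),
        )


def circumferential_fibers(mesh: TriSurfaceMesh) -> np.ndarray:
    """Unit fiber directions circling the apex (z) axis, one per element."""
    cen = mesh.centroids()
    phi = np.arctan2(cen[:, 1], cen[:, 0])
    fib = np.stack([-np.sin(phi), np.cos(phi), np.zeros_like(phi)], axis=1)
    return fib


def make_ground_truth(
    mesh: TriSurfaceMesh,
    n_regions: int = 4,
    param_ranges: dict | None = None,
    seed: int = 0,
    layout: str = "sectors",
    kappas=None,
    thickness: float | np.ndarray = 1.0,
) -> GroundTruth:
    """Draw a region-wise constant heterogeneous parameter map.

    ``layout='sectors'`` splits the shell into equal azimuthal sectors;
    ``layout='bands'`` into polar bands with equal element counts (so an
    equal-count percentile partition can align with the truth regions).
    Parameters are log-uniform within ``param_ranges``; kappa cycles through
    the measured per-subdomain values by default. Deterministic given seed.
    """
    if n_regions < 1:
        raise ParameterError("n_regions must be >= 1")
    if n_regions > mesh.n_triangles:
        raise ParameterError("more regions than elements")
    ranges = dict(DEFAULT_TRUTH_RANGES)
    ranges.update(param_ranges or {})
    rng = np.random.default_rng(seed)

    cen = mesh.centroids()
    if layout == "sectors":
        phi = np.mod(np.arctan2(cen[:, 1], cen[:, 0]), 2 * np.pi)
        labels = 1 + np.minimum((phi / (2 * np.pi) * n_regions).astype(int), n_regions - 1)
    elif layout == "bands":
        theta = np.arccos(np.clip(cen[:, 2] / np.linalg.norm(cen, axis=1), -1, 1))
        order = np.argsort(np.argsort(theta, kind="stable"), kind="stable")
        labels = 1 + (order * n_regions) // mesh.n_triangles
    else:
        raise ParameterError("layout must be 'sectors' or 'bands'")

    draws = {}
    for p in ("c10", "k1", "k2"):
        lo, hi = ranges[p]
        if not (0 < lo < hi):
            raise ParameterError(f"invalid range for {p}")
        draws[p] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_regions))
    if kappas is None:
        kappas = [PAPER_KAPPAS[i % len(PAPER_KAPPAS)] for i in range(n_regions)]
    kappas = np.asarray(kappas, dtype=float)
    if len(kappas) != n_regions or (kappas < 0).any() or (kappas > 1 / 3 + 1e-12).any():
        raise ParameterError("need one kappa in [0, 1/3] per region")

    thickness = np.broadcast_to(np.asarray(thickness, dtype=float), (mesh.n_triangles,)).copy()
    if (thickness <= 0).any():
        raise ParameterError("thickness must be positive")

    return GroundTruth(
        mesh=mesh,
        thickness=thickness,
        region_labels=labels,
        c10=draws["c10"],
        k1=draws["k1"],
        k2=draws["k2"],
        kappa=kappas,
        fibers=circumferential_fibers(mesh),
        seed=seed,
    )


def simulate_inflation_experiment(
    truth: GroundTruth,
    protocol: PressureProtocol,
    noise_sigma: float = 0.005,
    seed: int = 0,
    solver_config: SolverConfig | None = None,
) -> DisplacementField:
    """Forward-simulate the inflation and add S-DIC-like measurement noise.

    Full-shell solve with the rim clamped at each protocol step, then
    independent isotropic Gaussian noise (std ``noise_sigma`` mm) per node,
    component and loading step. The reference step stays exactly zero.
    """
    if noise_sigma < 0:
        raise ParameterError("noise_sigma must be non-negative")
    problem = truth.inflation_problem(protocol)
    result = solve_inflation(problem, solver_config or SolverConfig(sub_increments=2))
    if not result.success:
        from .errors import SolverFailureError

        raise SolverFailureError(f"synthetic forward solve failed: {result.message}")
    u = result.displacements.u.copy()
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        u[1:] += rng.normal(0.0, noise_sigma, size=u[1:].shape)
    return DisplacementField(result.displacements.pressures_mmhg, u)


def make_concentric_point_clouds(
    outer_radius: float,
    inner_radius: float,
    n_points: int = 10_000,
    seed: int = 0,
    outer_subdivisions: int = 4,
):
    """Closed concentric-sphere fixture for the thickness algorithm.

    Returns ``(outer TriSurfaceMesh, inner PointCloud3D)``; the inner cloud is
    a quasi-uniform Fibonacci-sphere sampling of exactly ``n_points`` points at
    ``inner_radius``. Deterministic given seed (a random golden-spiral phase).
    """
    if not (0 < inner_radius < outer_radius):
        raise InvalidGeometryError("require 0 < inner_radius < outer_radius")
    if n_points < 3:
        raise ParameterError("need at least 3 points")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi)

    i = np.arange(n_points)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    phi = golden * i + phase
    pts = inner_radius * np.column_stack([r * np.cos(phi), r * np.sin(phi), z])

    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=outer_subdivisions, radius=outer_radius)
    outer = TriSurfaceMesh(np.asarray(ico.vertices, dtype=float), np.asarray(ico.faces, dtype=int))
    return outer, PointCloud3D(pts)
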