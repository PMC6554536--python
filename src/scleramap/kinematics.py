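"""Surface kinematics: in-plane deformation gradients and Green-Lagrange strain.

Strain is measured element-wise on the shell surface. Each triangle carries a
local orthonormal frame (first axis along its first edge, second in-plane
perpendicular) in both the reference and the deformed configuration; the 2x2
in-plane deformation gradient F maps reference local edge coordinates to
deformed ones. E = 0.5 (F^T F - I) and the first principal strain E1 is the
larger eigenvalue of E. Rigid-body motion therefore produces E = 0 exactly
(up to round-off), and eigenvalues are invariant to the frame convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, SingularElementError
from .mesh import TriSurfaceMesh

__all__ = [
    "DisplacementField",
    "element_deformation_gradient",
    "green_lagrange_strain",
    "first_principal_strain",
    "accumulate_displacements",
    "local_edge_matrix",
    "strain_field",
]


@dataclass
class DisplacementField:
    """Per-node displacements (mm) at each pressure step, relative to reference.

    ``u`` has shape (n_steps, n_nodes, 3); ``pressures_mmhg`` are strictly
    increasing and the first entry is the reference pressure with u == 0.
    """

    pressures_mmhg: np.ndarray
    u: np.ndarray

    def __post_init__(self):
        self.pressures_mmhg = np.asarray(self.pressures_mmhg, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 3 or self.u.shape[2] != 3:
            raise ParameterError("u must have shape (n_steps, n_nodes, 3)")
        if len(self.pressures_mmhg) != self.u.shape[0]:
            raise ParameterError("one pressure label per step required")
        if (np.diff(self.pressures_mmhg) <= 0).any():
            raise ParameterError("pressure labels must be strictly increasing")
        if np.abs(self.u[0]).max(initial=0.0) != 0.0:
            raise ParameterError("reference-step displacement must be identically zero")

    @property
    def n_nodes(self) -> int:
        return self.u.shape[1]

    @property
    def n_steps(self) -> int:
        return self.u.shape[0]

    def step(self, index: int) -> np.ndarray:
        return self.u[index]


def local_edge_matrix(mesh: TriSurfaceMesh, positions: np.ndarray | None = None):
    """Per-element 2x2 local edge matrices G and the frames (e1, e2).

    Columns of G are the two edge vectors expressed in the element's local
    orthonormal frame. det G = 2 * area > 0 for non-degenerate triangles.
    """
    ev = mesh.edge_vectors(positions)  # (m, 2, 3)
    a1, a2 = ev[:, 0], ev[:, 1]
    n = np.cross(a1, a2)
    nn = np.linalg.norm(n, axis=1)
    bad = nn <= 1e-14
    if bad.any():
        raise SingularElementError(
            f"degenerate triangle {int(np.argmax(bad))} in configuration", int(np.argmax(bad))
        )
    e1 = a1 / np.linalg.norm(a1, axis=1)[:, None]
    e2 = np.cross(n / nn[:, None], e1)
    G = np.empty((mesh.n_triangles, 2, 2))
    G[:, 0, 0] = np.einsum("ij,ij->i", a1, e1)
    G[:, 0, 1] = np.einsum("ij,ij->i", a2, e1)
    G[:, 1, 0] = 0.0
    G[:, 1, 1] = np.einsum("ij,ij->i", a2, e2)
    return G, e1, e2


def element_deformation_gradient(
    mesh: TriSurfaceMesh, deformed_positions: np.ndarray
) -> np.ndarray:
    """In-plane 2x2 deformation gradient per element; det F > 0 guaranteed."""
    deformed_positions = np.asarray(deformed_positions, dtype=float)
    if not np.isfinite(deformed_positions).all():
        raise ParameterError("deformed positions must be finite")
    G_ref, _, _ = local_edge_matrix(mesh)
    G_def, _, _ = local_edge_matrix(mesh, deformed_positions)
    return G_def @ np.linalg.inv(G_ref)


def green_lagrange_strain(F: np.ndarray) -> np.ndarray:
    """E = 0.5 (F^T F - I), exactly symmetric; accepts (2,2) or (m,2,2)."""
    F = np.asarray(F, dtype=float)
    single = F.ndim == 2
    Fb = F[None] if single else F
    if (np.linalg.det(Fb) <= 0).any():
        raise SingularElementError(
            f"non-positive det F at element {int(np.argmax(np.linalg.det(Fb) <= 0))}",
            int(np.argmax(np.linalg.det(Fb) <= 0)),
        )
    C = np.einsum("mki,mkj->mij", Fb, Fb)
    E = 0.5 * (C - np.eye(2))
    E = 0.5 * (E + np.swapaxes(E, -1, -2))  # enforce exact symmetry
    return E[0] if single else E


def first_principal_strain(E: np.ndarray, sym_tol: float = 1e-10) -> np.ndarray:
    """Largest eigenvalue of the symmetric 2x2 strain; (m,2,2) -> (m,)."""
    E = np.asarray(E, dtype=float)
    single = E.ndim == 2
    Eb = E[None] if single else E
    asym = np.abs(Eb[:, 0, 1] - Eb[:, 1, 0])
    if (asym > sym_tol).any():
        raise ParameterError(
            f"strain tensor not symmetric (max |E12 - E21| = {asym.max():.3g})"
        )
    tr = Eb[:, 0, 0] + Eb[:, 1, 1]
    det = Eb[:, 0, 0] * Eb[:, 1, 1] - Eb[:, 0, 1] * Eb[:, 1, 0]
    disc = np.sqrt(np.maximum((tr / 2) ** 2 - det, 0.0))
    e1 = tr / 2 + disc
    return float(e1[0]) if single else e1


def accumulate_displacements(fields: list[DisplacementField]) -> DisplacementField:
    """Sum per-step displacement increments into a total reference->final field."""
    if not fields:
        raise ParameterError("no displacement fields to accumulate")
    n = fields[0].n_nodes
    for f in fields:
        if f.n_nodes != n:
            raise ParameterError("mismatched node counts across increments")
    total = np.zeros((2, n, 3))
    for f in fields:
        total[1] += f.u[-1]
    p0 = fields[0].pressures_mmhg[0]
    p1 = fields[-1].pressures_mmhg[-1]
    if p1 <= p0:
        p1 = p0 + 1.0
    return DisplacementField(np.array([p0, p1]), total)


def strain_field(
    mesh: TriSurfaceMesh,
    displacement: np.ndarray,
    smooth_iterations: int = 0,
    smooth_factor: float = 0.5,
) -> np.ndarray:
    """Per-element first principal strain for a nodal displacement (n, 3).

    Displacement smoothing (the subdomain-partition preprocessor) is applied to
    the nodal displacement components before differentiation when
    ``smooth_iterations > 0``; strain itself is never smoothed.
    """
    from .mesh import smooth_surface_field

    u = np.asarray(displacement, dtype=float)
    if smooth_iterations > 0:
        u = smooth_surface_field(mesh, u, iterations=smooth_iterations, factor=smooth_factor)
    F = element_deformation_gradient(mesh, mesh.nodes + u)
    return first_principal_strain(green_lagrange_strain(F))
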