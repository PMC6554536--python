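"""Strain-percentile subdomain partitioning and subdomain problem extraction.

The shell is split into K subdomains by equal-count percentile binning of the
min-max normalized per-element first principal strain. One-element-wide strips
of a label caught between other labels ("single-layer regions") are reassigned
to the neighboring subdomain whose adjacent elements' strain is closest to the
strip's. Each subdomain then becomes an independent inverse problem: its
boundary nodes carry prescribed experimental displacements while interior
nodes are free and provide the fit residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .errors import DegenerateSubdomainError, ParameterError
from .forward import InflationProblem, PressureProtocol
from .kinematics import DisplacementField
from .mesh import TriSurfaceMesh

logger = logging.getLogger(__name__)

__all__ = [
    "SubdomainLabeling",
    "SubdomainProblem",
    "partition_by_strain_percentile",
    "find_single_layer_regions",
    "reassign_single_layer",
    "extract_subdomain_problem",
]


@dataclass
class SubdomainLabeling:
    """Per-element labels in 1..K plus the percentile edges that produced them."""

    labels: np.ndarray
    edges: np.ndarray  # K-1 interior cut points in (0, 1), normalized strain
    K: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.edges = np.asarray(self.edges, dtype=float)
        present = np.unique(self.labels)
        if present.min(initial=1) < 1 or present.max(initial=self.K) > self.K:
            raise ParameterError("labels must lie in 1..K")

    def elements_of(self, label: int) -> np.ndarray:
        return np.where(self.labels == label)[0]


def partition_by_strain_percentile(
    E1: np.ndarray, K: int, edges: np.ndarray | None = None
) -> SubdomainLabeling:
    """Bin elements into K subdomains by normalized first principal strain.

    Strain is min-max normalized to [0, 1]. With ``edges=None`` equal-count
    percentile bins are used (ties at bin boundaries go to the lower bin via a
    stable sort on value then element index); explicit ``edges`` are K-1
    strictly increasing interior cut points on the normalized scale.
    """
    E1 = np.asarray(E1, dtype=float)
    if not np.isfinite(E1).all():
        raise ParameterError("E1 must be finite")
    m = len(E1)
    if K < 1:
        raise ParameterError("K must be >= 1")
    if K > m:
        raise ParameterError(f"K = {K} exceeds element count {m}")
    span = E1.max() - E1.min()
    if K > 1 and span == 0:
        raise ParameterError("all-equal strain field cannot be partitioned (K > 1)")
    norm = (E1 - E1.min()) / span if span > 0 else np.zeros(m)

    if edges is not None:
        edges = np.asarray(edges, dtype=float)
        if len(edges) != K - 1 or (np.diff(edges) <= 0).any() or edges.min(initial=1) <= 0 or edges.max(initial=0) >= 1:
            raise ParameterError("edges must be K-1 strictly increasing values in (0, 1)")
        labels = 1 + np.searchsorted(edges, norm, side="left")
        return SubdomainLabeling(labels, edges, K)

    order = np.lexsort((np.arange(m), norm))  # stable: value then index
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(m)
    labels = 1 + (ranks * K) // m
    cut_ranks = [(m * b) // K for b in range(1, K)]
    used_edges = np.array([norm[order[r]] for r in cut_ranks])
    return SubdomainLabeling(labels, used_edges, K)


def find_single_layer_regions(
    labeling: SubdomainLabeling, adjacency: list[np.ndarray]
) -> list[np.ndarray]:
    """Maximal same-label connected components with no interior element.

    An element is interior when all its edge neighbors share its label; a
    component consisting entirely of non-interior elements is a single-layer
    strip. Components are returned ordered by their lowest element index.
    """
    labels = labeling.labels
    m = len(labels)
    rows, cols = [], []
    for i, nb in enumerate(adjacency):
        same = nb[labels[nb] == labels[i]]
        rows.extend([i] * len(same))
        cols.extend(same.tolist())
    graph = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m))
    _, comp = connected_components(graph, directed=False)

    interior = np.array(
        [len(nb) > 0 and (labels[nb] == labels[i]).all() for i, nb in enumerate(adjacency)]
    )
    strips = []
    for cid in np.unique(comp):
        members = np.where(comp == cid)[0]
        if not interior[members].any():
            strips.append(members)
    strips.sort(key=lambda s: int(s.min()))
    return strips


def reassign_single_layer(
    labeling: SubdomainLabeling,
    strips: list[np.ndarray],
    E1: np.ndarray,
    adjacency: list[np.ndarray],
    max_rounds: int = 100,
) -> SubdomainLabeling:
    """Absorb single-layer strips into the strain-closest neighboring subdomain.

    For each strip the candidate labels are those of edge-adjacent elements
    outside the strip; the winner minimizes |mean E1 of its adjacent elements -
    mean E1 of the strip| with ties going to the lower label. Detection and
    reassignment repeat until no single-layer region remains.
    """
    E1 = np.asarray(E1, dtype=float)
    labels = labeling.labels.copy()
    current = strips
    for _ in range(max_rounds):
        if not current:
            break
        changed = False
        for strip in current:
            in_strip = np.zeros(len(labels), dtype=bool)
            in_strip[strip] = True
            touching: dict[int, list[int]] = {}
            for el in strip:
                for nb in adjacency[el]:
                    if not in_strip[nb]:
                        touching.setdefault(int(labels[nb]), []).append(int(nb))
            if not touching:
                logger.warning(
                    "single-layer region %s has no neighboring subdomain; left unchanged",
                    strip[:5],
                )
                continue
            strip_mean = E1[strip].mean()
            best = min(
                touching.items(),
                key=lambda kv: (abs(E1[np.unique(kv[1])].mean() - strip_mean), kv[0]),
            )[0]
            labels[strip] = best
            changed = True
        lab = SubdomainLabeling(labels, labeling.edges, labeling.K)
        current = find_single_layer_regions(lab, adjacency)
        if not changed and current:
            break  # only isolated unreassignable strips remain
    return SubdomainLabeling(labels, labeling.edges, labeling.K)


def split_into_connected_components(
    labeling: SubdomainLabeling, adjacency: list[np.ndarray]
) -> SubdomainLabeling:
    """Relabel each spatially disconnected piece of a bin as its own subdomain.

    By default a percentile bin is one subdomain even if disconnected; this
    optional step gives every edge-connected component its own label
    (ordered by lowest element index), trading more optimization problems
    for strictly local parameter support.
    """
    labels = labeling.labels
    m = len(labels)
    rows, cols = [], []
    for i, nb in enumerate(adjacency):
        same = nb[labels[nb] == labels[i]]
        rows.extend([i] * len(same))
        cols.extend(same.tolist())
    graph = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m))
    _, comp = connected_components(graph, directed=False)
    order = sorted(np.unique(comp), key=lambda c: int(np.argmax(comp == c)))
    remap = {c: i + 1 for i, c in enumerate(order)}
    new_labels = np.array([remap[c] for c in comp])
    return SubdomainLabeling(new_labels, labeling.edges, int(new_labels.max()))


@dataclass
class SubdomainProblem:
    """One subdomain's inverse problem in its own (re-indexed) node numbering."""

    subdomain_id: int
    elements: np.ndarray           # global element indices
    mesh: TriSurfaceMesh           # sub-mesh, local numbering
    node_map: np.ndarray           # local -> global node index
    interior_nodes: np.ndarray     # local indices
    boundary_nodes: np.ndarray     # local indices
    prescribed_u: np.ndarray       # (n_loading_steps, n_boundary, 3)
    target_u: np.ndarray           # (n_loading_steps, n_interior, 3)
    thickness: np.ndarray
    fibers: np.ndarray             # (m_sub, 3)
    kappa: np.ndarray              # (m_sub,)
    protocol: PressureProtocol

    def problem_for(self, c10: float, k1: float, k2: float) -> InflationProblem:
        """Forward problem for a candidate homogeneous parameter set.

        The measured displacements seed the Newton predictor: they are the
        correct boundary layer for any candidate parameters and a good
        interior start near the optimum.
        """
        nsteps = len(self.protocol.steps_mmhg)
        guess = np.zeros((nsteps, self.mesh.n_nodes, 3))
        guess[:, self.boundary_nodes, :] = self.prescribed_u
        guess[:, self.interior_nodes, :] = self.target_u
        return InflationProblem(
            self.mesh,
            self.thickness,
            c10,
            k1,
            k2,
            self.kappa,
            self.fibers,
            self.protocol,
            self.boundary_nodes,
            self.prescribed_u,
            initial_guess=guess,
        )


def extract_subdomain_problem(
    mesh: TriSurfaceMesh,
    labeling: SubdomainLabeling,
    subdomain_id: int,
    experimental: DisplacementField,
    thickness: np.ndarray,
    fibers: np.ndarray,
    kappa,
    protocol: PressureProtocol,
) -> SubdomainProblem:
    """Cut out one subdomain with experimental displacements as its BCs.

    Boundary nodes are subdomain nodes either shared with another subdomain or
    lying on the global rim/hole boundary; they receive the experimental
    displacements as prescribed values per loading step. Interior nodes are
    free; their experimental displacements become the fit targets.
    """
    if not (1 <= subdomain_id <= labeling.K):
        raise ParameterError(f"subdomain id {subdomain_id} not in 1..{labeling.K}")
    els = labeling.elements_of(subdomain_id)
    if len(els) == 0:
        raise DegenerateSubdomainError(f"subdomain {subdomain_id} has no elements")

    tris = mesh.triangles[els]
    sub_nodes = np.unique(tris)
    g2l = -np.ones(mesh.n_nodes, dtype=int)
    g2l[sub_nodes] = np.arange(len(sub_nodes))

    other_els = np.setdiff1d(np.arange(mesh.n_triangles), els, assume_unique=False)
    other_nodes = set(np.unique(mesh.triangles[other_els]).tolist()) if len(other_els) else set()
    global_bnd = set(mesh.rim_nodes.tolist()) | set(mesh.hole_nodes.tolist())
    boundary_global = np.array(
        sorted(n for n in sub_nodes.tolist() if n in other_nodes or n in global_bnd), dtype=int
    )
    interior_global = np.setdiff1d(sub_nodes, boundary_global)
    if len(interior_global) == 0:
        raise DegenerateSubdomainError(
            f"subdomain {subdomain_id} has no interior nodes; no residual can be formed"
        )

    sub_mesh = TriSurfaceMesh(
        mesh.nodes[sub_nodes],
        g2l[tris],
        rim_nodes=g2l[np.intersect1d(sub_nodes, mesh.rim_nodes)],
        hole_nodes=g2l[np.intersect1d(sub_nodes, mesh.hole_nodes)],
    )
    thickness = np.broadcast_to(np.asarray(thickness, float), (mesh.n_triangles,))
    fibers = np.broadcast_to(np.asarray(fibers, float), (mesh.n_triangles, 3))
    kappa_arr = np.broadcast_to(np.asarray(kappa, float), (mesh.n_triangles,))

    loading_u = experimental.u[1:]  # skip reference step
    if loading_u.shape[0] != len(protocol.steps_mmhg):
        raise ParameterError("experimental field steps do not match the protocol")
    return SubdomainProblem(
        subdomain_id=subdomain_id,
        elements=els,
        mesh=sub_mesh,
        node_map=sub_nodes,
        interior_nodes=g2l[interior_global],
        boundary_nodes=g2l[boundary_global],
        prescribed_u=loading_u[:, boundary_global, :],
        target_u=loading_u[:, interior_global, :],
        thickness=thickness[els],
        fibers=fibers[els],
        kappa=kappa_arr[els],
        protocol=protocol,
    )
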