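"""Triangulated shell meshes: construction, adjacency, and field smoothing.

The shell is a manifold-with-boundary triangle surface with two distinguished
boundary loops: the clamped base rim (equator of the posterior shell) and the
margin of the optic-nerve-head excision hole. Triangle winding is consistent
and chosen so that geometric normals point outward (away from the shell
interior), which fixes the sign conventions for inflation pressure and for the
normal-projection thickness algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

from .errors import InvalidGeometryError, NonManifoldError, ParameterError

__all__ = [
    "TriSurfaceMesh",
    "PointCloud3D",
    "build_edge_adjacency",
    "generate_hemisphere_shell",
    "smooth_surface_field",
    "refine_mesh",
]

_AREA_EPS = 1e-12


@dataclass
class PointCloud3D:
    """A bag of 3D points in mm."""

    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) == 0:
            raise InvalidGeometryError("point cloud must be a non-empty (n, 3) array")
        if not np.isfinite(self.points).all():
            raise InvalidGeometryError("point cloud contains non-finite coordinates")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class TriSurfaceMesh:
    """Shared-vertex triangle shell.

    Attributes
    ----------
    nodes : (n, 3) float array, coordinates in mm.
    triangles : (m, 3) int array, outward-consistent winding.
    rim_nodes : sorted int array, nodes on the clamped base boundary.
    hole_nodes : sorted int array, nodes on the ONH-margin boundary.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    rim_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    hole_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self):
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        self.rim_nodes = np.asarray(sorted(set(np.asarray(self.rim_nodes, dtype=int).tolist())), dtype=np.int64)
        self.hole_nodes = np.asarray(sorted(set(np.asarray(self.hole_nodes, dtype=int).tolist())), dtype=np.int64)
        self.validate()

    # -- basic queries -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def edge_vectors(self, positions: np.ndarray | None = None):
        """Edge vectors (x1-x0, x2-x0) per triangle, shape (m, 2, 3)."""
        x = self.nodes if positions is None else positions
        t = self.triangles
        return np.stack([x[t[:, 1]] - x[t[:, 0]], x[t[:, 2]] - x[t[:, 0]]], axis=1)

    def normals_area(self, positions: np.ndarray | None = None):
        """(unit normals, areas) per triangle for the given configuration."""
        ev = self.edge_vectors(positions)
        cr = np.cross(ev[:, 0], ev[:, 1])
        a2 = np.linalg.norm(cr, axis=1)
        return cr / a2[:, None], 0.5 * a2

    def areas(self, positions: np.ndarray | None = None):
        return self.normals_area(positions)[1]

    def centroids(self, positions: np.ndarray | None = None):
        x = self.nodes if positions is None else positions
        return x[self.triangles].mean(axis=1)

    def boundary_nodes(self) -> np.ndarray:
        """All nodes on edges used by exactly one triangle."""
        e, cnt = _edge_counts(self.triangles)
        return np.unique(e[cnt == 1])

    def node_adjacency(self):
        """List of neighboring node indices per node (mesh edges)."""
        if not hasattr(self, "_node_adj"):
            neigh = [set() for _ in range(self.n_nodes)]
            for a, b, c in self.triangles:
                neigh[a].update((b, c))
                neigh[b].update((a, c))
                neigh[c].update((a, b))
            self._node_adj = [np.asarray(sorted(s), dtype=int) for s in neigh]
        return self._node_adj

    # -- validation ----------------------------------------------------

    def validate(self):
        n, t = self.nodes, self.triangles
        if n.ndim != 2 or n.shape[1] != 3:
            raise InvalidGeometryError("nodes must be (n, 3)")
        if t.ndim != 2 or t.shape[1] != 3:
            raise InvalidGeometryError("triangles must be (m, 3)")
        if t.min(initial=0) < 0 or (len(t) and t.max() >= len(n)):
            raise InvalidGeometryError("triangle references an invalid node index")
        if len(t):
            if (t[:, 0] == t[:, 1]).any() or (t[:, 0] == t[:, 2]).any() or (t[:, 1] == t[:, 2]).any():
                raise InvalidGeometryError("triangle with repeated node indices")
            _, areas = _raw_areas(n, t)
            if (areas <= _AREA_EPS).any():
                bad = int(np.argmax(areas <= _AREA_EPS))
                raise InvalidGeometryError(f"degenerate (zero-area) triangle at index {bad}")
            _check_winding(t)

    def euler_characteristic(self) -> int:
        e, _ = _edge_counts(self.triangles)
        return self.n_nodes - len(e) + self.n_triangles


def _raw_areas(nodes, tris):
    ev1 = nodes[tris[:, 1]] - nodes[tris[:, 0]]
    ev2 = nodes[tris[:, 2]] - nodes[tris[:, 0]]
    cr = np.cross(ev1, ev2)
    return cr, 0.5 * np.linalg.norm(cr, axis=1)


def _edge_counts(tris):
    """Unique undirected edges and their incidence counts."""
    e = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    e = np.sort(e, axis=1)
    e, cnt = np.unique(e, axis=0, return_counts=True)
    return e, cnt


def _check_winding(tris):
    """Neighboring triangles must traverse a shared edge in opposite order."""
    directed = {}
    undirected: dict[tuple[int, int], int] = {}
    for it, (a, b, c) in enumerate(tris):
        for u, v in ((a, b), (b, c), (c, a)):
            key = (u, v) if u < v else (v, u)
            undirected[key] = undirected.get(key, 0) + 1
            if undirected[key] > 2:
                raise NonManifoldError(f"edge {key} shared by more than 2 triangles")
            if (u, v) in directed:
                raise InvalidGeometryError(
                    f"inconsistent winding: directed edge ({u},{v}) appears twice "
                    f"(triangles {directed[(u, v)]} and {it})"
                )
            directed[(u, v)] = it


def build_edge_adjacency(mesh: TriSurfaceMesh) -> list[np.ndarray]:
    """Edge-neighboring triangles per triangle (0-3 entries each).

    Raises :class:`NonManifoldError` if any edge is shared by more than two
    triangles. Adjacency is symmetric by construction.
    """
    tris = mesh.triangles
    owner: dict[tuple[int, int], list[int]] = {}
    for it, (a, b, c) in enumerate(tris):
        for u, v in ((a, b), (b, c), (c, a)):
            key = (u, v) if u < v else (v, u)
            owner.setdefault(key, []).append(it)
    neigh = [[] for _ in range(len(tris))]
    for key, owners in owner.items():
        if len(owners) > 2:
            raise NonManifoldError(f"edge {key} shared by {len(owners)} triangles")
        if len(owners) == 2:
            i, j = owners
            neigh[i].append(j)
            neigh[j].append(i)
    return [np.asarray(sorted(s), dtype=int) for s in neigh]


def adjacency_matrix(adjacency: list[np.ndarray]):
    """Sparse symmetric element-adjacency matrix (scipy CSR)."""
    from scipy import sparse

    rows, cols = [], []
    for i, nb in enumerate(adjacency):
        rows.extend([i] * len(nb))
        cols.extend(nb.tolist())
    m = len(adjacency)
    return sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m))


# ---------------------------------------------------------------------------
# Hemisphere generation
# ---------------------------------------------------------------------------

def generate_hemisphere_shell(
    radius: float,
    hole_radius: float,
    target_edge_length: float,
    seed: int = 0,
) -> TriSurfaceMesh:
    """Triangulated hemispherical cap with an apical hole.

    The cap spans polar angles from the hole margin (``asin(hole_radius /
    radius)``, or the pole when ``hole_radius == 0``) to the equator. Nodes are
    laid out on concentric rings of a Lambert equal-area planar parameterization
    and triangulated with a 2D Delaunay; triangles filling the hole are removed.
    ``rim_nodes`` lie on the equator, ``hole_nodes`` on the hole margin.

    The planar triangulation is counter-clockwise, so the lifted mesh winds
    consistently with outward (radially away from the center) normals.
    """
    if not (0 <= hole_radius < radius):
        raise InvalidGeometryError("require 0 <= hole_radius < radius")
    if target_edge_length <= 0:
        raise ParameterError("target_edge_length must be positive")

    rng = np.random.default_rng(seed)
    theta0 = float(np.arcsin(min(hole_radius / radius, 1.0)))
    theta1 = np.pi / 2
    # equal-area planar radius s(theta) = 2 R sin(theta/2)
    s0 = 2 * radius * np.sin(theta0 / 2)
    s1 = 2 * radius * np.sin(theta1 / 2)

    arc = radius * (theta1 - theta0)
    n_rings = max(2, int(round(arc / target_edge_length)) + 1)
    thetas = np.linspace(theta0, theta1, n_rings)
    svals = 2 * radius * np.sin(thetas / 2)

    pts2d = []
    ring_of = []
    has_hole = hole_radius > 0
    start = 0
    if not has_hole:
        pts2d.append((0.0, 0.0))
        ring_of.append(0)
        start = 1
    for k in range(start, n_rings):
        s = svals[k]
        circ = 2 * np.pi * radius * np.sin(thetas[k])
        n_phi = max(4, int(round(circ / target_edge_length)))
        phase = rng.uniform(0, 2 * np.pi)
        phis = phase + 2 * np.pi * np.arange(n_phi) / n_phi
        for p in phis:
            pts2d.append((s * np.cos(p), s * np.sin(p)))
            ring_of.append(k)
    pts2d = np.asarray(pts2d)
    ring_of = np.asarray(ring_of)

    tri = Delaunay(pts2d)
    simplices = tri.simplices.copy()
    # Qhull may return clockwise simplices; orient all counter-clockwise.
    v1 = pts2d[simplices[:, 1]] - pts2d[simplices[:, 0]]
    v2 = pts2d[simplices[:, 2]] - pts2d[simplices[:, 0]]
    cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    flip = cross < 0
    simplices[flip] = simplices[flip][:, [0, 2, 1]]

    if has_hole:
        cen = pts2d[simplices].mean(axis=1)
        inner = ring_of[simplices].max(axis=1) == 0
        inside = np.linalg.norm(cen, axis=1) < s0 * (1 - 1e-9)
        keep = ~(inner & inside)
        simplices = simplices[keep]
        cross = cross[keep] if len(cross) == len(keep) else None

    # drop sliver triangles from near-cocircular ring points
    v1 = pts2d[simplices[:, 1]] - pts2d[simplices[:, 0]]
    v2 = pts2d[simplices[:, 2]] - pts2d[simplices[:, 0]]
    area2 = np.abs(v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])
    simplices = simplices[area2 > 1e-10 * target_edge_length**2]

    used = np.unique(simplices)
    remap = -np.ones(len(pts2d), dtype=int)
    remap[used] = np.arange(len(used))
    simplices = remap[simplices]
    pts2d = pts2d[used]
    ring_of = ring_of[used]

    # lift: s -> theta, keep azimuth
    s = np.linalg.norm(pts2d, axis=1)
    with np.errstate(invalid="ignore"):
        phi = np.arctan2(pts2d[:, 1], pts2d[:, 0])
    theta = 2 * np.arcsin(np.clip(s / (2 * radius), 0, 1))
    nodes = np.column_stack(
        [
            radius * np.sin(theta) * np.cos(phi),
            radius * np.sin(theta) * np.sin(phi),
            radius * np.cos(theta),
        ]
    )
    nodes[s == 0] = [0.0, 0.0, radius]

    rim = np.where(ring_of == n_rings - 1)[0]
    hole = np.where(ring_of == 0)[0] if has_hole else np.empty(0, dtype=int)

    # planar CCW (seen from +z, i.e. from outside near the apex) lifts to
    # outward normals; verify rather than flip per-triangle.
    mesh = TriSurfaceMesh(nodes, simplices, rim_nodes=rim, hole_nodes=hole)
    normals, _ = mesh.normals_area()
    cen = mesh.centroids()
    if (np.einsum("ij,ij->i", normals, cen) <= 0).any():
        raise InvalidGeometryError("internal error: inward-pointing triangle after lift")
    return mesh


def refine_mesh(mesh: TriSurfaceMesh, project=None) -> TriSurfaceMesh:
    """One uniform 1:4 midpoint refinement.

    ``project`` optionally maps new midpoint coordinates onto the underlying
    smooth surface (e.g. radial projection for a sphere).
    """
    nodes = mesh.nodes.tolist()
    mid_cache: dict[tuple[int, int], int] = {}

    def midpoint(a, b):
        key = (a, b) if a < b else (b, a)
        if key not in mid_cache:
            p = 0.5 * (mesh.nodes[a] + mesh.nodes[b])
            if project is not None:
                p = project(p)
            mid_cache[key] = len(nodes)
            nodes.append(np.asarray(p, dtype=float).tolist())
        return mid_cache[key]

    tris = []
    for a, b, c in mesh.triangles:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        tris.extend([[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]])

    new_nodes = np.asarray(nodes)
    new_tris = np.asarray(tris, dtype=int)

    def lift_boundary(old_set):
        old = set(int(i) for i in old_set)
        out = set(old)
        for (a, b), m in mid_cache.items():
            if a in old and b in old:
                out.add(m)
        return np.asarray(sorted(out), dtype=int)

    return TriSurfaceMesh(
        new_nodes,
        new_tris,
        rim_nodes=lift_boundary(mesh.rim_nodes),
        hole_nodes=lift_boundary(mesh.hole_nodes),
    )


# ---------------------------------------------------------------------------
# Surface-field smoothing
# ---------------------------------------------------------------------------

def smooth_surface_field(
    mesh: TriSurfaceMesh,
    fld: np.ndarray,
    iterations: int = 25,
    factor: float = 0.5,
    adjacency: list[np.ndarray] | None = None,
    method: str = "laplacian",
    hc_alpha: float = 0.1,
) -> np.ndarray:
    """Iterative uniform-weight neighbor-averaging (Laplacian) relaxation.

    Works on per-node fields (length ``n_nodes``; neighbors via mesh edges) or
    per-element fields (length ``n_triangles``; neighbors via shared edges).
    Each sweep replaces a value by ``(1 - factor) * value + factor * mean of
    neighbors``, so the default output obeys the discrete maximum principle:
    every component stays within the [min, max] of the input.

    ``method="hc"`` adds a Humphrey-class back-projection after each sweep
    (correction by ``alpha d + (1 - alpha) mean of neighbor d`` with
    ``d = smoothed - input``), which counteracts the shrinkage of plain
    Laplacian smoothing at the cost of the strict maximum principle.
    """
    fld = np.asarray(fld, dtype=float)
    if iterations < 0:
        raise ParameterError("iterations must be >= 0")
    if not (0 < factor <= 1):
        raise ParameterError("factor must lie in (0, 1]")
    if len(fld) == mesh.n_nodes:
        neigh = mesh.node_adjacency()
    elif len(fld) == mesh.n_triangles:
        neigh = adjacency if adjacency is not None else build_edge_adjacency(mesh)
    else:
        raise ParameterError(
            f"field length {len(fld)} matches neither node count {mesh.n_nodes} "
            f"nor element count {mesh.n_triangles}"
        )
    if iterations == 0:
        return fld.copy()

    from scipy import sparse

    rows, cols, vals = [], [], []
    for i, nb in enumerate(neigh):
        if len(nb) == 0:
            continue
        rows.extend([i] * len(nb))
        cols.extend(nb.tolist())
        vals.extend([1.0 / len(nb)] * len(nb))
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(len(fld), len(fld)))
    isolated = np.asarray([len(nb) == 0 for nb in neigh])

    if method not in ("laplacian", "hc"):
        raise ParameterError("method must be 'laplacian' or 'hc'")
    out = fld.copy()
    for _ in range(iterations):
        avg = A @ out
        new = (1 - factor) * out + factor * avg
        if method == "hc":
            d = new - fld
            new = new - (hc_alpha * d + (1 - hc_alpha) * (A @ d))
        if isolated.any():
            new[isolated] = out[isolated]
        out = new
    return out
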