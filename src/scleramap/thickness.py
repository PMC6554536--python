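"""Normal-projection shell thickness from an interior point cloud.

For every triangle of the exterior surface the inward normal ray is cast from
the element centroid toward the interior boundary point cloud. The foot of the
ray on the cloud is located (projection of the ray-nearest cloud point), the
three cloud points closest to that foot define a plane, and the perpendicular
distance from the centroid to that plane is the local wall thickness. Using
the foot point rather than raw ray-line distance keeps the three points
azimuthally spread around the ray; three nearest-to-line points from a
structured cloud can be nearly collinear, which makes the fitted plane's tilt
arbitrary.
"""

from __future__ import annotations

import numpy as np

from .errors import FlaggedElementError, InsufficientDataError
from .mesh import PointCloud3D, TriSurfaceMesh

__all__ = ["compute_thickness"]


def compute_thickness(
    outer_mesh: TriSurfaceMesh,
    inner_cloud: PointCloud3D,
    chunk: int = 256,
) -> np.ndarray:
    """Per-element thickness (mm) of the shell.

    Parameters
    ----------
    outer_mesh : exterior surface with outward-consistent winding.
    inner_cloud : points sampled on the interior boundary; >= 3 required.
    chunk : elements processed per vectorized block (memory/speed knob).

    Returns
    -------
    (n_triangles,) array of strictly positive thickness values.

    Raises
    ------
    InsufficientDataError : fewer than 3 interior points.
    FlaggedElementError : an element produced a non-positive thickness.
    """
    pts = inner_cloud.points
    if len(pts) < 3:
        raise InsufficientDataError("thickness needs at least 3 interior points")

    normals, _ = outer_mesh.normals_area()
    centroids = outer_mesh.centroids()
    inward = -normals

    m = len(centroids)
    thickness = np.empty(m)
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        c = centroids[lo:hi]          # (b, 3)
        d = inward[lo:hi]             # (b, 3)
        rel = pts[None, :, :] - c[:, None, :]          # (b, p, 3)
        t = np.einsum("bpk,bk->bp", rel, d)            # ray parameter
        perp = rel - t[..., None] * d[:, None, :]
        dist2 = np.einsum("bpk,bpk->bp", perp, perp)
        # points behind the centroid cannot be the interior wall
        dist2 = np.where(t > 0, dist2, np.inf)
        # foot = first intersection of the ray with the cloud: among the
        # nearest-to-ray candidates take the smallest positive ray parameter
        # (a closed cloud is crossed twice; the far crossing must be ignored)
        k = min(8, dist2.shape[1])
        cand = np.argpartition(dist2, k - 1, axis=1)[:, :k]
        rows = np.arange(hi - lo)[:, None]
        t_cand = np.where(np.isfinite(dist2[rows, cand]), t[rows, cand], np.inf)
        nearest = cand[np.arange(hi - lo), np.argmin(t_cand, axis=1)]
        foot = c + t[np.arange(hi - lo), nearest][:, None] * d
        d2foot = np.einsum("bpk,bpk->bp", pts[None] - foot[:, None], pts[None] - foot[:, None])
        d2foot = np.where(t > 0, d2foot, np.inf)
        kk = min(8, d2foot.shape[1])
        idx8 = np.argpartition(d2foot, kk - 1, axis=1)[:, :kk]
        for j in range(hi - lo):
            order = idx8[j, np.argsort(d2foot[j, idx8[j]])]
            if not np.isfinite(d2foot[j, order[:3]]).all():
                raise FlaggedElementError(
                    f"element {lo + j}: fewer than 3 interior points on the inward side",
                    lo + j,
                )
            tri_pts = _well_conditioned_triple(pts, order)
            h = _point_plane_distance(c[j], tri_pts)
            if not h > 0:
                raise FlaggedElementError(
                    f"element {lo + j}: non-positive thickness {h:.3g} mm", lo + j
                )
            thickness[lo + j] = h
    return thickness


def _well_conditioned_triple(pts: np.ndarray, order: np.ndarray, quality: float = 0.05):
    """Closest three points, skipping third points that are nearly collinear
    with the first two (an ill-conditioned plane's tilt is arbitrary)."""
    p0, p1 = pts[order[0]], pts[order[1]]
    best = pts[order[:3]]
    for j in order[2:]:
        trial = np.array([p0, p1, pts[j]])
        e = np.linalg.norm(
            [trial[1] - trial[0], trial[2] - trial[0], trial[2] - trial[1]], axis=1
        ).max()
        area = 0.5 * np.linalg.norm(np.cross(trial[1] - trial[0], trial[2] - trial[0]))
        if e > 0 and area / e**2 > quality:
            return trial
    return best


def _point_plane_distance(point: np.ndarray, three_points: np.ndarray) -> float:
    """Distance from ``point`` to the (least-squares = exact) plane of 3 points."""
    p0 = three_points.mean(axis=0)
    n = np.cross(three_points[1] - three_points[0], three_points[2] - three_points[0])
    nn = np.linalg.norm(n)
    if nn == 0.0:
        # collinear points: fall back to distance to their centroid
        return float(np.linalg.norm(point - p0))
    return float(abs(np.dot(point - p0, n / nn)))
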