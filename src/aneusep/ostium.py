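"""Ostium reconstruction: the virtual opening surface spanning a neck curve.

The cap is seeded on the least-squares plane of the neck curve (boundary =
the curve points, bit-wise), interior Steiner points are added at roughly a
target edge length, and simple uniform Laplacian smoothing relaxes the
interior towards a smooth membrane while the boundary stays fixed.
Dragging a vertex moves its neighbourhood with a Gaussian falloff.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import Delaunay
from shapely.geometry import Point, Polygon

from .core_mesh import NeckCurve
from .errors import (DegeneratePlaneError, ProjectionError, ValidationError)

__all__ = ["OstiumPatch", "fit_plane", "triangulate_cap", "smooth_patch",
           "drag_vertex", "patch_area"]


@dataclass(frozen=True)
class OstiumPatch:
    """Triangulated disc spanning a neck curve.

    The first ``n_boundary`` vertices are the neck-curve polyline points in
    order (bit-wise identical to the curve); the rest are interior. The
    patch is a topological disc: Euler characteristic 1, one boundary loop.
    """

    vertices: np.ndarray
    faces: np.ndarray
    n_boundary: int
    curve: NeckCurve | None = None

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=np.float64)
        f = np.asarray(self.faces, dtype=np.int64)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        self.validate()

    @property
    def is_boundary(self) -> np.ndarray:
        mask = np.zeros(len(self.vertices), dtype=bool)
        mask[:self.n_boundary] = True
        return mask

    @property
    def boundary_points(self) -> np.ndarray:
        return self.vertices[:self.n_boundary]

    def validate(self) -> None:
        v, f, nb = self.vertices, self.faces, self.n_boundary
        if len(f) == 0 or f.min() < 0 or f.max() >= len(v):
            raise ValidationError("patch faces reference out-of-range vertices")
        if not (3 <= nb <= len(v)):
            raise ValidationError("patch needs >= 3 boundary vertices")
        areas = _areas(v, f)
        if (areas <= 0).any():
            raise ValidationError(
                f"patch triangle {int(np.argmin(areas))} has zero area")
        und = np.sort(np.concatenate(
            [f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1)
        uniq, counts = np.unique(und, axis=0, return_counts=True)
        if (counts > 2).any():
            raise ValidationError("patch is non-manifold")
        # disc topology: V - E + F = 1 and the boundary edges form one loop
        n_used = len(np.unique(f))
        euler = n_used - len(uniq) + len(f)
        if euler != 1:
            raise ValidationError(f"patch is not a disc (Euler characteristic {euler})")
        boundary_edges = uniq[counts == 1]
        if len(boundary_edges) != nb:
            raise ValidationError(
                f"boundary loop has {len(boundary_edges)} edges, expected {nb}")
        if self.curve is not None:
            bp = self.curve.points
            if not (self.boundary_points == bp).all():
                raise ValidationError(
                    "patch boundary must equal the neck-curve points bit-wise")

    def interior_neighbors(self) -> list[np.ndarray]:
        """Adjacency lists over all vertices (used by smoothing/metrics)."""
        nbrs: list[set[int]] = [set() for _ in range(len(self.vertices))]
        for a, b, c in self.faces:
            nbrs[a].update((b, c)); nbrs[b].update((a, c)); nbrs[c].update((a, b))
        return [np.fromiter(sorted(s), dtype=np.int64) for s in nbrs]

    def face_normals(self) -> np.ndarray:
        p = self.vertices[self.faces]
        n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def face_areas(self) -> np.ndarray:
        return _areas(self.vertices, self.faces)

    def oriented(self, toward: np.ndarray) -> "OstiumPatch":
        """Flip winding, if needed, so mean face normal points toward a point."""
        c = self.vertices[self.faces].mean(axis=(0, 1))
        mean_n = self.face_normals().mean(axis=0)
        if mean_n @ (np.asarray(toward, dtype=float) - c) < 0:
            return replace(self, faces=self.faces[:, ::-1].copy())
        return self


def _areas(v: np.ndarray, f: np.ndarray) -> np.ndarray:
    p = v[f]
    return 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)


# ---------------------------------------------------------------------------

def fit_plane(curve: NeckCurve | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane of the curve points.

    Returns (centroid, unit normal); the normal is the direction of least
    spread (smallest principal axis), with a deterministic sign (largest-
    magnitude component positive).
    """
    pts = curve.points if isinstance(curve, NeckCurve) else np.asarray(curve, float)
    if len(pts) < 3:
        raise DegeneratePlaneError("plane fit needs >= 3 points")
    centroid = pts.mean(axis=0)
    q = pts - centroid
    _, s, vt = np.linalg.svd(q, full_matrices=False)
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise DegeneratePlaneError("curve points are (near-)collinear")
    normal = vt[2]
    k = int(np.argmax(np.abs(normal)))
    if normal[k] < 0:
        normal = -normal
    return centroid, normal


def _project_to_plane(points: np.ndarray, centroid: np.ndarray, normal: np.ndarray):
    """In-plane 2-D coordinates plus the orthonormal basis used."""
    ref = np.eye(3)[int(np.argmin(np.abs(normal)))]
    u = np.cross(normal, ref); u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    q = points - centroid
    return np.stack([q @ u, q @ v], axis=1), u, v


def _ear_clip(poly2d: np.ndarray) -> np.ndarray:
    """Ear clipping of a simple polygon (indices into poly2d); O(n^2)."""
    n = len(poly2d)
    idx = list(range(n))
    x, y = poly2d[:, 0], poly2d[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if signed < 0:
        idx = idx[::-1]
    tris = []
    guard = 0
    while len(idx) > 3 and guard < 10 * n * n:
        guard += 1
        m = len(idx)
        clipped = False
        for i in range(m):
            a, b, c = idx[(i - 1) % m], idx[i], idx[(i + 1) % m]
            pa, pb, pc = poly2d[a], poly2d[b], poly2d[c]
            if _cross2(pb - pa, pc - pb) <= 1e-14:
                continue  # reflex or degenerate
            others = [j for j in idx if j not in (a, b, c)]
            if others and _any_inside(poly2d[others], pa, pb, pc):
                continue
            tris.append((a, b, c))
            del idx[i]
            clipped = True
            break
        if not clipped:
            raise ProjectionError("polygon could not be ear-clipped (self-intersecting?)")
    tris.append((idx[0], idx[1], idx[2]))
    return np.asarray(tris, dtype=np.int64)


def _any_inside(pts, a, b, c) -> bool:
    d1 = _cross2(b - a, pts - a)
    d2 = _cross2(c - b, pts - b)
    d3 = _cross2(a - c, pts - c)
    return bool(((d1 > 1e-14) & (d2 > 1e-14) & (d3 > 1e-14)).any())


def triangulate_cap(curve: NeckCurve, target_edge: float | None = None) -> OstiumPatch:
    """Triangulate the disc bounded by the neck curve.

    The curve is projected onto its fitted plane; the projection must be a
    simple polygon (otherwise a :class:`ProjectionError` is raised — the
    caller may subdivide or pre-smooth the curve, we never silently repair).
    Interior Steiner points are seeded on a triangular lattice at roughly
    ``target_edge`` spacing (default: median boundary edge length) and the
    point set is Delaunay-triangulated, keeping triangles inside the
    polygon. Boundary vertices are the curve points, bit-wise.
    """
    bp = curve.points
    nb = len(bp)
    centroid, normal = fit_plane(curve)
    p2, u, v = _project_to_plane(bp, centroid, normal)
    poly = Polygon(p2)
    if not poly.is_valid or poly.area <= 0:
        raise ProjectionError("curve projection self-intersects on the fitted plane")
    if target_edge is None:
        seg = np.linalg.norm(np.diff(np.vstack([p2, p2[:1]]), axis=0), axis=1)
        target_edge = float(np.median(seg))
    if target_edge <= 0:
        raise ValidationError("target_edge must be > 0")

    interior2 = _lattice_inside(poly, target_edge)
    pts2 = np.vstack([p2, interior2]) if len(interior2) else p2

    faces = _constrained_disc(pts2, nb, poly)
    if faces.max() < nb:       # ear-clip fallback used: boundary only
        vertices = bp
    else:
        vertices = np.vstack([
            bp,  # bit-wise boundary
            centroid + interior2[:, :1] * u + interior2[:, 1:] * v,
        ])
    return OstiumPatch(vertices=vertices, faces=faces, n_boundary=nb, curve=curve)


def _lattice_inside(poly: Polygon, spacing: float) -> np.ndarray:
    """Triangular lattice points strictly inside the polygon (margin 0.4h)."""
    minx, miny, maxx, maxy = poly.bounds
    inner = poly.buffer(-0.4 * spacing)
    if inner.is_empty:
        return np.empty((0, 2))
    pts = []
    dy = spacing * np.sqrt(3) / 2
    row = 0
    y = miny + dy
    while y < maxy:
        x0 = minx + (0.5 * spacing if row % 2 else spacing)
        x = x0
        while x < maxx:
            if inner.contains(Point(x, y)):
                pts.append((x, y))
            x += spacing
        y += dy
        row += 1
    return np.asarray(pts) if pts else np.empty((0, 2))


def _constrained_disc(pts2: np.ndarray, nb: int, poly: Polygon) -> np.ndarray:
    """Delaunay of boundary+interior points filtered to the polygon; falls
    back to ear clipping (boundary only) when the filtered complex is not a
    disc whose boundary is the input polygon."""
    try:
        tri = Delaunay(pts2)
        cent = pts2[tri.simplices].mean(axis=1)
        keep = np.fromiter(
            (poly.contains(Point(c)) for c in cent), bool, len(cent))
        faces = tri.simplices[keep]
        faces = _orient_ccw(pts2, faces)
        if len(faces) and _is_disc_with_boundary(faces, nb, len(pts2)):
            return faces
    except Exception:
        pass
    return _orient_ccw(pts2, _ear_clip(pts2[:nb]))


def _cross2(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    return u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]


def _orient_ccw(pts2: np.ndarray, faces: np.ndarray) -> np.ndarray:
    p = pts2[faces]
    signed = _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    out = faces.copy()
    out[signed < 0] = out[signed < 0][:, ::-1]
    return out


def _is_disc_with_boundary(faces: np.ndarray, nb: int, nv: int) -> bool:
    und = np.sort(np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1)
    uniq, counts = np.unique(und, axis=0, return_counts=True)
    if (counts > 2).any():
        return False
    boundary = uniq[counts == 1]
    expected = np.sort(np.stack(
        [np.arange(nb), np.roll(np.arange(nb), -1)], axis=1), axis=1)
    expected = expected[np.lexsort((expected[:, 1], expected[:, 0]))]
    boundary = boundary[np.lexsort((boundary[:, 1], boundary[:, 0]))]
    if boundary.shape != expected.shape or not (boundary == expected).all():
        return False
    used = np.unique(faces)
    if len(used) != nv:   # an interior point was dropped by the filter
        return False
    return (len(used) - len(uniq) + len(faces)) == 1


# ---------------------------------------------------------------------------

def smooth_patch(patch: OstiumPatch, lam: float = 0.5, max_iters: int = 500,
                 tol: float = 1e-4) -> OstiumPatch:
    """Uniform Laplacian smoothing of interior vertices; boundary fixed.

    x <- x + lam * (mean of neighbours - x), iterated until the maximum
    vertex displacement drops below ``tol`` (mm) or ``max_iters`` is hit.
    """
    if not (0 < lam <= 1):
        raise ValidationError("lambda must satisfy 0 < lambda <= 1")
    from scipy.sparse import csr_matrix

    nbrs = patch.interior_neighbors()
    v = patch.vertices.copy()
    interior = np.nonzero(~patch.is_boundary)[0]
    if len(interior) == 0:
        return patch
    rows = np.concatenate([np.full(len(nbrs[i]), k)
                           for k, i in enumerate(interior)])
    cols = np.concatenate([nbrs[i] for i in interior])
    vals = np.concatenate([np.full(len(nbrs[i]), 1.0 / len(nbrs[i]))
                           for i in interior])
    avg = csr_matrix((vals, (rows, cols)), shape=(len(interior), len(v)))
    for _ in range(max_iters):
        disp = lam * (avg @ v - v[interior])
        v[interior] += disp
        if np.abs(disp).max() < tol:
            break
    return replace(patch, vertices=v)


def drag_vertex(patch: OstiumPatch, vertex: int, displacement: np.ndarray,
                falloff_radius: float) -> OstiumPatch:
    """Move an interior vertex; neighbours follow with Gaussian falloff.

    Every other interior vertex at distance d from the dragged vertex's
    original position moves by displacement * exp(-d^2 / (2 sigma^2)) with
    sigma = falloff_radius / 2. The boundary never moves.
    """
    if falloff_radius <= 0:
        raise ValidationError("falloff_radius must be > 0")
    if patch.is_boundary[vertex]:
        raise ValidationError(f"vertex {vertex} is on the boundary and cannot be dragged")
    disp = np.asarray(displacement, dtype=np.float64)
    v = patch.vertices.copy()
    origin = v[vertex].copy()
    sigma = falloff_radius / 2.0
    interior = np.nonzero(~patch.is_boundary)[0]
    d2 = np.einsum("ij,ij->i", v[interior] - origin, v[interior] - origin)
    factor = np.exp(-d2 / (2.0 * sigma * sigma))
    v[interior] += factor[:, None] * disp
    v[vertex] = origin + disp
    return replace(patch, vertices=v)


def patch_area(patch: OstiumPatch) -> float:
    """Total patch area (mm^2)."""
    return float(patch.face_areas().sum())
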