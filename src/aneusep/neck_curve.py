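"""Neck-curve construction on the mesh edge graph.

The surface mesh is interpreted as an undirected graph whose nodes are the
mesh vertices and whose edge weights are Euclidean edge lengths (mm).
Picked points are snapped to their nearest vertices and consecutive snaps
are joined by A* shortest paths; the loop is always closed last->first.
Paths run along mesh edges only — the resulting resolution dependence is
mitigated by locally subdividing the neck region (4-to-1 midpoint splits
with a conforming red–green closure), which refines the graph without
changing the polyhedral surface at all.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core_mesh import NeckCurve, PickedPointSet, TriangleMesh
from .errors import (DegeneratePickError, NoPathError, NonSimpleCurveError,
                     ValidationError)

__all__ = ["EdgeGraph", "snap_points", "shortest_path", "build_neck_curve",
           "subdivide_region"]


# ---------------------------------------------------------------------------
# Edge graph + A*
# ---------------------------------------------------------------------------

@dataclass
class EdgeGraph:
    """Undirected graph over mesh vertices with Euclidean edge lengths."""

    positions: np.ndarray          # (V, 3) mm
    neighbors: list[np.ndarray]    # adjacency lists
    weights: list[np.ndarray]      # parallel edge lengths, > 0

    @classmethod
    def from_mesh(cls, mesh: TriangleMesh) -> "EdgeGraph":
        edges, lengths = mesh.edges_unique()
        if (lengths <= 0).any():
            raise ValidationError("edge graph requires strictly positive edge lengths")
        n = mesh.n_vertices
        src = np.concatenate([edges[:, 0], edges[:, 1]])
        dst = np.concatenate([edges[:, 1], edges[:, 0]])
        w = np.concatenate([lengths, lengths])
        order = np.argsort(src, kind="stable")
        src, dst, w = src[order], dst[order], w[order]
        starts = np.searchsorted(src, np.arange(n + 1))
        neighbors = [dst[starts[i]:starts[i + 1]] for i in range(n)]
        weights = [w[starts[i]:starts[i + 1]] for i in range(n)]
        return cls(mesh.vertices, neighbors, weights)

    @property
    def n_nodes(self) -> int:
        return len(self.neighbors)

    def edge_array(self) -> tuple[np.ndarray, np.ndarray]:
        """Undirected (E, 2) edges and weights (for sparse-matrix oracles)."""
        rows = []
        for i, nbrs in enumerate(self.neighbors):
            for j, wt in zip(nbrs, self.weights[i]):
                if i < j:
                    rows.append((i, int(j), float(wt)))
        arr = np.array([(a, b) for a, b, _ in rows], dtype=np.int64)
        return arr, np.array([w for _, _, w in rows])


def _reconstruct(parent: dict[int, int], node: int) -> list[int]:
    path = [node]
    while parent[node] != node:
        node = parent[node]
        path.append(node)
    return path[::-1]


def shortest_path(graph: EdgeGraph, a: int, b: int) -> list[int]:
    """Minimal-length vertex path from ``a`` to ``b`` along mesh edges.

    A* with the straight-line distance to ``b`` as heuristic — admissible
    (and consistent) because edge weights are the Euclidean edge lengths.
    Equal-cost ties are broken toward the lexicographically smallest vertex
    sequence so results are reproducible across runs and platforms.
    """
    n = graph.n_nodes
    if not (0 <= a < n and 0 <= b < n):
        raise ValidationError(f"path endpoints ({a}, {b}) out of range")
    if a == b:
        return [a]
    pos = graph.positions
    h = np.linalg.norm(pos - pos[b], axis=1)
    dist = {a: 0.0}
    parent = {a: a}
    closed: set[int] = set()
    heap: list[tuple[float, int]] = [(h[a], a)]
    # 1e-12 absolute tolerance for "equal cost": float paths of the same
    # geometric length can differ in the last ulps with summation order
    while heap:
        f, u = heapq.heappop(heap)
        if u in closed:
            continue
        if u == b:
            return _reconstruct(parent, u)
        closed.add(u)
        du = dist[u]
        for v, w in zip(graph.neighbors[u], graph.weights[u]):
            v = int(v)
            if v in closed:
                continue
            cand = du + w
            old = dist.get(v)
            if old is None or cand < old - 1e-12:
                dist[v] = cand
                parent[v] = u
                heapq.heappush(heap, (cand + h[v], v))
            elif abs(cand - old) <= 1e-12:
                # equal cost: keep the lexicographically smaller path
                old_parent = parent[v]
                parent[v] = u
                new_path = _reconstruct(parent, v)
                parent[v] = old_parent
                if new_path < _reconstruct(parent, v):
                    parent[v] = u
                    heapq.heappush(heap, (cand + h[v], v))
    raise NoPathError(f"vertices {a} and {b} lie in different components")


def path_length(graph: EdgeGraph, path: list[int]) -> float:
    p = graph.positions[np.asarray(path)]
    return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())


# ---------------------------------------------------------------------------
# Snapping and curve building
# ---------------------------------------------------------------------------

def snap_points(mesh: TriangleMesh, picked: PickedPointSet) -> np.ndarray:
    """Map each picked point to its nearest mesh vertex (ties -> lowest index).

    Order is preserved; consecutive duplicates (including wrap-around) are
    collapsed. Fewer than three distinct snapped vertices is a degenerate
    pick set.
    """
    tree = cKDTree(mesh.vertices)
    k = min(32, mesh.n_vertices)
    _, cand = tree.query(picked.points, k=k)
    cand = np.atleast_2d(cand)
    snapped = []
    for pt, row in zip(picked.points, cand):
        d2 = np.einsum("ij,ij->i", mesh.vertices[row] - pt, mesh.vertices[row] - pt)
        best = d2.min()
        snapped.append(int(row[d2 <= best].min()))
    out = []
    for s in snapped:
        if not out or out[-1] != s:
            out.append(s)
    if len(out) > 1 and out[0] == out[-1]:
        out.pop()
    if len(set(out)) < 3:
        raise DegeneratePickError(
            f"picks snap to only {len(set(out))} distinct vertices (need >= 3)")
    return np.asarray(out, dtype=np.int64)


def _simplify_loop(loop: list[int]) -> list[int]:
    """Remove consecutive duplicates and immediate backtracks (a, v, a -> a),
    cyclically, until stable."""
    changed = True
    while changed and len(loop) > 2:
        changed = False
        # consecutive duplicates
        out = []
        for v in loop:
            if not out or out[-1] != v:
                out.append(v)
        if len(out) > 1 and out[0] == out[-1]:
            out.pop()
        if out != loop:
            loop, changed = out, True
            continue
        # spurs: predecessor == successor means the edge is walked twice
        n = len(loop)
        for i in range(n):
            if loop[(i - 1) % n] == loop[(i + 1) % n]:
                del loop[i]
                changed = True
                break
    return loop


def build_neck_curve(mesh: TriangleMesh, picked: PickedPointSet,
                     graph: EdgeGraph | None = None,
                     annotator_id: str | None = None,
                     case_id: str | None = None,
                     group: str = "unknown") -> NeckCurve:
    """Closed neck curve through the picked points.

    Concatenates A* shortest paths between consecutive snapped vertices and
    unconditionally closes the loop last->first, then simplifies junction
    artefacts. A loop that would still traverse some edge twice is rejected
    as non-simple rather than repaired.
    """
    snapped = snap_points(mesh, picked)
    if graph is None:
        graph = EdgeGraph.from_mesh(mesh)
    loop: list[int] = []
    m = len(snapped)
    for i in range(m):
        seg = shortest_path(graph, int(snapped[i]), int(snapped[(i + 1) % m]))
        loop.extend(seg[:-1])  # drop duplicate junction vertex
    loop = _simplify_loop(loop)
    if len(loop) < 3:
        raise NonSimpleCurveError("curve collapsed during simplification")
    idx = np.asarray(loop, dtype=np.int64)
    edges = np.sort(np.stack([idx, np.roll(idx, -1)], axis=1), axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    if (counts > 1).any():
        a, b = uniq[counts > 1][0]
        raise NonSimpleCurveError(
            f"neck curve would traverse edge ({int(a)}, {int(b)}) twice")
    curve = NeckCurve(
        vertex_indices=idx,
        points=mesh.vertices[idx],
        annotator_id=annotator_id or picked.annotator_id,
        case_id=case_id or picked.case_id,
        group=group,
    )
    curve.validate_on(mesh)
    return curve


# ---------------------------------------------------------------------------
# Local red–green subdivision of the neck region
# ---------------------------------------------------------------------------

def _point_segment_distances(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Min distance from each point to any segment (a_i, b_i). Vectorised
    over both; O(P*S) memory in chunks."""
    P = len(points)
    out = np.full(P, np.inf)
    ab = b - a                                  # (S, 3)
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    chunk = max(1, int(4e6 // max(1, len(a))))
    for s in range(0, P, chunk):
        p = points[s:s + chunk]
        ap = p[:, None, :] - a[None, :, :]      # (p, S, 3)
        t = np.clip(np.einsum("psk,sk->ps", ap, ab) / denom, 0.0, 1.0)
        closest = a[None] + t[..., None] * ab[None]
        d = np.linalg.norm(p[:, None, :] - closest, axis=2)
        out[s:s + chunk] = d.min(axis=1)
    return out


def subdivide_region(mesh: TriangleMesh, curve: NeckCurve, radius: float
                     ) -> tuple[TriangleMesh, NeckCurve]:
    """Midpoint-subdivide every triangle near the curve; remap the curve.

    Triangles with a vertex within ``radius`` (mm, Euclidean) of the curve
    polyline get a 4-to-1 split; neighbours across the region border get
    conforming 1-to-2 (or promoted 4-to-1) splits so no T-junctions remain.
    All new vertices are original-edge midpoints, so the polyhedral surface
    — and hence total area — is unchanged exactly.
    """
    if radius <= 0:
        raise ValidationError("subdivision radius must be > 0")
    curve.validate_on(mesh)
    pts = curve.points
    seg_a, seg_b = pts, np.roll(pts, -1, axis=0)
    vdist = _point_segment_distances(mesh.vertices, seg_a, seg_b)
    near = vdist <= radius
    red = near[mesh.faces].any(axis=1)          # (F,) bool

    faces = mesh.faces
    # conforming closure: an edge is split iff it belongs to a red face;
    # any face with >= 2 split edges is promoted to red; iterate to fixpoint
    def face_edges(f):
        return [tuple(sorted((f[0], f[1]))), tuple(sorted((f[1], f[2]))),
                tuple(sorted((f[2], f[0])))]

    all_edges = [face_edges(f) for f in faces]
    while True:
        split_edges = set()
        for fi in np.nonzero(red)[0]:
            split_edges.update(all_edges[fi])
        promote = False
        for fi in np.nonzero(~red)[0]:
            k = sum(e in split_edges for e in all_edges[fi])
            if k >= 2:
                red[fi] = True
                promote = True
        if not promote:
            break

    midpoint: dict[tuple[int, int], int] = {}
    new_vertices = [mesh.vertices]
    next_id = mesh.n_vertices

    def mid(e: tuple[int, int]) -> int:
        nonlocal next_id
        if e not in midpoint:
            midpoint[e] = next_id
            new_vertices.append(
                0.5 * (mesh.vertices[e[0]] + mesh.vertices[e[1]])[None])
            next_id += 1
        return midpoint[e]

    new_faces: list[tuple[int, int, int]] = []
    for fi, f in enumerate(faces):
        a, b, c = (int(x) for x in f)
        eab, ebc, eca = all_edges[fi]
        if red[fi]:
            mab, mbc, mca = mid(eab), mid(ebc), mid(eca)
            new_faces += [(a, mab, mca), (mab, b, mbc), (mca, mbc, c), (mab, mbc, mca)]
        else:
            splits = [e for e in (eab, ebc, eca) if e in split_edges]
            if not splits:
                new_faces.append((a, b, c))
            else:
                # exactly one split edge (>=2 were promoted): green 1-to-2
                e = splits[0]
                m = mid(e)
                if e == eab:
                    new_faces += [(a, m, c), (m, b, c)]
                elif e == ebc:
                    new_faces += [(b, m, a), (m, c, a)]
                else:
                    new_faces += [(c, m, b), (m, a, b)]

    out = TriangleMesh(np.vstack(new_vertices), np.asarray(new_faces, dtype=np.int64))

    # remap the curve: insert midpoints on split curve edges
    idx = curve.vertex_indices
    new_idx: list[int] = []
    for i in range(len(idx)):
        u, v = int(idx[i]), int(idx[(i + 1) % len(idx)])
        new_idx.append(u)
        e = (min(u, v), max(u, v))
        if e in midpoint:
            new_idx.append(midpoint[e])
    new_curve = NeckCurve(
        vertex_indices=np.asarray(new_idx, dtype=np.int64),
        points=out.vertices[np.asarray(new_idx)],
        annotator_id=curve.annotator_id, case_id=curve.case_id, group=curve.group)
    new_curve.validate_on(out)
    return out, new_curve


def default_subdivision_radius(mesh: TriangleMesh) -> float:
    """10 x median edge length — wide enough to decouple the neck path from
    the segmentation's triangle size, narrow enough to stay local."""
    _, lengths = mesh.edges_unique()
    return 10.0 * float(np.median(lengths))
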