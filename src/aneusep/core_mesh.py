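"""Mesh and curve data model plus all file I/O.

All coordinates are in millimetres, vertex/triangle indices are 0-based.
Meshes are validated on construction: every triangle references three
distinct in-range vertices, every edge is shared by at most two triangles,
orientation is consistent across shared edges and no triangle is degenerate.
Non-conforming meshes are rejected rather than repaired — silent repair
would change the edge graph and therefore every geodesic computed on it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

from .errors import MeshValidationError, SchemaError, ValidationError

_MESH_FORMATS = ("stl", "obj", "ply")

GROUPS = ("clinical", "nonclinical", "unknown")


# ---------------------------------------------------------------------------
# TriangleMesh
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TriangleMesh:
    """Triangulated vessel-wall surface.

    Parameters
    ----------
    vertices : (V, 3) float array, mm
    faces : (F, 3) int array of vertex indices
    vertex_labels : optional per-vertex string/int labels
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_labels: np.ndarray | None = None

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        v, f = self.vertices, self.faces
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshValidationError("vertices must be an (V, 3) array")
        if f.ndim != 2 or f.shape[1] != 3:
            raise MeshValidationError("faces must be an (F, 3) array")
        if len(f) == 0:
            raise MeshValidationError("mesh has no triangles")
        if not np.isfinite(v).all():
            bad = int(np.argwhere(~np.isfinite(v).all(axis=1))[0, 0])
            raise MeshValidationError(f"vertex {bad} has non-finite coordinates")
        if f.min() < 0 or f.max() >= len(v):
            bad = int(np.argwhere((f < 0) | (f >= len(v)))[0, 0])
            raise MeshValidationError(f"triangle {bad} references an out-of-range vertex")
        same = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        if same.any():
            raise MeshValidationError(
                f"triangle {int(np.argwhere(same)[0, 0])} repeats a vertex index")
        areas = self.triangle_areas()
        if (areas <= 0).any() or not np.isfinite(areas).all():
            raise MeshValidationError(
                f"triangle {int(np.argmin(areas))} has zero (or invalid) area")
        # Manifoldness + orientation via directed edges: in a consistently
        # oriented manifold every directed edge occurs at most once and every
        # undirected edge at most twice.
        de = self._directed_edges()
        _, counts = np.unique(de, axis=0, return_counts=True)
        if (counts > 1).any():
            dup = np.unique(de, axis=0)[counts > 1][0]
            und = np.sort(de, axis=1)
            n_und = np.unique(und, axis=0, return_counts=True)[1]
            kind = "non-manifold edge" if (n_und > 2).any() else "inconsistently oriented edge"
            raise MeshValidationError(f"{kind} ({int(dup[0])}, {int(dup[1])})")

    def _directed_edges(self) -> np.ndarray:
        f = self.faces
        return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])

    # -- derived quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangle_areas(self) -> np.ndarray:
        p = self.vertices[self.faces]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def area(self) -> float:
        """Total surface area (mm^2)."""
        return float(self.triangle_areas().sum())

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def face_normals(self) -> np.ndarray:
        p = self.vertices[self.faces]
        n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def edges_unique(self) -> tuple[np.ndarray, np.ndarray]:
        """Undirected edge list (E, 2), sorted per edge, and lengths (mm)."""
        und = np.sort(self._directed_edges(), axis=1)
        edges = np.unique(und, axis=0)
        lengths = np.linalg.norm(
            self.vertices[edges[:, 0]] - self.vertices[edges[:, 1]], axis=1)
        return edges, lengths

    def edge_set(self) -> set[tuple[int, int]]:
        edges, _ = self.edges_unique()
        return {(int(a), int(b)) for a, b in edges}

    def has_edge(self, a: int, b: int) -> bool:
        return (min(a, b), max(a, b)) in self.edge_set()

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)


# ---------------------------------------------------------------------------
# Picked points and neck curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PickedPointSet:
    """Ordered 3-D points (mm) a user clicked, or a simulator produced."""

    points: np.ndarray
    annotator_id: str = "anonymous"
    case_id: str = "case"

    def __post_init__(self):
        p = np.asarray(self.points, dtype=np.float64)
        if p.ndim != 2 or p.shape[1] != 3 or len(p) < 3:
            raise ValidationError("a pick set needs >= 3 three-dimensional points")
        if not np.isfinite(p).all():
            raise ValidationError("picked points must be finite")
        object.__setattr__(self, "points", p)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class NeckCurve:
    """Closed edge-path on a mesh separating sac from parent vessel.

    ``vertex_indices`` stores the loop without repeating the first vertex at
    the end; ``points`` is the matching polyline (mm). The loop is validated
    against a mesh when one is supplied: consecutive indices (cyclically)
    must be joined by a mesh edge and no edge may be traversed twice.
    """

    vertex_indices: np.ndarray
    points: np.ndarray
    annotator_id: str = "anonymous"
    case_id: str = "case"
    group: str = "unknown"

    def __post_init__(self):
        idx = np.asarray(self.vertex_indices, dtype=np.int64)
        pts = np.asarray(self.points, dtype=np.float64)
        if idx.ndim != 1 or len(idx) < 3:
            raise ValidationError("a neck curve needs >= 3 vertices")
        if pts.shape != (len(idx), 3):
            raise ValidationError("points must be an (L, 3) array matching vertex_indices")
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}")
        if len(idx) != len(np.unique(idx)):
            # repeated vertices are allowed only as pinch points, which still
            # have distinct incident edges; repeated *consecutive* ones never
            dup = idx[np.r_[idx[1:] == idx[:-1], idx[0] == idx[-1]]]
            if dup.size:
                raise ValidationError(f"curve repeats consecutive vertex {int(dup[0])}")
        object.__setattr__(self, "vertex_indices", idx)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.vertex_indices)

    def loop_edges(self) -> np.ndarray:
        """Undirected (L, 2) edge list of the closed loop, sorted per edge."""
        idx = self.vertex_indices
        nxt = np.roll(idx, -1)
        return np.sort(np.stack([idx, nxt], axis=1), axis=1)

    def length(self) -> float:
        """Closed polyline length (mm)."""
        d = np.roll(self.points, -1, axis=0) - self.points
        return float(np.linalg.norm(d, axis=1).sum())

    def validate_on(self, mesh: TriangleMesh) -> None:
        idx = self.vertex_indices
        if idx.min() < 0 or idx.max() >= mesh.n_vertices:
            raise ValidationError("curve index out of range for the supplied mesh")
        # tolerance covers float32 exchange formats (PLY binary)
        if not np.allclose(self.points, mesh.vertices[idx], atol=1e-4):
            raise ValidationError("curve points do not match mesh vertex positions")
        edges = self.loop_edges()
        eset = mesh.edge_set()
        for a, b in edges:
            if (int(a), int(b)) not in eset:
                raise ValidationError(f"curve step ({int(a)}, {int(b)}) is not a mesh edge")
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        if (counts > 1).any():
            a, b = uniq[counts > 1][0]
            raise ValidationError(f"curve traverses edge ({int(a)}, {int(b)}) twice")
        if self.length() <= 0:
            raise ValidationError("curve has zero length")

    def resample(self, n: int) -> np.ndarray:
        """Uniform arc-length resampling of the closed polyline to ``n`` points."""
        pts = np.vstack([self.points, self.points[:1]])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        t = np.linspace(0.0, total, n, endpoint=False)
        out = np.empty((n, 3))
        for k in range(3):
            out[:, k] = np.interp(t, s, pts[:, k])
        return out


@dataclass
class CurveSet:
    """All annotators' neck curves for one case."""

    curves: list[NeckCurve] = field(default_factory=list)
    case_id: str = "case"

    def __post_init__(self):
        ids = [c.annotator_id for c in self.curves]
        if len(ids) != len(set(ids)):
            raise ValidationError("annotator ids must be unique within a CurveSet")
        for c in self.curves:
            if c.case_id != self.case_id:
                raise ValidationError(
                    f"curve from {c.annotator_id} belongs to case {c.case_id!r}, "
                    f"not {self.case_id!r}")

    def __len__(self) -> int:
        return len(self.curves)

    def __iter__(self):
        return iter(self.curves)

    def __getitem__(self, i: int) -> NeckCurve:
        return self.curves[i]

    @property
    def annotator_ids(self) -> list[str]:
        return [c.annotator_id for c in self.curves]

    @property
    def groups(self) -> list[str]:
        return [c.group for c in self.curves]


# ---------------------------------------------------------------------------
# Surface field series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurfaceFieldSeries:
    """Time-sampled vector field on mesh elements over one cardiac period.

    ``vectors`` has shape (n_times, n_elements, 3); WSS in Pa, velocity in
    mm/s. ``element_ids`` index either vertices or triangles of the owning
    geometry (``on`` says which).
    """

    element_ids: np.ndarray
    times: np.ndarray
    vectors: np.ndarray
    on: str = "face"  # "face" | "vertex"

    def __post_init__(self):
        ids = np.asarray(self.element_ids, dtype=np.int64)
        t = np.asarray(self.times, dtype=np.float64)
        v = np.asarray(self.vectors, dtype=np.float64)
        if t.ndim != 1 or len(t) < 2:
            raise ValidationError("a field series needs >= 2 time samples")
        if (np.diff(t) <= 0).any():
            raise ValidationError("time samples must be strictly increasing")
        if v.shape != (len(t), len(ids), 3):
            raise ValidationError(
                f"vectors must have shape ({len(t)}, {len(ids)}, 3), got {v.shape}")
        if self.on not in ("face", "vertex"):
            raise ValidationError("field must live on 'face' or 'vertex' elements")
        object.__setattr__(self, "element_ids", ids)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "vectors", v)

    @property
    def period(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def n_elements(self) -> int:
        return len(self.element_ids)


# ---------------------------------------------------------------------------
# Mesh file I/O (trimesh backend)
# ---------------------------------------------------------------------------

def _infer_format(path: str | Path, format: str | None) -> str:
    fmt = (format or Path(path).suffix.lstrip(".")).lower()
    if fmt not in _MESH_FORMATS:
        raise ValidationError(f"unsupported mesh format {fmt!r}; use one of {_MESH_FORMATS}")
    return fmt


def _weld_exact_duplicates(vertices: np.ndarray, faces: np.ndarray):
    """Merge bit-identical duplicate vertices, keeping first-occurrence order.

    STL stores an unindexed triangle soup, so connectivity must be rebuilt
    by welding. Only exact duplicates are merged — tolerance-based welding
    could fuse genuinely distinct vertices on fine meshes.
    """
    uniq, first, inverse = np.unique(
        vertices, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first)
    rank = np.empty(len(order), dtype=np.int64)
    rank[order] = np.arange(len(order))
    return uniq[order], rank[inverse][faces]


def read_mesh(path: str | Path, format: str | None = None) -> TriangleMesh:
    """Read an STL/OBJ/PLY surface mesh; coordinates are taken as mm verbatim.

    The mesh is validated and rejected (never repaired) if non-manifold,
    inconsistently oriented or degenerate.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise ValidationError(f"mesh file not found: {path}")
    try:
        m = _trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # trimesh raises assorted types on corrupt files
        raise ValidationError(f"unreadable mesh file {path}: {exc}") from exc
    vertices = np.asarray(m.vertices, dtype=np.float64)
    faces = np.asarray(m.faces, dtype=np.int64)
    if fmt == "stl":
        vertices, faces = _weld_exact_duplicates(vertices, faces)
    return TriangleMesh(vertices, faces)


def write_mesh(mesh: TriangleMesh, path: str | Path, format: str | None = None) -> Path:
    """Write a mesh; the file re-reads (via :func:`read_mesh`) to an equal mesh."""
    path = Path(path)
    fmt = _infer_format(path, format)
    mesh.validate()
    tm = mesh.to_trimesh()
    try:
        tm.export(str(path), file_type=fmt)
    except OSError as exc:
        raise ValidationError(f"cannot write mesh to {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# Curve JSON exchange format
# ---------------------------------------------------------------------------
#
# {
#   "case_id": str, "annotator_id": str,
#   "group": "clinical" | "nonclinical" | "unknown",
#   "vertex_indices": [int, ...]            # 0-based, loop not re-closed
#   "points": [[x, y, z], ...]              # mm, parallel to vertex_indices
# }

_CURVE_FIELDS = ("case_id", "annotator_id", "group", "vertex_indices", "points")


def write_curve_json(curve: NeckCurve, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "case_id": curve.case_id,
        "annotator_id": curve.annotator_id,
        "group": curve.group,
        "vertex_indices": [int(i) for i in curve.vertex_indices],
        "points": [[float(x) for x in p] for p in curve.points],
    }
    path.write_text(json.dumps(doc, indent=1))
    return path


def read_curve_json(path: str | Path, mesh: TriangleMesh | None = None) -> NeckCurve:
    """Read a neck curve; if ``mesh`` is given, indices are validated on it."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"curve file not found: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"invalid JSON in {path}: {exc}") from exc
    missing = [k for k in _CURVE_FIELDS if k not in doc]
    if missing:
        raise SchemaError(f"{path}: missing field(s) {missing}")
    curve = NeckCurve(
        vertex_indices=np.asarray(doc["vertex_indices"], dtype=np.int64),
        points=np.asarray(doc["points"], dtype=np.float64),
        annotator_id=str(doc["annotator_id"]),
        case_id=str(doc["case_id"]),
        group=str(doc["group"]),
    )
    if mesh is not None:
        curve.validate_on(mesh)
    return curve


def read_curve_directory(directory: str | Path, mesh: TriangleMesh | None = None,
                         case_id: str | None = None) -> CurveSet:
    """Read every ``*.json`` curve in a directory into one CurveSet."""
    directory = Path(directory)
    files = sorted(directory.glob("*.json"))
    if not files:
        raise SchemaError(f"no curve JSON files in {directory}")
    curves = [read_curve_json(f, mesh) for f in files]
    cid = case_id or curves[0].case_id
    return CurveSet(curves=curves, case_id=cid)
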