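"""Sac extraction and standard aneurysm morphometry.

The neck curve splits the wall surface into the aneurysm sac and the
parent-vessel side; a flood fill over face adjacency, forbidden to cross
curve edges, recovers the two regions. Morphometric descriptors follow the
conventions common in aneurysm rupture-risk studies:

* ``D_max`` — maximum sac diameter (largest pairwise vertex distance, mm)
* ``N_avg`` / ``N_max`` — average / maximum neck-curve diameter (mm)
* ``H_max`` — maximum sac height above the ostium plane (mm)
* ``AR`` — aspect ratio, here H_max / N_avg (height relative to neck width)
* ``A_a`` — sac wall area (cm^2), ostium cap excluded

"Average neck diameter" has no single published definition; we resample the
curve to 2k uniform arc-length points and average the k opposite-point
chords (k = 50). The equivalent-circle diameter (perimeter / pi) is emitted
alongside for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .core_mesh import NeckCurve, TriangleMesh
from .errors import NonSeparatingCurveError, ValidationError
from .ostium import fit_plane

__all__ = ["SacRegion", "MorphometryRecord", "extract_sac", "sac_area",
           "morphometry"]


@dataclass(frozen=True)
class SacRegion:
    """Triangle ids of the sac-side surface component."""

    face_ids: np.ndarray
    mesh: TriangleMesh
    curve: NeckCurve

    def __post_init__(self):
        ids = np.unique(np.asarray(self.face_ids, dtype=np.int64))
        if len(ids) == 0:
            raise ValidationError("sac region is empty")
        if ids.min() < 0 or ids.max() >= self.mesh.n_faces:
            raise ValidationError("sac face id out of range")
        object.__setattr__(self, "face_ids", ids)

    @property
    def faces(self) -> np.ndarray:
        return self.mesh.faces[self.face_ids]

    @property
    def vertex_ids(self) -> np.ndarray:
        return np.unique(self.faces)

    def areas(self) -> np.ndarray:
        return self.mesh.triangle_areas()[self.face_ids]


@dataclass(frozen=True)
class MorphometryRecord:
    """Table-style morphology row for one (mesh, neck curve) pair."""

    D_max: float   # mm
    N_avg: float   # mm
    N_max: float   # mm
    AR: float      # dimensionless
    A_a: float     # cm^2
    H_max: float   # mm
    N_eq: float    # mm, equivalent-circle neck diameter (perimeter / pi)

    def __post_init__(self):
        if not (self.N_max >= self.N_avg > 0):
            raise ValidationError("need N_max >= N_avg > 0")
        if self.D_max <= 0 or self.A_a <= 0 or self.AR <= 0:
            raise ValidationError("D_max, A_a and AR must be positive")


# ---------------------------------------------------------------------------

def _face_adjacency(mesh: TriangleMesh) -> np.ndarray:
    """(P, 2) face pairs sharing an edge, plus the shared edge per pair."""
    f = mesh.faces
    edges = np.sort(np.concatenate(
        [f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1)
    owner = np.tile(np.arange(len(f)), 3)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    edges, owner = edges[order], owner[order]
    same = (edges[1:] == edges[:-1]).all(axis=1)
    pairs = np.stack([owner[:-1][same], owner[1:][same]], axis=1)
    shared = edges[:-1][same]
    return pairs, shared


def extract_sac(mesh: TriangleMesh, curve: NeckCurve,
                dome_seed: np.ndarray | None = None) -> SacRegion:
    """Flood-fill the sac-side faces, never crossing a neck-curve edge.

    With ``dome_seed`` the sac is the component containing the face nearest
    the seed; otherwise it is the component reaching farthest from the
    ostium fitted plane (the dome sticks out, the vessel runs along it).
    """
    curve.validate_on(mesh)
    pairs, shared = _face_adjacency(mesh)
    loop = curve.loop_edges()
    loop_set = {(int(a), int(b)) for a, b in loop}
    keep = np.fromiter(
        ((int(a), int(b)) not in loop_set for a, b in shared), bool, len(shared))
    pairs = pairs[keep]
    n = mesh.n_faces
    adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp < 2:
        raise NonSeparatingCurveError(
            "the neck curve does not separate the surface into two regions")
    centroids = mesh.face_centroids()
    if dome_seed is not None:
        seed_face = int(np.argmin(
            np.linalg.norm(centroids - np.asarray(dome_seed, float), axis=1)))
        sac_label = labels[seed_face]
    else:
        centroid, normal = fit_plane(curve)
        height = np.abs((centroids - centroid) @ normal)
        reach = np.zeros(n_comp)
        np.maximum.at(reach, labels, height)
        sac_label = int(np.argmax(reach))
    return SacRegion(np.nonzero(labels == sac_label)[0], mesh, curve)


def sac_area(sac: SacRegion) -> float:
    """Sac wall area in cm^2 (sum of sac triangle areas / 100)."""
    return float(sac.areas().sum()) / 100.0


def max_diameter(points: np.ndarray) -> float:
    """Largest pairwise distance; convex-hull accelerated above 64 points."""
    pts = np.asarray(points, float)
    if len(pts) > 64:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass  # degenerate (coplanar) clouds: fall through to brute force
    return float(pdist(pts).max())


def neck_diameters(curve: NeckCurve, k: int = 50) -> tuple[float, float, float]:
    """(N_avg, N_max, N_eq) from a 2k-point uniform arc-length resampling.

    N_avg averages the k opposite-point chords ||p_i - p_{i+k}||, N_max is
    the maximum pairwise distance among the resampled points, N_eq is the
    equivalent-circle diameter perimeter / pi.
    """
    rs = curve.resample(2 * k)
    chords = np.linalg.norm(rs[:k] - rs[k:], axis=1)
    n_avg = float(chords.mean())
    n_max = float(pdist(rs).max())
    n_eq = curve.length() / np.pi
    return n_avg, n_max, n_eq


def morphometry(mesh: TriangleMesh, curve: NeckCurve,
                sac: SacRegion | None = None, k: int = 50) -> MorphometryRecord:
    """Morphology record for one neck-curve annotation."""
    if sac is None:
        sac = extract_sac(mesh, curve)
    sac_pts = mesh.vertices[sac.vertex_ids]
    d_max = max_diameter(sac_pts)
    n_avg, n_max, n_eq = neck_diameters(curve, k=k)
    centroid, normal = fit_plane(curve)
    h_max = float(np.abs((sac_pts - centroid) @ normal).max())
    return MorphometryRecord(
        D_max=d_max, N_avg=n_avg, N_max=n_max, AR=h_max / n_avg,
        A_a=sac_area(sac), H_max=h_max, N_eq=n_eq)
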