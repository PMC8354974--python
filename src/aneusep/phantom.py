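"""Parametric aneurysm phantoms with analytic ground truth.

A phantom is the implicit union of a vessel capsule (a tube along the
x-axis), a spherical sac whose centre sits ``h`` mm above the axis, and
optionally extra tubes (a bifurcation daughter pair or a small side
branch). The signed-distance union is sampled on a regular grid at voxel
size ``voxel`` and iso-surfaced with marching cubes.

For a hard union (``beta = 0``) the true neck curve — the intersection of
the sac sphere with the vessel cylinder — is known in closed form: with
the vessel along x, cylinder y^2 + z^2 = r_v^2 and sphere centre
(x_c, 0, h), points on both surfaces satisfy

    x = x_c +/- sqrt(r_a^2 - r_v^2 - h^2 + 2 h z),   y^2 + z^2 = r_v^2,

a closed quartic space curve (not a planar circle unless h -> infinity).
It is returned as a dense polyline and drives simulated annotators and
recovery tests. Smooth blends (``beta > 0``) displace the true neck, so
their ground truth is flagged approximate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from skimage.measure import marching_cubes

from .core_mesh import (CurveSet, PickedPointSet, SurfaceFieldSeries,
                        TriangleMesh)
from .errors import ValidationError
from .neck_curve import EdgeGraph, build_neck_curve
from .ostium import OstiumPatch

__all__ = ["PhantomSpec", "phantom_mesh", "analytic_neck_curve",
           "simulated_annotators", "synthetic_fields", "FieldParams",
           "lateral_preset", "bifurcation_preset", "sidebranch_preset",
           "uv_sphere"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry + sampling parameters of one phantom (all lengths mm)."""

    vessel_radius: float = 2.0
    vessel_length: float = 20.0
    sac_radius: float = 3.0
    sac_offset: float = 4.0            # sphere-centre height above the axis
    sac_center_x: float = 0.0          # position along the vessel
    voxel: float = 0.15
    beta: float = 0.0                  # smooth-min blending; 0 = hard union
    branch_radius: float | None = None
    branch_start: tuple[float, float, float] | None = None
    branch_direction: tuple[float, float, float] | None = None
    branch_length: float = 6.0
    daughters: bool = False            # bifurcation daughter pair
    seed: int = 0
    name: str = "phantom"

    def __post_init__(self):
        if min(self.vessel_radius, self.sac_radius, self.vessel_length,
               self.voxel) <= 0 or self.sac_offset <= 0:
            raise ValidationError("phantom lengths must be positive")
        r_v, r_a, h = self.vessel_radius, self.sac_radius, self.sac_offset
        if not (abs(h - r_v) < r_a < h + r_v):
            raise ValidationError(
                "sphere and vessel must intersect in a band that does not "
                "swallow the vessel cross-section: |h - r_v| < r_a < h + r_v")
        if self.neck_halfwidth() < 3 * self.voxel:
            raise ValidationError(
                f"voxel {self.voxel} too coarse: the neck half-width "
                f"{self.neck_halfwidth():.3f} mm needs >= 3 voxels")

    def neck_halfwidth(self) -> float:
        """Half-extent of the neck along the vessel axis (mm)."""
        r_v, r_a, h = self.vessel_radius, self.sac_radius, self.sac_offset
        return float(np.sqrt(r_a ** 2 - (h - r_v) ** 2))

    @property
    def sac_center(self) -> np.ndarray:
        return np.array([self.sac_center_x, 0.0, self.sac_offset])

    @property
    def dome_apex(self) -> np.ndarray:
        return self.sac_center + np.array([0.0, 0.0, self.sac_radius])

    # -- primitives ---------------------------------------------------------

    def _capsules(self) -> list[tuple[np.ndarray, np.ndarray, float]]:
        L = self.vessel_length
        caps = []
        if self.daughters:
            caps.append((np.array([-L / 2, 0.0, 0.0]), np.zeros(3),
                         self.vessel_radius))
            ang = np.deg2rad(35.0)
            d1 = np.array([np.cos(ang), np.sin(ang), 0.0])
            d2 = np.array([np.cos(ang), -np.sin(ang), 0.0])
            for d in (d1, d2):
                caps.append((np.zeros(3), d * (L / 2), 0.8 * self.vessel_radius))
        else:
            caps.append((np.array([-L / 2, 0.0, 0.0]),
                         np.array([L / 2, 0.0, 0.0]), self.vessel_radius))
        if self.branch_radius is not None:
            a = np.asarray(self.branch_start, float)
            d = np.asarray(self.branch_direction, float)
            d = d / np.linalg.norm(d)
            caps.append((a, a + d * self.branch_length, self.branch_radius))
        return caps

    def sdf(self, points: np.ndarray) -> np.ndarray:
        """Signed distance of the implicit union at the given points."""
        pts = np.atleast_2d(points)
        fields = [_capsule_sdf(pts, a, b, r) for a, b, r in self._capsules()]
        fields.append(np.linalg.norm(pts - self.sac_center, axis=1) - self.sac_radius)
        F = np.stack(fields)
        if self.beta <= 0:
            return F.min(axis=0)
        return -self.beta * np.log(np.exp(-F / self.beta).sum(axis=0))


def _capsule_sdf(pts: np.ndarray, a: np.ndarray, b: np.ndarray, r: float) -> np.ndarray:
    ab = b - a
    t = np.clip((pts - a) @ ab / (ab @ ab), 0.0, 1.0)
    return np.linalg.norm(pts - (a + t[:, None] * ab), axis=1) - r


def lateral_preset(voxel: float = 0.15, seed: int = 0) -> PhantomSpec:
    return PhantomSpec(voxel=voxel, seed=seed, name="lateral")


def bifurcation_preset(voxel: float = 0.15, seed: int = 0) -> PhantomSpec:
    return PhantomSpec(voxel=voxel, seed=seed, name="bifurcation",
                       daughters=True, sac_center_x=-5.0)


def sidebranch_preset(voxel: float = 0.15, seed: int = 0) -> PhantomSpec:
    return PhantomSpec(voxel=voxel, seed=seed, name="sidebranch",
                       branch_radius=0.6,
                       branch_start=(3.5, 0.0, 0.0),
                       branch_direction=(0.45, -0.75, 0.45))


# ---------------------------------------------------------------------------

def analytic_neck_curve(spec: PhantomSpec, n_points: int = 512) -> np.ndarray:
    """Dense polyline of the exact sphere-cylinder neck curve (hard union).

    Raises if another primitive encroaches on the curve (which would make
    the closed form only approximate).
    """
    r_v, r_a, h = spec.vessel_radius, spec.sac_radius, spec.sac_offset
    cos_max = (r_v ** 2 + h ** 2 - r_a ** 2) / (2.0 * h * r_v)
    psi_max = np.arccos(np.clip(cos_max, -1.0, 1.0))
    half = n_points // 2
    psi = np.linspace(-psi_max, psi_max, half + 2)[1:-1]  # open: avoid x=0 dups
    z = r_v * np.cos(psi)
    y = r_v * np.sin(psi)
    x2 = np.maximum(r_a ** 2 - r_v ** 2 - h ** 2 + 2.0 * h * z, 0.0)
    x = np.sqrt(x2)
    fwd = np.stack([spec.sac_center_x + x, y, z], axis=1)
    bwd = np.stack([spec.sac_center_x - x, y, z], axis=1)[::-1]
    # close the loop through the two x=0 crossings
    tips = [np.array([spec.sac_center_x, r_v * np.sin(s * psi_max),
                      r_v * np.cos(s * psi_max)]) for s in (+1.0, -1.0)]
    curve = np.vstack([tips[1][None], fwd, tips[0][None], bwd])
    if spec.beta > 0:
        return curve  # approximate ground truth for smooth blends
    others = [c for c in spec._capsules()]
    # the curve lies on the main tube; every *other* primitive must stay clear
    main = others[0]
    for a, b, r in others:
        if np.array_equal(a, main[0]) and np.array_equal(b, main[1]):
            continue
        if _capsule_sdf(curve, a, b, r).min() < 2 * spec.voxel:
            raise ValidationError(
                "a secondary tube encroaches on the analytic neck curve; "
                "move the sac or the branch")
    return curve


def phantom_mesh(spec: PhantomSpec) -> tuple[TriangleMesh, np.ndarray]:
    """Iso-surface the phantom; returns (mesh, analytic neck polyline)."""
    caps = spec._capsules()
    lo = np.min([np.minimum(a, b) - r for a, b, r in caps], axis=0)
    hi = np.max([np.maximum(a, b) + r for a, b, r in caps], axis=0)
    lo = np.minimum(lo, spec.sac_center - spec.sac_radius)
    hi = np.maximum(hi, spec.sac_center + spec.sac_radius)
    margin = 2.5 * spec.voxel + spec.beta
    lo, hi = lo - margin, hi + margin
    nx, ny, nz = (np.ceil((hi - lo) / spec.voxel).astype(int) + 1)
    xs = lo[0] + np.arange(nx) * spec.voxel
    ys = lo[1] + np.arange(ny) * spec.voxel
    zs = lo[2] + np.arange(nz) * spec.voxel
    grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
    vol = spec.sdf(grid.reshape(-1, 3)).reshape(nx, ny, nz)
    verts, faces, _, _ = marching_cubes(vol, level=0.0, spacing=(spec.voxel,) * 3)
    verts = verts + lo
    verts, faces = _clean(verts, faces)
    verts, faces = _largest_component(verts, faces)
    mesh = TriangleMesh(verts, faces)
    return mesh, analytic_neck_curve(spec)


def _clean(verts: np.ndarray, faces: np.ndarray):
    """Weld exact duplicates and drop degenerate triangles."""
    uniq, first, inverse = np.unique(verts, axis=0, return_index=True,
                                     return_inverse=True)
    order = np.argsort(first)
    rank = np.empty(len(order), dtype=np.int64); rank[order] = np.arange(len(order))
    verts, faces = uniq[order], rank[inverse][faces]
    p = verts[faces]
    areas = 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)
    keep = areas > 1e-12
    same = (faces[:, 0] == faces[:, 1]) | (faces[:, 1] == faces[:, 2]) \
        | (faces[:, 0] == faces[:, 2])
    return verts, faces[keep & ~same]


def _largest_component(verts: np.ndarray, faces: np.ndarray):
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    n = len(verts)
    adj = coo_matrix((np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    counts = np.bincount(labels)
    big = int(np.argmax(counts))
    vkeep = labels == big
    fkeep = vkeep[faces].all(axis=1)
    remap = -np.ones(n, dtype=np.int64)
    remap[vkeep] = np.arange(vkeep.sum())
    return verts[vkeep], remap[faces[fkeep]]


def uv_sphere(radius: float = 1.0, n_lon: int = 64, n_lat: int = 32,
              center=(0.0, 0.0, 0.0)) -> tuple[TriangleMesh, np.ndarray]:
    """Latitude/longitude sphere whose equator is an exact vertex ring.

    Useful as an analytic calibration surface (a hemispherical sac with a
    perfectly circular neck). ``n_lat`` must be even so a ring sits exactly
    on the equator. Returns (mesh, ordered equator vertex indices).
    """
    if n_lat % 2:
        raise ValidationError("n_lat must be even for an exact equator ring")
    center = np.asarray(center, float)
    verts = [center + np.array([0.0, 0.0, radius])]
    rings = []
    for i in range(1, n_lat):
        theta = np.pi * i / n_lat
        ring = []
        for j in range(n_lon):
            phi = 2 * np.pi * j / n_lon
            ring.append(len(verts))
            verts.append(center + radius * np.array(
                [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi),
                 np.cos(theta)]))
        rings.append(ring)
    south = len(verts)
    verts.append(center + np.array([0.0, 0.0, -radius]))
    faces = []
    for j in range(n_lon):
        faces.append((0, rings[0][j], rings[0][(j + 1) % n_lon]))
    for i in range(len(rings) - 1):
        a, b = rings[i], rings[i + 1]
        for j in range(n_lon):
            jn = (j + 1) % n_lon
            faces.append((a[j], b[j], b[jn]))
            faces.append((a[j], b[jn], a[jn]))
    for j in range(n_lon):
        faces.append((south, rings[-1][(j + 1) % n_lon], rings[-1][j]))
    mesh = TriangleMesh(np.asarray(verts), np.asarray(faces, dtype=np.int64))
    return mesh, np.asarray(rings[n_lat // 2 - 1], dtype=np.int64)


# ---------------------------------------------------------------------------
# Simulated annotators
# ---------------------------------------------------------------------------

def _arc_positions(polyline: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    closed = np.vstack([polyline, polyline[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = fractions * s[-1]
    out = np.empty((len(t), 3))
    for k in range(3):
        out[:, k] = np.interp(t, s, closed[:, k])
    return out


def simulated_annotators(mesh: TriangleMesh, spec: PhantomSpec,
                         gt_curve: np.ndarray, n_users: int = 10,
                         k_picks: int = 8, noise_sd: float | None = None,
                         outlier_frac: float = 0.1, offset: float = 5.0,
                         seed: int | None = None,
                         graph: EdgeGraph | None = None) -> CurveSet:
    """Simulate annotators clicking near the true neck curve.

    Each user places ``k_picks`` points at uniform arc-length positions
    (random common phase), perturbed tangentially on the surface with
    Gaussian sd ``noise_sd`` (default: one voxel), snapped to mesh vertices
    and closed into a neck curve. The last ``round(outlier_frac*n_users)``
    users are outliers whose picks are additionally slid ``offset`` mm
    toward the dome along the sac sphere. Groups alternate clinical /
    nonclinical.
    """
    if n_users < 1:
        raise ValidationError("need at least one simulated user")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if noise_sd is None:
        noise_sd = spec.voxel
    if graph is None:
        graph = EdgeGraph.from_mesh(mesh)
    n_out = int(round(outlier_frac * n_users))
    case_id = f"{spec.name}-seed{spec.seed}"
    curves = []
    # one shared phase: with zero noise every user submits the same curve
    phase = rng.uniform(0.0, 1.0)
    for u in range(n_users):
        fr = (phase + np.arange(k_picks) / k_picks) % 1.0
        pts = _arc_positions(gt_curve, np.sort(fr))
        if noise_sd > 0:
            pts = _tangential_noise(spec, pts, noise_sd, rng)
        if u >= n_users - n_out:
            pts = _slide_toward_dome(spec, pts, offset)
        picked = PickedPointSet(pts, annotator_id=f"user{u:02d}", case_id=case_id)
        group = "clinical" if u % 2 == 0 else "nonclinical"
        curves.append(build_neck_curve(mesh, picked, graph=graph, group=group))
    return CurveSet(curves=curves, case_id=case_id)


def _tangential_noise(spec: PhantomSpec, pts: np.ndarray, sd: float,
                      rng: np.random.Generator) -> np.ndarray:
    eps = 1e-4
    out = pts.copy()
    for i, p in enumerate(pts):
        g = np.array([
            spec.sdf(p + np.array([eps, 0, 0])) - spec.sdf(p - np.array([eps, 0, 0])),
            spec.sdf(p + np.array([0, eps, 0])) - spec.sdf(p - np.array([0, eps, 0])),
            spec.sdf(p + np.array([0, 0, eps])) - spec.sdf(p - np.array([0, 0, eps])),
        ]).ravel()
        n = g / (np.linalg.norm(g) + 1e-30)
        ref = np.eye(3)[int(np.argmin(np.abs(n)))]
        t1 = np.cross(n, ref); t1 /= np.linalg.norm(t1)
        t2 = np.cross(n, t1)
        out[i] = p + rng.normal(0.0, sd) * t1 + rng.normal(0.0, sd) * t2
    return out


def _slide_toward_dome(spec: PhantomSpec, pts: np.ndarray, offset: float) -> np.ndarray:
    """Rotate points about the sac centre toward the dome apex by an arc of
    ``offset`` mm along the sphere."""
    c, r = spec.sac_center, spec.sac_radius
    apex_dir = np.array([0.0, 0.0, 1.0])
    ang = offset / r
    out = np.empty_like(pts)
    for i, p in enumerate(pts):
        v = p - c
        vn = v / np.linalg.norm(v)
        axis = np.cross(vn, apex_dir)
        na = np.linalg.norm(axis)
        if na < 1e-12:
            out[i] = p
            continue
        axis /= na
        a = min(ang, np.arccos(np.clip(vn @ apex_dir, -1, 1)))  # stop at apex
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)
        out[i] = c + r * (R @ vn)
    return out


# ---------------------------------------------------------------------------
# Synthetic hemodynamic fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldParams:
    """Parameters of the synthetic WSS / velocity generator.

    Defaults mimic the qualitative picture of aneurysm CFD: a few Pa of
    baseline wall shear, a pronounced high-shear band at the neck, mild
    pulsatility, and an oscillatory (direction-alternating) dome patch.
    """

    period: float = 1.0          # s, one cardiac cycle
    n_samples: int = 33
    base_wss: float = 2.0        # Pa
    neck_amp: float = 10.0       # Pa, Gaussian bump at the neck
    neck_sigma: float = 1.0      # mm
    pulsatility: float = 0.5     # waveform = 1 + p*sin(2 pi t / T)
    dome_radius: float = 2.0     # mm around the apex
    dome_osc_amp: float = 2.0    # Pa, zero-mean alternating component
    dome_reversing: bool = False # True: dome field is purely oscillatory
    q0: float = 1.0              # mL/s prescribed net ostium inflow
    steady_inflow: bool = True


def synthetic_fields(mesh: TriangleMesh, neck_polyline: np.ndarray,
                     patch: OstiumPatch, params: FieldParams = FieldParams(),
                     spec: PhantomSpec | None = None, seed: int = 0,
                     ) -> tuple[SurfaceFieldSeries, SurfaceFieldSeries]:
    """(WSS on mesh faces, velocity on ostium-patch faces).

    WSS magnitude = base + amp * exp(-d_neck^2 / (2 sigma^2)) with a
    tangential direction and a pulsatile waveform; faces near the dome apex
    get a zero-mean alternating component (fully reversing if requested).
    Velocity is a paraboloid profile through the patch scaled so the steady
    net inflow equals ``q0`` mL/s exactly under the midpoint quadrature.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, params.period, params.n_samples)
    wave = 1.0 + params.pulsatility * np.sin(2 * np.pi * t / params.period)
    osc = np.sin(2 * np.pi * t / params.period)

    cent = mesh.face_centroids()
    normals = mesh.face_normals()
    d_neck = _min_dist_to_polyline(cent, neck_polyline)
    mag = params.base_wss + params.neck_amp * np.exp(
        -d_neck ** 2 / (2 * params.neck_sigma ** 2))
    t1 = _tangent_dirs(normals, np.array([1.0, 0.0, 0.0]))
    t2 = np.cross(normals, t1)

    apex = (spec.dome_apex if spec is not None
            else neck_polyline.mean(axis=0) + np.array([0, 0, 1e3]))
    dome = np.linalg.norm(cent - apex, axis=1) <= params.dome_radius
    steady_mag = mag.copy()
    if params.dome_reversing:
        steady_mag[dome] = 0.0
    osc_amp = np.where(dome, params.dome_osc_amp
                       + (params.base_wss if params.dome_reversing else 0.0), 0.0)

    wss = (wave[:, None, None] * steady_mag[None, :, None] * t1[None]
           + osc[:, None, None] * osc_amp[None, :, None] * t2[None])
    wss_series = SurfaceFieldSeries(np.arange(mesh.n_faces), t, wss, on="face")

    vel_series = paraboloid_inflow(patch, params.q0, t,
                                   None if params.steady_inflow else wave)
    return wss_series, vel_series


def paraboloid_inflow(patch: OstiumPatch, q0: float, times: np.ndarray,
                      waveform: np.ndarray | None = None) -> SurfaceFieldSeries:
    """Velocity series on patch faces with prescribed net inflow (mL/s)."""
    normals = patch.face_normals()
    areas = patch.face_areas()
    cent = patch.vertices[patch.faces].mean(axis=1)
    c0 = (cent * areas[:, None]).sum(axis=0) / areas.sum()
    rho = np.linalg.norm(cent - c0, axis=1)
    R = rho.max() * 1.05 + 1e-12
    profile = 1.0 - (rho / R) ** 2
    flux = (profile * areas).sum()         # mm^3/s per unit speed scale
    scale = q0 * 1000.0 / flux
    v = scale * profile[:, None] * normals
    w = np.ones(len(times)) if waveform is None else waveform
    vecs = w[:, None, None] * v[None]
    return SurfaceFieldSeries(np.arange(len(patch.faces)), times, vecs, on="face")


def _tangent_dirs(normals: np.ndarray, ref: np.ndarray) -> np.ndarray:
    t = ref[None] - (normals @ ref)[:, None] * normals
    bad = np.linalg.norm(t, axis=1) < 1e-8
    if bad.any():
        alt = np.array([0.0, 1.0, 0.0])
        t[bad] = alt[None] - (normals[bad] @ alt)[:, None] * normals[bad]
    return t / np.linalg.norm(t, axis=1, keepdims=True)


def _min_dist_to_polyline(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    from .neck_curve import _point_segment_distances
    a = polyline
    b = np.roll(polyline, -1, axis=0)
    return _point_segment_distances(points, a, b)
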