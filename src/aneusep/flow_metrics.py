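"""Neck-curve-dependent hemodynamic summaries.

These are post-processing quantities computed from supplied wall-shear and
velocity field series (CFD solving itself is upstream):

* OSI  = 0.5 * (1 - ||int tau dt|| / int ||tau|| dt)  in [0, 0.5]
* AWSS_bar = area-weighted sac mean of the cycle-averaged |tau|  (Pa)
* Q_in = cycle-average of the inward flux  int max(0, v.n) dA  over the
  ostium patch, reported in mL/s (mm^3/s / 1000)

Time integrals use the trapezoidal rule over one cardiac period; vertex
fields are averaged onto faces before area weighting. OSI of an element
with zero cumulative shear is defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_mesh import NeckCurve, SurfaceFieldSeries, TriangleMesh
from .errors import ValidationError
from .morphometry import SacRegion, extract_sac, sac_area
from .ostium import OstiumPatch, smooth_patch, triangulate_cap
from .variability import relative_report

__all__ = ["HemoMetrics", "osi_per_element", "awss", "q_in",
           "metrics_for_solutions"]

SOLUTION_LABELS = ("min", "median", "max")


@dataclass(frozen=True)
class HemoMetrics:
    """Per-solution hemodynamic summary row."""

    Q_in: float       # mL/s
    AWSS_bar: float   # Pa
    OSI_bar: float    # dimensionless, area-weighted sac mean
    OSI_max: float    # dimensionless
    OSI_bar_plain: float = float("nan")  # unweighted mean, for comparison
    Q_net: float = float("nan")          # signed net flux, mL/s
    solution: str = "median"

    def __post_init__(self):
        if self.solution not in SOLUTION_LABELS:
            raise ValidationError(f"solution must be one of {SOLUTION_LABELS}")
        if self.Q_in < 0 or self.AWSS_bar < 0:
            raise ValidationError("Q_in and AWSS_bar must be non-negative")
        if not (0 <= self.OSI_bar <= self.OSI_max <= 0.5 + 1e-12):
            raise ValidationError("need 0 <= OSI_bar <= OSI_max <= 0.5")


def _face_series(series: SurfaceFieldSeries, mesh_faces: np.ndarray) -> np.ndarray:
    """(T, F, 3) face-valued samples; vertex fields averaged per face."""
    if series.on == "face":
        return series.vectors
    vid = {int(e): k for k, e in enumerate(series.element_ids)}
    try:
        cols = np.array([[vid[int(v)] for v in f] for f in mesh_faces])
    except KeyError as exc:
        raise ValidationError(f"vertex {exc} missing from field series") from exc
    return series.vectors[:, cols, :].mean(axis=2)


def osi_per_element(series: SurfaceFieldSeries) -> np.ndarray:
    """Oscillatory shear index per element, in [0, 0.5]."""
    t, v = series.times, series.vectors
    mean_vec = np.trapezoid(v, t, axis=0)
    mean_mag = np.trapezoid(np.linalg.norm(v, axis=2), t, axis=0)
    osi = np.zeros(series.n_elements)
    nz = mean_mag > 0
    osi[nz] = 0.5 * (1.0 - np.linalg.norm(mean_vec[nz], axis=1) / mean_mag[nz])
    return np.clip(osi, 0.0, 0.5)


def awss(series: SurfaceFieldSeries, sac: SacRegion) -> float:
    """Area-weighted sac mean of the cycle-averaged WSS magnitude (Pa)."""
    face_vals = _face_series(series, sac.mesh.faces)
    period = series.period
    tavg_mag = np.trapezoid(np.linalg.norm(face_vals, axis=2),
                            series.times, axis=0) / period
    if series.on == "face":
        lookup = {int(e): k for k, e in enumerate(series.element_ids)}
        try:
            idx = np.array([lookup[int(f)] for f in sac.face_ids])
        except KeyError as exc:
            raise ValidationError(f"face {exc} missing from WSS series") from exc
        vals = tavg_mag[idx]
    else:
        vals = tavg_mag[sac.face_ids]
    w = sac.areas()
    return float((vals * w).sum() / w.sum())


def osi_summary(series: SurfaceFieldSeries, sac: SacRegion
                ) -> tuple[float, float, float]:
    """(area-weighted mean, plain mean, max) OSI over the sac."""
    osi = osi_per_element(series)
    lookup = {int(e): k for k, e in enumerate(series.element_ids)}
    if series.on == "face":
        idx = np.array([lookup[int(f)] for f in sac.face_ids])
        vals = osi[idx]
    else:
        cols = np.array([[lookup[int(v)] for v in f] for f in sac.faces])
        vals = osi[cols].mean(axis=1)
    w = sac.areas()
    return (float((vals * w).sum() / w.sum()), float(vals.mean()), float(vals.max()))


def q_in(series: SurfaceFieldSeries, patch: OstiumPatch) -> tuple[float, float]:
    """(Q_in, Q_net) in mL/s through the ostium patch.

    The velocity series lives on patch faces (mm/s); the patch must already
    be oriented with normals toward the sac. Per-face flux uses the
    midpoint rule v_f . n_f * A_f; only inward (positive) flux counts for
    Q_in, the signed sum is Q_net.
    """
    if series.on != "face":
        raise ValidationError("q_in expects a face-valued velocity series")
    if series.n_elements != len(patch.faces):
        raise ValidationError("velocity series does not match the patch faces")
    normals = patch.face_normals()
    areas = patch.face_areas()
    vn = np.einsum("tfk,fk->tf", series.vectors, normals)         # mm/s
    inward = np.maximum(vn, 0.0) * areas                          # mm^3/s
    signed = vn * areas
    period = series.period
    q_inward = np.trapezoid(inward.sum(axis=1), series.times) / period
    q_signed = np.trapezoid(signed.sum(axis=1), series.times) / period
    return q_inward / 1000.0, q_signed / 1000.0


def metrics_for_solutions(mesh: TriangleMesh,
                          curves: dict[str, NeckCurve],
                          wss: SurfaceFieldSeries,
                          velocity_for_patch,
                          dome_seed: np.ndarray | None = None,
                          ) -> tuple[dict[str, HemoMetrics], "object"]:
    """Hemodynamic summaries for the min/median/max-area neck curves.

    ``velocity_for_patch(patch, label) -> SurfaceFieldSeries`` supplies the
    ostium velocity field per solution (the ostium geometry depends on the
    curve, so the field cannot be shared). Returns the per-solution metrics
    and a tidy report DataFrame with columns A_a, Q_in, AWSS_bar, OSI_bar,
    OSI_max and the percent differences of min/max against the median.
    """
    import pandas as pd

    for label in SOLUTION_LABELS:
        if label not in curves:
            raise ValidationError(f"curves must contain a {label!r} solution")
    rows: dict[str, HemoMetrics] = {}
    areas: dict[str, float] = {}
    for label in SOLUTION_LABELS:
        curve = curves[label]
        sac = extract_sac(mesh, curve, dome_seed=dome_seed)
        patch = smooth_patch(triangulate_cap(curve))
        sac_centroid = mesh.vertices[sac.vertex_ids].mean(axis=0)
        patch = patch.oriented(toward=sac_centroid)
        vel = velocity_for_patch(patch, label)
        qi, qn = q_in(vel, patch)
        aw = awss(wss, sac)
        osi_w, osi_plain, osi_mx = osi_summary(wss, sac)
        rows[label] = HemoMetrics(Q_in=qi, AWSS_bar=aw, OSI_bar=osi_w,
                                  OSI_max=osi_mx, OSI_bar_plain=osi_plain,
                                  Q_net=qn, solution=label)
        areas[label] = sac_area(sac)

    columns = ["A_a", "Q_in", "AWSS_bar", "OSI_bar", "OSI_max"]
    data = {
        "A_a": areas,
        "Q_in": {s: rows[s].Q_in for s in SOLUTION_LABELS},
        "AWSS_bar": {s: rows[s].AWSS_bar for s in SOLUTION_LABELS},
        "OSI_bar": {s: rows[s].OSI_bar for s in SOLUTION_LABELS},
        "OSI_max": {s: rows[s].OSI_max for s in SOLUTION_LABELS},
    }
    table = pd.DataFrame(data, columns=columns).loc[list(SOLUTION_LABELS)]
    for col in columns:
        rel = relative_report(dict(zip(SOLUTION_LABELS,
                                       table[col][list(SOLUTION_LABELS)])))
        table[f"{col}_rel_pct"] = [rel["min"], 0.0, rel["max"]]
    return rows, table
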