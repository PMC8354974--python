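"""Multi-annotator neck-curve variability.

The directed distance between two curves is

    D'(A, B) = sqrt( sum_i  min_j ||p_i - q_j||^2 )

over the stored polyline points of A against those of B (point counts may
differ), and the symmetrised pairwise difference is D = (D'(A,B) +
D'(B,A)) / 2. The annotator whose row sum over the distance matrix is
smallest provides the *median* neck curve. D is a symmetric premetric
(non-negative, zero on the diagonal); it does not satisfy the triangle
inequality in general and grows with point count, so an optional uniform
arc-length resampling (0.1 mm step) is offered — off by default to stay
faithful to the stored annotations.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .core_mesh import CurveSet, NeckCurve
from .errors import ValidationError

__all__ = ["CurveDistanceMatrix", "directed_distance", "pairwise_distance",
           "distance_matrix", "median_curve", "group_split",
           "relative_report", "export_heatmap"]

RESAMPLE_STEP = 0.1  # mm, when resampling is requested


@dataclass(frozen=True)
class CurveDistanceMatrix:
    """Symmetric pairwise curve-distance matrix (mm) with annotator order."""

    values: np.ndarray
    annotator_ids: tuple[str, ...]
    groups: tuple[str, ...] = ()

    def __post_init__(self):
        m = np.asarray(self.values, dtype=np.float64)
        n = len(self.annotator_ids)
        if m.shape != (n, n):
            raise ValidationError("matrix shape must match annotator count")
        if (m < 0).any() or not np.allclose(np.diag(m), 0):
            raise ValidationError("distances must be non-negative with a zero diagonal")
        if not np.allclose(m, m.T):
            raise ValidationError("distance matrix must be symmetric")
        object.__setattr__(self, "values", m)
        object.__setattr__(self, "annotator_ids", tuple(self.annotator_ids))
        groups = tuple(self.groups) if self.groups else ("unknown",) * n
        if len(groups) != n:
            raise ValidationError("group labels must match annotator count")
        object.__setattr__(self, "groups", groups)

    def __len__(self) -> int:
        return len(self.annotator_ids)

    def row_sums(self) -> np.ndarray:
        return self.values.sum(axis=1)


def _curve_points(curve: NeckCurve | np.ndarray, resample_step: float | None):
    if isinstance(curve, NeckCurve):
        if resample_step is not None:
            n = max(3, int(np.ceil(curve.length() / resample_step)))
            return curve.resample(n)
        return curve.points
    pts = np.asarray(curve, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) == 0:
        raise ValidationError("curve must be a non-empty (N, 3) point array")
    return pts


def directed_distance(curve_a, curve_b, resample_step: float | None = None) -> float:
    """D'(A, B): root of summed squared nearest-point distances, A onto B."""
    pa = _curve_points(curve_a, resample_step)
    pb = _curve_points(curve_b, resample_step)
    d = cdist(pa, pb)
    return float(np.sqrt((d.min(axis=1) ** 2).sum()))


def pairwise_distance(curve_a, curve_b, resample_step: float | None = None) -> float:
    """Symmetrised pairwise difference D = (D'(A,B) + D'(B,A)) / 2 (mm)."""
    return 0.5 * (directed_distance(curve_a, curve_b, resample_step)
                  + directed_distance(curve_b, curve_a, resample_step))


def distance_matrix(curves: CurveSet, resample_step: float | None = None
                    ) -> CurveDistanceMatrix:
    n = len(curves)
    if n == 0:
        raise ValidationError("empty curve set")
    pts = [_curve_points(c, resample_step) for c in curves]
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = cdist(pts[i], pts[j])
            dij = np.sqrt((d.min(axis=1) ** 2).sum())
            dji = np.sqrt((d.min(axis=0) ** 2).sum())
            m[i, j] = m[j, i] = 0.5 * (dij + dji)
    return CurveDistanceMatrix(m, tuple(curves.annotator_ids), tuple(curves.groups))


def median_curve(matrix: CurveDistanceMatrix) -> int:
    """Index of the annotator with the smallest cumulative distance to all
    others (row-sum argmin; ties -> lowest index)."""
    return int(np.argmin(matrix.row_sums()))


def group_split(matrix: CurveDistanceMatrix, group: str
                ) -> tuple[CurveDistanceMatrix, int]:
    """Principal sub-matrix for one annotator group and its median index
    (relative to the sub-matrix order)."""
    sel = [i for i, g in enumerate(matrix.groups) if g == group]
    if not sel:
        raise ValidationError(f"no annotators in group {group!r}")
    idx = np.asarray(sel)
    sub = CurveDistanceMatrix(
        matrix.values[np.ix_(idx, idx)],
        tuple(matrix.annotator_ids[i] for i in sel),
        tuple(matrix.groups[i] for i in sel))
    return sub, median_curve(sub)


def _round_half_away(x: float, decimals: int = 1) -> float:
    scale = 10.0 ** decimals
    return float(np.sign(x) * np.floor(np.abs(x) * scale + 0.5) / scale)


def relative_report(values: dict[str, float]) -> dict[str, float]:
    """Percent differences of the min/max solutions against the median.

    ``values`` maps {'min', 'median', 'max'} to per-solution scalars;
    returns {'min', 'max'} -> 100 * (v - v_median) / v_median, rounded to
    one decimal half-away-from-zero (the convention used in tabulated
    min/median/max comparisons).
    """
    for key in ("min", "median", "max"):
        if key not in values:
            raise ValidationError(f"relative_report needs a {key!r} entry")
    med = values["median"]
    if med == 0:
        # a zero median is meaningful only when nothing differs (e.g. OSI
        # of a steady field); any actual difference is then undefined
        if all(values[s] == 0 for s in ("min", "max")):
            return {"min": 0.0, "max": 0.0}
        raise ValidationError("median value must be non-zero")
    return {s: _round_half_away(100.0 * (values[s] - med) / med)
            for s in ("min", "max")}


def export_heatmap(matrix: CurveDistanceMatrix, path: str | Path,
                   vmax: float | None = None, render: bool = False) -> Path:
    """CSV of the distance matrix (annotator ids as header row/column; the
    median annotator flagged with ``*``). With ``render=True`` a PNG
    heatmap is written next to the CSV; ``vmax`` pins the colour scale so a
    batch of cases shares one scale."""
    path = Path(path)
    med = median_curve(matrix)
    ids = [f"{a}*" if i == med else a for i, a in enumerate(matrix.annotator_ids)]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["annotator"] + ids)
        for i, row in enumerate(matrix.values):
            w.writerow([ids[i]] + [repr(float(x)) for x in row])
    if render:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(matrix.values, cmap="viridis", vmin=0.0,
                       vmax=vmax if vmax is not None else matrix.values.max())
        ax.set_xticks(range(len(ids)), ids, rotation=90, fontsize=6)
        ax.set_yticks(range(len(ids)), ids, fontsize=6)
        fig.colorbar(im, ax=ax, label="pairwise curve distance D (mm)")
        fig.tight_layout()
        fig.savefig(path.with_suffix(".png"), dpi=150)
        plt.close(fig)
    return path


def read_heatmap_csv(path: str | Path) -> CurveDistanceMatrix:
    """Round-trip reader for :func:`export_heatmap` CSVs."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    ids = [h.rstrip("*") for h in rows[0][1:]]
    values = np.array([[float(x) for x in r[1:]] for r in rows[1:]])
    return CurveDistanceMatrix(values, tuple(ids))


def batch_export(matrices: dict[str, CurveDistanceMatrix], out_dir: str | Path,
                 render: bool = False) -> float:
    """Export several cases with a shared colour scale; the global maximum
    is recorded in ``scale.json`` beside the CSVs and returned."""
    import json
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vmax = max(float(m.values.max()) for m in matrices.values())
    for name, m in matrices.items():
        export_heatmap(m, out_dir / f"{name}.csv", vmax=vmax, render=render)
    (out_dir / "scale.json").write_text(json.dumps({"vmax": vmax}))
    return vmax
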