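"""CSV exchange for surface field series.

Long format, one sample per row: ``element_id, t, vx, vy, vz`` with time in
seconds and vectors in Pa (WSS) or mm/s (velocity). Every element must be
sampled at every time point.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core_mesh import SurfaceFieldSeries
from .errors import SchemaError

COLUMNS = ["element_id", "t", "vx", "vy", "vz"]


def write_field_csv(series: SurfaceFieldSeries, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for ti, t in enumerate(series.times):
        for ei, e in enumerate(series.element_ids):
            v = series.vectors[ti, ei]
            rows.append((int(e), float(t), v[0], v[1], v[2]))
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False)
    return path


def read_field_csv(path: str | Path, on: str = "face") -> SurfaceFieldSeries:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    times = np.sort(df["t"].unique())
    elements = np.sort(df["element_id"].unique())
    pivot = df.set_index(["t", "element_id"]).sort_index()
    try:
        vecs = pivot[["vx", "vy", "vz"]].to_numpy().reshape(
            len(times), len(elements), 3)
    except ValueError as exc:
        raise SchemaError(
            f"{path}: every element must be sampled at every time") from exc
    return SurfaceFieldSeries(elements, times, vecs, on=on)
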