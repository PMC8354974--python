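"""Published reference measurements bundled for worked examples.

A multi-reader study of aneurysm neck-curve variability reported, for five
patient cases, the sac surface area and four hemodynamic parameters of the
CFD solutions built from the minimum-, median- and maximum-area neck
curves. Those printed absolute values are bundled here so the relative-
difference reporting (:func:`aneusep.variability.relative_report`) and its
aggregates can be exercised on real published numbers without any patient
geometry.

Units: ``A_a`` cm^2, ``Q_in`` mL/s, ``AWSS_bar`` Pa, ``OSI_bar`` 1e-3,
``OSI_max`` dimensionless.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # case, solution, A_a,   Q_in,  AWSS_bar, OSI_bar(1e-3), OSI_max
    (1, "min",    0.274, 0.483, 10.856, 0.659,  0.069),
    (1, "median", 0.284, 0.479, 11.823, 0.666,  0.069),
    (1, "max",    0.312, 0.589, 13.573, 0.884,  0.131),
    (2, "min",    0.480, 0.426,  4.738, 1.890,  0.385),
    (2, "median", 0.508, 0.435,  4.900, 1.890,  0.380),
    (2, "max",    0.528, 0.426,  5.326, 2.250,  0.385),
    (3, "min",    4.020, 6.064,  3.722, 81.150, 0.490),
    (3, "median", 4.632, 7.749,  4.862, 73.970, 0.491),
    (3, "max",    4.803, 6.222,  5.206, 71.820, 0.491),
    (4, "min",    1.101, 1.034,  6.258, 5.700,  0.424),
    (4, "median", 1.154, 1.543,  7.547, 5.790,  0.424),
    (4, "max",    1.213, 1.887,  8.887, 5.700,  0.424),
    (5, "min",    2.158, 1.737,  2.901, 20.200, 0.473),
    (5, "median", 2.209, 1.754,  3.014, 19.800, 0.473),
    (5, "max",    2.290, 1.867,  3.157, 19.300, 0.473),
]

METRICS = ("A_a", "Q_in", "AWSS_bar", "OSI_bar", "OSI_max")


def neck_variability_study_table() -> pd.DataFrame:
    """Published min/median/max solution values, indexed (case, solution)."""
    df = pd.DataFrame(_ROWS, columns=["case", "solution", *METRICS])
    return df.set_index(["case", "solution"])


def solution_values(case: int, metric: str) -> dict[str, float]:
    """{'min','median','max'} -> published value for one case/metric."""
    df = neck_variability_study_table()
    return {s: float(df.loc[(case, s), metric]) for s in ("min", "median", "max")}


def aggregate_solution_reldiffs(metric: str = "AWSS_bar"):
    """Across the five cases: mean and population SD of the unrounded
    percent difference of the min- and max-area solutions vs the median.

    Returns {'min': (mean, sd), 'max': (mean, sd)} in percent points.
    """
    import numpy as np

    df = neck_variability_study_table()
    out = {}
    for sol in ("min", "max"):
        rel = []
        for case in sorted({c for c, _ in df.index}):
            med = df.loc[(case, "median"), metric]
            rel.append(100.0 * (df.loc[(case, sol), metric] - med) / med)
        rel = np.asarray(rel)
        out[sol] = (float(rel.mean()), float(rel.std(ddof=0)))
    return out
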