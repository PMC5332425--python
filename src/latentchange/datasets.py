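"""Packaged empirical fixture: the prosociality intervention summary table.

The published evaluation of the Young Prosocial Animation program reports,
for the intervention group (G1) and control group (G2) separately, the
pairwise-complete correlations, means, SDs, reliabilities and distributional
shape of two parallel 8-item parcels of a 16-item prosociality scale at
pretest (T1) and six-month posttest (T2).  Pretest n was 137/113 and posttest
n (after ~18-20% attrition) 113/91.  These printed statistics are the only
public form of the data; raw cases were never deposited, so model fits to
this fixture use the per-group posttest n as the single summary-statistic n —
the closest complete-data analogue to the original FIML analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimation import GroupData

__all__ = [
    "VARIABLES",
    "prosociality_summary",
    "prosociality_table",
]

VARIABLES = ["pr1_t1", "pr2_t1", "pr1_t2", "pr2_t2"]

# printed descriptive statistics, per group
_G1 = {
    "n_pretest": 137, "n_posttest": 113,
    "means": [3.44, 3.49, 3.62, 3.71],
    "sds": [0.75, 0.72, 0.60, 0.62],
    "skewness": [-0.51, -0.60, -0.34, -0.61],
    "kurtosis": [-0.06, 0.43, -0.13, 0.02],
    "alphas": [0.80, 0.80, 0.74, 0.79],
    "corr_lower": [[1.00],
                   [0.81, 1.00],
                   [0.51, 0.52, 1.00],
                   [0.48, 0.59, 0.78, 1.00]],
}
_G2 = {
    "n_pretest": 113, "n_posttest": 91,
    "means": [3.42, 3.49, 3.49, 3.55],
    "sds": [0.70, 0.71, 0.65, 0.64],
    "skewness": [-0.39, -0.55, -0.27, -0.41],
    "kurtosis": [-0.12, -0.01, -0.44, -0.49],
    "alphas": [0.77, 0.76, 0.75, 0.75],
    "corr_lower": [[1.00],
                   [0.76, 1.00],
                   [0.74, 0.67, 1.00],
                   [0.65, 0.73, 0.78, 1.00]],
}
_RAW = {"G1": _G1, "G2": _G2}


def _corr_full(lower: list[list[float]]) -> np.ndarray:
    p = len(lower)
    r = np.eye(p)
    for i, row in enumerate(lower):
        for j, v in enumerate(row):
            r[i, j] = r[j, i] = v
    return r


def prosociality_summary(n: str = "posttest") -> dict[str, GroupData]:
    """Per-group summary moments of the prosociality evaluation.

    ``n`` selects which printed sample size is attached to the moments:
    ``"posttest"`` (113/91, the default used for model fitting) or
    ``"pretest"`` (137/113).
    """
    if n not in ("posttest", "pretest"):
        raise ValueError("n must be 'posttest' or 'pretest'")
    out = {}
    for gid, d in _RAW.items():
        out[gid] = GroupData.from_summary(
            gid, d[f"n_{n}"], d["means"], d["sds"], _corr_full(d["corr_lower"]),
            names=VARIABLES)
    return out


def prosociality_table() -> pd.DataFrame:
    """The full printed descriptive table (both groups) as a data frame."""
    rows = []
    for gid, d in _RAW.items():
        for i, var in enumerate(VARIABLES):
            rows.append({
                "group": gid, "variable": var,
                "n": d["n_pretest"] if var.endswith("t1") else d["n_posttest"],
                "mean": d["means"][i], "sd": d["sds"][i],
                "skewness": d["skewness"][i], "kurtosis": d["kurtosis"][i],
                "alpha": d["alphas"][i],
            })
    return pd.DataFrame(rows)
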