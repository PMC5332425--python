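"""Reading and writing the package's plain-text data formats.

Raw data: delimited text, one row per case, a group column, NaN/empty cells
for missing values.  Summary statistics: a YAML document with per-group
blocks carrying n, means, SDs and the lower-triangular correlation matrix —
exactly the information a published descriptive table prints.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .estimation import GroupData

__all__ = [
    "read_raw_csv",
    "write_raw_csv",
    "read_summary_yaml",
    "write_summary_yaml",
]


def read_raw_csv(path, *, group_col: str = "group",
                 missing_token: str = "") -> dict[str, GroupData]:
    """Read case-level data; returns one :class:`GroupData` per group."""
    df = pd.read_csv(path, na_values=[missing_token] if missing_token else None,
                     keep_default_na=True)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if group_col not in df.columns:
        raise ValueError(f"{path}: missing group column {group_col!r}")
    value_cols = [c for c in df.columns if c != group_col]
    if not value_cols:
        raise ValueError(f"{path}: no indicator columns")
    return {str(gid): GroupData.from_raw(str(gid), sub[value_cols])
            for gid, sub in df.groupby(group_col, sort=False)}


def write_raw_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_summary_yaml(path) -> dict[str, GroupData]:
    """Read per-group summary statistics from a YAML block file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not doc or "groups" not in doc:
        raise ValueError(f"{path}: expected a top-level 'groups' mapping")
    out = {}
    for gid, block in doc["groups"].items():
        names = block.get("variables")
        means = block["means"]
        sds = block["sds"]
        lower = block["correlations"]
        p = len(means)
        corr = np.eye(p)
        for i, row in enumerate(lower):
            for j, v in enumerate(row):
                corr[i, j] = corr[j, i] = float(v)
        out[str(gid)] = GroupData.from_summary(
            str(gid), int(block["n"]), means, sds, corr, names=names)
    return out


def write_summary_yaml(data: Mapping[str, GroupData], path) -> None:
    doc = {"groups": {}}
    for gid, gd in data.items():
        m, s, n = gd.moments()
        sd = np.sqrt(np.diag(s))
        corr = s / np.outer(sd, sd)
        doc["groups"][gid] = {
            "n": int(n),
            "variables": list(gd.names),
            "means": [round(float(v), 6) for v in m],
            "sds": [round(float(v), 6) for v in sd],
            "correlations": [[round(float(corr[i, j]), 6) for j in range(i + 1)]
                             for i in range(len(m))],
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
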