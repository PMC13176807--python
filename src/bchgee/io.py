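"""Tabular I/O and validation for school panels and child tables.

Interchange format is plain CSV.  A school panel has columns
``school_id, time, u_1 .. u_J`` (one row per school-time, balanced); a
child table has ``school_id, time, child, y`` plus covariate columns
(``z`` in the simulated designs).
"""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone

import numpy as np
import pandas as pd

__all__ = [
    "provenance_record",
    "read_child_table",
    "read_school_table",
    "write_child_table",
    "write_school_table",
]


def read_school_table(path) -> pd.DataFrame:
    """Read and validate a school count panel from CSV."""
    df = pd.read_csv(path)
    for col in ("school_id", "time"):
        if col not in df.columns:
            raise ValueError(f"school table is missing column {col!r}")
    ucols = [c for c in df.columns if c.startswith("u_")]
    if not ucols:
        raise ValueError("school table has no count columns u_1..u_J")
    for col in ucols:
        vals = df[col].to_numpy()
        bad = ~np.isfinite(vals) | (vals != np.floor(vals)) | (vals < 0)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"column {col!r} row {i}: {vals[i]!r} is not a "
                f"nonnegative integer count")
        df[col] = vals.astype(np.int64)
    counts = df.groupby("school_id")["time"].agg(["count", "nunique"])
    T = df["time"].nunique()
    unbalanced = counts[(counts["count"] != T) | (counts["nunique"] != T)]
    if len(unbalanced):
        raise ValueError(
            f"panel is unbalanced for school_id(s) "
            f"{unbalanced.index.tolist()[:10]} (expected one row for each "
            f"of {T} time points)")
    return df


def read_child_table(path, school_panel: pd.DataFrame | None = None
                     ) -> pd.DataFrame:
    """Read and validate a child outcome table from CSV.

    When a school panel is supplied, every child's (school_id, time) must
    exist in it.
    """
    df = pd.read_csv(path)
    for col in ("school_id", "time", "y"):
        if col not in df.columns:
            raise ValueError(f"child table is missing column {col!r}")
    if not np.all(np.isfinite(df["y"].to_numpy(dtype=float))):
        i = int(np.flatnonzero(~np.isfinite(df["y"].to_numpy(float)))[0])
        raise ValueError(f"non-finite outcome at row {i}")
    if school_panel is not None:
        keys = set(map(tuple, school_panel[["school_id", "time"]].to_numpy()))
        child_keys = df[["school_id", "time"]].drop_duplicates()
        missing = [k for k in map(tuple, child_keys.to_numpy())
                   if k not in keys]
        if missing:
            raise ValueError(
                f"child rows reference unknown school-times: {missing[:10]}")
    return df


def write_school_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_child_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def provenance_record(config: dict, seed) -> dict:
    """Machine-readable record tying an output artifact to its inputs."""
    import bchgee

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config": config,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "package_version": bchgee.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "python_version": platform.python_version(),
        "created_utc": datetime.now(timezone.utc).isoformat(),
    }
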