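"""Event-record and results I/O.

The event-record table is a NONMEM-like CSV dialect: one row per dose or
observation with columns ID, TIME (h), AMT (mg), DV (ng/mL), EVID (1 = dose,
0 = observation), ROUTE, plus covariate columns (AGE, WT, BCCL, ASIAN, AST,
BPLTS, STUDY).  Missing DV is coded as an empty field.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_event_records", "read_event_records", "write_outcomes", "read_outcomes"]

EVENT_COLUMNS = ["ID", "TIME", "AMT", "DV", "EVID", "ROUTE"]


def write_event_records(df: pd.DataFrame, path) -> None:
    """Write an event-record CSV; DV of dose rows is left empty."""
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event-record table missing columns: {missing}")
    out = df.copy()
    cols = EVENT_COLUMNS + [c for c in out.columns if c not in EVENT_COLUMNS]
    out[cols].to_csv(path, index=False, na_rep="")


def read_event_records(path) -> pd.DataFrame:
    """Read an event-record CSV written by :func:`write_event_records`."""
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event-record file {path} missing columns: {missing}")
    df["DV"] = pd.to_numeric(df["DV"], errors="coerce")
    df["EVID"] = df["EVID"].astype(int)
    return df


def write_outcomes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_outcomes(path) -> pd.DataFrame:
    return pd.read_csv(path)
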