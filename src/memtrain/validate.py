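"""Validation of long-format visit tables supplied by users."""

from __future__ import annotations

from typing import Union

import numpy as np
import pandas as pd

from .design import ARM_PERIODS, STATUS_LEVELS, VISIT_COLUMNS, AGE_GROUPS


def validate_input_table(table: Union[str, pd.DataFrame]) -> list[str]:
    """Check a visit table against the long-format contract.

    Returns a machine-readable list of violation messages; an empty list
    means the table is valid.  Nothing is coerced silently.
    """
    if isinstance(table, (str, bytes)) or hasattr(table, "__fspath__"):
        table = pd.read_csv(table, dtype={"participant_id": str})
    errors: list[str] = []
    missing = [c for c in VISIT_COLUMNS if c not in table.columns]
    if missing:
        errors.append(f"missing columns: {missing}")
        return errors

    def _check_range(col, low, high):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[vals.notna() & ((vals < low) | (vals > high))]
        for i in bad:
            errors.append(f"row {i}: {col}={table.loc[i, col]!r} outside [{low}, {high}]")

    _check_range("memory_score", 0, 100)
    _check_range("wordpair_score", 0, 36)
    for col in ("hippocampus_mm3", "icv_mm3"):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[vals.notna() & (vals <= 0)]
        for i in bad:
            errors.append(f"row {i}: {col} must be positive")
    for i in table.index[~table["status"].isin(STATUS_LEVELS)]:
        errors.append(f"row {i}: unknown status {table.loc[i, 'status']!r}")
    for i in table.index[~table["arm"].isin(ARM_PERIODS)]:
        errors.append(f"row {i}: unknown arm {table.loc[i, 'arm']!r}")
    for i in table.index[~table["age_group"].isin(AGE_GROUPS)]:
        errors.append(f"row {i}: unknown age_group {table.loc[i, 'age_group']!r}")
    x1 = pd.to_numeric(table["x1"], errors="coerce")
    x2 = pd.to_numeric(table["x2"], errors="coerce")
    for i in table.index[(x1 + x2) > 1]:
        errors.append(f"row {i}: x1 + x2 > 1")
    for pid, sub in table.groupby("participant_id"):
        t = pd.to_numeric(sub.sort_values("visit_index")["t_years"], errors="coerce")
        if t.isna().any():
            errors.append(f"participant {pid}: non-numeric t_years")
        elif (np.diff(t.to_numpy()) <= 0).any():
            errors.append(f"participant {pid}: t_years not strictly increasing")
    return errors
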