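"""Cohort-demographics summarization (a Table-1-style report).

For each categorical characteristic the report lists category counts, the
denominator and the percentage rounded to the nearest integer, half away
from zero.  Missing values are coded "Unknown".
"""

from __future__ import annotations

import math
from typing import Iterable

import pandas as pd

from .errors import FormatError

UNKNOWN = "Unknown"


def round_half_away(x: float) -> int:
    """Round to nearest integer with halves away from zero (1.5 -> 2, 0.5 -> 1)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def summarize(table: pd.DataFrame, characteristics: Iterable[str]) -> pd.DataFrame:
    """Counts and rounded percentages per category of each characteristic.

    Columns: characteristic, category, count, denominator, percent.
    Categories appear in order of first appearance, Unknown last.
    """
    if table.empty:
        raise FormatError("cannot summarize an empty table")
    denom = len(table)
    rows = []
    for char in characteristics:
        if char not in table.columns:
            raise FormatError(f"missing column {char}")
        col = table[char].astype(object).where(table[char].notna(), UNKNOWN).astype(str)
        cats = [c for c in pd.unique(col) if c != UNKNOWN]
        if (col == UNKNOWN).any():
            cats.append(UNKNOWN)
        for cat in cats:
            count = int((col == cat).sum())
            rows.append(
                {
                    "characteristic": char,
                    "category": cat,
                    "count": count,
                    "denominator": denom,
                    "percent": round_half_away(100.0 * count / denom),
                }
            )
    return pd.DataFrame(rows)


def compare_printed(report: pd.DataFrame, printed: pd.DataFrame) -> pd.DataFrame:
    """Flag rows whose recomputed percent disagrees with a printed table.

    ``printed`` needs columns characteristic, category, percent.  Returns
    the merged report with ``printed_percent`` and a ``mismatch`` flag,
    so internally inconsistent source rows can be surfaced rather than
    silently reproduced.
    """
    merged = report.merge(
        printed.rename(columns={"percent": "printed_percent"}),
        on=["characteristic", "category"],
        how="left",
    )
    merged["mismatch"] = merged["printed_percent"].notna() & (
        merged["printed_percent"] != merged["percent"]
    )
    return merged
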