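"""Readers and writers for the pipeline's tabular formats.

Two dialects are used throughout:

* **cell tables** — tab-separated, UTF-8, one row per segmented cell with
  ``cell_id``, ``core_id``, centroid coordinates ``x_um``/``y_um`` in
  micrometres (origin at the core's top-left bounding box, y increasing
  downward, i.e. image convention) and one strictly binary {0,1} column per
  marker.  Marker columns are auto-detected as every column that is not a
  reserved name.
* **clinical tables** — comma-separated, one row per case with metastasis-
  and recurrence-free survival times (months) and event indicators plus the
  initial-metastasis flag used to exclude cases from survival analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import FormatError

#: Columns of a cell table that are never treated as markers.
RESERVED_CELL_COLUMNS = ("cell_id", "core_id", "x_um", "y_um", "phenotype", "true_phenotype")

REQUIRED_CELL_COLUMNS = ("cell_id", "core_id", "x_um", "y_um")

CLINICAL_COLUMNS = (
    "case_id",
    "initial_metastasis",
    "met_event",
    "met_time",
    "rec_event",
    "rec_time",
)

_BOOL_OK = {0, 1, True, False}


def marker_columns(cells: pd.DataFrame) -> list[str]:
    """Marker columns of a cell table = everything not reserved."""
    return [c for c in cells.columns if c not in RESERVED_CELL_COLUMNS]


def validate_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Validate a cell table in memory; returns the (typed) table.

    Raises :class:`FormatError` naming the offending column or 1-based data
    row on the first violation found.
    """
    for col in REQUIRED_CELL_COLUMNS:
        if col not in cells.columns:
            raise FormatError(f"missing column {col}")
    for col in ("x_um", "y_um"):
        vals = pd.to_numeric(cells[col], errors="coerce")
        if not np.isfinite(vals.to_numpy(dtype=float)).all():
            bad = int(np.flatnonzero(~np.isfinite(vals.to_numpy(dtype=float)))[0]) + 1
            raise FormatError(f"non-finite coordinate in column {col} at row {bad}")
    dup = cells.duplicated(subset=["core_id", "cell_id"])
    if dup.any():
        core, cell = cells.loc[dup.idxmax(), ["core_id", "cell_id"]]
        raise FormatError(f"duplicate cell_id {cell!r} within core {core!r}")
    out = cells.copy()
    out["x_um"] = pd.to_numeric(out["x_um"])
    out["y_um"] = pd.to_numeric(out["y_um"])
    for col in marker_columns(cells):
        arr = cells[col].to_numpy()
        if arr.dtype.kind in "iufb":
            ok = (arr == 0) | (arr == 1)
        else:
            ok = np.isin(arr, (0, 1, "0", "1", 0.0, 1.0, True, False))
        if not ok.all():
            row = int(np.flatnonzero(~ok)[0]) + 1  # 1-based data row
            raise FormatError(
                f"non-binary value {arr[~ok][0]!r} for marker {col} at row {row}"
            )
        out[col] = arr.astype(np.int8)
    return out


def read_cell_table(path) -> pd.DataFrame:
    """Read and validate a tab-separated cell table."""
    cells = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "core_id": str})
    return validate_cell_table(cells)


def write_cell_table(cells: pd.DataFrame, path) -> None:
    """Write a cell table: tab delimiter, UTF-8, '.' decimals, no quoting."""
    cells.to_csv(path, sep="\t", index=False, encoding="utf-8")


def validate_clinical(clin: pd.DataFrame) -> pd.DataFrame:
    for col in CLINICAL_COLUMNS:
        if col not in clin.columns:
            raise FormatError(f"missing column {col}")
    dup = clin["case_id"].duplicated()
    if dup.any():
        ids = sorted(set(clin.loc[dup, "case_id"].astype(str)))
        raise FormatError(f"duplicate case_id: {', '.join(ids)}")
    out = clin.copy()
    out["case_id"] = out["case_id"].astype(str)
    for col in ("initial_metastasis", "met_event", "rec_event"):
        if not clin[col].isin(_BOOL_OK).all():
            raise FormatError(f"non-boolean value in column {col}")
        out[col] = clin[col].astype(bool)
    for col in ("met_time", "rec_time"):
        vals = pd.to_numeric(clin[col])
        if (vals < 0).any():
            case = clin.loc[vals.lt(0).idxmax(), "case_id"]
            raise FormatError(f"negative time in column {col} for case {case!r}")
        out[col] = vals.astype(float)
    for ev, tm in (("met_event", "met_time"), ("rec_event", "rec_time")):
        bad = out[ev] & ~(out[tm] > 0)
        if bad.any():
            case = out.loc[bad.idxmax(), "case_id"]
            raise FormatError(f"{ev} with non-positive {tm} for case {case!r}")
    return out


def read_clinical(path) -> pd.DataFrame:
    """Read and validate a comma-separated clinical table."""
    return validate_clinical(pd.read_csv(path, dtype={"case_id": str}))


def write_clinical(clin: pd.DataFrame, path) -> None:
    out = clin.copy()
    for col in ("initial_metastasis", "met_event", "rec_event"):
        if col in out.columns:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False, encoding="utf-8")
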