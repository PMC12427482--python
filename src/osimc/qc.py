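"""Core- and marker-level quality control.

Core QC: the fraction of nuclear-stain-positive (Ir191+) cells relative to
all nuclear-segmented cells is computed per tissue core; cores with <25%
Ir191+ cells are excluded and downstream analysis is restricted to the
Ir191+ cells of the retained cores, so "total detectable cells" always means
Ir191+ nucleated cells.

Marker QC: a case (one core per case) is positive for a marker if at least 3
cells in its core stain positive; markers positive in fewer than 10% of
cases are excluded.  Both thresholds keep the boundary value, because the
exclusions are phrased with strict "<".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import FormatError
from .io import marker_columns

IR191 = "Ir191"


@dataclass
class QCReport:
    """Per-core and per-marker QC outcome plus the thresholds applied."""

    cores: pd.DataFrame | None = None    # core_id, ir191_fraction, n_cells, pass
    markers: pd.DataFrame | None = None  # marker, positive_case_fraction, n_positive_cases, pass
    thresholds: dict = field(default_factory=dict)


def core_qc(
    cells: pd.DataFrame,
    min_ir191_frac: float = 0.25,
    ir191_col: str = IR191,
) -> tuple[pd.DataFrame, QCReport]:
    """Filter cores by nuclear-stain quality.

    A core is retained iff its Ir191+ fraction is >= ``min_ir191_frac``
    (exactly at the boundary passes).  Returns the retained cells —
    restricted to Ir191+ cells of retained cores — and a :class:`QCReport`.
    """
    if ir191_col not in cells.columns:
        raise FormatError(f"no {ir191_col} column in cell table")
    grp = cells.groupby("core_id", sort=True)[ir191_col]
    frac = grp.mean()
    n = grp.size()
    passed = frac >= min_ir191_frac
    report = pd.DataFrame(
        {
            "core_id": frac.index,
            "n_cells": n.to_numpy(),
            "ir191_fraction": frac.to_numpy(),
            "pass": passed.to_numpy(),
        }
    ).reset_index(drop=True)
    keep_cores = set(frac.index[passed])
    filtered = cells[
        cells["core_id"].isin(keep_cores) & (cells[ir191_col] == 1)
    ].reset_index(drop=True)
    qc = QCReport(cores=report, thresholds={"min_ir191_frac": min_ir191_frac})
    return filtered, qc


def marker_qc(
    cells: pd.DataFrame,
    min_cells_per_core: int = 3,
    min_case_frac: float = 0.10,
    markers: list[str] | None = None,
) -> tuple[list[str], QCReport]:
    """Filter markers by case-level positivity.

    A case is positive for a marker iff >= ``min_cells_per_core`` cells of
    its core are marker-positive; the marker is retained iff the fraction of
    positive cases is >= ``min_case_frac`` (both boundaries keep).  The
    nuclear stain column is not itself subject to marker QC.
    """
    if cells["core_id"].nunique() < 1:
        raise FormatError("marker QC requires at least one core")
    if markers is None:
        markers = [m for m in marker_columns(cells) if m != IR191]
    n_cases = cells["core_id"].nunique()
    pos_cells = cells.groupby("core_id", sort=True)[markers].sum()
    pos_cases = (pos_cells >= min_cells_per_core).sum(axis=0)
    frac = pos_cases / n_cases
    passed = frac >= min_case_frac
    report = pd.DataFrame(
        {
            "marker": markers,
            "n_positive_cases": pos_cases.to_numpy(),
            "positive_case_fraction": frac.to_numpy(),
            "pass": passed.to_numpy(),
        }
    )
    retained = [m for m in markers if passed[m]]
    qc = QCReport(
        markers=report,
        thresholds={
            "min_cells_per_core": min_cells_per_core,
            "min_case_frac": min_case_frac,
        },
    )
    return retained, qc


def drop_failed_markers(cells: pd.DataFrame, retained: list[str]) -> pd.DataFrame:
    """Restrict a cell table to reserved columns, Ir191 and retained markers."""
    keep = [
        c
        for c in cells.columns
        if c in retained or c == IR191 or c not in marker_columns(cells)
    ]
    return cells[keep].copy()
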