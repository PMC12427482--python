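"""Per-core phenotype abundances and composite immunosuppressive-cell scores.

Abundance of a cell type in a core is the percentage of that core's
detectable (Ir191+, QC-passed) cells carrying the label, so each core's row —
including the Unassigned remainder — sums to 100.

The IMSC composite aggregates the three immunosuppressive populations
(M2 macrophages, MDSC = mMDSC + pMDSC pooled, Treg).  ``mean`` mode averages
the three percentages, ``sum`` mode adds them; the two differ by the factor
3, a strictly monotone map, so median-dichotomized groups are identical
under either mode.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .errors import FormatError

MDSC_LABELS = ("mMDSC", "pMDSC")
IMSC_COMPONENTS = ("M2", "MDSC", "Treg")


def abundance_matrix(
    cells: pd.DataFrame,
    label_col: str = "phenotype",
    labels: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Cores x labels matrix of percentages of detectable cells.

    ``labels`` optionally lists the full label set so phenotypes with zero
    cells appear as explicit 0% columns.
    """
    if label_col not in cells.columns:
        raise FormatError(f"cells lack a {label_col!r} column; run phenotyping first")
    if cells.empty:
        raise FormatError("cannot compute abundances of an empty cell table")
    counts = pd.crosstab(cells["core_id"], cells[label_col])
    if labels is not None:
        want = list(dict.fromkeys(list(labels) + list(counts.columns)))
        counts = counts.reindex(columns=want, fill_value=0)
    totals = counts.sum(axis=1)
    empty = totals[totals == 0]
    if len(empty):
        raise FormatError(f"core {empty.index[0]!r} has 0 cells")
    ab = counts.div(totals, axis=0) * 100.0
    ab.columns.name = None
    ab.index.name = "core_id"
    return ab


def pooled_mdsc(ab: pd.DataFrame, mdsc_labels: Iterable[str] = MDSC_LABELS) -> pd.Series:
    """MDSC% = sum of the MDSC subtype percentages."""
    present = [lab for lab in mdsc_labels if lab in ab.columns]
    if not present:
        raise FormatError(
            f"missing component column 'MDSC' (none of {tuple(mdsc_labels)} present)"
        )
    return ab[present].sum(axis=1)


def pairwise_composites(
    ab: pd.DataFrame,
    components: Iterable[str],
    mode: str = "mean",
    mdsc_labels: Iterable[str] = MDSC_LABELS,
) -> pd.Series:
    """Composite abundance over an arbitrary component set.

    ``"MDSC"`` as a component means the pooled mMDSC+pMDSC percentage.
    """
    if mode not in ("mean", "sum"):
        raise ValueError(f"unknown composite mode {mode!r}")
    components = list(components)
    if not components:
        raise FormatError("composite needs at least one component")
    cols = []
    for comp in components:
        if comp == "MDSC" and "MDSC" not in ab.columns:
            cols.append(pooled_mdsc(ab, mdsc_labels).rename("MDSC"))
        elif comp in ab.columns:
            cols.append(ab[comp])
        else:
            raise FormatError(f"missing component column {comp!r}")
    stacked = pd.concat(cols, axis=1)
    score = stacked.sum(axis=1)
    if mode == "mean":
        score = score / len(components)
    score.name = f"{mode}({'+'.join(components)})"
    return score


def imsc_score(ab: pd.DataFrame, mode: str = "mean") -> pd.Series:
    """IMSC composite: mean (or sum) of M2%, MDSC% and Treg% per core."""
    return pairwise_composites(ab, IMSC_COMPONENTS, mode=mode)
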