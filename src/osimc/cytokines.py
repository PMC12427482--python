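"""Co-culture cytokine differential-abundance screen.

Bead-array median fluorescence intensities (MFI) from macrophage–tumor
co-cultures and their mono-culture controls are background-subtracted
(floored at 0 — MFIs are non-negative physical quantities), then screened
analyte by analyte: a two-way ANOVA over culture condition and cell line is
followed by Tukey-HSD-adjusted contrasts of the co-culture against the
mono-culture controls within each cell line.  An analyte is *differentially
abundant* when the contrast is significant in at least ``min_lines`` of the
cell lines (2 of 3 by default).

By default a cell line counts as significant only if the co-culture differs
from **both** its controls (the tumor mono-culture and the macrophage
mono-culture); ``control_mode="either"`` relaxes this to one.
The analysis runs on the linear MFI scale; set ``log=True`` to screen
log-transformed values instead.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import FormatError

CONDITIONS = ("mono_OS", "mono_mac", "co_culture")
CELL_LINES = ("143B", "LM7", "MG63.3")
BACKGROUND = "background"


def subtract_background(raw: pd.DataFrame) -> pd.DataFrame:
    """Subtract the per-analyte mean background MFI, flooring at 0.

    ``raw`` is a long table with columns analyte, condition, cell_line,
    replicate, mfi; rows with ``condition == "background"`` supply the
    blank wells and are removed from the output.
    """
    for col in ("analyte", "condition", "mfi"):
        if col not in raw.columns:
            raise FormatError(f"missing column {col}")
    bg = raw[raw["condition"] == BACKGROUND].groupby("analyte")["mfi"].mean()
    plate = raw[raw["condition"] != BACKGROUND].copy()
    missing = sorted(set(plate["analyte"]) - set(bg.index))
    if missing:
        raise FormatError(f"no background rows for analyte(s): {', '.join(missing)}")
    plate["mfi"] = np.maximum(
        plate["mfi"].to_numpy(float) - bg.reindex(plate["analyte"]).to_numpy(float), 0.0
    )
    return plate.reset_index(drop=True)


def _check_factorial(plate: pd.DataFrame) -> None:
    have = set(zip(plate["analyte"], plate["condition"], plate["cell_line"]))
    missing = [
        (a, c, l)
        for a in plate["analyte"].unique()
        for c in CONDITIONS
        for l in CELL_LINES
        if (a, c, l) not in have
    ]
    if missing:
        cells = "; ".join(f"{a}/{c}/{l}" for a, c, l in missing[:5])
        raise FormatError(f"missing factorial cell(s): {cells}")


def _tukey_pvalues(sub: pd.DataFrame, alpha: float) -> dict[tuple[str, str], float]:
    """Tukey-adjusted p for every pair of condition:line groups of one analyte."""
    group = (sub["condition"] + ":" + sub["cell_line"]).to_numpy()
    res = pairwise_tukeyhsd(sub["mfi"].to_numpy(float), group, alpha=alpha)
    pairs = list(combinations(res.groupsunique, 2))
    return {pair: float(p) for pair, p in zip(pairs, res.pvalues)}


def screen_differential(
    plate: pd.DataFrame,
    alpha: float = 0.05,
    min_lines: int = 2,
    control_mode: str = "both",
    log: bool = False,
) -> tuple[set[str], pd.DataFrame]:
    """Select differentially abundant analytes by the >=2-of-3 rule.

    Returns the selected analyte set and a per-(analyte, cell line) report
    with the Tukey-adjusted contrast p-values and the two-way-ANOVA main and
    interaction effects.
    """
    if control_mode not in ("both", "either"):
        raise ValueError(f"unknown control_mode {control_mode!r}")
    _check_factorial(plate)
    plate = plate.copy()
    if log:
        plate["mfi"] = np.log1p(plate["mfi"].to_numpy(float))
    rows = []
    selected: set[str] = set()
    for analyte, sub in plate.groupby("analyte", sort=True):
        fit = smf.ols("mfi ~ C(condition) * C(cell_line)", data=sub).fit()
        anova = sm.stats.anova_lm(fit, typ=2)
        p_cond = float(anova.loc["C(condition)", "PR(>F)"])
        p_line = float(anova.loc["C(cell_line)", "PR(>F)"])
        p_int = float(anova.loc["C(condition):C(cell_line)", "PR(>F)"])
        tukey = _tukey_pvalues(sub, alpha)

        n_sig = 0
        line_rows = []
        for line in CELL_LINES:
            co = f"co_culture:{line}"
            p_os = tukey.get((co, f"mono_OS:{line}"), tukey.get((f"mono_OS:{line}", co)))
            p_mac = tukey.get((co, f"mono_mac:{line}"), tukey.get((f"mono_mac:{line}", co)))
            if control_mode == "both":
                sig = (p_os < alpha) and (p_mac < alpha)
            else:
                sig = (p_os < alpha) or (p_mac < alpha)
            n_sig += int(sig)
            line_rows.append(
                {
                    "analyte": analyte,
                    "cell_line": line,
                    "p_vs_mono_OS": p_os,
                    "p_vs_mono_mac": p_mac,
                    "line_significant": bool(sig),
                    "anova_p_condition": p_cond,
                    "anova_p_cell_line": p_line,
                    "anova_p_interaction": p_int,
                }
            )
        is_selected = n_sig >= min_lines
        if is_selected:
            selected.add(analyte)
        for r in line_rows:
            r["n_lines_significant"] = n_sig
            r["selected"] = is_selected
        rows.extend(line_rows)
    return selected, pd.DataFrame(rows)
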