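"""Median-dichotomized Kaplan–Meier / log-rank / Cox survival analysis.

Cases with metastasis at initial presentation are excluded before any
survival analysis.  A per-core metric is split at its median **within the
analysis set**: values <= median form the "low" (abundance/density) or
"near" (distance) group, values above form "high"/"far"; ties at the median
therefore go to the low/near side.  Group differences are tested with a
two-sided log-rank test and effect sizes come from a univariable Cox
proportional-hazards model of high (near) vs low (far), with a Wald 95% CI.

No multiple-testing correction is applied by default — the screen is
exploratory — but an adjusted-p column can be added as a clearly labeled
extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateSplitError, FormatError, NoEventsError

ENDPOINT_COLUMNS = {"MFS": ("met_time", "met_event"), "RFS": ("rec_time", "rec_event")}

GROUP_NAMES = {"abundance": ("low", "high"), "distance": ("near", "far")}


def dichotomize_at_median(values: pd.Series, direction: str = "abundance") -> pd.Series:
    """Split values at their median into two named groups.

    Values <= median go to ``low``/``near``, values > median to
    ``high``/``far``.  Missing values are dropped.  Raises
    :class:`DegenerateSplitError` when all values coincide.
    """
    if direction not in GROUP_NAMES:
        raise ValueError(f"unknown direction {direction!r}")
    lo_name, hi_name = GROUP_NAMES[direction]
    vals = pd.Series(values).dropna().astype(float)
    if vals.nunique() < 2:
        raise DegenerateSplitError(
            f"degenerate split: fewer than 2 distinct values (n={len(vals)})"
        )
    med = float(vals.median())
    return pd.Series(np.where(vals <= med, lo_name, hi_name), index=vals.index)


@dataclass
class SurvivalResult:
    """Log-rank p, Cox hazard ratio with CI, group sizes and KM curves."""

    logrank_p: float
    hazard_ratio: float
    hr_ci: tuple[float, float]
    log_hr: float
    log_hr_se: float
    n_per_group: dict[str, int]
    n_events: int
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)


def km_logrank(time, event, group) -> SurvivalResult:
    """Kaplan–Meier curves, log-rank test and univariable Cox HR.

    ``group`` must take exactly two values; the hazard ratio is for the
    "high"/"far" group relative to "low"/"near" (alphabetically later label
    if custom names are used, chosen so the standard group names order
    correctly: far>near, high>low).
    """
    df = pd.DataFrame(
        {"time": np.asarray(time, float), "event": np.asarray(event, bool), "group": group}
    )
    levels = sorted(df["group"].unique())
    if len(levels) != 2:
        raise FormatError(f"need exactly 2 groups, got {levels}")
    lo, hi = levels[0], levels[1]
    if lo in ("high", "far"):  # order standard names reference-first
        lo, hi = hi, lo
    for lev in (lo, hi):
        if (df["group"] == lev).sum() == 0:
            raise FormatError(f"group {lev!r} is empty")
    if int(df["event"].sum()) == 0:
        raise NoEventsError("no events observed in either group")

    a = df[df["group"] == lo]
    b = df[df["group"] == hi]
    lr = logrank_test(a["time"], b["time"], a["event"], b["event"])

    cox_df = df.assign(ind=(df["group"] == hi).astype(float))[["time", "event", "ind"]]
    cph = CoxPHFitter()
    cph.fit(cox_df, duration_col="time", event_col="event")
    coef = float(cph.params_["ind"])
    se = float(cph.standard_errors_["ind"])
    ci = (float(np.exp(coef - 1.959963984540054 * se)), float(np.exp(coef + 1.959963984540054 * se)))

    curves = {}
    for lev, sub in ((lo, a), (hi, b)):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(lev))
        curves[str(lev)] = kmf.survival_function_

    return SurvivalResult(
        logrank_p=float(lr.p_value),
        hazard_ratio=float(np.exp(coef)),
        hr_ci=ci,
        log_hr=coef,
        log_hr_se=se,
        n_per_group={str(lo): int(len(a)), str(hi): int(len(b))},
        n_events=int(df["event"].sum()),
        km_curves=curves,
    )


def exclude_initial_metastasis(clinical: pd.DataFrame) -> pd.DataFrame:
    """The survival analysis set: cases without metastasis at presentation."""
    return clinical[~clinical["initial_metastasis"].astype(bool)].copy()


def analyze_metric(
    metric: pd.Series,
    clinical: pd.DataFrame,
    endpoint: str = "MFS",
    direction: str = "abundance",
) -> SurvivalResult:
    """Median-dichotomize one per-case metric and run KM/log-rank/Cox."""
    tcol, ecol = ENDPOINT_COLUMNS[endpoint]
    clin = exclude_initial_metastasis(clinical).set_index("case_id")
    common = metric.dropna().index.intersection(clin.index)
    if len(common) == 0:
        raise FormatError("no overlapping case ids between metric and clinical table")
    groups = dichotomize_at_median(metric.loc[common], direction=direction)
    sub = clin.loc[common]
    return km_logrank(sub[tcol], sub[ecol], groups)


def infer_direction(metric_name: str) -> str:
    return "distance" if "dist" in metric_name.lower() else "abundance"


def screen_metrics(
    metrics: pd.DataFrame,
    clinical: pd.DataFrame,
    endpoints: Iterable[str] = ("MFS", "RFS"),
    directions: Mapping[str, str] | None = None,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Run the survival screen: one row per (metric, endpoint).

    ``directions`` overrides the per-metric group naming; by default metric
    names containing "dist" are treated as distances (near/far).  Degenerate
    splits are flagged, not fatal.  ``adjust`` optionally adds a
    multiplicity-adjusted p column (e.g. "fdr_bh") as a labeled extension;
    the primary p-values stay unadjusted.
    """
    clin = exclude_initial_metastasis(clinical)
    if not set(metrics.index) & set(clin["case_id"]):
        raise FormatError("no overlapping case ids between metrics and clinical table")
    rows = []
    for metric_name in metrics.columns:
        direction = (directions or {}).get(metric_name, infer_direction(metric_name))
        lo_name, hi_name = GROUP_NAMES[direction]
        for endpoint in endpoints:
            row = {
                "metric": metric_name,
                "endpoint": endpoint,
                "direction": direction,
                "status": "ok",
            }
            try:
                res = analyze_metric(
                    metrics[metric_name], clinical, endpoint=endpoint, direction=direction
                )
                row.update(
                    n_low=res.n_per_group[lo_name],
                    n_high=res.n_per_group[hi_name],
                    n_events=res.n_events,
                    logrank_p=res.logrank_p,
                    hazard_ratio=res.hazard_ratio,
                    ci_low=res.hr_ci[0],
                    ci_high=res.hr_ci[1],
                )
            except DegenerateSplitError:
                row["status"] = "skipped: degenerate"
            except NoEventsError:
                row["status"] = "skipped: no events"
            rows.append(row)
    out = pd.DataFrame(rows)
    if adjust is not None and "logrank_p" in out.columns:
        ok = out["logrank_p"].notna()
        adj = np.full(len(out), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(out.loc[ok, "logrank_p"], method=adjust)[1]
        out[f"logrank_p_adj_{adjust}"] = adj
    return out
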