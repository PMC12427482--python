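"""End-to-end pipeline orchestration: qc → phenotype → abundance → spatial → survival.

The run configuration is a YAML (or plain dict) with either an ``inputs``
block (paths to a cell table and clinical table) or a ``simulate`` block
(cohort-generator parameters) — never both — plus optional ``qc``,
``spatial`` and ``survival`` blocks overriding the default thresholds.
Every stage writes its TSV output into the run directory and the report
echoes every seed and threshold actually applied, for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import abundance as ab
from . import io as oio
from . import qc as oqc
from . import spatial as osp
from . import survival as osv
from .errors import ConfigError, PipelineError
from .phenotyping import RuleSet, assign_phenotypes, default_ruleset
from .synthetic import CohortConfig, SurvivalConfig, simulate_cohort

log = logging.getLogger("osimc")


def load_config(config) -> dict:
    if isinstance(config, Mapping):
        return dict(config)
    with open(config) as fh:
        return yaml.safe_load(fh) or {}


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


@_stage("input")
def _load_cells(cfg: dict) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    has_inputs = "inputs" in cfg
    has_sim = "simulate" in cfg
    if has_inputs and has_sim:
        raise ConfigError("ambiguous input: both 'inputs' and 'simulate' blocks present")
    if not has_inputs and not has_sim:
        raise ConfigError("config needs an 'inputs' or a 'simulate' block")
    if has_inputs:
        cells = oio.read_cell_table(cfg["inputs"]["cells"])
        clinical = oio.read_clinical(cfg["inputs"]["clinical"])
        return cells, clinical, {"source": "files", **cfg["inputs"]}
    sim = dict(cfg["simulate"])
    surv_cfg = sim.pop("survival", None)
    cc = CohortConfig(**sim)
    sc = SurvivalConfig(**surv_cfg) if surv_cfg else None
    cohort = simulate_cohort(cc, survival=sc)
    prov = {"source": "simulate", "seed": cc.seed, "n_cores": cc.n_cores}
    return cohort.cells.drop(columns=["true_phenotype"]), cohort.clinical, prov


def run_pipeline(config, out_dir) -> dict:
    """Execute the full pipeline and return (and write) the report bundle."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": []}

    cells, clinical, prov = _load_cells(cfg)
    report["input"] = prov
    report["stages"].append("input")
    log.info("input: %d cells, %d cases", len(cells), len(clinical))

    # --- QC ---------------------------------------------------------------
    qc_cfg = cfg.get("qc", {})
    min_ir = float(qc_cfg.get("min_ir191_frac", 0.25))
    min_cells = int(qc_cfg.get("min_cells_per_core", 3))
    min_case = float(qc_cfg.get("min_case_frac", 0.10))

    @_stage("qc")
    def do_qc():
        filtered, core_rep = oqc.core_qc(cells, min_ir191_frac=min_ir)
        if filtered.empty or filtered["core_id"].nunique() == 0:
            raise ConfigError("no cores passed QC")
        retained, marker_rep = oqc.marker_qc(
            filtered, min_cells_per_core=min_cells, min_case_frac=min_case
        )
        filtered = oqc.drop_failed_markers(filtered, retained)
        core_rep.cores.to_csv(out / "qc_cores.tsv", sep="\t", index=False)
        marker_rep.markers.to_csv(out / "qc_markers.tsv", sep="\t", index=False)
        return filtered, retained, core_rep, marker_rep

    filtered, retained_markers, core_rep, marker_rep = do_qc()
    report["qc"] = {
        "thresholds": {**core_rep.thresholds, **marker_rep.thresholds},
        "cores_retained": int(filtered["core_id"].nunique()),
        "cores_total": int(cells["core_id"].nunique()),
        "markers_retained": len(retained_markers),
    }
    report["stages"].append("qc")

    # --- Phenotyping ------------------------------------------------------
    rules_cfg = cfg.get("rules")
    rules: RuleSet = RuleSet.from_config(rules_cfg) if rules_cfg else default_ruleset()

    @_stage("phenotype")
    def do_phenotype():
        usable = RuleSet(
            tuple(
                r
                for r in rules
                if (r.positive | r.negative) <= set(retained_markers)
            )
        )
        labeled = assign_phenotypes(filtered, usable)
        oio.write_cell_table(labeled, out / "cells_phenotyped.tsv")
        return labeled, usable

    labeled, usable_rules = do_phenotype()
    report["phenotype"] = {
        "n_rules": len(usable_rules),
        "labels": usable_rules.labels(),
    }
    report["stages"].append("phenotype")

    # --- Abundance --------------------------------------------------------
    @_stage("abundance")
    def do_abundance():
        mat = ab.abundance_matrix(labeled, labels=usable_rules.labels())
        mode = cfg.get("abundance", {}).get("imsc_mode", "mean")
        imsc = ab.imsc_score(mat, mode=mode)
        mat_out = mat.copy()
        mat_out["IMSC"] = imsc
        mat_out.to_csv(out / "abundance.tsv", sep="\t")
        return mat, imsc, mode

    mat, imsc, imsc_mode = do_abundance()
    report["abundance"] = {"imsc_mode": imsc_mode, "n_cores": int(len(mat))}
    report["stages"].append("abundance")

    # --- Spatial ----------------------------------------------------------
    sp_cfg = cfg.get("spatial", {})
    params = osp.SpatialParams(
        radius=float(sp_cfg.get("radius", 250.0)),
        center_label=sp_cfg.get("center_label", "M2"),
        missing_policy=sp_cfg.get("missing_policy", "missing"),
        clip_area=bool(sp_cfg.get("clip_area", False)),
    )

    @_stage("spatial")
    def do_spatial():
        geo = None
        if params.clip_area:
            d = float(cfg.get("simulate", {}).get("core_diameter", 1000.0))
            geo = {cid: (d / 2, d / 2, d) for cid in labeled["core_id"].unique()}
        sm = osp.spatial_metrics(labeled, params, core_geometry=geo)
        sm.to_csv(out / "spatial_metrics.tsv", sep="\t")
        return sm

    sm = do_spatial()
    report["spatial"] = {
        "radius_um": params.radius,
        "center_label": params.center_label,
        "missing_policy": params.missing_policy,
        "clip_area": params.clip_area,
    }
    report["stages"].append("spatial")

    # --- Survival ---------------------------------------------------------
    sv_cfg = cfg.get("survival", {})
    endpoints = tuple(sv_cfg.get("endpoints", ("MFS", "RFS")))

    @_stage("survival")
    def do_survival():
        metrics = pd.concat([imsc.rename("IMSC"), sm], axis=1)
        res = osv.screen_metrics(metrics, clinical, endpoints=endpoints)
        res.to_csv(out / "survival_screen.tsv", sep="\t", index=False)
        return res

    surv = do_survival()
    report["survival"] = {
        "endpoints": list(endpoints),
        "n_tests": int(len(surv)),
        "n_significant_unadjusted": int(
            (surv.get("logrank_p", pd.Series(dtype=float)) < 0.05).sum()
        ),
        "cutoff": "median within analysis set (initially metastatic cases excluded)",
        "tie_rule": "values at the median join the low/near group",
    }
    report["stages"].append("survival")

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %s", out / "report.json")
    return report
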