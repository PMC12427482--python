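import math

import numpy as np
import pandas as pd
import pytest

from osimc.errors import ConfigError, DegenerateSplitError
from osimc.spatial import median_pair_distance
from osimc.synthetic import (
    CohortConfig,
    SurvivalConfig,
    simulate_cohort,
    simulate_cytokine_plate,
    simulate_survival,
)


def test_empty_cohort():
    co = simulate_cohort(CohortConfig(n_cores=0, seed=1))
    assert len(co.cells) == 0
    assert len(co.clinical) == 0


def test_reproducibility_byte_identical():
    cfg = dict(n_cores=4, cells_per_core=200, seed=9, marker_flip_prob=0.05)
    a = simulate_cohort(CohortConfig(**cfg))
    b = simulate_cohort(CohortConfig(**cfg))
    assert a.cells.to_csv() == b.cells.to_csv()
    assert a.clinical.to_csv() == b.clinical.to_csv()


def test_all_cells_inside_core_disc():
    cfg = CohortConfig(
        n_cores=6,
        cells_per_core=500,
        seed=2,
        clustering_sigma=200.0,
        clustered_children={"mMDSC": 2.0},
    )
    co = simulate_cohort(cfg)
    r = cfg.core_diameter / 2
    d = np.hypot(co.cells["x_um"] - r, co.cells["y_um"] - r)
    assert (d <= r + 1e-9).all()


def test_every_core_has_one_clinical_case():
    co = simulate_cohort(CohortConfig(n_cores=7, cells_per_core=100, seed=3))
    assert sorted(co.clinical["case_id"]) == sorted(co.cells["core_id"].unique())
    assert co.clinical["case_id"].is_unique


def test_mixture_recovery_at_zero_noise():
    mix = {"M2": 0.3, "Treg": 0.1, "Fibroblast": 0.6}
    cfg = CohortConfig(
        n_cores=20, cells_per_core=5000, seed=5, phenotype_mix=mix, marker_flip_prob=0.0
    )
    co = simulate_cohort(cfg)
    n = len(co.cells)
    props = co.cells["true_phenotype"].value_counts(normalize=True)
    for lab, p in mix.items():
        sd = math.sqrt(p * (1 - p) / n)
        assert abs(props[lab] - p) < 3 * sd


def test_zero_sigma_children_coincide_with_parents():
    """At sigma=0 every clustered MDSC sits exactly on an M2 parent, and in
    single-parent cores the median M2-MDSC distance is 0."""
    mix = {"M2": 0.9, "mMDSC": 0.1}
    cfg = CohortConfig(
        n_cores=100,
        cells_per_core=1.2,
        seed=7,
        phenotype_mix=mix,
        clustering_sigma=0.0,
        clustered_children={"mMDSC": 1.0},
    )
    co = simulate_cohort(cfg)
    labeled = co.cells.rename(columns={"true_phenotype": "phenotype"})
    checked_median = 0
    for _, core in labeled.groupby("core_id"):
        m2 = core[core["phenotype"] == "M2"][["x_um", "y_um"]].to_numpy()
        md = core[core["phenotype"] == "mMDSC"][["x_um", "y_um"]].to_numpy()
        for child in md:
            assert np.min(np.hypot(*(m2 - child).T)) == 0.0
        if len(m2) == 1 and len(md) >= 1:
            assert median_pair_distance(core, "M2", "mMDSC") == 0.0
            checked_median += 1
    assert checked_median > 5


def test_clustered_label_multinomial_draw_replaced():
    """Counts of a clustered phenotype follow the Thomas draw, not the mix."""
    cfg = CohortConfig(
        n_cores=1,
        cells_per_core=500,
        seed=12,
        phenotype_mix={"M2": 0.1, "mMDSC": 0.3, "Unassigned": 0.6},
        clustering_sigma=30.0,
        clustered_children={"mMDSC": 0.2},
    )
    co = simulate_cohort(cfg)
    counts = co.cells["true_phenotype"].value_counts()
    # ~0.2 children per parent on ~50 parents: far below the 150 the mix implies
    assert counts.get("mMDSC", 0) < 50


def test_clustering_monotone_in_sigma():
    """Median M2-MDSC distance grows with the child displacement scale."""
    mix = {"M2": 0.02, "mMDSC": 0.05, "Unassigned": 0.93}
    sigmas = [5.0, 50.0, 200.0]
    means = []
    for sigma in sigmas:
        meds = []
        for seed in range(20):
            cfg = CohortConfig(
                n_cores=1,
                cells_per_core=150,
                seed=seed,
                phenotype_mix=mix,
                clustering_sigma=sigma,
                clustered_children={"mMDSC": 2.0},
            )
            core = simulate_cohort(cfg).cells.rename(
                columns={"true_phenotype": "phenotype"}
            )
            med = median_pair_distance(core, "M2", "mMDSC")
            if not math.isnan(med):
                meds.append(med)
        means.append(np.mean(meds))
    assert means[0] <= means[1] <= means[2]


def test_clustered_child_not_in_mix_rejected():
    cfg = CohortConfig(
        n_cores=1, phenotype_mix={"M2": 1.0}, clustered_children={"Treg": 1.0}
    )
    with pytest.raises(ConfigError, match="Treg"):
        simulate_cohort(cfg)


def test_mix_must_sum_to_one():
    with pytest.raises(ConfigError, match="sum to 1"):
        CohortConfig(n_cores=1, phenotype_mix={"M2": 0.5}).validate()


# --- survival generator ----------------------------------------------------


def test_survival_degenerate_covariate_rejected():
    with pytest.raises(DegenerateSplitError):
        simulate_survival({"a": 5.0, "b": 5.0, "c": 5.0}, SurvivalConfig(seed=1))


def test_survival_needs_two_cores():
    with pytest.raises(ConfigError):
        simulate_survival({"a": 1.0}, SurvivalConfig(seed=1))


def test_survival_censor_fraction_calibrated():
    rng = np.random.default_rng(0)
    cov = {f"c{i}": float(v) for i, v in enumerate(rng.normal(size=4000))}
    clin = simulate_survival(
        cov, SurvivalConfig(log_hr=math.log(2.0), censor_frac=0.3, seed=8)
    )
    frac = 1.0 - clin["met_event"].mean()
    assert abs(frac - 0.3) < 3 * math.sqrt(0.3 * 0.7 / 4000)


def test_survival_null_hazard_ratio_near_one():
    from osimc.survival import dichotomize_at_median, km_logrank

    rng = np.random.default_rng(1)
    cov = pd.Series(rng.normal(size=500), index=[f"c{i}" for i in range(500)])
    clin = simulate_survival(cov.to_dict(), SurvivalConfig(log_hr=0.0, seed=2))
    clin = clin.set_index("case_id")
    g = dichotomize_at_median(cov)
    res = km_logrank(clin.loc[g.index, "met_time"], clin.loc[g.index, "met_event"], g)
    assert abs(res.log_hr) < 3 * res.log_hr_se


# --- cytokine plate generator ----------------------------------------------


def test_cytokine_plate_validation():
    with pytest.raises(ConfigError):
        simulate_cytokine_plate({}, noise_sd=0.0)
    with pytest.raises(ConfigError):
        simulate_cytokine_plate({}, n_replicates=1)
    with pytest.raises(ConfigError):
        simulate_cytokine_plate({("NotAnAnalyte", "143B"): 1.0})


def test_cytokine_plate_factorial_complete():
    plate = simulate_cytokine_plate({}, seed=3, analytes=("IL-6", "EGF"))
    counts = plate.groupby(["analyte", "condition", "cell_line"]).size()
    culture = counts[
        counts.index.get_level_values("condition") != "background"
    ]
    assert (culture == 2).all()
    assert set(plate["condition"]) == {"mono_OS", "mono_mac", "co_culture", "background"}


def test_cytokine_effect_shifts_co_culture_only():
    plate = simulate_cytokine_plate(
        {("IL-6", "143B"): 2.0}, noise_sd=0.1, seed=4, analytes=("IL-6",)
    )
    g = plate.groupby(["condition", "cell_line"])["mfi"].mean()
    assert g["co_culture", "143B"] > 4 * g["mono_OS", "143B"]
    assert abs(np.log(g["co_culture", "LM7"] / g["mono_OS", "LM7"])) < 0.5
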