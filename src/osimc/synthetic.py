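"""Synthetic tissue-microarray cohorts, survival outcomes and cytokine plates.

The generator emulates the statistical structure the analysis assumes, so
every downstream stage can be exercised without the (unreleased) raw data:

* **cores** — circular 1.0 mm tissue cores, one per case, with cell counts
  Poisson around a configurable mean (the profiled cohort averaged
  111,980 / 51 ≈ 2196 detectable cells per core);
* **phenotypes** — a multinomial mixture dominated by macrophages and
  stroma with sparse lymphocytes; optionally, selected phenotypes are
  placed as Gaussian-displaced children of M2 parents (Thomas-process
  style) to emulate immunosuppressive niches clustering around M2;
* **marker calls** — each cell's binary marker vector is its phenotype's
  gating-rule truth table (positive markers on, everything else off) with
  independent per-marker flip noise, so gating inverts the generator
  exactly at zero noise;
* **nuclear stain** — cells are Ir191+ with a per-core probability, letting
  fixtures span the 25% core-QC boundary;
* **survival** — exponential event times under a two-group proportional-
  hazards model on a median-split per-core covariate, with uniform
  censoring calibrated numerically to a target censor fraction;
* **cytokine plates** — log-normal MFIs over the full
  condition x cell-line x replicate factorial (plus background wells), with
  chosen log-fold-changes injected into the co-culture condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigError, DegenerateSplitError
from .phenotyping import RuleSet, default_ruleset, truth_tables
from .qc import IR191

#: Default phenotype mixture (fractions of detectable cells per core):
#: macrophage-dominated myeloid compartment (~38%), sparse lymphocytes
#: (~6%), prominent stroma, and an unassigned remainder.
DEFAULT_PHENOTYPE_MIX: dict[str, float] = {
    "M0": 0.14,
    "M2": 0.11,
    "M1": 0.02,
    "mMDSC": 0.025,
    "pMDSC": 0.025,
    "cMono": 0.02,
    "ncMono": 0.015,
    "Neutrophil": 0.015,
    "DC": 0.01,
    "Treg": 0.006,
    "hT": 0.012,
    "cT": 0.012,
    "mhT": 0.008,
    "mcT": 0.008,
    "tNK": 0.004,
    "aNK": 0.003,
    "cNK": 0.003,
    "Endothelial": 0.10,
    "Fibroblast": 0.11,
    "Epithelial-like": 0.03,
    "StemC": 0.09,
    "Proliferating": 0.08,
    "Unassigned": 0.154,
}

#: The 48-plex cytokine/chemokine panel measured in the co-culture screen.
DEFAULT_ANALYTES: tuple[str, ...] = (
    "sCD40L", "EGF", "Eotaxin", "FGF-2", "Flt-3L", "Fractalkine", "G-CSF",
    "GM-CSF", "GROa", "IFNa2", "IFNg", "IL-1a", "IL-1b", "IL-1ra", "IL-2",
    "IL-3", "IL-4", "IL-5", "IL-6", "IL-7", "IL-8", "IL-9", "IL-10",
    "IL-12p40", "IL-12p70", "IL-13", "IL-15", "IL-17A", "IL-17E", "IL-17F",
    "IL-18", "IL-22", "IL-27", "CXCL10", "MCP-1", "MCP-3", "M-CSF", "MDC",
    "MIG", "MIP-1a", "MIP-1b", "PDGF-AA", "PDGF-AB/BB", "TGFa", "TNFa",
    "TNFb", "VEGF-A",
)

CONDITIONS = ("mono_OS", "mono_mac", "co_culture")
CELL_LINES = ("143B", "LM7", "MG63.3")


@dataclass
class CohortConfig:
    """Generating parameters of a synthetic TMA cohort.

    cells_per_core is the Poisson mean; core_diameter is in µm;
    clustering_sigma (µm) is the Gaussian child displacement around M2
    parents (0 = complete spatial randomness); clustered_children maps a
    phenotype to its mean number of children per M2 parent;
    marker_flip_prob is the independent per-marker positivity noise;
    ir191_pos_frac is the per-core nuclear-stain positivity probability
    (a scalar, or one value per core).
    """

    n_cores: int = 51
    core_diameter: float = 1000.0
    cells_per_core: float = 111980 / 51
    phenotype_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPE_MIX)
    )
    clustering_sigma: float = 0.0
    clustered_children: Mapping[str, float] = field(default_factory=dict)
    marker_flip_prob: float = 0.0
    ir191_pos_frac: float | Sequence[float] = 0.85
    seed: int = 0

    def validate(self) -> None:
        if self.n_cores < 0:
            raise ConfigError("n_cores must be >= 0")
        if self.core_diameter <= 0:
            raise ConfigError("core_diameter must be positive")
        if self.cells_per_core < 0:
            raise ConfigError("cells_per_core must be >= 0")
        if self.clustering_sigma < 0:
            raise ConfigError("clustering_sigma must be >= 0")
        if not 0 <= self.marker_flip_prob <= 1:
            raise ConfigError("marker_flip_prob must be in [0, 1]")
        mix = dict(self.phenotype_mix)
        if any(p < 0 for p in mix.values()):
            raise ConfigError("phenotype_mix proportions must be non-negative")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ConfigError(f"phenotype_mix must sum to 1 (got {sum(mix.values())!r})")
        for lab in self.clustered_children:
            if lab not in mix:
                raise ConfigError(
                    f"clustered_children references phenotype {lab!r} absent from phenotype_mix"
                )
        if self.clustered_children and "M2" not in mix:
            raise ConfigError("clustered_children requires M2 parents in phenotype_mix")
        fracs = np.atleast_1d(np.asarray(self.ir191_pos_frac, dtype=float))
        if ((fracs < 0) | (fracs > 1)).any():
            raise ConfigError("ir191_pos_frac must be in [0, 1]")


@dataclass
class SurvivalConfig:
    """Proportional-hazards outcome generator parameters.

    Event times are exponential with hazard
    ``baseline_hazard * exp(log_hr * I[covariate > median])`` in abstract
    months; censoring is uniform on [0, T] with T solved numerically for the
    target expected censor fraction.  ``initial_met_frac`` is the Bernoulli
    probability of the metastasis-at-presentation flag (those cases are
    excluded from survival analyses downstream).
    """

    baseline_hazard: float = 0.02
    log_hr: float = 0.0
    censor_frac: float = 0.3
    covariate_name: str = "covariate"
    initial_met_frac: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be positive")
        if not 0 <= self.censor_frac < 1:
            raise ConfigError("censor_frac must be in [0, 1)")
        if not 0 <= self.initial_met_frac <= 1:
            raise ConfigError("initial_met_frac must be in [0, 1]")


@dataclass
class SyntheticCohort:
    """Cells, clinical outcomes and the generating truth of one cohort."""

    cells: pd.DataFrame
    clinical: pd.DataFrame
    truth: dict


def _uniform_disc(rng: np.random.Generator, n: int, center: np.ndarray, radius: float):
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
    return center + np.column_stack((r * np.cos(theta), r * np.sin(theta)))


def _thomas_children(
    rng: np.random.Generator,
    parents: np.ndarray,
    n: int,
    sigma: float,
    center: np.ndarray,
    radius: float,
) -> np.ndarray:
    """Gaussian-displaced children of random parents, rejected back into the disc."""
    idx = rng.integers(0, len(parents), size=n)
    pos = parents[idx] + rng.normal(0.0, sigma, size=(n, 2))
    if sigma > 0:
        for _ in range(1000):
            outside = np.linalg.norm(pos - center, axis=1) > radius
            if not outside.any():
                break
            k = int(outside.sum())
            pos[outside] = parents[idx[outside]] + rng.normal(0.0, sigma, size=(k, 2))
    return pos


def simulate_cohort(
    config: CohortConfig,
    rules: RuleSet | None = None,
    survival: SurvivalConfig | None = None,
) -> SyntheticCohort:
    """Generate one cohort of cores with cells, markers and clinical outcomes.

    Deterministic given ``config.seed``.  Cells of phenotypes listed in
    ``clustered_children`` are placed as Poisson(children_mean x n_M2)
    Gaussian-displaced children of the core's M2 cells (replacing that
    label's multinomial draw); every other phenotype is placed uniformly in
    the core disc.  The per-case covariate driving survival is the true
    IMSC percentage of the core (M2 + MDSC + Treg).
    """
    config.validate()
    if rules is None:
        rules = default_ruleset()
    # independent child streams: the survival draws must not replay the bit
    # stream that placed the cells, or outcomes couple to core composition
    cells_ss, surv_ss = np.random.SeedSequence(config.seed).spawn(2)
    if survival is None:
        survival = SurvivalConfig(
            log_hr=math.log(2.5),
            censor_frac=0.3,
            covariate_name="imsc_pct_true",
            initial_met_frac=8 / 51,
            seed=int(surv_ss.generate_state(1)[0] % (2**31)),
        )
    survival.validate()
    rng = np.random.default_rng(cells_ss)

    markers = sorted(rules.markers())
    tables = truth_tables(rules, markers)
    mix_labels = list(config.phenotype_mix)
    mix_p = np.array([config.phenotype_mix[l] for l in mix_labels], dtype=float)
    fracs = np.atleast_1d(np.asarray(config.ir191_pos_frac, dtype=float))

    radius = config.core_diameter / 2.0
    center = np.array([radius, radius])  # origin at top-left bounding box

    frames = []
    for i in range(config.n_cores):
        core_id = f"core{i + 1:03d}"
        n = int(rng.poisson(config.cells_per_core))
        counts = rng.multinomial(n, mix_p) if n > 0 else np.zeros(len(mix_p), int)
        count_of = dict(zip(mix_labels, counts))

        # uniform placements first, so M2 parents exist for the children
        labels_u: list[str] = []
        for lab, c in count_of.items():
            if lab in config.clustered_children:
                continue
            labels_u.extend([lab] * int(c))
        xy_u = _uniform_disc(rng, len(labels_u), center, radius)
        labels_all = list(labels_u)
        xy_parts = [xy_u]

        parents = xy_u[np.asarray(labels_u, dtype=object) == "M2"] if labels_u else np.empty((0, 2))
        for lab, mean_children in config.clustered_children.items():
            n_child = int(rng.poisson(mean_children * len(parents))) if len(parents) else 0
            if n_child > 0:
                xy_c = _thomas_children(
                    rng, parents, n_child, config.clustering_sigma, center, radius
                )
                labels_all.extend([lab] * n_child)
                xy_parts.append(xy_c)

        xy = np.concatenate(xy_parts) if labels_all else np.empty((0, 2))
        m = len(labels_all)
        marker_mat = np.zeros((m, len(markers)), dtype=np.int8)
        for j, lab in enumerate(labels_all):
            tab = tables.get(lab)
            if tab is not None:
                marker_mat[j] = [tab[mk] for mk in markers]
        if config.marker_flip_prob > 0 and m > 0:
            flips = rng.random(marker_mat.shape) < config.marker_flip_prob
            marker_mat = np.where(flips, 1 - marker_mat, marker_mat)

        frac = float(fracs[i % len(fracs)])
        ir = (rng.random(m) < frac).astype(np.int8)

        frame = pd.DataFrame(
            {
                "cell_id": [f"{core_id}_c{j + 1:05d}" for j in range(m)],
                "core_id": core_id,
                "x_um": xy[:, 0] if m else np.empty(0),
                "y_um": xy[:, 1] if m else np.empty(0),
            }
        )
        frame[IR191] = ir
        for k, mk in enumerate(markers):
            frame[mk] = marker_mat[:, k]
        frame["true_phenotype"] = labels_all
        frames.append(frame)

    if frames:
        cells = pd.concat(frames, ignore_index=True)
    else:
        cols = ["cell_id", "core_id", "x_um", "y_um", IR191] + markers + ["true_phenotype"]
        cells = pd.DataFrame(columns=cols)

    # true per-core IMSC covariate, in percent of all cells of the core
    core_ids = [f"core{i + 1:03d}" for i in range(config.n_cores)]
    covariate = pd.Series(0.0, index=pd.Index(core_ids, name="core_id"))
    if len(cells):
        imsc = cells["true_phenotype"].isin(("M2", "mMDSC", "pMDSC", "Treg"))
        tot = cells.groupby("core_id").size()
        pos = imsc.groupby(cells["core_id"]).sum()
        covariate.update(100.0 * pos / tot)

    if config.n_cores >= 2 and covariate.nunique() >= 2:
        clinical = simulate_survival(covariate.to_dict(), survival)
    else:
        clinical = pd.DataFrame(
            {
                "case_id": core_ids,
                "initial_metastasis": False,
                "met_event": False,
                "met_time": 1.0,
                "rec_event": False,
                "rec_time": 1.0,
            }
        )

    truth = {
        "config": config,
        "survival_config": survival,
        "covariate": covariate,
        "true_phenotype": cells["true_phenotype"] if len(cells) else pd.Series(dtype=object),
    }
    return SyntheticCohort(cells=cells, clinical=clinical, truth=truth)


def _solve_censor_horizon(lams: np.ndarray, censor_frac: float) -> float:
    """Horizon T of Uniform(0, T) censoring with the target expected fraction.

    P(censored | rate lam) = (1 - exp(-lam T)) / (lam T), averaged over
    cases; decreasing in T from 1 to 0, so a bracketed root always exists.
    """

    def f(t: float) -> float:
        x = lams * t
        return float(np.mean((1.0 - np.exp(-x)) / x)) - censor_frac

    lo, hi = 1e-9, 1.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            break
    return float(brentq(f, lo, hi))


def simulate_survival(
    core_covariate: Mapping[str, float], config: SurvivalConfig
) -> pd.DataFrame:
    """Exponential two-group proportional-hazards outcomes per core/case.

    The hazard of cases above the covariate median is multiplied by
    exp(log_hr).  Metastasis- and recurrence-type endpoints are drawn
    independently under the same model.  Deterministic given ``config.seed``.
    """
    config.validate()
    if len(core_covariate) < 2:
        raise ConfigError("need at least 2 cores for survival simulation")
    cov = pd.Series(core_covariate, dtype=float)
    if cov.nunique() < 2:
        raise DegenerateSplitError("degenerate covariate: all values equal")
    rng = np.random.default_rng(config.seed)
    high = (cov > cov.median()).to_numpy()
    lam = config.baseline_hazard * np.exp(config.log_hr * high)

    def endpoint():
        x = rng.exponential(1.0 / lam)
        if config.censor_frac > 0:
            horizon = _solve_censor_horizon(lam, config.censor_frac)
            c = rng.uniform(0.0, horizon, size=len(lam))
            event = x <= c
            time = np.minimum(x, c)
        else:
            event = np.ones(len(lam), dtype=bool)
            time = x
        return time, event

    met_time, met_event = endpoint()
    rec_time, rec_event = endpoint()
    init_met = rng.random(len(lam)) < config.initial_met_frac
    return pd.DataFrame(
        {
            "case_id": cov.index.astype(str),
            "initial_metastasis": init_met,
            "met_event": met_event,
            "met_time": met_time,
            "rec_event": rec_event,
            "rec_time": rec_time,
        }
    )


def simulate_cytokine_plate(
    effects: Mapping[tuple[str, str], float],
    noise_sd: float = 0.25,
    n_replicates: int = 2,
    seed: int = 0,
    analytes: Sequence[str] | None = None,
    base_mfi: float = 1000.0,
    background_mfi: float = 40.0,
) -> pd.DataFrame:
    """Long-format raw MFI plate over the full factorial design.

    ``effects`` maps (analyte, cell_line) to the log-fold-change added to
    that co-culture mean on the log scale.  MFIs are log-normal with
    log-scale SD ``noise_sd``; a ``background`` condition is included for
    subtraction.  Deterministic given ``seed``.
    """
    if noise_sd <= 0:
        raise ConfigError("noise_sd must be positive")
    if n_replicates < 2:
        raise ConfigError("n_replicates must be >= 2 (all measurements are duplicated)")
    if analytes is None:
        analytes = DEFAULT_ANALYTES
    for (a, l) in effects:
        if a not in analytes:
            raise ConfigError(f"effect references unknown analyte {a!r}")
        if l not in CELL_LINES:
            raise ConfigError(f"effect references unknown cell line {l!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for analyte in analytes:
        for line in CELL_LINES:
            for cond in CONDITIONS:
                mu = math.log(base_mfi)
                if cond == "co_culture":
                    mu += float(effects.get((analyte, line), 0.0))
                for rep in range(1, n_replicates + 1):
                    rows.append(
                        {
                            "analyte": analyte,
                            "condition": cond,
                            "cell_line": line,
                            "replicate": rep,
                            "mfi": float(np.exp(mu + rng.normal(0.0, noise_sd))),
                        }
                    )
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "analyte": analyte,
                    "condition": "background",
                    "cell_line": "none",
                    "replicate": rep,
                    "mfi": float(
                        np.exp(math.log(background_mfi) + rng.normal(0.0, noise_sd))
                    ),
                }
            )
    return pd.DataFrame(rows)
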