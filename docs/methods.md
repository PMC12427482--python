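# Methods

## Setting

One ~1.0 mm-diameter tissue core per case (analyzable area
π·0.5² ≈ 0.785 mm²) is profiled by imaging mass cytometry; segmentation
yields one row per cell with centroid coordinates in µm (image convention:
origin at the core's top-left bounding box, y downward) and binary
positivity calls for each antibody plus the Ir191 DNA intercalator
(nuclear stain).  The pipeline operates entirely on these exported tables;
it contains no image processing.

## Quality control

Nuclear staining quality is summarized per core as the Ir191⁺ fraction of
all segmented cells.  Cores with a fraction strictly below
`min_ir191_frac = 0.25` are excluded, and all downstream statistics are
computed on the Ir191⁺ cells of the retained cores — "detectable cells"
always means Ir191⁺ nucleated cells.  Marker-level QC declares a case
positive for a marker when at least `min_cells_per_core = 3` cells of its
core are positive and drops markers positive in fewer than
`min_case_frac = 10%` of cases.  Both thresholds keep the boundary value,
because the exclusion criteria are phrased with a strict "<"; boundary
behavior is pinned by tests.  Both filters are idempotent and monotone in
their thresholds.

## Phenotyping

A phenotype is a gating rule: required-positive markers, required-negative
markers, a priority rank.  Unlisted markers are "don't care".  Rules are
evaluated lowest-rank-first and the first match wins, so the labeling is a
partition.  The default rule set covers 22 populations (plus the
Unassigned fallback): macrophage subtypes M0/M1/M2, monocytic and
polymorphonuclear MDSC, classical/non-classical monocytes, neutrophils,
dendritic cells, NK subtypes, helper/cytotoxic/memory/regulatory T cells,
endothelial cells, fibroblasts, epithelial-like cells (two rules — Pan-CK
or E-cadherin — sharing one label), CD44⁺ stem-like cells and Ki-67⁺
proliferating cells.

Design choices the marker table alone does not determine:

* **Priority order** is most-specific-first (memory T subsets above their
  hT/cT parents, Treg above hT, macrophage subtypes above generic myeloid
  gates, mMDSC above cMono).  This makes the single-label output
  deterministic for cells satisfying several gates.
* **M1 carries an explicit CD163⁻ constraint** beyond its CD68⁺HLA-DR⁺
  definition so that M1 and M2 are disjoint; a CD68⁺CD163⁺HLA-DR⁺ cell is
  M2.  The rule set is user-replaceable via config, so a different
  convention is one YAML block away.
* Whether MDSC gates should also demand CD68⁻ is handled by priority
  (macrophage gates fire first) rather than extra constraints.

The engine is vectorized; tests hold it equal to a naive per-cell priority
scan on random binary tables, and equal to generator truth on zero-noise
synthetic cohorts (the truth-table construction below makes gating exactly
invertible at zero noise for every default label — verified exhaustively).

## Abundance and composites

Abundance is `100 · n(label)/n(detectable cells in core)`; rows, including
Unassigned, sum to 100.  The IMSC composite aggregates M2%, pooled MDSC%
(mMDSC + pMDSC) and Treg%.  Both a `mean` and a `sum` mode exist because
the two conventions circulate; since sum = 3 × mean is strictly monotone,
median-dichotomized groups — and hence every downstream survival result —
are identical under either, which a test verifies.  `mean` is the default
and the report records the mode used.  Pairwise composites (M2+MDSC,
M2+Treg, MDSC+Treg) use the same machinery.

## Spatial statistics

All statistics are M2-centric with query radius r = 250 µm (the reported
upper range for meaningful hematopoietic cell–cell communication) and
Euclidean centroid distances:

* **Median pair distance** per core for M2–M2, M2–MDSC, M2–Treg over the
  pooled qualifying pairs (same-label pairs unordered, self-pairs
  excluded).  The **M2–IMSC composite** is the arithmetic mean of the three
  medians.
* **Density**: for each M2, the count of target cells within r (the center
  excluded); the per-core *median over M2 cells* of that count, divided by
  the neighborhood area in mm².  Note the deliberate asymmetry — pooled
  median for distances, median-of-counts for densities — following the two
  distinct definitions being reproduced.
* **IMSC count sum**: the median per-M2 counts of M2, MDSC and Treg,
  summed.

Cores with no qualifying pairs follow a `missing_policy`: `missing`
(default; the core drops out of that metric's dichotomization), `zero`, or
`radius_cap` (code the median as r).  `zero` exists because published
near-group medians of 0 µm are most easily explained by empty-neighborhood
zero-coding; `missing` is the statistically safer default and the report
states the policy used.

The area divisor is πr² by default.  Because r is a quarter of the core
diameter, neighborhoods overhang the core and πr² under-estimates density
near the edge; `clip_area=true` instead divides by the mean intersection
area of the query disc with the core disc (analytic lens formula).  A test
confirms the clipped estimator recovers the intensity of a homogeneous
process without edge bias.  No edge correction is applied by default since
the procedure being reproduced mentions none.

Neighbor queries use `scipy.spatial.cKDTree`; tests hold every statistic
equal (to 1e−9) to a brute-force O(n²) scan on 100 random cores, and check
rigid-motion invariance and scaling covariance (distances ∝ c, densities ∝
1/c²).

## Survival analysis

Cases with metastasis at initial presentation are excluded first; the
median cutoff is computed within this analysis set (the natural reading of
a median split applied to the analyzed cases).  Values ≤ median form the
low/near group, values > median the high/far group, so ties at the median
go low/near; group sizes can therefore differ by the tie count, which the
screen reports.  Per metric and endpoint (MFS, RFS): Kaplan–Meier curves,
a two-sided log-rank test, and a univariable Cox proportional-hazards
model of the binary group (lifelines), reporting HR = exp(β) with Wald 95%
CI.  Degenerate splits and zero-event strata are flagged and skipped, not
fatal.  P-values are unadjusted by default — the screen is exploratory and
deliberately mirrors that practice — with an optional, clearly-labeled
Benjamini–Hochberg column as an extension.

## Cytokine screen

Raw bead MFIs are background-subtracted per analyte (mean of blank wells)
and floored at 0, as MFIs are non-negative physical quantities.  Per
analyte, a two-way ANOVA over culture condition (tumor mono-culture,
macrophage mono-culture, co-culture) and cell line (143B, LM7, MG63.3) is
recorded, and selection is driven by Tukey-HSD-adjusted pairwise contrasts
over the 9 condition×line groups: a cell line counts as significant when
its co-culture differs from **both** mono-culture controls at the adjusted
α = 0.05 (`control_mode="either"` relaxes this); an analyte is selected
when ≥ 2 of 3 lines are significant.  Analysis is on the linear MFI scale
(a log option exists).  Under the null the rule is conservative: the mean
selected count over simulated null plates stays below the naive
48·(3α)² bound, checked by Monte-Carlo.

## Demographics

`summarize` produces a per-characteristic category/count/percent table,
percentages rounded half-away-from-zero to integers; `compare_printed`
flags disagreements with an external printed table rather than reproducing
them (the motivating table's sex row is internally inconsistent, so the
package reports computed values and surfaces the mismatch).

## Synthetic cohorts

The generator defines the conditions under which the pipeline is validated:

* **Geometry**: cells uniform in a disc of diameter 1000 µm (rejection-free
  polar sampling); per-core counts Poisson with mean 111,980/51 ≈ 2196 —
  the profiled cohort's scale.  Overdispersion is deliberately not modeled.
* **Mixture**: a 23-component phenotype mixture (macrophage-dominated
  myeloid compartment ≈ 38%, lymphoid ≈ 6%, prominent stroma, 15%
  unassigned) chosen to echo the reported composition ranking (M0, M2,
  fibroblasts, endothelial, stem-like most abundant).
* **Clustering**: phenotypes listed in `clustered_children` are placed
  Thomas-style — Poisson(children-per-parent × n_M2) children, Gaussian
  displacement `clustering_sigma`, rejected back into the disc — replacing
  that label's multinomial draw.  At σ = 0 children coincide with parents;
  the median M2–child distance is non-decreasing in σ (tested over seeds).
* **Markers**: each cell's binary vector is its phenotype's gating
  truth-table (positive markers 1, all else 0) with independent per-marker
  flip probability; Ir191 positivity is Bernoulli with a per-core
  probability (scalar or per-core list), letting fixtures straddle the 25%
  QC boundary.
* **Survival**: event times are exponential with hazard
  h₀·exp(β·1[covariate > median]); h₀ = 0.02/month, β = log 2.5 and 30%
  censoring by default, matching the effect sizes the analysis is meant to
  detect; the driving covariate is the core's true IMSC fraction.
  Censoring is uniform on [0, T] with T solved by root-finding so the
  expected censored fraction hits the target
  (P(cens | λ) = (1 − e^{−λT})/(λT), averaged over cases).  The
  initial-metastasis flag is Bernoulli(8/51).  Metastasis and recurrence
  endpoints are independent draws of the same model.
* **Cytokine plates**: log-normal MFIs (log-scale SD 0.25 by default,
  duplicates) over the full factorial plus background wells at a lower
  mean; effects are log-fold-changes added to chosen (analyte, cell line)
  co-culture means.  The default panel is the 47 printed analyte names of
  the 48-plex kit.

Everything is deterministic given the config seed.  The cell-placement and
survival streams are spawned as independent `SeedSequence` children of
that seed: reusing one integer for both lets the survival exponentials
replay the bit stream that placed the cells and couples outcomes to core
composition — an artifact we observed and now guard against.

What the generator does **not** emulate — and hence what passing tests do
not establish about real tissue: marker intensities (only binary calls with
symmetric flip noise), spatially varying staining quality, cell-shape and
segmentation error, correlated marker noise, tissue substructure beyond
single-scale Thomas clustering, informative censoring, and any dependence
between core composition and follow-up beyond the planted covariate.

## Problem sizes and numerical choices

Validation runs use cohorts of 5–58 cores at 100–2200 cells/core, survival
recovery at 200 cases × 50 seeds, oracle comparisons on 100 random cores ≤
500 cells, and cytokine null calibration at 48 analytes × 20–30 seeds —
sizes at which every statistic is stable while the whole suite stays
convenient to run.  Distance comparisons against the O(n²) oracle use
absolute tolerance 1e−9; KD-tree radius queries are inclusive (≤ r), as is
the brute force.  Wald CIs use z = 1.96; the censoring horizon is solved
with Brent's method on a bracketed, monotone function.  Degenerate inputs
(empty cores, all-equal metrics, zero events, missing factorial cells) are
defined errors with named messages rather than silent NaNs.

## Known limitations

* The 0 µm near-group medians reported for the motivating cohort cannot be
  reproduced mechanistically from centroid distances; the `zero` policy
  emulates the most plausible coding but the true origin is undecidable
  from the text.
* Memory/naïve T-cell subtypes beyond mhT/mcT (tfhT, ahT, ecT, acT, nhT,
  ncT) are omitted from the default rule set — their full definitions live
  in a supplementary marker table not available here — and can be supplied
  via config.
* The headline cohort-specific survival statistics (e.g. MFS p ≈ 0.02,
  HR ≈ 2.6) depend on the unreleased 51-core dataset; the pipeline
  validates the *procedure* (parameter recovery, invariances, oracles),
  not those numbers.
* Cox fits on small strata can sit near separation; lifelines convergence
  warnings are surfaced, not suppressed.
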