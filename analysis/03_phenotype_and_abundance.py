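"""Phenotype every detectable cell and compute per-core abundances.

Applies the default marker-combination gating rules (M2 = CD68+CD163+,
mMDSC = CD11b+CD14+CD15-, Treg = CD3+FoxP3+, ...), then quantifies each
population as a percentage of the core's detectable cells and computes the
composite immunosuppressive-cell (IMSC) score per core.
"""

from osimc.abundance import abundance_matrix, imsc_score, pairwise_composites
from osimc.io import read_cell_table, write_cell_table
from osimc.phenotyping import assign_phenotypes, default_ruleset

from _paths import RESULTS


def main():
    cells = read_cell_table(RESULTS / "cells_qc.tsv")
    rules = default_ruleset()
    usable = [r for r in rules if (r.positive | r.negative) <= set(cells.columns)]
    from osimc.phenotyping import RuleSet

    labeled = assign_phenotypes(cells, RuleSet(tuple(usable)))
    write_cell_table(labeled, RESULTS / "cells_phenotyped.tsv")

    ab = abundance_matrix(labeled)
    ab["IMSC"] = imsc_score(ab, mode="mean")
    for pair in (("M2", "MDSC"), ("M2", "Treg"), ("MDSC", "Treg")):
        ab["+".join(pair)] = pairwise_composites(ab, pair, mode="mean")
    ab.to_csv(RESULTS / "abundance.tsv", sep="\t")

    top = ab.drop(columns=["IMSC", "M2+MDSC", "M2+Treg", "MDSC+Treg"]).mean().nlargest(5)
    print("top-5 populations (mean % of detectable cells):")
    for lab, pct in top.items():
        print(f"  {lab:<15s} {pct:5.1f}%")
    print(f"median IMSC composite: {ab['IMSC'].median():.2f}%")


if __name__ == "__main__":
    main()
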