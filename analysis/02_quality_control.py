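"""Core- and marker-level quality control of the simulated TMA.

Drops cores with <25% Ir191+ cells (the engineered poor-staining cores),
restricts the table to Ir191+ cells of retained cores, and applies the
>=3 cells / >=10%-of-cases marker filter.
"""

from osimc.io import read_cell_table, write_cell_table
from osimc.qc import core_qc, drop_failed_markers, marker_qc

from _paths import RESULTS


def main():
    cells = read_cell_table(RESULTS / "cells.tsv")
    n_before = cells["core_id"].nunique()
    filtered, core_rep = core_qc(cells)
    retained, marker_rep = marker_qc(filtered)
    filtered = drop_failed_markers(filtered, retained)

    core_rep.cores.to_csv(RESULTS / "qc_cores.tsv", sep="\t", index=False)
    marker_rep.markers.to_csv(RESULTS / "qc_markers.tsv", sep="\t", index=False)
    write_cell_table(filtered, RESULTS / "cells_qc.tsv")

    print(f"cores: {filtered['core_id'].nunique()}/{n_before} retained "
          f"(threshold {core_rep.thresholds['min_ir191_frac']:.0%} Ir191+)")
    print(f"markers: {len(retained)} retained of {len(marker_rep.markers)}")
    print(f"detectable (Ir191+) cells remaining: {len(filtered)}")


if __name__ == "__main__":
    main()
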