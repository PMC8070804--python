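#!/usr/bin/env python
"""Generate the 7-patient x 4-condition synthetic cohort at table level.

Each row is one cell with its ground-truth OMI variables.  The cohort
design encodes which patients respond to which treatments (see the
synthetic_data module docstring).  Writes results/cohort_cells.csv.
"""

from omiflim import io_formats as iof
from omiflim import synthetic_data as sd

SEED = 11
OUT = "results/cohort_cells.csv"


def main() -> None:
    table = sd.cohort(seed=SEED)
    counts = table.groupby(["patient_id", "condition"]).size()
    print(f"{len(table)} cells, {counts.index.get_level_values(0).nunique()} "
          f"patients, group sizes {sorted(set(counts))}")
    iof.write_cell_table(table, OUT, seed=SEED,
                         config=iof.RunConfig(seed=SEED))
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
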