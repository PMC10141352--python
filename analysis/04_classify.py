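#!/usr/bin/env python
"""Stage 4 — validate the allocation against waiting times.

Units are binned into waiting-time strata (Q1 shortest quarter, Q2 middle
half, Q3 longest quarter) and classified into categories A-G or unclassified
by crossing the allocation delta with the stratum.  Writes the assignments,
the per-category statistics and the waiting-group descriptive summary.
"""

from pathlib import Path

import pandas as pd

from ctalloc.feasibility import classify, group_stats, quartile_bins
from ctalloc.report import describe_by_waiting_group
from ctalloc.synth import read_units_csv

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    units = read_units_csv(ROOT / "results" / "units.csv")
    alloc = pd.read_csv(ROOT / "results" / "allocation.csv", dtype={"unit_code": str})

    quart = quartile_bins(units["waiting_days"], unit_codes=units["unit_code"], mode="rank")
    assigned = classify(
        alloc["ea_scanners"].to_numpy(),
        alloc["historical_scanners"].to_numpy(dtype=float),
        quart, similar_tolerance=1,
        unit_codes=units["unit_code"].to_numpy(),
    )
    assigned.to_csv(ROOT / "results" / "assignments.csv", index=False)
    stats = group_stats(assigned, units, alloc["ea_scanners"].to_numpy())
    stats.to_csv(ROOT / "results" / "group_stats.csv", index=False)
    describe_by_waiting_group(units).to_csv(
        ROOT / "results" / "waiting_group_summary.csv", index=False
    )

    counts = assigned.category.value_counts()
    print(f"classified {len(assigned)} of {len(units)} units:")
    for cat in "ABCDEFG":
        print(f"  {cat}: {counts.get(cat, 0)}")
    print(f"  unclassified: {counts.get('unclassified', 0)}")
    below = sum(counts.get(c, 0) for c in "CDF")
    above = sum(counts.get(c, 0) for c in "ABE")
    print(f"model below history in {below} units, above in {above}, "
          f"agreement in {counts.get('G', 0)}")


if __name__ == "__main__":
    main()
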