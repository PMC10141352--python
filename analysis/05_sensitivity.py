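#!/usr/bin/env python
"""Stage 5 — weight sensitivity of the optimise-then-classify pipeline.

Re-runs the full pipeline under the published weight design (baseline,
population weight raised to 0.5 and 1.0, demographic weights raised to 0.5
and 1.0), five seeds each, and tabulates mean per-category unit counts.
"""

from pathlib import Path

import pandas as pd

from ctalloc.ea import EAConfig
from ctalloc.feasibility import CATEGORIES
from ctalloc.sensitivity import compare_scenarios, default_scenarios, run_scenarios
from ctalloc.synth import read_units_csv

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    units = read_units_csv(ROOT / "results" / "units.csv")
    table = run_scenarios(units, default_scenarios(), EAConfig())
    table.to_csv(ROOT / "results" / "sensitivity.csv", index=False)
    print(table[["scenario", *CATEGORIES]].to_string(index=False))

    base = table.set_index("scenario").loc["baseline", list(CATEGORIES)].astype(float)
    for label in table.scenario:
        if label == "baseline":
            continue
        other = table.set_index("scenario").loc[label, list(CATEGORIES)].astype(float)
        _, tv = compare_scenarios(base, other)
        print(f"total variation vs baseline — {label}: {tv:.3f}")


if __name__ == "__main__":
    main()
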