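#!/usr/bin/env python
"""Stage 2 — rank ICD-10 codes, keep the TOP-K core set, count green patients.

Reads scratch/claims.csv (regenerated from results/units.csv if missing),
applies the packaged illustrative appropriateness map, and writes the code
ranking plus the per-unit green-indication patient counts to results/.
"""

from pathlib import Path

import pandas as pd

from ctalloc import clinical
from ctalloc.synth import generate_claims, read_units_csv

TOP_K = 20  # the claim generator draws from a 30-code pool
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    claims_path = ROOT / "scratch" / "claims.csv"
    if claims_path.exists():
        claims = pd.read_csv(claims_path, dtype={"unit_code": str})
    else:
        units = read_units_csv(ROOT / "results" / "units.csv")
        claims = generate_claims(units, seed=2)
    clinical.validate_claims(claims)

    ranked = clinical.rank_icd_codes(claims)
    ranked.to_csv(ROOT / "results" / "icd_ranking.csv", index=False)
    core, share = clinical.select_core_set(ranked, k=TOP_K)
    print(f"TOP-{TOP_K} core set covers {100 * share:.1f}% of {len(claims):,} claims")

    amap = clinical.default_appropriateness()
    shares = clinical.category_shares(claims, core, amap)
    print("appropriateness breakdown of core-set claims: "
          + ", ".join(f"{k} {100 * v:.1f}%" for k, v in shares.items()))

    green = clinical.count_green_patients(claims, core, amap)
    green.reset_index().to_csv(ROOT / "results" / "green_counts.csv", index=False)
    print(f"green patients per unit: median {green.median():,.0f}, "
          f"range {green.min():,}-{green.max():,} -> results/green_counts.csv")


if __name__ == "__main__":
    main()
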