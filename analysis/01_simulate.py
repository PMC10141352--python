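#!/usr/bin/env python
"""Stage 1 — synthesise the county table and claim-level records.

The registry data behind the original analysis are access-restricted, so the
study conditions are emulated: 130 units, lognormal populations around
1.25e5, 52% female share, age strata as binomial fractions, ~6.5 CT
referrals per 100 inhabitants, and waiting times driven by the
demand-to-capacity ratio.  Writes the unit table to results/units.csv and
the (large, regenerable) claim table to scratch/claims.csv.
"""

from pathlib import Path

from ctalloc.synth import SynthParams, generate_claims, generate_units, units_to_frame

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    units = units_to_frame(generate_units(SynthParams(seed=SEED)))
    (ROOT / "results").mkdir(exist_ok=True)
    units.to_csv(ROOT / "results" / "units.csv", index=False)
    print(f"simulated {len(units)} units (seed={SEED}):")
    print(f"  population mean {units.population.mean():,.0f}, "
          f"female share {units.female_ratio.mean():.3f}, "
          f"waiting {units.waiting_days.min():.0f}-{units.waiting_days.max():.0f} days")

    claims = generate_claims(units, seed=SEED + 1)
    (ROOT / "scratch").mkdir(exist_ok=True)
    claims.to_csv(ROOT / "scratch" / "claims.csv", index=False)
    print(f"  {len(claims):,} claims across {claims.icd10.nunique()} ICD-10 codes "
          f"-> scratch/claims.csv")


if __name__ == "__main__":
    main()
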