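"""Synthetic geographic-unit tables and claim-level records.

The study's raw county data (National Health Fund claims, Ministry of Health
scanner registries) are access-restricted, so this module generates tables
with the same statistical structure: ~130 units whose populations are
right-skewed (lognormal), female share near 52%, age strata drawn as
binomial fractions of population, CT referral counts roughly proportional to
population, and waiting times that grow with the demand-to-capacity ratio
(referred patients per scanner) — the signal the downstream feasibility
classifier needs.  The printed summary tables of the original study ship as
small CSV fixtures for arithmetic cross-checks.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UnitRecord",
    "SynthParams",
    "generate_units",
    "generate_claims",
    "units_to_frame",
    "load_fixture",
    "read_units_csv",
    "write_units_csv",
    "DEFAULT_ICD_POOL",
]

UNIT_COLUMNS = [
    "unit_code",
    "unit_name",
    "population",
    "female_ratio",
    "over65",
    "under14",
    "referred_patients",
    "historical_scanners",
    "waiting_days",
]

FIXTURE_FILES = {
    "table1_summaries": "table1_summaries.csv",
    "table2_allocations": "table2_allocations.csv",
    "table3_group_stats": "table3_group_stats.csv",
    "table4_sensitivity": "table4_sensitivity.csv",
}


@dataclasses.dataclass(frozen=True)
class UnitRecord:
    """One geographic unit's need predictors and historical CT provision."""

    unit_code: str
    unit_name: str
    population: int
    female_ratio: float
    over65: int
    under14: int
    referred_patients: int
    historical_scanners: int
    waiting_days: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.female_ratio <= 1.0:
            raise ValueError("female_ratio must lie in [0, 1]")
        for name in ("population", "over65", "under14", "referred_patients", "historical_scanners"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.over65 + self.under14 > self.population:
            raise ValueError("age strata exceed population")
        if self.waiting_days < 0:
            raise ValueError("waiting_days must be non-negative")


@dataclasses.dataclass(frozen=True)
class SynthParams:
    """Parameters of the unit generator.

    Defaults are calibrated to the study population: 130 units, mean county
    population ~1.25e5 with a max/min ratio of roughly twenty (lognormal),
    female share 52% (sd ~1.1 points), over-65 share ~19%, under-14 share
    ~15%, about 6.5 CT referrals per 100 inhabitants over the five-year
    window, ~1 scanner per 26 000 inhabitants (at least two per included
    unit, mirroring the study's inclusion rule), and mean waits of a few
    weeks produced by ``waiting_link_slope`` days per referred patient per
    scanner.
    """

    n_units: int = 130
    population_log_mean: float = 11.611  # exp(mu + sd^2/2) ~ 1.25e5
    population_log_sd: float = 0.5
    female_ratio_mean: float = 0.52
    female_ratio_sd: float = 0.011
    over65_frac_mean: float = 0.19
    over65_frac_sd: float = 0.02
    under14_frac_mean: float = 0.15
    under14_frac_sd: float = 0.015
    referral_rate_per_capita: float = 0.065
    referral_noise_sd: float = 0.35
    scanner_per_capita: float = 3.8e-5
    waiting_link_slope: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_units < 2:
            raise ValueError("n_units must be at least 2")
        for name in (
            "female_ratio_mean", "over65_frac_mean", "under14_frac_mean",
            "referral_rate_per_capita", "scanner_per_capita",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "population_log_sd", "female_ratio_sd", "over65_frac_sd",
            "under14_frac_sd", "referral_noise_sd", "waiting_link_slope",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def generate_units(params: SynthParams) -> list[UnitRecord]:
    """Generate ``params.n_units`` synthetic units; identical seeds give identical output."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_units

    population = np.round(
        rng.lognormal(params.population_log_mean, params.population_log_sd, n)
    ).astype(np.int64)
    population = np.maximum(population, 1000)

    female_ratio = np.clip(
        rng.normal(params.female_ratio_mean, params.female_ratio_sd, n), 0.0, 1.0
    )
    over65_frac = np.clip(rng.normal(params.over65_frac_mean, params.over65_frac_sd, n), 0.0, 0.5)
    under14_frac = np.clip(rng.normal(params.under14_frac_mean, params.under14_frac_sd, n), 0.0, 0.5)
    over65 = rng.binomial(population, over65_frac)
    under14 = rng.binomial(population, under14_frac)
    # truncate so the strata never exceed the population
    excess = np.maximum(over65 + under14 - population, 0)
    under14 = under14 - excess

    referred = np.round(
        population
        * params.referral_rate_per_capita
        * rng.lognormal(0.0, params.referral_noise_sd, n)
    ).astype(np.int64)
    referred = np.maximum(referred, 1)

    # at least two scanners per unit, mirroring the study's inclusion rule
    scanners = np.maximum(rng.poisson(population * params.scanner_per_capita), 2)

    demand_ratio = referred / np.maximum(scanners, 1)
    waiting = params.waiting_link_slope * demand_ratio * rng.lognormal(0.0, 0.15, n)

    return [
        UnitRecord(
            unit_code=f"U{i:04d}",
            unit_name=f"unit-{i:04d}",
            population=int(population[i]),
            female_ratio=float(female_ratio[i]),
            over65=int(over65[i]),
            under14=int(under14[i]),
            referred_patients=int(referred[i]),
            historical_scanners=int(scanners[i]),
            waiting_days=float(waiting[i]),
        )
        for i in range(n)
    ]


#: Illustrative ICD-10 pool (code, relative frequency) used by the claim
#: generator; roughly Zipf-shaped, overlapping the packaged appropriateness map.
DEFAULT_ICD_POOL: list[tuple[str, float]] = [
    ("C34", 100.0), ("I63", 80.0), ("S06", 65.0), ("C71", 50.0), ("R51", 45.0),
    ("C18", 40.0), ("J18", 35.0), ("K80", 30.0), ("M54", 28.0), ("C61", 25.0),
    ("I60", 22.0), ("R10", 20.0), ("C50", 18.0), ("N20", 16.0), ("J44", 14.0),
    ("C25", 12.0), ("G40", 10.0), ("R07", 9.0), ("K35", 8.0), ("C16", 7.0),
    ("I71", 6.0), ("R06", 5.0), ("C64", 4.5), ("S32", 4.0), ("H66", 3.0),
    ("C78", 2.5), ("K57", 2.0), ("R55", 1.5), ("M51", 1.2), ("C22", 1.0),
]


def generate_claims(
    units: Sequence[UnitRecord] | pd.DataFrame,
    icd_pool: Sequence[tuple[str, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate one claim per referred patient.

    Per-unit claim counts sum exactly to each unit's ``referred_patients``;
    ICD-10 codes are drawn from the pool proportionally to the given
    frequencies; each claim carries a distinct patient id and a study-window
    year.  Returns a frame with columns unit_code, icd10, patient_id, year.
    """
    if isinstance(units, pd.DataFrame):
        frame = units
    else:
        frame = units_to_frame(units)
    if len(frame) == 0:
        raise ValueError("unit list is empty")
    pool = list(DEFAULT_ICD_POOL if icd_pool is None else icd_pool)
    codes = np.array([c for c, _ in pool])
    freqs = np.array([f for _, f in pool], dtype=float)
    if (freqs < 0).any() or freqs.sum() <= 0:
        raise ValueError("ICD pool frequencies must be non-negative with at least one positive")
    probs = freqs / freqs.sum()

    rng = np.random.default_rng(seed)
    counts = frame["referred_patients"].to_numpy(dtype=np.int64)
    total = int(counts.sum())
    unit_codes = np.repeat(frame["unit_code"].to_numpy(), counts)
    icd = codes[rng.choice(codes.size, size=total, p=probs)]
    years = rng.integers(2015, 2020, size=total)
    patient_ids = np.char.add("P", np.arange(total).astype(str))
    return pd.DataFrame(
        {"unit_code": unit_codes, "icd10": icd, "patient_id": patient_ids, "year": years}
    )


def units_to_frame(units: Sequence[UnitRecord]) -> pd.DataFrame:
    """Tabulate unit records with the canonical column order."""
    return pd.DataFrame([dataclasses.asdict(u) for u in units], columns=UNIT_COLUMNS)


def read_units_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"unit_code": str}, float_precision="round_trip")
    missing = [c for c in UNIT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"unit CSV is missing columns: {missing}")
    return frame[UNIT_COLUMNS]


def write_units_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the packaged study-table transcriptions.

    Known names: ``table1_summaries``, ``table2_allocations``,
    ``table3_group_stats``, ``table4_sensitivity``.  Values are transcribed
    verbatim from the printed tables; "ND" (no data) entries are returned as
    NaN and are never imputed.
    """
    try:
        filename = FIXTURE_FILES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURE_FILES)}"
        ) from None
    ref = resources.files("ctalloc.data").joinpath(filename)
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, dtype={"unit_code": str}, na_values=["ND"])
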