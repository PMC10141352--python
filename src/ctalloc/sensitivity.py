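"""Weight sensitivity analysis of the optimise-then-classify pipeline.

Each scenario fixes the five fitness weights and a list of seeds; the full
evolutionary run plus feasibility classification is repeated per seed and
the per-category unit counts (averaged over seeds) are tabulated, one row
per scenario.  The default scenario set is the published design: baseline
(all weights 0.1), population weight raised to 0.5 and 1.0, and the three
demographic weights (female ratio, over-65, under-14) raised to 0.5 and 1.0.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .ea import EAConfig, evolve
from .feasibility import CATEGORIES, classify, quartile_bins

__all__ = ["Scenario", "default_scenarios", "run_scenarios", "compare_scenarios"]

WEIGHT_FIELDS = ("w_population", "w_females", "w_old", "w_young", "w_patients")


@dataclasses.dataclass(frozen=True)
class Scenario:
    """One weight setting to evaluate, replicated over ``seeds``."""

    label: str
    weights: dict[str, float]
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)

    def __post_init__(self) -> None:
        unknown = set(self.weights) - set(WEIGHT_FIELDS)
        if unknown:
            raise ValueError(f"unknown weight fields: {sorted(unknown)}")
        values = [self.weights.get(f, 0.1) for f in WEIGHT_FIELDS]
        if any(v < 0 for v in values):
            raise ValueError("weights must be non-negative")
        if all(v == 0 for v in values):
            raise ValueError("weights must not all be zero")
        object.__setattr__(self, "seeds", tuple(self.seeds))


def default_scenarios(seeds: Sequence[int] = (0, 1, 2, 3, 4)) -> list[Scenario]:
    """Baseline plus the four published weight variations."""
    seeds = tuple(seeds)
    base = {f: 0.1 for f in WEIGHT_FIELDS}
    rows = [
        ("baseline", {}),
        ("population_0.5", {"w_population": 0.5}),
        ("population_1.0", {"w_population": 1.0}),
        ("demographic_0.5", {"w_females": 0.5, "w_old": 0.5, "w_young": 0.5}),
        ("demographic_1.0", {"w_females": 1.0, "w_old": 1.0, "w_young": 1.0}),
    ]
    return [Scenario(label, {**base, **delta}, seeds) for label, delta in rows]


def run_scenarios(
    units: pd.DataFrame,
    scenarios: Sequence[Scenario],
    cfg: EAConfig,
    quartile_mode: str = "rank",
    similar_tolerance: int = 1,
) -> pd.DataFrame:
    """Evolve + classify per scenario and seed; tabulate per-category counts.

    Returns one row per scenario with the weight columns, the per-category
    mean unit count over seeds (columns A..G and unclassified) and the
    number of seeds.  Counts in every underlying run partition the
    classifiable units.
    """
    if len(scenarios) == 0:
        raise ValueError("at least one scenario is required")
    quart = quartile_bins(
        units["waiting_days"], unit_codes=units["unit_code"], mode=quartile_mode
    )
    hist = units["historical_scanners"].to_numpy()
    rows = []
    for sc in scenarios:
        per_seed = []
        for seed in sc.seeds:
            run_cfg = cfg.replace(seed=seed, **sc.weights)
            result = evolve(units, run_cfg)
            assigned = classify(
                result.best.genes, hist, quart,
                similar_tolerance=similar_tolerance,
                unit_codes=units["unit_code"].to_numpy(),
            )
            counts = assigned["category"].value_counts()
            per_seed.append([counts.get(c, 0) for c in CATEGORIES])
        mean_counts = np.mean(per_seed, axis=0)
        row = {"scenario": sc.label, "n_seeds": len(sc.seeds)}
        row.update({f: sc.weights.get(f, 0.1) for f in WEIGHT_FIELDS})
        row.update(dict(zip(CATEGORIES, mean_counts)))
        rows.append(row)
    return pd.DataFrame(rows)


def compare_scenarios(table_a: pd.Series, table_b: pd.Series) -> tuple[pd.Series, float]:
    """Per-category absolute count differences and total variation distance.

    Both inputs are category → count series over the same category set.  The
    total variation distance is computed on the count-normalised
    distributions; it is symmetric and zero iff the tables are identical.
    """
    if set(table_a.index) != set(table_b.index):
        raise ValueError("scenario tables cover different category sets")
    b = table_b.reindex(table_a.index)
    abs_diff = (table_a - b).abs()
    pa = table_a / table_a.sum() if table_a.sum() else table_a * 0.0
    pb = b / b.sum() if b.sum() else b * 0.0
    tv = float(0.5 * (pa - pb).abs().sum())
    return abs_diff, tv
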