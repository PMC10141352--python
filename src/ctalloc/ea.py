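"""Evolutionary search over integer scanner allocations.

A candidate allocation (*chromosome*) is a vector of non-negative integer
scanner counts, one gene per geographic unit.  Its fitness is a weighted sum
of mean squared errors between the min-max-scaled allocation and five
min-max-scaled need-predictor series (female ratio, over-65 share, under-14
share, population, CT-referred patients).  Lower fitness is better: a zero
score means the scaled allocation tracks every predictor exactly.

The generation loop is the classical genetic-algorithm cycle — roulette-wheel
selection on inverse fitness, per-gene uniform crossover within a randomly
paired 30% pool, and per-gene additive integer mutation clamped at zero —
with the best chromosome ever evaluated tracked outside the evolving
population (no elitist operator inside it).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Chromosome",
    "EAConfig",
    "PredictorSeries",
    "FitnessBreakdown",
    "EAResult",
    "minmax_scale",
    "mse",
    "fitness",
    "init_population",
    "roulette_select",
    "crossover",
    "mutate",
    "evolve",
]

log = logging.getLogger(__name__)

#: floor applied to fitness totals before inversion in roulette selection,
#: so a perfect (zero-fitness) chromosome does not divide by zero.
ZERO_FITNESS_FLOOR = 1e-12

PREDICTOR_NAMES = ("females", "old", "young", "population", "patients")


@dataclasses.dataclass(frozen=True)
class Chromosome:
    """One candidate allocation: a non-negative integer scanner count per unit."""

    genes: np.ndarray

    def __post_init__(self) -> None:
        genes = np.asarray(self.genes, dtype=np.int64)
        if genes.ndim != 1:
            raise ValueError("genes must be a 1-D integer vector")
        if (genes < 0).any():
            raise ValueError("genes must be non-negative")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return self.genes.size


@dataclasses.dataclass(frozen=True)
class EAConfig:
    """Hyperparameters of the evolutionary search.

    Defaults are the study settings: 100 chromosomes evolved for 1000
    generations; 30% of chromosomes enter the crossover pool and paired
    chromosomes swap each gene with probability 0.10; each gene mutates with
    probability 0.005 by adding a uniform integer in [-5, 10] (asymmetric so
    under-supplied units can grow quickly), clamped at zero; all five
    predictor weights equal 0.1 (deliberately not renormalised to sum to 1).
    """

    pop_size: int = 100
    generations: int = 1000
    crossover_chrom_prob: float = 0.30
    crossover_gene_prob: float = 0.10
    mutation_gene_prob: float = 0.005
    mutation_low: int = -5
    mutation_high: int = 10
    w_females: float = 0.1
    w_old: float = 0.1
    w_young: float = 0.1
    w_population: float = 0.1
    w_patients: float = 0.1
    init_gene_max: int = 10
    age_as_counts: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("crossover_chrom_prob", "crossover_gene_prob", "mutation_gene_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.mutation_low > self.mutation_high:
            raise ValueError("mutation_low must not exceed mutation_high")
        if self.pop_size < 2:
            raise ValueError("pop_size must be at least 2")
        if self.generations < 1:
            raise ValueError("generations must be at least 1")
        if self.init_gene_max < 0:
            raise ValueError("init_gene_max must be non-negative")
        for name in ("w_females", "w_old", "w_young", "w_population", "w_patients"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def weights(self) -> np.ndarray:
        """Predictor weights in canonical order (females, old, young, population, patients)."""
        return np.array(
            [self.w_females, self.w_old, self.w_young, self.w_population, self.w_patients]
        )

    def replace(self, **kwargs) -> "EAConfig":
        return dataclasses.replace(self, **kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclasses.dataclass(frozen=True)
class PredictorSeries:
    """The five need-predictor series, aligned to the unit order of the genes."""

    v_females: np.ndarray
    v_old: np.ndarray
    v_young: np.ndarray
    v_population: np.ndarray
    v_patients: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        length = None
        for f in dataclasses.fields(self):
            a = np.asarray(getattr(self, f.name), dtype=float)
            if a.ndim != 1 or a.size == 0:
                raise ValueError(f"{f.name} must be a non-empty 1-D series")
            if np.isnan(a).any():
                raise ValueError(f"{f.name} contains missing values")
            if length is None:
                length = a.size
            elif a.size != length:
                raise ValueError("all predictor series must have equal length")
            arrays[f.name] = a
        for name, a in arrays.items():
            object.__setattr__(self, name, a)

    def __len__(self) -> int:
        return self.v_population.size

    def as_matrix(self) -> np.ndarray:
        """(5, G) matrix in canonical predictor order."""
        return np.stack(
            [self.v_females, self.v_old, self.v_young, self.v_population, self.v_patients]
        )

    @classmethod
    def from_units(cls, units: pd.DataFrame, age_as_counts: bool = False) -> "PredictorSeries":
        """Build the series from a unit table.

        The age strata enter as shares of the county population by default
        (``over65/population``, ``under14/population``); with
        ``age_as_counts=True`` the raw counts are used instead.
        """
        pop = units["population"].to_numpy(dtype=float)
        old = units["over65"].to_numpy(dtype=float)
        young = units["under14"].to_numpy(dtype=float)
        if not age_as_counts:
            old = old / pop
            young = young / pop
        return cls(
            v_females=units["female_ratio"].to_numpy(dtype=float),
            v_old=old,
            v_young=young,
            v_population=pop,
            v_patients=units["referred_patients"].to_numpy(dtype=float),
        )


@dataclasses.dataclass(frozen=True)
class FitnessBreakdown:
    """Per-predictor MSE components and their weighted total (lower is better)."""

    p_females: float
    p_old: float
    p_young: float
    p_population: float
    p_patients: float
    total: float

    def components(self) -> np.ndarray:
        return np.array(
            [self.p_females, self.p_old, self.p_young, self.p_population, self.p_patients]
        )


@dataclasses.dataclass
class EAResult:
    best: Chromosome
    best_fitness: FitnessBreakdown
    history: np.ndarray  # best-ever total per generation, non-increasing


def minmax_scale(v: Sequence[float] | np.ndarray) -> np.ndarray:
    """Scale a series to [0, 1] by (v - min) / (max - min).

    A constant series (max == min) maps to all zeros: the formula is undefined
    there and zero is the conventional degenerate value used throughout.
    """
    a = np.asarray(v, dtype=float)
    if a.size == 0:
        raise ValueError("cannot scale an empty series")
    lo = a.min()
    span = a.max() - lo
    if span == 0:
        return np.zeros_like(a)
    return (a - lo) / span


def mse(a: Sequence[float] | np.ndarray, b: Sequence[float] | np.ndarray) -> float:
    """Mean squared error (1/n) * sum((a_i - b_i)^2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def _scaled_predictor_matrix(series: PredictorSeries) -> np.ndarray:
    return np.stack([minmax_scale(row) for row in series.as_matrix()])


def _scale_rows(pop: np.ndarray) -> np.ndarray:
    """Min-max scale each row of a population matrix; constant rows map to zeros."""
    pop = pop.astype(float)
    lo = pop.min(axis=1, keepdims=True)
    span = pop.max(axis=1, keepdims=True) - lo
    out = np.zeros_like(pop)
    np.divide(pop - lo, span, out=out, where=span != 0)
    return out


def batch_fitness(
    population: np.ndarray, scaled_predictors: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Fitness components and totals for a whole (P, G) population at once.

    Returns ``(components, totals)`` with shapes (P, 5) and (P,).
    """
    scaled = _scale_rows(population)  # (P, G)
    diffs = scaled[:, None, :] - scaled_predictors[None, :, :]  # (P, 5, G)
    components = np.mean(diffs**2, axis=2)
    return components, components @ weights


def fitness(chrom: Chromosome | np.ndarray, series: PredictorSeries, cfg: EAConfig) -> FitnessBreakdown:
    """Score one allocation against the predictor series (lower is better).

    Each component is ``mse(minmax_scale(series_x), minmax_scale(genes))`` and
    the total is the weighted sum of the five components.
    """
    genes = chrom.genes if isinstance(chrom, Chromosome) else np.asarray(chrom)
    if genes.size != len(series):
        raise ValueError(
            f"chromosome length {genes.size} does not match series length {len(series)}"
        )
    scaled_genes = minmax_scale(genes)
    comps = np.array(
        [mse(minmax_scale(row), scaled_genes) for row in series.as_matrix()]
    )
    total = float(comps @ cfg.weights)
    return FitnessBreakdown(*comps.tolist(), total=total)


def init_population(cfg: EAConfig, n_genes: int, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw the initial population: genes i.i.d. uniform on {0, ..., init_gene_max}.

    Returns a (pop_size, n_genes) integer matrix, one chromosome per row.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be at least 1")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    return rng.integers(0, cfg.init_gene_max + 1, size=(cfg.pop_size, n_genes), dtype=np.int64)


def roulette_select(
    population: np.ndarray,
    fitness_totals: np.ndarray,
    cfg: EAConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sample the next generation with replacement, favouring low fitness.

    Selection probability of chromosome i is (1/f_i) / sum_j (1/f_j); totals
    are floored at a tiny epsilon so perfect chromosomes remain selectable.
    An all-zero-fitness population degenerates to uniform selection.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    totals = np.asarray(fitness_totals, dtype=float)
    if totals.size != population.shape[0]:
        raise ValueError("one fitness total per chromosome required")
    if (totals <= 0).all():
        log.warning("all fitness totals are zero; falling back to uniform selection")
    inv = 1.0 / np.maximum(totals, ZERO_FITNESS_FLOOR)
    probs = inv / inv.sum()
    idx = rng.choice(totals.size, size=cfg.pop_size, replace=True, p=probs)
    return population[idx].copy()


def crossover(
    population: np.ndarray, cfg: EAConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Uniform per-gene crossover within a randomly paired pool.

    Each chromosome independently enters the pool with probability
    ``crossover_chrom_prob``; pool members are shuffled and paired adjacently
    (an odd leftover passes through unchanged); paired chromosomes swap each
    gene position with probability ``crossover_gene_prob``.  Swapping only
    permutes values within a position, so the per-position multiset of gene
    values across the population is conserved exactly.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    out = population.copy()
    pool = np.flatnonzero(rng.random(out.shape[0]) < cfg.crossover_chrom_prob)
    rng.shuffle(pool)
    for k in range(0, pool.size - 1, 2):
        i, j = pool[k], pool[k + 1]
        swap = rng.random(out.shape[1]) < cfg.crossover_gene_prob
        out[i, swap], out[j, swap] = out[j, swap].copy(), out[i, swap].copy()
    return out


def mutate(
    population: np.ndarray, cfg: EAConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Additive integer mutation, clamped at zero.

    Each gene independently mutates with probability ``mutation_gene_prob``;
    a uniform integer delta in [mutation_low, mutation_high] inclusive is
    added and negative results are set to zero.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    mask = rng.random(population.shape) < cfg.mutation_gene_prob
    deltas = rng.integers(cfg.mutation_low, cfg.mutation_high + 1, size=population.shape)
    mutated = np.where(mask, population + deltas, population)
    return np.maximum(mutated, 0).astype(np.int64)


def evolve(
    units: pd.DataFrame | PredictorSeries, cfg: EAConfig
) -> EAResult:
    """Run the full generation loop and return the best-ever allocation.

    ``units`` may be a unit table (the predictor series are derived from it,
    honouring ``cfg.age_as_counts``) or a ready-made :class:`PredictorSeries`.
    Each generation the population is scored, the incumbent best is updated,
    and selection, crossover and mutation produce the next generation.  The
    returned history holds the best-ever total after each generation and is
    non-increasing by construction.
    """
    if isinstance(units, PredictorSeries):
        series = units
    else:
        if len(units) < 2:
            raise ValueError("at least 2 units are required")
        series = PredictorSeries.from_units(units, age_as_counts=cfg.age_as_counts)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    scaled_pred = _scaled_predictor_matrix(series)
    weights = cfg.weights

    population = init_population(cfg, len(series), rng)
    best_genes: np.ndarray | None = None
    best_total = np.inf
    history = np.empty(cfg.generations)

    for gen in range(cfg.generations):
        _, totals = batch_fitness(population, scaled_pred, weights)
        i = int(np.argmin(totals))
        if totals[i] < best_total:
            best_total = float(totals[i])
            best_genes = population[i].copy()
        history[gen] = best_total
        population = roulette_select(population, totals, cfg, rng)
        population = crossover(population, cfg, rng)
        population = mutate(population, cfg, rng)

    assert best_genes is not None
    best = Chromosome(best_genes)
    breakdown = fitness(best, series, cfg)
    log.info(
        "evolve finished: seed=%s config=%s best_fitness=%.6g",
        cfg.seed, cfg.config_hash(), breakdown.total,
    )
    return EAResult(best=best, best_fitness=breakdown, history=history)
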