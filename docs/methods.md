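# Methods

## Problem and model

The package allocates CT scanners across G geographic units (counties) from
need predictors rather than from historical provision. A candidate
allocation is an integer vector **c** = (c₁, …, c_G), cᵢ ≥ 0 scanners in
unit i. Five predictor series describe need: female ratio, over-65 share,
under-14 share, population, and CT-referred patients (optionally replaced by
the clinically filtered green-indication patient count). With v′ denoting
min-max scaling v′ᵢ = (vᵢ − min v)/(max v − min v), the objective is

    f(c) = w_f·MSE(v′_females, c′) + w_o·MSE(v′_old, c′) + w_y·MSE(v′_young, c′)
         + w_p·MSE(v′_population, c′) + w_t·MSE(v′_patients, c′)

minimised over allocations; f = 0 means the scaled allocation tracks every
scaled predictor exactly. All weights default to 0.1 and are deliberately
not renormalised (their sum is 0.5), preserving the original design.

A genetic algorithm minimises f: a population of 100 integer chromosomes is
initialised uniformly on {0,…,10} per gene, and each generation applies

1. **fitness evaluation** (the incumbent best-ever chromosome is updated
   here, outside the evolving population — there is no elitist operator);
2. **roulette-wheel selection on inverse fitness**: chromosome i is drawn
   with probability (1/fᵢ)/Σⱼ(1/fⱼ), with fitness floored at 1e−12 so a
   perfect chromosome remains selectable (an all-zero-fitness population
   degenerates to uniform selection, which is logged);
3. **crossover**: each chromosome enters a pool with probability 0.30; the
   pool is shuffled and paired adjacently (odd leftover unchanged); paired
   chromosomes swap each gene with probability 0.10. This conserves the
   per-position multiset of values across the population;
4. **mutation**: each gene mutates with probability 0.005 by adding a
   uniform integer from {−5,…,10}; negative results clamp to 0. The range
   is asymmetric so under-supplied units can grow quickly.

The loop runs a fixed 1000 generations (no convergence test); the
per-generation best-ever history is exported so the plateau can be
inspected. All randomness flows through one seeded `numpy` generator per
run, so a seed plus a config reproduces every output byte for byte.

### Numerical choices

- Constant series scale to all zeros (the min-max formula is undefined
  there); this is logged nowhere but documented, and property-tested.
- Ranking ties (ICD-10 frequency) break lexicographically; waiting-time
  ties in stratification break by unit code. Both make outputs
  order-independent and deterministic.
- The mutation delta is an **integer** uniform over the 16 values −5…10,
  since genes are integer counts.
- "Best across all generations" is tracked as an incumbent outside the
  population rather than via elitism, so selection pressure is unchanged.

### A consequence of scale invariance

f depends on the genes only through their min-max image, so multiplying an
allocation by any positive constant (or shifting it) leaves f unchanged.
The *absolute* scanner totals of the evolved allocation are therefore
anchored only by the initialisation range and by mutation drift — the
asymmetric delta (mean +2.5, clamped at zero) pushes the population's
absolute level slowly upward over many generations. Consequently the sign
balance of (model − historical) deltas in the downstream classification is
sensitive to initialisation and run length, not only to the predictors.
Users comparing against historical counts should treat the *relative*
allocation as the model's signal; this is a known limitation inherited from
the objective's design.

## Clinical need filter

Claims (unit, ICD-10 code, patient, year) are ranked by code frequency; the
TOP-K prefix (K = 50 by default, a free parameter) is the core set; an
appropriateness map rates each code green ("usually appropriate" for CT),
yellow ("may be appropriate") or red ("usually not appropriate"); and the
clinical demand series is the number of **distinct patients** per unit with
a green core-set indication (a flag switches to counting procedures, for
comparison). Yellow and red codes contribute nothing downstream; their
shares are reported for completeness. The packaged default map
(`default_appropriateness_synthetic.csv`) is an illustrative synthetic
stand-in — the guideline-derived map behind the original analysis is not
public — and must be replaced for any real use.

## Feasibility classification

Waiting times are held out of the optimisation and used as an external
check. Units are stratified into Q1/Q2/Q3. Two conventions are implemented
because the source describes both:

- **rank** (default): order units by waiting time and cut at the 25th/75th
  percentile of *units* (ceil(0.25 n) / ceil(0.75 n)), reproducing the
  published 33/65/32 split at n = 130;
- **value**: cut at 25% and 75% of the *longest* waiting time.

Each unit with non-missing history is then classified from
direction × stratum, where direction compares delta = model − historical to
±`similar_tolerance` (default 1 scanner; strict equality is ruled out by the
published group statistics):

| direction | Q1 | Q2 | Q3 |
|-----------|----|----|----|
| greater   | B  | E  | A  |
| similar   | unclassified | G | unclassified |
| lower     | D  | F  | C  |

The B/E and D/F split and the unclassified rule are **reconstructions**:
the textual category list gives B and E (and D and F) identical conditions,
and the published group statistics (B and D have mean waits of ~7 and ~6
days, E and F ~18 and ~30; the unclassified units agree with history but
have extreme waits) pin down the assignment used here. Units with missing
historical counts are excluded with a warning, never imputed.

## Synthetic data generator

`generate_units` emulates the study's county statistics: lognormal
populations (right-skewed, mean ≈ 1.25e5, max/min ratio ≈ 20), female share
Normal(0.52, 0.011), over-65 and under-14 counts binomial with mean shares
0.19 and 0.15 (truncated so the strata never exceed the population),
referral counts ≈ 6.5 per 100 inhabitants with lognormal noise (hence
positively correlated with population), at least two scanners per unit
(the study's inclusion rule), and waiting times proportional to the
demand-to-capacity ratio (referred patients per scanner, slope 0.02
days) with mild lognormal noise — giving the classifier a real signal to
detect. `generate_claims` emits one claim per referred patient with codes
drawn from a configurable ~30-code pool with Zipf-like frequencies.

What the generator does **not** emulate: spatial structure and patient
mobility between units, the five big-city district split, correlated
year-to-year dynamics, repeat procedures per patient (each synthetic
patient has one claim), and any real epidemiology behind the ICD mix.
Passing tests on synthetic data therefore demonstrate the machinery's
correctness and the pipeline's statistical behaviour under known
conditions, not the clinical validity of any particular allocation.

## Sensitivity analysis

Scenarios fix the five weights; each runs the full evolve-and-classify
pipeline over ≥ 5 seeds (the underlying study reported single runs while
acknowledging the randomness), and mean per-category counts are tabulated.
The default scenario set is the published design: baseline, population
weight at 0.5 and 1.0, and the three demographic weights jointly at 0.5 and
1.0. `compare_scenarios` reports per-category absolute differences and the
total variation distance between count distributions.

## Problem sizes used in checks

The packaged checks run at deliberately small, fully stated scales: the
brute-force optimality check enumerates all 4⁴ = 256 allocations on a
4-unit instance; parameter recovery uses 20 units and 1000 generations;
selection and mutation laws use 10⁵–10⁶ draws; the end-to-end
reproducibility check runs the 130-unit pipeline at 200 generations. The
analysis scripts run the full 130-unit, 1000-generation configuration.

## Known limitations

- The published per-county allocation is not reproducible: it depends on
  restricted registry data and an unpublished 27-code clinical filter; only
  the printed tables (shipped as verbatim transcriptions, ND preserved as
  missing) support arithmetic cross-checks.
- The unclassified rule and the B/E–D/F split are reconstructions (above).
- No geographic distance or patient-mobility modelling; no morbidity or
  mortality based need model; categories carry no causal interpretation.
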