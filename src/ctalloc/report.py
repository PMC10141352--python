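"""Descriptive reporting and the end-to-end pipeline.

``describe_by_waiting_group`` reproduces the study's opening descriptive
table: units split into the three waiting-time strata with basic statistics
of every need predictor per stratum.  ``run_pipeline`` chains all stages —
synthesise (or load) units, generate and filter claims, evolve the
allocation, classify it against waiting times, and write every table plus a
manifest of checksums — so a fixed seed and config reproduce the outputs
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical, synth
from .ea import EAConfig, PredictorSeries, evolve
from .feasibility import classify, group_stats, quartile_bins

__all__ = ["PipelineConfig", "describe_by_waiting_group", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Everything one end-to-end run needs.

    With ``units_csv=None`` the synthetic generator supplies the unit table
    (the demo mode of the command line).  ``use_green_counts`` substitutes
    the clinically filtered green-patient counts for raw referral counts as
    the patient-need series.
    """

    out_dir: Path
    units_csv: Path | None = None
    claims_csv: Path | None = None
    appropriateness_csv: Path | None = None
    ea: EAConfig = dataclasses.field(default_factory=EAConfig)
    synth_params: synth.SynthParams = dataclasses.field(default_factory=synth.SynthParams)
    quartile_mode: str = "rank"
    similar_tolerance: int = 1
    top_k: int = 50
    use_green_counts: bool = True
    seed: int = 0


def describe_by_waiting_group(
    units: pd.DataFrame, quartile_mode: str = "rank"
) -> pd.DataFrame:
    """Per-stratum descriptive statistics of the need predictors.

    Returns one row per (stratum, variable) with n, sum, mean, sd, min and
    max for population, female percentage, over-65 and under-14 counts,
    CT-referred patients and historical scanner counts.
    """
    if len(units) < 4:
        raise ValueError("at least 4 units are required")
    quart = quartile_bins(
        units["waiting_days"], unit_codes=units["unit_code"], mode=quartile_mode
    )
    frame = units.copy()
    frame["group"] = quart.loc[frame["unit_code"]].to_numpy()
    frame["female_pct"] = frame["female_ratio"] * 100.0

    variables = [
        "population", "female_pct", "over65", "under14",
        "referred_patients", "historical_scanners", "waiting_days",
    ]
    rows = []
    for group in ("Q1", "Q2", "Q3"):
        sub = frame[frame["group"] == group]
        for var in variables:
            s = sub[var]
            rows.append({
                "group": group,
                "n_units": len(sub),
                "variable": var,
                "sum": float(s.sum()),
                "mean": float(s.mean()) if len(s) else np.nan,
                "sd": float(s.std(ddof=1)) if len(s) > 1 else 0.0,
                "min": float(s.min()) if len(s) else np.nan,
                "max": float(s.max()) if len(s) else np.nan,
            })
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in order and return the output manifest.

    Writes units, green patient counts, the best allocation, the fitness
    history, the feasibility assignments, the per-category statistics and a
    waiting-group summary to ``cfg.out_dir``, plus ``manifest.json``
    recording the seed, a config hash and the SHA-256 checksum of every
    file.  Identical config + seed reproduce identical checksums.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- units: load or synthesise -------------------------------------
    if cfg.units_csv is not None:
        units = synth.read_units_csv(cfg.units_csv)
    else:
        params = dataclasses.replace(cfg.synth_params, seed=cfg.seed)
        units = synth.units_to_frame(synth.generate_units(params))
    units_path = out / "units.csv"
    units.to_csv(units_path, index=False)

    # --- claims + clinical filter --------------------------------------
    if cfg.claims_csv is not None:
        claims = pd.read_csv(cfg.claims_csv, dtype={"unit_code": str})
    else:
        claims = synth.generate_claims(units, seed=cfg.seed + 1)
    clinical.validate_claims(claims)
    amap = (
        clinical.load_appropriateness(cfg.appropriateness_csv)
        if cfg.appropriateness_csv is not None
        else clinical.default_appropriateness()
    )
    ranked = clinical.rank_icd_codes(claims)
    core, core_share = clinical.select_core_set(ranked, k=cfg.top_k)
    core = [c for c in core if c in amap]
    green = clinical.count_green_patients(claims, core, amap)
    green_path = out / "green_counts.csv"
    green.reset_index().to_csv(green_path, index=False)

    # --- evolve ---------------------------------------------------------
    series = PredictorSeries.from_units(units, age_as_counts=cfg.ea.age_as_counts)
    if cfg.use_green_counts:
        patients = green.reindex(units["unit_code"]).fillna(0).to_numpy(dtype=float)
        series = dataclasses.replace(series, v_patients=patients)
    ea_cfg = cfg.ea.replace(seed=cfg.seed)
    result = evolve(series, ea_cfg)

    alloc = pd.DataFrame({
        "unit_code": units["unit_code"],
        "ea_scanners": result.best.genes,
        "historical_scanners": units["historical_scanners"],
    })
    alloc_path = out / "allocation.csv"
    alloc.to_csv(alloc_path, index=False)
    history = pd.DataFrame({
        "generation": np.arange(len(result.history)),
        "best_fitness": result.history,
    })
    history_path = out / "fitness_history.csv"
    history.to_csv(history_path, index=False)

    # --- feasibility -----------------------------------------------------
    quart = quartile_bins(
        units["waiting_days"], unit_codes=units["unit_code"], mode=cfg.quartile_mode
    )
    assignments = classify(
        alloc["ea_scanners"].to_numpy(),
        alloc["historical_scanners"].to_numpy(dtype=float),
        quart,
        similar_tolerance=cfg.similar_tolerance,
        unit_codes=units["unit_code"].to_numpy(),
    )
    assign_path = out / "assignments.csv"
    assignments.to_csv(assign_path, index=False)
    stats = group_stats(assignments, units, alloc["ea_scanners"].to_numpy())
    stats_path = out / "group_stats.csv"
    stats.to_csv(stats_path, index=False)

    # --- descriptive report ---------------------------------------------
    waiting = describe_by_waiting_group(units, quartile_mode=cfg.quartile_mode)
    waiting_path = out / "waiting_group_summary.csv"
    waiting.to_csv(waiting_path, index=False)

    files = [units_path, green_path, alloc_path, history_path,
             assign_path, stats_path, waiting_path]
    manifest = {
        "seed": cfg.seed,
        "config_hash": ea_cfg.config_hash(),
        "quartile_mode": cfg.quartile_mode,
        "similar_tolerance": cfg.similar_tolerance,
        "core_set_share": round(core_share, 6),
        "best_fitness": result.best_fitness.total,
        "files": {p.name: _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline finished: %d output files in %s", len(files) + 1, out)
    return manifest
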