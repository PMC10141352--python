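"""Clinical need predictors from claim-level ICD-10 records.

The clinical demand signal is built in three steps: rank ICD-10 codes by CT
procedure frequency, keep the TOP-K core set, and count — per geographic
unit — the distinct patients whose claims carry a core-set code rated
"green" ("usually appropriate" for CT) in a user-supplied appropriateness
map.  Yellow ("may be appropriate") and red ("usually not appropriate")
codes contribute nothing downstream; their shares can still be reported.

The appropriateness map shipped with the package
(``default_appropriateness_synthetic.csv``) is an illustrative synthetic
stand-in, not clinical guidance: the guideline-derived map behind the
original analysis is not publicly available.
"""

from __future__ import annotations

import re
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "ICD_PATTERN",
    "validate_claims",
    "load_appropriateness",
    "default_appropriateness",
    "rank_icd_codes",
    "select_core_set",
    "count_green_patients",
    "category_shares",
]

ICD_PATTERN = re.compile(r"^[A-Z]\d{2}(\.\d)?$")
CATEGORIES = ("green", "yellow", "red")

CLAIM_COLUMNS = ["unit_code", "icd10", "patient_id", "year"]


def validate_claims(claims: pd.DataFrame) -> pd.DataFrame:
    """Check claim-table shape and ICD-10 code syntax (letter + 2 digits, optional .d)."""
    missing = [c for c in CLAIM_COLUMNS if c not in claims.columns]
    if missing:
        raise ValueError(f"claims table is missing columns: {missing}")
    bad = claims.loc[~claims["icd10"].astype(str).str.match(ICD_PATTERN), "icd10"]
    if len(bad):
        raise ValueError(f"malformed ICD-10 codes: {sorted(bad.unique())[:5]}")
    return claims


def load_appropriateness(path) -> dict[str, str]:
    """Read an ICD-10 → {green, yellow, red} map from a two-column CSV."""
    frame = pd.read_csv(path)
    if not {"icd10", "category"}.issubset(frame.columns):
        raise ValueError("appropriateness CSV needs columns icd10, category")
    bad = set(frame["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown appropriateness categories: {sorted(bad)}")
    if frame["icd10"].duplicated().any():
        dups = frame.loc[frame["icd10"].duplicated(), "icd10"].tolist()
        raise ValueError(f"codes mapped more than once: {dups}")
    return dict(zip(frame["icd10"], frame["category"]))


def default_appropriateness() -> dict[str, str]:
    """The packaged illustrative map (synthetic; ~30 codes; not clinical guidance)."""
    ref = resources.files("ctalloc.data").joinpath("default_appropriateness_synthetic.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return load_appropriateness(fh)


def rank_icd_codes(claims: pd.DataFrame) -> pd.DataFrame:
    """Rank ICD-10 codes from most to least frequent.

    Returns a frame with columns icd10, count, cumulative_share, ordered by
    descending count with frequency ties broken lexicographically by code.
    The final cumulative share is 1 up to floating-point rounding.
    """
    if len(claims) == 0:
        raise ValueError("claims table is empty")
    counts = (
        claims.groupby("icd10").size().rename("count").reset_index()
        .sort_values(["count", "icd10"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    counts["cumulative_share"] = counts["count"].cumsum() / counts["count"].sum()
    return counts


def select_core_set(ranked: pd.DataFrame, k: int = 50) -> tuple[list[str], float]:
    """Keep the first min(k, len) codes of the ranking.

    Returns the code list and the cumulative share of all claims it covers.
    Because the ranking is sorted by count, no other k-code subset covers a
    larger share.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    head = ranked.head(k)
    share = float(head["count"].sum() / ranked["count"].sum())
    return head["icd10"].tolist(), share


def count_green_patients(
    claims: pd.DataFrame,
    core_set: Sequence[str],
    amap: Mapping[str, str],
    distinct_patients: bool = True,
) -> pd.Series:
    """Per-unit count of patients with a green core-set indication.

    Counts distinct patient ids per unit over claims whose code is in the
    core set AND rated green (set ``distinct_patients=False`` to count
    procedures instead).  Units present in the claims but with no green
    claims appear with count 0.  Every core-set code must be present in the
    map; a missing code is a configuration error.
    """
    missing = [c for c in core_set if c not in amap]
    if missing:
        raise KeyError(f"core-set codes missing from appropriateness map: {missing}")
    green = {c for c in core_set if amap[c] == "green"}
    sub = claims[claims["icd10"].isin(green)]
    if distinct_patients:
        counts = sub.groupby("unit_code")["patient_id"].nunique()
    else:
        counts = sub.groupby("unit_code").size()
    all_units = pd.Index(claims["unit_code"].unique(), name="unit_code").sort_values()
    return counts.reindex(all_units, fill_value=0).rename("green_patients").astype(int)


def category_shares(
    claims: pd.DataFrame, core_set: Sequence[str], amap: Mapping[str, str]
) -> pd.Series:
    """Share of core-set claims per appropriateness category (reporting only)."""
    sub = claims[claims["icd10"].isin(set(core_set))]
    cats = sub["icd10"].map(amap)
    shares = cats.value_counts(normalize=True)
    return shares.reindex(CATEGORIES, fill_value=0.0).rename("share")
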