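"""Case-level processing: deduplication, drug-name standardization, ATC
classification, age harmonization and target-event case selection.

Spontaneous reports arrive as versioned documents: several PRIMARYIDs can
describe the same clinical case (shared CASEID). Following the FDA
deduplication guidance, only the most recent version of each case is
analyzed: group by CASEID, keep the latest FDA_DT, and break FDA_DT ties by
the higher PRIMARYID. Undated versions lose to any dated version.

Drug names are reported verbatim ("LITHIUM CARBONATE", "Precedex") and are
standardized to active-ingredient names through an exact dictionary lookup
after light normalization; only primary-suspect (PS) drugs enter the
disproportionality screen.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .faers_io import CaseData, ReportCase

__all__ = [
    "UNMAPPED",
    "UNCLASSIFIED",
    "AGE_UNIT_FACTORS",
    "TargetCase",
    "TargetCases",
    "normalize_token",
    "normalize_drug",
    "assign_atc",
    "age_to_years",
    "deduplicate",
    "ps_ingredients",
    "select_target_cases",
]

UNMAPPED = "UNMAPPED"
UNCLASSIFIED = "UNCLASSIFIED"

_WS = re.compile(r"\s+")
_EDGE_PUNCT = re.compile(r"^[^0-9a-z]+|[^0-9a-z]+$")

#: Multiplicative factor from one unit to years.
AGE_UNIT_FACTORS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

AGE_PLAUSIBLE_MAX_YEARS = 120.0


def normalize_token(verbatim: str) -> str:
    """Case-fold, collapse internal whitespace, strip surrounding punctuation."""
    s = _WS.sub(" ", str(verbatim).casefold()).strip()
    return _EDGE_PUNCT.sub("", s)


def normalize_drug(verbatim: str, synonym_map: dict[str, str],
                   counters: Counter | None = None) -> str:
    """Standardize one verbatim drug name by exact lookup after normalization.

    Misses return :data:`UNMAPPED` and increment ``counters["unmapped"]``.
    No fuzzy matching: the synonym map is the single source of truth.
    """
    hit = synonym_map.get(normalize_token(verbatim))
    if hit is None:
        if counters is not None:
            counters["unmapped"] += 1
        return UNMAPPED
    return hit


def assign_atc(ingredient: str, atc_map: dict[str, tuple[str, str]],
               counters: Counter | None = None) -> str:
    """Map a standardized ingredient to its ATC anatomical main group code."""
    hit = atc_map.get(ingredient)
    if hit is None:
        if counters is not None:
            counters["unclassified"] += 1
        return UNCLASSIFIED
    return hit[0]


def age_to_years(age, unit_code: str | None,
                 counters: Counter | None = None) -> float | None:
    """Convert a reported age to years; implausible or unconvertible -> None.

    An absent unit with a present age is read as years (the dominant FAERS
    convention). Results outside [0, 120] years are treated as data errors.
    """
    if age is None:
        return None
    try:
        value = float(age)
    except (TypeError, ValueError):
        return None
    unit = (unit_code or "").strip().upper()
    if unit == "":
        factor = 1.0
    elif unit in AGE_UNIT_FACTORS:
        factor = AGE_UNIT_FACTORS[unit]
    else:
        if counters is not None:
            counters["unknown_age_unit"] += 1
        return None
    years = value * factor
    if years < 0 or years > AGE_PLAUSIBLE_MAX_YEARS:
        if counters is not None:
            counters["implausible_age"] += 1
        return None
    return years


# ---------------------------------------------------------------------------
# Deduplication


def _fda_dt_key(s: pd.Series) -> pd.Series:
    """Sortable FDA_DT: 8-digit dates as ints, anything else loses (-1)."""
    v = pd.to_numeric(s.where(s.str.fullmatch(r"\d{8}", na=False)), errors="coerce")
    return v.fillna(-1).astype(np.int64)


def _primaryid_key(s: pd.Series) -> pd.Series:
    """Numeric PRIMARYID ordering when every id parses as an integer,
    lexicographic otherwise."""
    v = pd.to_numeric(s, errors="coerce")
    if v.notna().all():
        return v.astype(np.int64)
    return s.astype(str)


def deduplicate(cases: CaseData) -> tuple[CaseData, dict]:
    """Keep one report version per CASEID.

    Latest FDA_DT wins; FDA_DT ties go to the higher PRIMARYID; versions
    without a parseable FDA_DT lose to any dated version and tie-break by
    PRIMARYID among themselves. Idempotent, and never increases case count.
    """
    demo = cases.demo
    if demo.empty:
        return cases.subset([]), {"n_versions": 0, "n_cases": 0, "n_removed": 0}
    keys = pd.DataFrame({
        "caseid": demo["caseid"].values,
        "fda_key": _fda_dt_key(demo["fda_dt"]).values,
        "pid_key": _primaryid_key(demo["primaryid"]).values,
        "primaryid": demo["primaryid"].values,
    })
    keys = keys.sort_values(["caseid", "fda_key", "pid_key"], kind="mergesort")
    winners = keys.drop_duplicates("caseid", keep="last")["primaryid"]
    out = cases.subset(winners)
    log = {
        "n_versions": int(len(demo)),
        "n_cases": int(len(winners)),
        "n_removed": int(len(demo) - len(winners)),
    }
    return out, log


# ---------------------------------------------------------------------------
# Target-event selection


def ps_ingredients(cases: CaseData, synonym_map: dict[str, str]
                   ) -> tuple[pd.DataFrame, Counter]:
    """Unique (primaryid, caseid, ingredient) pairs for primary-suspect drugs.

    Verbatim names are standardized through the synonym map; unmapped
    verbatims are counted and excluded (they cannot be attributed to an
    ingredient). A drug counts once per case however many records repeat it.
    """
    counters: Counter = Counter()
    ps = cases.drug[cases.drug["role_cod"] == "PS"]
    if ps.empty:
        return pd.DataFrame(columns=["primaryid", "caseid", "ingredient"]), counters
    norm = (
        ps["drugname"].astype(str).str.casefold()
        .str.replace(_WS, " ", regex=True).str.strip()
        .str.replace(_EDGE_PUNCT, "", regex=True)
    )
    ing = norm.map(synonym_map)
    counters["unmapped"] = int(ing.isna().sum())
    pairs = pd.DataFrame({
        "primaryid": ps["primaryid"].values,
        "caseid": ps["caseid"].values,
        "ingredient": ing.values,
    }).dropna(subset=["ingredient"]).drop_duplicates(["primaryid", "ingredient"])
    return pairs.reset_index(drop=True), counters


def target_flags(cases: CaseData, target_pt_code: int) -> pd.Series:
    """Boolean per DEMO primaryid: does the case report the target PT?"""
    codes = pd.to_numeric(cases.reac["pt_cod"], errors="coerce")
    hit_pids = set(cases.reac.loc[codes == target_pt_code, "primaryid"])
    return cases.demo["primaryid"].isin(hit_pids)


@dataclass
class TargetCase:
    """One deduplicated case reporting the target event."""

    case: ReportCase
    ps_ingredients: frozenset[str]
    target_pt_present: bool = True


@dataclass
class TargetCases:
    """Target-event cases with their standardized PS ingredients."""

    data: CaseData                       # subset of the deduplicated cases
    ingredients: pd.DataFrame            # primaryid, caseid, ingredient
    counters: Counter = field(default_factory=Counter)

    @property
    def n_cases(self) -> int:
        return self.data.n_cases

    def to_records(self) -> list[TargetCase]:
        by_pid: dict[str, set[str]] = {}
        for row in self.ingredients.itertuples(index=False):
            by_pid.setdefault(row.primaryid, set()).add(row.ingredient)
        return [
            TargetCase(case=c, ps_ingredients=frozenset(by_pid.get(c.primaryid, ())))
            for c in self.data.iter_cases()
        ]


def select_target_cases(cases: CaseData, target_pt_code: int,
                        synonym_map: dict[str, str]) -> TargetCases:
    """Every deduplicated case whose reaction set contains the target PT.

    Cases whose only suspect drugs are SS/C/I (or unmapped) contribute an
    empty ingredient set but still count as target cases.
    """
    flags = target_flags(cases, target_pt_code)
    pids = cases.demo.loc[flags.values, "primaryid"]
    sub = cases.subset(pids)
    pairs, counters = ps_ingredients(sub, synonym_map)
    return TargetCases(data=sub, ingredients=pairs, counters=counters)
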