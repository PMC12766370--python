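"""Time-to-onset (TTO) analysis.

TTO is the interval in whole days from the suspect drug's initiation date
(START_DT) to the adverse-event occurrence date (EVENT_DT). Spontaneous
reports carry dates of wildly varying quality, so a strict policy applies:
only complete 8-digit YYYYMMDD values encoding a real calendar date are
used; partial (YYYYMM / YYYY), empty, non-numeric and impossible dates are
excluded, each with a reason code so the exclusion tally is auditable.

When a case has several start dates for one ingredient, the earliest valid
one is used (first exposure). THER records (joined to the drug record via
dsg_drug_seq) are preferred; the drug record's own start date is the
fallback. Event-before-start intervals are excluded as data errors, with
their own reason code so a sensitivity analysis can re-admit them.

Per-drug summaries are the median and quartiles with linear interpolation
between order statistics (quantile position 1 + p*(n-1), numpy's default).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .cases import TargetCase

__all__ = [
    "OnsetRecord",
    "OnsetRejection",
    "OnsetSummary",
    "parse_strict_date",
    "compute_tto",
    "collect_onsets",
    "summarize_tto",
    "onset_frame",
]

# rejection reason codes
R_MISSING = "missing"        # empty field
R_PARTIAL = "partial"        # 4- or 6-digit truncated date
R_MALFORMED = "malformed"    # non-numeric / wrong length
R_INVALID = "invalid"        # 8 digits but not a calendar date
R_NEGATIVE = "negative"      # event precedes drug start
R_NO_START = "no_start"      # no start-date field at all for the ingredient


def parse_strict_date(field: str | None) -> tuple[date | None, str | None]:
    """Parse an 8-digit YYYYMMDD field; return ``(date, None)`` or
    ``(None, reason)``. Rejection is a value, never an exception."""
    s = "" if field is None else str(field).strip()
    if s == "":
        return None, R_MISSING
    if not s.isdigit():
        return None, R_MALFORMED
    if len(s) in (4, 6):
        return None, R_PARTIAL
    if len(s) != 8:
        return None, R_MALFORMED
    try:
        return date(int(s[:4]), int(s[4:6]), int(s[6:8])), None
    except ValueError:
        return None, R_INVALID


@dataclass(frozen=True)
class OnsetRecord:
    caseid: str
    ingredient: str
    tto_days: int


@dataclass(frozen=True)
class OnsetRejection:
    caseid: str
    ingredient: str
    reason: str


def _candidate_starts(tc: TargetCase, ingredient: str, synonym_map: dict[str, str]):
    """Raw start-date fields for one ingredient: (therapy fields, drug fields)."""
    from .cases import normalize_drug  # local import to avoid cycle at load

    seqs = {
        d.drug_seq for d in tc.case.drugs
        if d.role_code == "PS" and normalize_drug(d.drugname_verbatim, synonym_map) == ingredient
    }
    ther = [t.start_dt for t in tc.case.therapies if t.dsg_drug_seq in seqs]
    drug = [d.start_dt for d in tc.case.drugs if d.drug_seq in seqs]
    return ther, drug


def compute_tto(tc: TargetCase, ingredient: str, synonym_map: dict[str, str]
                ) -> OnsetRecord | OnsetRejection:
    """TTO for one (case, ingredient) pair, or a reason-coded rejection.

    EVENT_DT comes from the report; START_DT is the earliest strictly valid
    date among the ingredient's THER records, falling back to the drug
    records' start dates when no THER date parses.
    """
    caseid = tc.case.caseid
    event, ev_reason = parse_strict_date(tc.case.event_dt)
    if event is None:
        return OnsetRejection(caseid, ingredient, f"event_{ev_reason}")

    ther_fields, drug_fields = _candidate_starts(tc, ingredient, synonym_map)
    if not ther_fields and not drug_fields:
        return OnsetRejection(caseid, ingredient, R_NO_START)

    start = None
    first_reason = None
    for fields in (ther_fields, drug_fields):
        parsed = []
        for f in fields:
            d, reason = parse_strict_date(f)
            if d is not None:
                parsed.append(d)
            elif first_reason is None:
                first_reason = reason
        if parsed:
            start = min(parsed)
            break  # THER preferred; fall back only if none parsed
    if start is None:
        return OnsetRejection(caseid, ingredient, f"start_{first_reason or R_MISSING}")

    tto = (event - start).days
    if tto < 0:
        return OnsetRejection(caseid, ingredient, R_NEGATIVE)
    return OnsetRecord(caseid=caseid, ingredient=ingredient, tto_days=tto)


def collect_onsets(target_cases: list[TargetCase], synonym_map: dict[str, str],
                   ingredients: set[str] | None = None
                   ) -> tuple[list[OnsetRecord], Counter]:
    """TTO for every (target case, PS ingredient) pair, with exclusion tally.

    ``ingredients`` restricts the computation (e.g. to signal-positive drugs).
    included + excluded == candidate pair count.
    """
    records: list[OnsetRecord] = []
    exclusions: Counter = Counter()
    for tc in target_cases:
        for ing in sorted(tc.ps_ingredients):
            if ingredients is not None and ing not in ingredients:
                continue
            res = compute_tto(tc, ing, synonym_map)
            if isinstance(res, OnsetRecord):
                records.append(res)
            else:
                exclusions[res.reason] += 1
    return records, exclusions


@dataclass(frozen=True)
class OnsetSummary:
    ingredient: str
    n_available: int
    median_days: float
    q1_days: float
    q3_days: float


def summarize_tto(ingredient: str, values) -> OnsetSummary:
    """Median and IQR by linear interpolation between order statistics."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("summarize_tto requires at least one observation")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return OnsetSummary(
        ingredient=ingredient,
        n_available=int(arr.size),
        median_days=float(med),
        q1_days=float(q1),
        q3_days=float(q3),
    )


def onset_frame(records: list[OnsetRecord],
                atc_map: dict[str, tuple[str, str]] | None = None,
                ingredients: set[str] | None = None) -> pd.DataFrame:
    """Per-drug TTO summary table; drugs with no usable record are omitted.

    ``ingredients`` restricts rows (the published convention summarizes only
    signal-positive drugs).
    """
    by_ing: dict[str, list[int]] = {}
    for r in records:
        if ingredients is not None and r.ingredient not in ingredients:
            continue
        by_ing.setdefault(r.ingredient, []).append(r.tto_days)
    rows = []
    for ing in sorted(by_ing):
        s = summarize_tto(ing, by_ing[ing])
        label = atc_map.get(ing, ("", ""))[1] if atc_map else ""
        rows.append({
            "ingredient": ing,
            "atc_label": label,
            "n_available": s.n_available,
            "median_days": s.median_days,
            "q1_days": s.q1_days,
            "q3_days": s.q3_days,
        })
    cols = ["ingredient", "atc_label", "n_available", "median_days", "q1_days", "q3_days"]
    return pd.DataFrame(rows, columns=cols)
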