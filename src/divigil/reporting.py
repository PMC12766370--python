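"""Descriptive reporting and end-to-end pipeline orchestration.

Produces the descriptive outputs of a disproportionality study — target-case
demographics (sex, age bands, weight bands, outcomes, reporter occupations,
top countries, annual counts), top-drug rankings by case count and by ROR,
ATC class composition of positive signals — and drives the whole analysis
from quarterly tables to a written artifact bundle.

All percentages are printed to one decimal with half-up rounding. Figures
are emitted as tidy plot-ready CSVs rather than rendered images.
"""

from __future__ import annotations

import json
import os
import shutil
import tempfile
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cases as _cases
from . import disproportionality as _dispro
from . import faers_io as _io
from . import onset as _onset
from .resources import TARGET_PT_CODE, load_atc_map, load_synonym_map

__all__ = [
    "DemographicsTable",
    "RunConfig",
    "PipelineResult",
    "round_percent",
    "demographics",
    "rank_drugs",
    "class_composition",
    "run_pipeline",
]

AGE_BANDS = ((0.0, 18.0, "<18"), (18.0, 65.0, "18-64"), (65.0, float("inf"), ">=65"))
WEIGHT_BANDS = ((0.0, 80.0, "<80"), (80.0, float("inf"), ">=80"))
OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-threatening",
    "HO": "Hospitalization - initial or prolonged",
    "DS": "Disability",
    "CA": "Congenital anomaly",
    "RI": "Required intervention",
    "OT": "Other serious",
}


def round_percent(count: int, total: int) -> float:
    """count/total*100 to one decimal, half-up (reporting convention)."""
    if total == 0:
        return 0.0
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _median_iqr(values: list[float]) -> tuple[float, float, float] | None:
    if not values:
        return None
    q1, med, q3 = np.percentile(np.asarray(values, dtype=float), [25, 50, 75])
    return float(med), float(q1), float(q3)


@dataclass
class DemographicsTable:
    """Target-case descriptives, one categorical block per attribute.

    Within each block except outcomes, counts sum to the case total; a case
    contributes once per distinct outcome code, so the outcome block may sum
    past the total. Percentages use the case total as denominator.
    """

    total: int
    sex: dict[str, int]
    age_bands: dict[str, int]
    age_median_iqr: tuple[float, float, float] | None
    weight_bands: dict[str, int]
    weight_median_iqr: tuple[float, float, float] | None
    outcomes: dict[str, int]
    reporters: dict[str, int]
    top_countries: list[tuple[str, int]]
    yearly_counts: dict[int, int]
    counters: Counter = field(default_factory=Counter)

    def to_frame(self) -> pd.DataFrame:
        rows = []

        def block(name, items):
            for category, count in items:
                rows.append({
                    "block": name, "category": category, "count": count,
                    "percent": round_percent(count, self.total),
                })

        block("sex", self.sex.items())
        block("age_band", self.age_bands.items())
        block("weight_band", self.weight_bands.items())
        block("outcome", [(OUTCOME_LABELS.get(k, k), v) for k, v in self.outcomes.items()])
        block("reporter", self.reporters.items())
        block("country_top5", self.top_countries)
        block("year", sorted(self.yearly_counts.items()))
        return pd.DataFrame(rows, columns=["block", "category", "count", "percent"])


def demographics(target_cases: list[_cases.TargetCase]) -> DemographicsTable:
    """Describe the target cases the way pharmacovigilance reports do.

    Ages are harmonized to years (with unit conversion and a 0-120 y
    plausibility window); unconvertible values land in the "unknown" band.
    Reporting year is taken from the FDA receipt date.
    """
    total = len(target_cases)
    counters: Counter = Counter()
    sex = Counter()
    age_bands = Counter({label: 0 for _, _, label in AGE_BANDS} | {"unknown": 0})
    ages: list[float] = []
    weight_bands = Counter({label: 0 for _, _, label in WEIGHT_BANDS} | {"unknown": 0})
    weights: list[float] = []
    outcomes = Counter()
    reporters = Counter()
    countries = Counter()
    yearly = Counter()

    for tc in target_cases:
        case = tc.case
        sex[case.sex if case.sex in ("F", "M") else "unknown"] += 1

        years = _cases.age_to_years(case.age if case.age != "" else None,
                                    case.age_unit, counters)
        if years is None:
            age_bands["unknown"] += 1
        else:
            ages.append(years)
            for lo, hi, label in AGE_BANDS:
                if lo <= years < hi:
                    age_bands[label] += 1
                    break

        try:
            w = float(case.weight)
        except (TypeError, ValueError):
            w = None
        if w is None or w <= 0:
            weight_bands["unknown"] += 1
        else:
            weights.append(w)
            for lo, hi, label in WEIGHT_BANDS:
                if lo <= w < hi:
                    weight_bands[label] += 1
                    break

        codes = {o.outcome_code for o in case.outcomes if o.outcome_code in OUTCOME_LABELS}
        if codes:
            for code in sorted(codes):
                outcomes[code] += 1
        else:
            outcomes["unknown"] += 1

        occ = case.reporter_occupation
        reporters[occ if occ else "unknown"] += 1
        countries[case.country if case.country else "unknown"] += 1

        fda, _ = _onset.parse_strict_date(case.fda_dt)
        if fda is not None:
            yearly[fda.year] += 1

    top5 = sorted(((c, n) for c, n in countries.items() if c != "unknown"),
                  key=lambda kv: (-kv[1], kv[0]))[:5]
    return DemographicsTable(
        total=total,
        sex={"F": sex["F"], "M": sex["M"], "unknown": sex["unknown"]},
        age_bands=dict(age_bands),
        age_median_iqr=_median_iqr(ages),
        weight_bands=dict(weight_bands),
        weight_median_iqr=_median_iqr(weights),
        outcomes=dict(outcomes),
        reporters=dict(reporters),
        top_countries=top5,
        yearly_counts=dict(yearly),
        counters=counters,
    )


def rank_drugs(signals: list[_dispro.SignalRecord], k: int = 50,
               by: str = "cases") -> pd.DataFrame:
    """Top-k positive drugs by case count (``by="cases"``) or by ROR
    (``by="ror"``); ties break on ingredient name ascending."""
    pos = [s for s in signals if s.positive]
    if by == "cases":
        key = lambda s: (-s.a, s.ingredient)
    elif by == "ror":
        key = lambda s: (-s.ror.ror, s.ingredient)
    else:
        raise ValueError(f"unknown ranking key {by!r}")
    ranked = sorted(pos, key=key)[:k]
    return pd.DataFrame([
        {
            "rank": i + 1, "ingredient": s.ingredient, "atc_class": s.atc_class,
            "n_cases": s.a, "ror": s.ror.ror, "ci_low": s.ror.ci_low,
            "ci_high": s.ror.ci_high, "ic025": s.ic.ic025, "strength": s.strength,
        }
        for i, s in enumerate(ranked)
    ], columns=["rank", "ingredient", "atc_class", "n_cases", "ror",
                "ci_low", "ci_high", "ic025", "strength"])


def class_composition(signals: list[_dispro.SignalRecord],
                      atc_map: dict[str, tuple[str, str]] | None = None) -> pd.DataFrame:
    """ATC level-1 composition of the positive drugs, with one-decimal shares."""
    if atc_map is None:
        atc_map = load_atc_map()
    labels = {code: label for code, label in atc_map.values()}
    pos = [s for s in signals if s.positive]
    counts = Counter(s.atc_class for s in pos)
    rows = [
        {
            "atc_class": code,
            "label": labels.get(code, ""),
            "n_drugs": n,
            "share_percent": round_percent(n, len(pos)),
        }
        for code, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["atc_class", "label", "n_drugs", "share_percent"])


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class RunConfig:
    """Inputs and knobs for one full analysis run."""

    table_paths: dict[str, str]                 # demo/drug/reac/ther/outc
    out_dir: str
    synonym_path: str | None = None             # None -> bundled map
    atc_path: str | None = None
    target_pt: int = TARGET_PT_CODE
    bcpnn: _dispro.BcpnnHyperparameters = field(default_factory=_dispro.BcpnnHyperparameters)
    ic025_rule: str = "two_sd"
    top_k: int = 50
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "bcpnn" in doc:
            doc["bcpnn"] = _dispro.BcpnnHyperparameters(**doc["bcpnn"])
        return cls(**doc)


@dataclass
class PipelineResult:
    signals: pd.DataFrame
    onset: pd.DataFrame
    demographics: DemographicsTable
    class_composition: pd.DataFrame
    rank_by_cases: pd.DataFrame
    rank_by_ror: pd.DataFrame
    run_log: dict


def analyze_cases(linked: _io.CaseData, target_pt: int,
                  synonym_map: dict[str, str],
                  atc_map: dict[str, tuple[str, str]],
                  bcpnn: _dispro.BcpnnHyperparameters = _dispro.BcpnnHyperparameters(),
                  ic025_rule: str = "two_sd",
                  top_k: int = 50) -> PipelineResult:
    """The in-memory analysis: dedup -> target cases -> signals -> onset ->
    descriptives. Shared by the CLI pipeline and the test harness."""
    deduped, dedup_log = _cases.deduplicate(linked)
    target = _cases.select_target_cases(deduped, target_pt, synonym_map)
    tables, n_total = _dispro.build_tables(deduped, target_pt, synonym_map)
    signals = _dispro.evaluate_signals(tables, atc_map, bcpnn, ic025_rule)
    positive = {s.ingredient for s in signals if s.positive}

    target_records = target.to_records()
    onset_records, onset_excl = _onset.collect_onsets(
        target_records, synonym_map, ingredients=positive)
    onset_df = _onset.onset_frame(onset_records, atc_map, ingredients=positive)
    demo_table = demographics(target_records)

    strata = Counter(s.strength for s in signals if s.positive)
    run_log = {
        "n_report_versions": dedup_log["n_versions"],
        "n_cases": dedup_log["n_cases"],
        "n_duplicates_removed": dedup_log["n_removed"],
        "n_target_cases": target.n_cases,
        "unmapped_ps_drugnames": int(target.counters.get("unmapped", 0)),
        "n_drugs_screened": len(tables),
        "n_positive": len(positive),
        "strata": {k: strata.get(k, 0) for k in ("weak", "medium", "strong")},
        "onset_included": len(onset_records),
        "onset_excluded": dict(onset_excl),
        "orphans": dict(linked.orphans),
        "total_n_for_tables": n_total,
    }
    return PipelineResult(
        signals=_dispro.signal_frame(signals),
        onset=onset_df,
        demographics=demo_table,
        class_composition=class_composition(signals, atc_map),
        rank_by_cases=rank_drugs(signals, top_k, by="cases"),
        rank_by_ror=rank_drugs(signals, top_k, by="ror"),
        run_log=run_log,
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis from quarterly tables and write the artifact
    bundle (CSV tables + JSON run log) atomically to ``config.out_dir``.

    Outputs are staged in a temporary directory and moved into place only
    when every stage has succeeded, so a failed run leaves no partial bundle.
    """
    for kind, p in config.table_paths.items():
        if not Path(p).exists():
            raise FileNotFoundError(f"[read] {kind} table not found: {p}")
    try:
        synonym_map = load_synonym_map(config.synonym_path)
        atc_map = load_atc_map(config.atc_path)
    except FileNotFoundError as e:
        raise FileNotFoundError(f"[maps] {e}") from e

    bundle = _io.read_quarter(config.table_paths)
    linked = _io.link_cases(bundle)
    result = analyze_cases(linked, config.target_pt, synonym_map, atc_map,
                           config.bcpnn, config.ic025_rule, config.top_k)
    result.run_log["parse"] = {k: v.to_dict() for k, v in bundle.logs.items()}
    result.run_log["seed"] = config.seed

    out_dir = Path(config.out_dir)
    out_dir.parent.mkdir(parents=True, exist_ok=True)
    tmp = Path(tempfile.mkdtemp(prefix=".divigil-", dir=out_dir.parent))
    try:
        result.signals.to_csv(tmp / "signals.csv", index=False)
        result.onset.to_csv(tmp / "onset.csv", index=False)
        result.demographics.to_frame().to_csv(tmp / "demographics.csv", index=False)
        result.class_composition.to_csv(tmp / "class_composition.csv", index=False)
        result.rank_by_cases.to_csv(tmp / "top_drugs_by_cases.csv", index=False)
        result.rank_by_ror.to_csv(tmp / "top_drugs_by_ror.csv", index=False)
        with open(tmp / "run_log.json", "w") as fh:
            json.dump(result.run_log, fh, indent=2, sort_keys=True)
        out_dir.mkdir(parents=True, exist_ok=True)
        for f in tmp.iterdir():
            os.replace(f, out_dir / f.name)
    finally:
        shutil.rmtree(tmp, ignore_errors=True)
    return result
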