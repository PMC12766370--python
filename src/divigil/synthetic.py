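"""Synthetic FAERS-like quarters with known ground truth.

The generator emulates the structure of spontaneous-report quarters —
versioned cases, PS/SS/C/I drug roles, MedDRA-coded reactions, therapy
dates, partial and malformed dates, duplicate report versions — under a
deliberately simple generative model whose 2x2 drug-by-event expectations
are available in closed form, so every downstream stage can be tested
against analytic ground truth.

Generative model, per report:

* one suspect-drug slot is drawn from the catalog's baseline probabilities
  (the remaining mass produces an unmappable "other" product); the suspect
  record is coded PS with a configurable fraction, SS otherwise;
* given the suspect drug d, each catalog event e occurs independently with
  probability clip(q_e * rr(d, e), 0.95), where q_e is the event's baseline
  probability and rr is the planted relative reporting ratio (1 when no
  signal is planted). This tilts the drug-event joint by rr exactly, so
  expected 2x2 cells follow directly (see :func:`expected_counts`);
* extra concomitant/interacting drug records, demographics, outcomes and
  dates are decorated around that core and never perturb the 2x2.

Duplicate cases are emitted as 2-3 report versions sharing a CASEID: the
true (latest-FDA_DT) version plus earlier versions with decremented FDA_DT
and shuffled PRIMARYID suffixes, so deduplication must use the receipt
date rather than id or row order. Event and start dates are corrupted to
6-digit partial, empty or non-numeric forms at configured rates to
exercise the strict onset-date policy.

Everything is driven by one :class:`numpy.random.Generator` seeded from the
config, so identical (config, seed) pairs give byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .faers_io import QuarterBundle
from .resources import TARGET_PT_CODE, TARGET_PT_NAME, load_atc_map

__all__ = [
    "CatalogDrug",
    "CatalogEvent",
    "PlantedSignal",
    "SimulationConfig",
    "GroundTruth",
    "ExpectedTable",
    "default_drug_catalog",
    "default_event_catalog",
    "paper_scale_config",
    "generate_quarter",
    "generate_quarter_with_truth",
    "expected_counts",
]

OTHER_DRUG_VERBATIM = "UNSPECIFIED PRODUCT"
_EVENT_PROB_CAP = 0.95


@dataclass(frozen=True)
class CatalogDrug:
    drug_id: str            # standardized ingredient name
    ingredient: str
    atc_class: str
    p: float                # baseline probability of being the suspect drug


@dataclass(frozen=True)
class CatalogEvent:
    pt_code: int
    pt_name: str
    p: float                # baseline per-report occurrence probability


@dataclass(frozen=True)
class PlantedSignal:
    """A planted drug-event association.

    ``rr`` multiplies the joint drug-event probability; ``onset_median_days``
    and ``onset_sigma`` parameterize the log-normal start-to-event lag
    (median exp(mu) in days, log-scale spread sigma).
    """

    drug_id: str
    event_pt_code: int
    rr: float
    onset_median_days: float = 30.0
    onset_sigma: float = 1.0


@dataclass
class SimulationConfig:
    n_reports: int
    drug_catalog: list[CatalogDrug]
    event_catalog: list[CatalogEvent]
    planted_signals: list[PlantedSignal] = field(default_factory=list)
    duplicate_rate: float = 0.05
    partial_date_rate: float = 0.04
    missing_date_rate: float = 0.08
    malformed_date_rate: float = 0.01
    ps_fraction: float = 0.95
    concomitant_rate: float = 1.2       # Poisson mean extra SS/C/I records
    ther_rate: float = 0.7              # P(THER row for the suspect drug)
    drug_start_rate: float = 0.5        # P(DRUG.start_dt populated)
    # demographics (roughly matched to published DI-case descriptives)
    sex_weights: dict = field(default_factory=lambda: {"F": 0.443, "M": 0.466, "": 0.091})
    age_mean: float = 47.0
    age_sd: float = 22.0
    age_missing_rate: float = 0.21
    age_unit_rates: dict = field(default_factory=lambda: {"YR": 0.90, "MON": 0.05, "DY": 0.05})
    weight_mean: float = 74.5
    weight_sd: float = 16.0
    weight_missing_rate: float = 0.76
    country_weights: dict = field(default_factory=lambda: {
        "US": 0.36, "JP": 0.13, "FR": 0.09, "CA": 0.07, "GB": 0.06,
        "DE": 0.05, "IT": 0.04, "": 0.20,
    })
    occupation_weights: dict = field(default_factory=lambda: {
        "MD": 0.37, "PH": 0.08, "OT": 0.36, "CN": 0.13, "LW": 0.004, "": 0.056,
    })
    outcome_count_weights: tuple = (0.35, 0.50, 0.15)   # P(0, 1, 2 outcome rows)
    outcome_code_weights: dict = field(default_factory=lambda: {
        "OT": 0.44, "HO": 0.35, "DE": 0.12, "LT": 0.06, "DS": 0.01,
        "RI": 0.01, "CA": 0.01,
    })
    # dates
    quarter_start: str = "2023-01-01"
    quarter_days: int = 90
    report_delay_median: float = 30.0   # days from event to FDA receipt
    report_delay_sigma: float = 1.2
    default_onset_median: float = 30.0  # start-to-event lag without a signal law
    default_onset_sigma: float = 1.5
    seed: int = 0

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if not isinstance(self.n_reports, (int, np.integer)) or self.n_reports < 0:
            raise ValueError("n_reports must be a non-negative integer")
        if not self.drug_catalog:
            raise ValueError("drug_catalog must not be empty")
        if not self.event_catalog:
            raise ValueError("event_catalog must not be empty")
        p_sum = 0.0
        for dspec in self.drug_catalog:
            if not 0.0 <= dspec.p <= 1.0:
                raise ValueError(f"drug_catalog: baseline probability of {dspec.drug_id!r} not in [0, 1]")
            p_sum += dspec.p
        if p_sum > 1.0 + 1e-12:
            raise ValueError("drug_catalog: baseline probabilities sum above 1 per report slot")
        for espec in self.event_catalog:
            if not 0.0 <= espec.p <= 1.0:
                raise ValueError(f"event_catalog: baseline probability of PT {espec.pt_code} not in [0, 1]")
        drug_ids = {dspec.drug_id for dspec in self.drug_catalog}
        pt_codes = {espec.pt_code for espec in self.event_catalog}
        if len(drug_ids) != len(self.drug_catalog):
            raise ValueError("drug_catalog: duplicate drug_id")
        if len(pt_codes) != len(self.event_catalog):
            raise ValueError("event_catalog: duplicate pt_code")
        for sig in self.planted_signals:
            if sig.drug_id not in drug_ids:
                raise ValueError(f"planted_signals: unknown drug_id {sig.drug_id!r}")
            if sig.event_pt_code not in pt_codes:
                raise ValueError(f"planted_signals: unknown event_pt_code {sig.event_pt_code}")
            if not (np.isfinite(sig.rr) and sig.rr >= 0):
                raise ValueError(f"planted_signals: rr for {sig.drug_id!r} must be finite and >= 0")
            if sig.onset_median_days < 0:
                raise ValueError(f"planted_signals: onset_median_days for {sig.drug_id!r} must be >= 0")
        for name in ("duplicate_rate", "partial_date_rate", "missing_date_rate",
                     "malformed_date_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.partial_date_rate + self.missing_date_rate + self.malformed_date_rate >= 1.0:
            raise ValueError("date corruption rates must sum below 1")
        for name in ("ps_fraction", "ther_rate", "drug_start_rate",
                     "age_missing_rate", "weight_missing_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    # -- config file round-trip --------------------------------------------

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["outcome_count_weights"] = list(self.outcome_count_weights)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["drug_catalog"] = [CatalogDrug(**d) for d in doc.get("drug_catalog", [])]
        doc["event_catalog"] = [CatalogEvent(**e) for e in doc.get("event_catalog", [])]
        doc["planted_signals"] = [PlantedSignal(**s) for s in doc.get("planted_signals", [])]
        if "outcome_count_weights" in doc:
            doc["outcome_count_weights"] = tuple(doc["outcome_count_weights"])
        cfg = cls(**doc)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# Default study-scale configuration


def default_drug_catalog(n_drugs: int = 50, total_p: float = 0.9) -> list[CatalogDrug]:
    """A catalog of real ingredient names (from the bundled ATC map) with a
    gently decaying baseline suspect probability summing to ``total_p``."""
    atc = load_atc_map()
    names = sorted(atc)[:n_drugs]
    if len(names) < n_drugs:
        raise ValueError(f"bundled ATC map has only {len(names)} ingredients")
    w = 1.0 / (np.arange(n_drugs) + 5.0)
    p = w / w.sum() * total_p
    return [
        CatalogDrug(drug_id=name, ingredient=name, atc_class=atc[name][0], p=float(pi))
        for name, pi in zip(names, p)
    ]


#: Paper-scale target-event marginal: 2,189 DI cases among 18,627,667 reports.
TARGET_BASELINE_P = 2189 / 18627667

def default_event_catalog(target_p: float = TARGET_BASELINE_P) -> list[CatalogEvent]:
    """The target PT (diabetes insipidus) at its database-wide marginal plus
    a background of common adverse-event PTs."""
    background = [
        (10017955, "Drug ineffective", 0.15),
        (10028813, "Nausea", 0.12),
        (10019211, "Headache", 0.10),
        (10047700, "Vomiting", 0.08),
        (10012735, "Diarrhoea", 0.07),
        (10013573, "Dizziness", 0.06),
        (10016256, "Fatigue", 0.06),
        (10037844, "Rash", 0.05),
        (10037660, "Pyrexia", 0.05),
        (10021036, "Hyponatraemia", 0.01),
        (10036142, "Polyuria", 0.008),
    ]
    events = [CatalogEvent(pt_code=TARGET_PT_CODE, pt_name=TARGET_PT_NAME, p=float(target_p))]
    events += [CatalogEvent(pt_code=c, pt_name=n, p=p) for c, n, p in background]
    return events


def paper_scale_config(n_reports: int = 200_000, seed: int = 0) -> SimulationConfig:
    """Study conditions scaled to desk size: the target event at its
    database-wide marginal and a handful of planted associations whose
    relative reporting ratios and onset medians echo the published ones."""
    cfg = SimulationConfig(
        n_reports=n_reports,
        drug_catalog=default_drug_catalog(),
        event_catalog=default_event_catalog(),
        planted_signals=[
            PlantedSignal("demeclocycline", TARGET_PT_CODE, rr=850.0, onset_median_days=14.0, onset_sigma=1.0),
            PlantedSignal("dexmedetomidine", TARGET_PT_CODE, rr=440.0, onset_median_days=0.7, onset_sigma=0.8),
            PlantedSignal("lithium", TARGET_PT_CODE, rr=150.0, onset_median_days=226.0, onset_sigma=1.5),
            PlantedSignal("hydrocortisone", TARGET_PT_CODE, rr=60.0, onset_median_days=77.0, onset_sigma=1.5),
            PlantedSignal("ketamine", TARGET_PT_CODE, rr=30.0, onset_median_days=7.0, onset_sigma=1.0),
            PlantedSignal("doxycycline", TARGET_PT_CODE, rr=12.0, onset_median_days=21.0, onset_sigma=1.0),
            PlantedSignal("letrozole", TARGET_PT_CODE, rr=5.0, onset_median_days=147.0, onset_sigma=1.0),
        ],
        seed=seed,
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Analytic expectations (test oracle)


@dataclass(frozen=True)
class ExpectedTable:
    """Real-valued expected 2x2 cells; sums exactly to n_reports."""

    a: float
    b: float
    c: float
    d: float

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d


def _rr_matrix(config: SimulationConfig) -> np.ndarray:
    """Event-occurrence probability r[d, e] = clip(q_e * rr, cap) with an
    extra final row for the uncataloged "other" suspect slot (rr = 1)."""
    n_drugs = len(config.drug_catalog)
    q = np.array([e.p for e in config.event_catalog])
    r = np.tile(q, (n_drugs + 1, 1))
    drug_idx = {d.drug_id: i for i, d in enumerate(config.drug_catalog)}
    event_idx = {e.pt_code: j for j, e in enumerate(config.event_catalog)}
    for sig in config.planted_signals:
        r[drug_idx[sig.drug_id], event_idx[sig.event_pt_code]] = q[event_idx[sig.event_pt_code]] * sig.rr
    return np.clip(r, 0.0, _EVENT_PROB_CAP)


def expected_counts(config: SimulationConfig, drug_id: str, pt_code: int) -> ExpectedTable:
    """Closed-form expected 2x2 cells before duplication/missingness.

    With suspect-slot probabilities p_d (remainder to the "other" product),
    PS fraction f and occurrence probabilities r[d, e]:

        a = n * p_d * f * r[d, e]
        b = n * p_d * f * (1 - r[d, e])
        c = n * sum_d' p_d' * r[d', e]  -  a
        d = n - a - b - c
    """
    config.validate()
    drug_idx = {d.drug_id: i for i, d in enumerate(config.drug_catalog)}
    event_idx = {e.pt_code: j for j, e in enumerate(config.event_catalog)}
    if drug_id not in drug_idx:
        raise KeyError(f"unknown drug_id {drug_id!r}")
    if pt_code not in event_idx:
        raise KeyError(f"unknown pt_code {pt_code}")
    n = float(config.n_reports)
    di, ej = drug_idx[drug_id], event_idx[pt_code]
    r = _rr_matrix(config)
    p = np.array([d.p for d in config.drug_catalog] + [0.0])
    p[-1] = max(0.0, 1.0 - p[:-1].sum())
    f = config.ps_fraction
    a = n * p[di] * f * r[di, ej]
    b = n * p[di] * f * (1.0 - r[di, ej])
    total_event = n * float((p * r[:, ej]).sum())
    c = total_event - a
    d = n - a - b - c
    return ExpectedTable(a=float(a), b=float(b), c=float(c), d=float(d))


# ---------------------------------------------------------------------------
# Generation


@dataclass
class GroundTruth:
    """Per-case generator truth for oracle-based testing."""

    cases: pd.DataFrame     # caseid, primaryid (surviving), suspect_ingredient,
                            # suspect_role, has_target, n_versions, lag_days
    n_distinct_cases: int
    seed: int

    def target_case_count(self) -> int:
        return int(self.cases["has_target"].sum())


def _dates_to_str(days: np.ndarray) -> np.ndarray:
    """datetime64[D] -> 8-digit YYYYMMDD strings."""
    iso = np.datetime_as_string(days, unit="D")
    return np.char.replace(iso, "-", "")


def _corrupt_dates(s: np.ndarray, rng: np.random.Generator,
                   config: SimulationConfig) -> np.ndarray:
    """Degrade complete dates: empty, 6-digit partial, or non-numeric."""
    u = rng.random(s.shape[0])
    m, p, g = (config.missing_date_rate, config.partial_date_rate,
               config.malformed_date_rate)
    out = s.astype(object)
    present = out != ""
    out[present & (u < m)] = ""
    partial_mask = present & (u >= m) & (u < m + p)
    out[partial_mask] = [v[:6] for v in out[partial_mask]]
    bad_mask = present & (u >= m + p) & (u < m + p + g)
    out[bad_mask] = [v[:6] + "XX" for v in out[bad_mask]]
    return out


def _weighted_choice(rng, keys, weights_map, size):
    keys = list(keys)
    w = np.array([weights_map[k] for k in keys], dtype=float)
    return rng.choice(np.array(keys, dtype=object), size=size, p=w / w.sum())


def generate_quarter_with_truth(config: SimulationConfig, seed: int | None = None
                                ) -> tuple[QuarterBundle, GroundTruth]:
    """Simulate one quarter; returns the five-table bundle plus ground truth."""
    config.validate()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = config.n_reports
    n_drugs = len(config.drug_catalog)
    events = config.event_catalog

    # --- core joint: suspect drug slot and event occurrences
    p = np.array([d.p for d in config.drug_catalog])
    p_other = max(0.0, 1.0 - p.sum())
    drug_idx = rng.choice(n_drugs + 1, size=n, p=np.append(p, p_other))
    r = _rr_matrix(config)
    occ = rng.random((n, len(events))) < r[drug_idx]
    suspect_role = np.where(rng.random(n) < config.ps_fraction, "PS", "SS")

    # --- identifiers
    caseid_int = 10_000_000 + np.arange(n, dtype=np.int64)
    caseid = caseid_int.astype(str)

    # --- dates
    qstart = np.datetime64(config.quarter_start, "D")
    fda = qstart + rng.integers(0, config.quarter_days, n)
    delay = np.round(rng.lognormal(np.log(config.report_delay_median),
                                   config.report_delay_sigma, n)).astype(np.int64)
    event_date = fda - delay
    lag = np.round(rng.lognormal(np.log(max(config.default_onset_median, 0.5)),
                                 config.default_onset_sigma, n)).astype(np.int64)
    event_col = {e.pt_code: j for j, e in enumerate(events)}
    drug_row = {d.drug_id: i for i, d in enumerate(config.drug_catalog)}
    for sig in config.planted_signals:
        mask = (drug_idx == drug_row[sig.drug_id]) & occ[:, event_col[sig.event_pt_code]]
        k = int(mask.sum())
        if k:
            lag[mask] = np.round(rng.lognormal(
                np.log(max(sig.onset_median_days, 0.5)), sig.onset_sigma, k)).astype(np.int64)
    start_date = event_date - lag

    fda_str = _dates_to_str(fda)
    event_str = _corrupt_dates(_dates_to_str(event_date), rng, config)
    start_str_full = _dates_to_str(start_date)

    # --- duplicate report versions (true version carries the latest FDA_DT)
    dup_mask = rng.random(n) < config.duplicate_rate
    k_extra = np.where(dup_mask, rng.integers(1, 3, n), 0)
    n_versions = 1 + k_extra
    version_digit = np.ones(n, dtype=np.int64)   # suffix of the true version
    ext_case, ext_pid, ext_fda = [], [], []
    for i in np.nonzero(dup_mask)[0]:
        k = int(n_versions[i])
        digits = rng.permutation(np.arange(1, k + 1))
        version_digit[i] = digits[-1]
        back = np.cumsum(rng.integers(1, 91, k - 1))
        for j in range(k - 1):
            ext_case.append(i)
            ext_pid.append(caseid_int[i] * 10 + digits[j])
            ext_fda.append(fda[i] - back[k - 2 - j])
    primaryid_int = caseid_int * 10 + version_digit
    primaryid = primaryid_int.astype(str)

    # --- demographics
    sex = _weighted_choice(rng, config.sex_weights, config.sex_weights, n)
    age_years = np.clip(rng.normal(config.age_mean, config.age_sd, n), 0.1, 100.0)
    age_missing = rng.random(n) < config.age_missing_rate
    unit = _weighted_choice(rng, config.age_unit_rates, config.age_unit_rates, n)
    age_value = np.round(np.where(unit == "MON", age_years * 12,
                         np.where(unit == "DY", age_years * 365.25, age_years))).astype(np.int64)
    age_str = age_value.astype(str).astype(object)
    age_str[age_missing] = ""
    unit = unit.astype(object)
    unit[age_missing] = ""
    wt = np.round(np.clip(rng.normal(config.weight_mean, config.weight_sd, n), 2.0, 250.0), 1)
    wt_str = wt.astype(str).astype(object)
    wt_str[rng.random(n) < config.weight_missing_rate] = ""
    occp = _weighted_choice(rng, config.occupation_weights, config.occupation_weights, n)
    country = _weighted_choice(rng, config.country_weights, config.country_weights, n)

    demo = pd.DataFrame({
        "primaryid": primaryid, "caseid": caseid, "fda_dt": fda_str,
        "event_dt": event_str, "age": age_str, "age_cod": unit, "sex": sex,
        "wt": wt_str, "occp_cod": occp, "occr_country": country,
    }).astype(str)

    # --- drug records: suspect + concomitants
    ing_names = np.array([d.ingredient for d in config.drug_catalog] + [OTHER_DRUG_VERBATIM],
                         dtype=object)

    def verbatims(idx: np.ndarray) -> np.ndarray:
        base = ing_names[idx].astype(str)
        forms = rng.integers(0, 3, idx.shape[0])
        upper = np.char.upper(base)
        out = np.where(forms == 0, upper,
                       np.where(forms == 1, np.char.title(base),
                                np.char.add(np.char.add(" ", upper), " ")))
        out = np.where(idx == n_drugs, OTHER_DRUG_VERBATIM, out)
        return out.astype(object)

    drug_start = start_str_full.astype(object)
    drug_start[rng.random(n) >= config.drug_start_rate] = ""
    drug_start = _corrupt_dates(np.asarray(drug_start, dtype=object), rng, config)
    suspect = pd.DataFrame({
        "case_idx": np.arange(n),
        "drug_seq": "1",
        "role_cod": suspect_role,
        "drugname": verbatims(drug_idx),
        "start_dt": drug_start,
    })
    n_con = rng.poisson(config.concomitant_rate, n)
    con_case = np.repeat(np.arange(n), n_con)
    con_idx = rng.integers(0, n_drugs, con_case.shape[0])
    offsets = con_case_pos = np.arange(con_case.shape[0]) - np.repeat(
        np.concatenate(([0], np.cumsum(n_con)[:-1])), n_con)
    concomitant = pd.DataFrame({
        "case_idx": con_case,
        "drug_seq": (offsets + 2).astype(str),
        "role_cod": rng.choice(np.array(["SS", "C", "I"], dtype=object),
                               size=con_case.shape[0], p=[0.2, 0.7, 0.1]),
        "drugname": verbatims(con_idx),
        "start_dt": "",
    })
    drug_base = pd.concat([suspect, concomitant], ignore_index=True)

    # --- reactions
    rc_case, rc_event = np.nonzero(occ)
    pt_names = np.array([e.pt_name for e in events], dtype=object)
    pt_codes = np.array([str(e.pt_code) for e in events], dtype=object)
    reac_base = pd.DataFrame({
        "case_idx": rc_case,
        "pt": pt_names[rc_event],
        "pt_cod": pt_codes[rc_event],
    })

    # --- therapy rows for the suspect drug
    ther_mask = rng.random(n) < config.ther_rate
    ther_start = _corrupt_dates(start_str_full[ther_mask].astype(object), rng, config)
    ther_base = pd.DataFrame({
        "case_idx": np.nonzero(ther_mask)[0],
        "dsg_drug_seq": "1",
        "start_dt": ther_start,
    })

    # --- outcomes
    n_outc = rng.choice(np.arange(3), size=n, p=np.asarray(config.outcome_count_weights))
    oc_case = np.repeat(np.arange(n), n_outc)
    oc_codes = _weighted_choice(rng, config.outcome_code_weights,
                                config.outcome_code_weights, oc_case.shape[0])
    outc_base = pd.DataFrame({"case_idx": oc_case, "outc_cod": oc_codes})

    # --- replicate child rows for earlier report versions
    id_map = pd.DataFrame({
        "case_idx": np.arange(n), "primaryid": primaryid, "caseid": caseid,
    })
    if ext_case:
        ext_map = pd.DataFrame({
            "case_idx": np.asarray(ext_case),
            "primaryid": np.asarray(ext_pid).astype(str),
            "caseid": caseid[np.asarray(ext_case)],
        })
        all_map = pd.concat([id_map, ext_map], ignore_index=True)
        demo_ext = demo.iloc[np.asarray(ext_case)].copy()
        demo_ext["primaryid"] = np.asarray(ext_pid).astype(str)
        demo_ext["fda_dt"] = _dates_to_str(np.asarray(ext_fda))
        demo_ext["age"] = ""          # earlier versions are less complete
        demo_ext["age_cod"] = ""
        demo_all = pd.concat([demo, demo_ext], ignore_index=True)
    else:
        all_map = id_map
        demo_all = demo

    def attach_ids(base: pd.DataFrame) -> pd.DataFrame:
        out = base.merge(all_map, on="case_idx", how="inner")
        return out.drop(columns="case_idx")

    drug_df = attach_ids(drug_base)[["primaryid", "caseid", "drug_seq", "role_cod",
                                     "drugname", "start_dt"]].astype(str)
    reac_df = attach_ids(reac_base)[["primaryid", "caseid", "pt", "pt_cod"]].astype(str)
    ther_df = attach_ids(ther_base)[["primaryid", "caseid", "dsg_drug_seq",
                                     "start_dt"]].astype(str)
    outc_df = attach_ids(outc_base)[["primaryid", "caseid", "outc_cod"]].astype(str)

    bundle = QuarterBundle(demo=demo_all.astype(str), drug=drug_df, reac=reac_df,
                           ther=ther_df, outc=outc_df)
    target_col = event_col.get(TARGET_PT_CODE)
    has_target = occ[:, target_col] if target_col is not None else np.zeros(n, bool)
    truth = GroundTruth(
        cases=pd.DataFrame({
            "caseid": caseid,
            "primaryid": primaryid,
            "suspect_ingredient": np.where(drug_idx < n_drugs, ing_names[drug_idx], ""),
            "suspect_role": suspect_role,
            "has_target": has_target,
            "n_versions": n_versions,
            "lag_days": lag,
        }),
        n_distinct_cases=n,
        seed=seed,
    )
    return bundle, truth


def generate_quarter(config: SimulationConfig, seed: int | None = None) -> QuarterBundle:
    """Simulate one FAERS-like quarter (see module docstring for the model)."""
    bundle, _ = generate_quarter_with_truth(config, seed)
    return bundle
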