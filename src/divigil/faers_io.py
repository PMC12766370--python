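"""Reading, writing and linking of FAERS-style quarterly ASCII tables.

FAERS quarters are distributed as ``$``-delimited ASCII files with a header
row: DEMO (demographics and administration), DRUG (drug records with role
codes), REAC (MedDRA-coded reactions), THER (therapy dates) and OUTC
(outcome codes). One safety report version is keyed by PRIMARYID; report
versions of the same case share a CASEID. This module parses those files
into pandas DataFrames with an explicit reject log (malformed rows are
counted, never silently dropped), writes them back, and links the five
tables into per-case views.

Only the analysis-relevant column subset is required; unknown columns are
carried through opaquely so read/write round-trips are lossless.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd

__all__ = [
    "TABLE_COLUMNS",
    "ParseLog",
    "QuarterBundle",
    "CaseData",
    "ReportCase",
    "DrugRecord",
    "ReacRecord",
    "TherRecord",
    "OutcRecord",
    "read_table",
    "write_table",
    "read_quarter",
    "write_quarter",
    "link_cases",
]

ROLE_CODES = ("PS", "SS", "C", "I")
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")
AGE_UNIT_CODES = ("YR", "MON", "DY", "DEC", "WK", "HR")

#: Mandatory columns per table kind (lower-case canonical names).
TABLE_COLUMNS: dict[str, list[str]] = {
    "demo": [
        "primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
        "sex", "wt", "occp_cod", "occr_country",
    ],
    "drug": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname", "start_dt"],
    "reac": ["primaryid", "caseid", "pt", "pt_cod"],
    "ther": ["primaryid", "caseid", "dsg_drug_seq", "start_dt"],
    "outc": ["primaryid", "caseid", "outc_cod"],
}


@dataclass
class ParseLog:
    """Accounting for one parsed table: every input data row is either
    parsed or counted under a reject reason."""

    table: str
    n_data_rows: int = 0
    n_parsed: int = 0
    reject_reasons: Counter = field(default_factory=Counter)
    non_ascii_replaced: int = 0

    @property
    def n_rejected(self) -> int:
        return sum(self.reject_reasons.values())

    def to_dict(self) -> dict:
        return {
            "table": self.table,
            "n_data_rows": self.n_data_rows,
            "n_parsed": self.n_parsed,
            "n_rejected": self.n_rejected,
            "reject_reasons": dict(self.reject_reasons),
            "non_ascii_replaced": self.non_ascii_replaced,
        }


def _check_kind(table_kind: str) -> list[str]:
    if table_kind not in TABLE_COLUMNS:
        raise ValueError(
            f"unknown table kind {table_kind!r}; expected one of {sorted(TABLE_COLUMNS)}"
        )
    return TABLE_COLUMNS[table_kind]


def read_table(path: str | Path, table_kind: str) -> tuple[pd.DataFrame, ParseLog]:
    """Parse one ``$``-delimited quarterly table.

    Rows whose field count disagrees with the header, or whose primaryid is
    empty, are rejected and tallied in the :class:`ParseLog`. Non-ASCII bytes
    are replaced with ``?`` and counted. All cells are kept as strings;
    downstream stages own the typed parsing.
    """
    required = _check_kind(table_kind)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table file not found: {path}")
    raw = path.read_bytes()
    n_non_ascii = sum(1 for b in raw if b > 127)
    text = raw.decode("ascii", errors="replace").replace("�", "?")

    lines = text.splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file, expected a $-delimited header")
    header = [c.strip().lower() for c in lines[0].split("$")]
    missing = [c for c in required if c not in header]
    if missing:
        raise ValueError(f"{path}: header missing mandatory columns {missing}")

    log = ParseLog(table=table_kind, non_ascii_replaced=n_non_ascii)
    ncol = len(header)
    pid_idx = header.index("primaryid")
    rows: list[list[str]] = []
    for line in lines[1:]:
        if line == "":
            continue
        fields = line.split("$")
        log.n_data_rows += 1
        if len(fields) != ncol:
            log.reject_reasons["column_count"] += 1
            continue
        if fields[pid_idx].strip() == "":
            log.reject_reasons["missing_primaryid"] += 1
            continue
        rows.append(fields)
    log.n_parsed = len(rows)
    df = pd.DataFrame(rows, columns=header, dtype=str)
    if df.empty:
        df = pd.DataFrame({c: pd.Series(dtype=str) for c in header})
    return df, log


def write_table(df: pd.DataFrame, path: str | Path, table_kind: str) -> None:
    """Write a table in the ``$``-delimited dialect; absent values become
    empty cells. Cells may not themselves contain ``$`` or newlines."""
    required = _check_kind(table_kind)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cannot write {table_kind}: missing columns {missing}")
    out = df.fillna("").astype(str)
    bad = out.apply(lambda s: s.str.contains(r"[$\n\r]", regex=True)).any()
    if bad.any():
        cols = list(bad[bad].index)
        raise ValueError(f"unserializable field value (contains '$' or newline) in columns {cols}")
    with open(path, "w", newline="\n") as fh:
        fh.write("$".join(out.columns) + "\n")
        for row in out.itertuples(index=False):
            fh.write("$".join(row) + "\n")


def read_quarter(paths: dict[str, str | Path]) -> "QuarterBundle":
    """Read the five tables given ``{"demo": path, "drug": path, ...}``."""
    missing = [k for k in TABLE_COLUMNS if k not in paths]
    if missing:
        raise ValueError(f"missing table paths for {missing}")
    tables = {}
    logs = {}
    for kind in TABLE_COLUMNS:
        tables[kind], logs[kind] = read_table(paths[kind], kind)
    return QuarterBundle(logs=logs, **tables)


def write_quarter(bundle: "QuarterBundle", out_dir: str | Path, suffix: str = "") -> dict[str, Path]:
    """Write all five tables as ``DEMO<suffix>.txt`` etc.; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for kind in TABLE_COLUMNS:
        p = out_dir / f"{kind.upper()}{suffix}.txt"
        write_table(getattr(bundle, kind), p, kind)
        paths[kind] = p
    return paths


@dataclass
class QuarterBundle:
    """The five quarterly tables plus per-table parse logs."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    logs: dict[str, ParseLog] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Linked case views


@dataclass
class DrugRecord:
    primaryid: str
    drug_seq: int
    role_code: str
    drugname_verbatim: str
    start_dt: str  # raw date field; "" when absent


@dataclass
class ReacRecord:
    primaryid: str
    pt_name: str
    pt_code: int | None


@dataclass
class TherRecord:
    primaryid: str
    dsg_drug_seq: int
    start_dt: str


@dataclass
class OutcRecord:
    primaryid: str
    outcome_code: str


@dataclass
class ReportCase:
    """One safety report (one DEMO row) with its linked child records."""

    primaryid: str
    caseid: str
    fda_dt: str
    event_dt: str
    age: str
    age_unit: str
    sex: str
    weight: str
    reporter_occupation: str
    country: str
    drugs: list[DrugRecord] = field(default_factory=list)
    reactions: list[ReacRecord] = field(default_factory=list)
    therapies: list[TherRecord] = field(default_factory=list)
    outcomes: list[OutcRecord] = field(default_factory=list)


def _to_int(s: str) -> int | None:
    try:
        return int(s)
    except (TypeError, ValueError):
        return None


@dataclass
class CaseData:
    """Linked tables restricted to DEMO-anchored report versions.

    Holds the vectorized (DataFrame) representation used by the pipeline;
    :meth:`iter_cases` materializes :class:`ReportCase` objects for
    small-scale inspection and the onset/demographics stages.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    orphans: dict[str, int] = field(default_factory=dict)

    @property
    def n_cases(self) -> int:
        return len(self.demo)

    def subset(self, primaryids) -> "CaseData":
        keep = set(primaryids)
        return CaseData(
            demo=self.demo[self.demo["primaryid"].isin(keep)].copy(),
            drug=self.drug[self.drug["primaryid"].isin(keep)].copy(),
            reac=self.reac[self.reac["primaryid"].isin(keep)].copy(),
            ther=self.ther[self.ther["primaryid"].isin(keep)].copy(),
            outc=self.outc[self.outc["primaryid"].isin(keep)].copy(),
            orphans=dict(self.orphans),
        )

    def iter_cases(self) -> Iterator[ReportCase]:
        drug_g = {k: v for k, v in self.drug.groupby("primaryid")}
        reac_g = {k: v for k, v in self.reac.groupby("primaryid")}
        ther_g = {k: v for k, v in self.ther.groupby("primaryid")}
        outc_g = {k: v for k, v in self.outc.groupby("primaryid")}
        for row in self.demo.itertuples(index=False):
            pid = row.primaryid
            case = ReportCase(
                primaryid=pid,
                caseid=row.caseid,
                fda_dt=row.fda_dt,
                event_dt=row.event_dt,
                age=row.age,
                age_unit=row.age_cod,
                sex=row.sex,
                weight=row.wt,
                reporter_occupation=row.occp_cod,
                country=row.occr_country,
            )
            if pid in drug_g:
                for d in drug_g[pid].itertuples(index=False):
                    case.drugs.append(DrugRecord(
                        primaryid=pid,
                        drug_seq=_to_int(d.drug_seq) or 0,
                        role_code=d.role_cod,
                        drugname_verbatim=d.drugname,
                        start_dt=d.start_dt,
                    ))
            if pid in reac_g:
                for r in reac_g[pid].itertuples(index=False):
                    case.reactions.append(ReacRecord(
                        primaryid=pid, pt_name=r.pt, pt_code=_to_int(r.pt_cod),
                    ))
            if pid in ther_g:
                for t in ther_g[pid].itertuples(index=False):
                    case.therapies.append(TherRecord(
                        primaryid=pid,
                        dsg_drug_seq=_to_int(t.dsg_drug_seq) or 0,
                        start_dt=t.start_dt,
                    ))
            if pid in outc_g:
                for o in outc_g[pid].itertuples(index=False):
                    case.outcomes.append(OutcRecord(primaryid=pid, outcome_code=o.outc_cod))
            yield case


def link_cases(bundle: QuarterBundle) -> CaseData:
    """Anchor every child record to a DEMO report version.

    Child rows whose primaryid has no DEMO row are orphans: counted per
    table, then dropped (never fatal).
    """
    known = set(bundle.demo["primaryid"])
    orphans: dict[str, int] = {}
    kept = {}
    for kind in ("drug", "reac", "ther", "outc"):
        df = getattr(bundle, kind)
        mask = df["primaryid"].isin(known)
        orphans[kind] = int((~mask).sum())
        kept[kind] = df[mask].copy()
    return CaseData(demo=bundle.demo.copy(), orphans=orphans, **kept)
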