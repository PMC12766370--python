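"""Disproportionality statistics: ROR and BCPNN information component.

For each standardized primary-suspect ingredient the deduplicated database
is collapsed to a 2x2 table against the target event:

    a  target-event cases with the drug        b  other cases with the drug
    c  target-event cases, other drugs         d  other cases, other drugs

Two screening statistics are computed per table.

Reporting odds ratio (Woolf log-scale interval):

    ROR    = a*d / (b*c)
    95% CI = exp( ln ROR +- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d) )

Any zero cell leaves the ROR undefined (no continuity correction; the
case-count floor below makes one irrelevant for reported signals).

BCPNN information component, IC = log2 of the observed-to-expected
co-reporting ratio with Bayesian shrinkage. With Dirichlet/beta priors
(alpha, beta, alpha_i, beta_j, gamma_ij; classical defaults 2, 2, 1, 1, 1
centering the prior IC at 0 under independence):

    gamma = gamma_ij * (N+alpha)(N+beta) / ((a+b+alpha_i)(a+c+beta_j))
    E(IC) = log2( (a+gamma_ij)(N+alpha)(N+beta)
                  / ((N+gamma)(a+b+alpha_i)(a+c+beta_j)) )
    V(IC) = (1/ln 2)^2 * [ (N-a+gamma-gamma_ij) / ((a+gamma_ij)(1+N+gamma))
                         + (N-a-b+alpha-alpha_i) / ((a+b+alpha_i)(1+N+alpha))
                         + (N-a-c+beta-beta_j) / ((a+c+beta_j)(1+N+beta)) ]
    IC_025 = E(IC) - 2*sqrt(V(IC))

A drug is signal-positive only when both algorithms agree: ROR CI lower
bound > 1, case count a >= 3, and IC_025 > 0. Positive signals are
stratified by IC_025: weak (0, 1.5], medium (1.5, 3], strong (3, inf).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cases import UNCLASSIFIED, ps_ingredients, target_flags
from .faers_io import CaseData

__all__ = [
    "ContingencyTable",
    "BcpnnHyperparameters",
    "RorResult",
    "IcResult",
    "SignalRecord",
    "build_tables",
    "compute_ror",
    "compute_ic",
    "call_signal",
    "stratify",
    "evaluate_signals",
    "signal_frame",
    "reconstruct_table",
]

Z_95 = 1.96
STRATA_BOUNDS = (1.5, 3.0)  # weak/medium and medium/strong IC_025 cutpoints


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 drug-by-event case counts."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class BcpnnHyperparameters:
    alpha: float = 2.0
    beta: float = 2.0
    alpha_i: float = 1.0
    beta_j: float = 1.0
    gamma_ij: float = 1.0

    def __post_init__(self):
        for name in ("alpha", "beta", "alpha_i", "beta_j", "gamma_ij"):
            if not getattr(self, name) > 0:
                raise ValueError(f"BCPNN hyperparameter {name} must be strictly positive")


@dataclass(frozen=True)
class RorResult:
    ror: float
    ci_low: float
    ci_high: float
    defined: bool


@dataclass(frozen=True)
class IcResult:
    e_ic: float
    v_ic: float
    ic025: float


def compute_ror(table, b=None, c=None, d=None) -> RorResult:
    """ROR with Woolf 95% CI; accepts a :class:`ContingencyTable` or the four
    cell values (real-valued cells allowed for reconstructed margins)."""
    if b is None:
        a, b, c, d = table.a, table.b, table.c, table.d
    else:
        a = table
    if min(a, b, c, d) <= 0:
        return RorResult(ror=float("nan"), ci_low=float("nan"),
                         ci_high=float("nan"), defined=False)
    ror = (a * d) / (b * c)
    half = Z_95 * math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    log_ror = math.log(ror)
    return RorResult(
        ror=ror,
        ci_low=math.exp(log_ror - half),
        ci_high=math.exp(log_ror + half),
        defined=True,
    )


def compute_ic(table: ContingencyTable,
               hyper: BcpnnHyperparameters = BcpnnHyperparameters(),
               ic025_rule: str = "two_sd") -> IcResult:
    """BCPNN E(IC), V(IC) and the lower credibility bound IC_025.

    ``ic025_rule`` selects the lower-bound convention: ``"two_sd"`` (default)
    is E(IC) - 2*sqrt(V(IC)); ``"minus_2v"`` is the raw E(IC) - 2*V(IC)
    variant, kept for sensitivity checks only.
    """
    if ic025_rule not in ("two_sd", "minus_2v"):
        raise ValueError(f"unknown ic025_rule {ic025_rule!r}")
    a, b, c = float(table.a), float(table.b), float(table.c)
    n = float(table.n)
    h = hyper
    row = a + b + h.alpha_i          # drug margin + prior
    col = a + c + h.beta_j           # event margin + prior
    gamma = h.gamma_ij * (n + h.alpha) * (n + h.beta) / (row * col)
    e_ic = math.log2((a + h.gamma_ij) * (n + h.alpha) * (n + h.beta)
                     / ((n + gamma) * row * col))
    ln2_sq = math.log(2) ** 2
    v_ic = (1.0 / ln2_sq) * (
        (n - a + gamma - h.gamma_ij) / ((a + h.gamma_ij) * (1.0 + n + gamma))
        + (n - a - b + h.alpha - h.alpha_i) / (row * (1.0 + n + h.alpha))
        + (n - a - c + h.beta - h.beta_j) / (col * (1.0 + n + h.beta))
    )
    if ic025_rule == "two_sd":
        ic025 = e_ic - 2.0 * math.sqrt(v_ic)
    else:
        ic025 = e_ic - 2.0 * v_ic
    return IcResult(e_ic=e_ic, v_ic=v_ic, ic025=ic025)


def call_signal(ror: RorResult, ic: IcResult, a: int) -> bool:
    """Dual positivity criterion: ROR CI lower > 1, a >= 3, IC_025 > 0."""
    return bool(ror.defined and ror.ci_low > 1.0 and a >= 3 and ic.ic025 > 0.0)


def stratify(ic025: float) -> str:
    """Signal-strength stratum of a positive signal's IC_025."""
    if not ic025 > 0:
        raise ValueError("stratify() is defined only for positive signals (IC_025 > 0)")
    if ic025 <= STRATA_BOUNDS[0]:
        return "weak"
    if ic025 <= STRATA_BOUNDS[1]:
        return "medium"
    return "strong"


# ---------------------------------------------------------------------------
# Table construction and pipeline assembly


def build_tables(cases: CaseData, target_pt_code: int,
                 synonym_map: dict[str, str]) -> tuple[dict[str, ContingencyTable], int]:
    """Per-ingredient 2x2 tables against the target event.

    The counting unit is the deduplicated case: an ingredient counts once per
    case regardless of record multiplicity, and only primary-suspect records
    contribute. Every table sums to the same N (total cases).
    """
    n_total = cases.n_cases
    flags = target_flags(cases, target_pt_code)
    target_pids = set(cases.demo.loc[flags.values, "primaryid"])
    n_target = len(target_pids)

    pairs, _ = ps_ingredients(cases, synonym_map)
    if pairs.empty:
        return {}, n_total
    pairs = pairs.assign(is_target=pairs["primaryid"].isin(target_pids))
    g = pairs.groupby("ingredient")["is_target"].agg(["sum", "count"])
    tables = {}
    for ingredient, row in g.iterrows():
        a = int(row["sum"])
        exposed = int(row["count"])
        b = exposed - a
        c = n_target - a
        d = n_total - a - b - c
        tables[ingredient] = ContingencyTable(a=a, b=b, c=c, d=d)
    return tables, n_total


@dataclass
class SignalRecord:
    ingredient: str
    atc_class: str
    a: int
    ror: RorResult
    ic: IcResult
    positive: bool
    strength: str = "none"
    table: ContingencyTable | None = field(default=None, repr=False)


def evaluate_signals(tables: dict[str, ContingencyTable],
                     atc_map: dict[str, tuple[str, str]],
                     hyper: BcpnnHyperparameters = BcpnnHyperparameters(),
                     ic025_rule: str = "two_sd") -> list[SignalRecord]:
    """Score every ingredient's table and sort by ROR descending (undefined
    RORs last; ties broken by ingredient name for a total order)."""
    out = []
    for ingredient, t in tables.items():
        ror = compute_ror(t)
        ic = compute_ic(t, hyper, ic025_rule)
        positive = call_signal(ror, ic, t.a)
        strength = stratify(ic.ic025) if positive else "none"
        atc = atc_map.get(ingredient, (UNCLASSIFIED, ""))[0]
        out.append(SignalRecord(
            ingredient=ingredient, atc_class=atc, a=t.a, ror=ror, ic=ic,
            positive=positive, strength=strength, table=t,
        ))
    out.sort(key=lambda s: (-(s.ror.ror if s.ror.defined else float("-inf")), s.ingredient))
    return out


def signal_frame(signals: list[SignalRecord]) -> pd.DataFrame:
    """Flat signal table (forest-plot ready; one row per ingredient)."""
    return pd.DataFrame([
        {
            "ingredient": s.ingredient,
            "atc_class": s.atc_class,
            "a": s.a,
            "ror": s.ror.ror,
            "ci_low": s.ror.ci_low,
            "ci_high": s.ror.ci_high,
            "e_ic": s.ic.e_ic,
            "ic025": s.ic.ic025,
            "positive": s.positive,
            "strength": s.strength,
        }
        for s in signals
    ])


def reconstruct_table(a: float, c: float, n: float, ror: float
                      ) -> tuple[float, float, float, float]:
    """Back-solve the full 2x2 from (a, c, N) and a published ROR point
    estimate, using d = N - a - b - c:

        ROR = a*d/(b*c)  =>  b = a*(N - a - c) / (ROR*c + a)

    Returns real-valued (a, b, c, d); used to check published confidence
    intervals for self-consistency.
    """
    if min(a, c) <= 0 or n <= a + c or ror <= 0:
        raise ValueError("need a > 0, c > 0, N > a + c and ROR > 0")
    b = a * (n - a - c) / (ror * c + a)
    d = n - a - b - c
    return a, b, c, d
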