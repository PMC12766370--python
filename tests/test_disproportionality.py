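"""ROR / BCPNN statistics, signal calls, strength strata and 2x2 building."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from divigil.disproportionality import (
    BcpnnHyperparameters,
    ContingencyTable,
    build_tables,
    call_signal,
    compute_ic,
    compute_ror,
    evaluate_signals,
    reconstruct_table,
    stratify,
)
from divigil.faers_io import link_cases
from divigil.resources import TARGET_PT_CODE

from conftest import demo_row, make_bundle
from oracle_formulas import bcpnn_ic, ror_with_ci

cells = st.integers(0, 200)


class TestComputeRor:
    def test_proportional_table_has_ror_one(self):
        r = compute_ror(ContingencyTable(10, 90, 100, 900))
        assert r.defined
        assert r.ror == pytest.approx(1.0)

    def test_ci_matches_hand_evaluation(self):
        # frozen from a step-by-step evaluation of the Woolf interval
        r = compute_ror(ContingencyTable(10, 90, 100, 900))
        assert r.ci_low == pytest.approx(0.5039784444345278, rel=1e-12)
        assert r.ci_high == pytest.approx(1.9842118468420147, rel=1e-12)

    def test_zero_cell_is_undefined_no_continuity_correction(self):
        r = compute_ror(ContingencyTable(0, 90, 100, 900))
        assert not r.defined
        assert math.isnan(r.ror)

    def test_agrees_with_statsmodels_odds_ratio(self):
        # independent route: statsmodels' 2x2 odds ratio (its CI uses the
        # exact normal quantile, so compare the point estimate only)
        from statsmodels.stats.contingency_tables import Table2x2
        t = ContingencyTable(37, 1500, 120, 48000)
        sm = Table2x2([[t.a, t.b], [t.c, t.d]])
        assert compute_ror(t).ror == pytest.approx(sm.oddsratio, rel=1e-12)

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_swapping_rows_inverts_ror_and_keeps_log_width(self, a, b, c, d):
        r1 = compute_ror(ContingencyTable(a, b, c, d))
        r2 = compute_ror(ContingencyTable(c, d, a, b))
        assert r1.defined == r2.defined
        if r1.defined:
            assert r2.ror == pytest.approx(1.0 / r1.ror, rel=1e-9)
            w1 = math.log(r1.ci_high) - math.log(r1.ci_low)
            w2 = math.log(r2.ci_high) - math.log(r2.ci_low)
            assert w1 == pytest.approx(w2, rel=1e-9)


class TestComputeIc:
    def test_empty_table_prior_centered_at_zero(self):
        ic = compute_ic(ContingencyTable(0, 0, 0, 0))
        assert ic.e_ic == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_transcription_on_example(self):
        # frozen from the literal step-by-step transcription (oracle_formulas)
        ic = compute_ic(ContingencyTable(25, 75, 75, 825))
        assert ic.e_ic == pytest.approx(1.2201334764534484, rel=1e-12)
        assert ic.v_ic == pytest.approx(0.11511053983469498, rel=1e-12)
        assert ic.ic025 == pytest.approx(0.5415745922445834, rel=1e-12)

    def test_large_proportional_table_shrinks_to_null(self):
        ic = compute_ic(ContingencyTable(100, 9900, 900, 89100))
        assert abs(ic.e_ic) < 0.05

    def test_literal_minus_2v_variant_available(self):
        t = ContingencyTable(25, 75, 75, 825)
        lit = compute_ic(t, ic025_rule="minus_2v")
        two_sd = compute_ic(t)
        assert lit.ic025 == pytest.approx(two_sd.e_ic - 2 * two_sd.v_ic, rel=1e-12)

    def test_nonpositive_hyperparameter_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            BcpnnHyperparameters(alpha=0.0)

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_ic025_strictly_below_e_ic(self, a, b, c, d):
        ic = compute_ic(ContingencyTable(a, b, c, d))
        assert ic.ic025 < ic.e_ic
        assert ic.v_ic >= 0

    @given(a=st.integers(1, 50), b=st.integers(1, 200), c=st.integers(1, 200),
           n_extra=st.integers(2, 5000))
    def test_monotone_in_a_with_fixed_margins(self, a, b, c, n_extra):
        """With the drug margin a+b, event margin a+c and N held fixed,
        moving one case into the 'both' cell raises both ROR and E(IC)."""
        d = n_extra + 2  # ensure d stays positive after the shift
        t1 = ContingencyTable(a, b, c, d)
        t2 = ContingencyTable(a + 1, b - 1, c - 1, d + 1) if min(b, c) > 1 else None
        if t2 is None:
            return
        assert compute_ic(t2).e_ic > compute_ic(t1).e_ic
        r1, r2 = compute_ror(t1), compute_ror(t2)
        if r1.defined and r2.defined:
            assert r2.ror > r1.ror


class TestSignalCallAndStrata:
    def make(self, ci_low, ic025, a):
        ror = compute_ror(ContingencyTable(1, 1, 1, 1))
        ror = type(ror)(ror=ci_low * 1.5, ci_low=ci_low, ci_high=ci_low * 3, defined=True)
        ic = compute_ic(ContingencyTable(1, 1, 1, 1))
        ic = type(ic)(e_ic=ic025 + 1, v_ic=0.25, ic025=ic025)
        return ror, ic, a

    @pytest.mark.parametrize("ci_low, a, ic025, expected", [
        (1.2, 5, 0.4, True),
        (1.2, 2, 0.4, False),     # case-count floor a >= 3
        (0.9, 50, 1.0, False),    # ROR criterion fails
        (1.2, 5, -0.1, False),    # IC criterion fails
    ])
    def test_dual_criterion(self, ci_low, a, ic025, expected):
        ror, ic, n = self.make(ci_low, ic025, a)
        assert call_signal(ror, ic, n) is expected

    def test_undefined_ror_never_positive(self):
        ror = compute_ror(ContingencyTable(5, 0, 10, 1000))
        ic = compute_ic(ContingencyTable(5, 0, 10, 1000))
        assert call_signal(ror, ic, 5) is False

    @pytest.mark.parametrize("ic025, stratum", [
        (0.5, "weak"),
        (1.31, "weak"),     # published octreotide bound falls in the weak band
        (1.5, "weak"),      # boundary: half-open on the right
        (2.0, "medium"),
        (3.0, "medium"),
        (3.32, "strong"),   # published doxycycline bound is a strong signal
        (6.79, "strong"),
    ])
    def test_strata_boundaries(self, ic025, stratum):
        assert stratify(ic025) == stratum

    def test_stratify_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            stratify(0.0)


class TestBuildTables:
    def brute_force(self, case_drugs, case_targets, ingredient):
        """Nested-loop recount over cases; the independent counting oracle."""
        a = b = c = d = 0
        for drugs, is_target in zip(case_drugs, case_targets):
            has = ingredient in drugs
            if has and is_target:
                a += 1
            elif has:
                b += 1
            elif is_target:
                c += 1
            else:
                d += 1
        return a, b, c, d

    def test_overlap_example_counted_per_case(self, synonym_map):
        # 10 cases: drugX PS in 4, target PT in 3, overlap 2
        demo = [demo_row(str(100 + i), str(i)) for i in range(10)]
        drug = [(str(100 + i), str(i), "1", "PS", "LITHIUM", "") for i in range(4)]
        drug += [(str(100 + i), str(i), "1", "PS", "KEPPRA", "") for i in range(4, 10)]
        reac = [(str(100 + i), str(i), "Diabetes insipidus", str(TARGET_PT_CODE))
                for i in (0, 1, 5)]
        cases = link_cases(make_bundle(demo, drug, reac))
        tables, n = build_tables(cases, TARGET_PT_CODE, synonym_map)
        t = tables["lithium"]
        assert (t.a, t.b, t.c, t.d) == (2, 2, 1, 5)
        assert n == 10

    def test_concomitant_only_drug_not_counted_as_exposure(self, synonym_map):
        b = make_bundle(
            demo_rows=[demo_row("101", "10"), demo_row("102", "11")],
            drug_rows=[("101", "10", "1", "C", "LITHIUM", ""),
                       ("102", "11", "1", "PS", "KEPPRA", "")],
            reac_rows=[("101", "10", "Diabetes insipidus", str(TARGET_PT_CODE))],
        )
        tables, _ = build_tables(link_cases(b), TARGET_PT_CODE, synonym_map)
        assert "lithium" not in tables
        assert tables["levetiracetam"].a == 0

    def test_repeated_records_count_once_per_case(self, synonym_map):
        b = make_bundle(
            demo_rows=[demo_row("101", "10")],
            drug_rows=[("101", "10", "1", "PS", "LITHIUM", ""),
                       ("101", "10", "2", "PS", "Lithium Carbonate", "")],
            reac_rows=[("101", "10", "Diabetes insipidus", str(TARGET_PT_CODE))],
        )
        tables, _ = build_tables(link_cases(b), TARGET_PT_CODE, synonym_map)
        assert tables["lithium"].a == 1
        assert tables["lithium"].n == 1

    def test_matches_brute_force_on_synthetic_bundle(self, synonym_map):
        from divigil.cases import deduplicate, normalize_drug
        from divigil.synthetic import (SimulationConfig, default_drug_catalog,
                                       default_event_catalog, generate_quarter)
        cfg = SimulationConfig(
            n_reports=400, drug_catalog=default_drug_catalog(8),
            event_catalog=default_event_catalog(0.08), seed=5,
        )
        cases, _ = deduplicate(link_cases(generate_quarter(cfg)))
        tables, n = build_tables(cases, TARGET_PT_CODE, synonym_map)
        case_drugs, case_targets = [], []
        for case in cases.iter_cases():
            case_drugs.append({normalize_drug(d.drugname_verbatim, synonym_map)
                               for d in case.drugs if d.role_code == "PS"})
            case_targets.append(any(r.pt_code == TARGET_PT_CODE for r in case.reactions))
        for ingredient, t in tables.items():
            assert (t.a, t.b, t.c, t.d) == self.brute_force(
                case_drugs, case_targets, ingredient)
            assert t.n == n


class TestReconstruction:
    def test_back_solved_table_reproduces_the_point_estimate(self):
        a, b, c, d = reconstruct_table(a=114, c=2189 - 114, n=18_627_667, ror=147.71)
        assert a * d / (b * c) == pytest.approx(147.71, rel=1e-12)
        assert a + b + c + d == pytest.approx(18_627_667)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_table(a=0, c=10, n=100, ror=2.0)


def test_evaluate_signals_orders_by_ror_descending(synonym_map, atc_map):
    tables = {
        "lithium": ContingencyTable(30, 100, 100, 10000),
        "letrozole": ContingencyTable(5, 500, 125, 9600),
        "famotidine": ContingencyTable(0, 200, 130, 9900),  # undefined ROR -> last
    }
    signals = evaluate_signals(tables, atc_map)
    assert [s.ingredient for s in signals] == ["lithium", "letrozole", "famotidine"]
    assert signals[0].positive and signals[0].strength != "none"
    assert not signals[2].positive
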