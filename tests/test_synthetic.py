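"""Generator contracts: determinism, analytic expectations, planted structure."""

import math

import numpy as np
import pytest

from divigil.cases import deduplicate
from divigil.faers_io import link_cases, write_quarter
from divigil.resources import TARGET_PT_CODE
from divigil.synthetic import (
    CatalogDrug,
    CatalogEvent,
    PlantedSignal,
    SimulationConfig,
    default_drug_catalog,
    default_event_catalog,
    expected_counts,
    generate_quarter,
    generate_quarter_with_truth,
    paper_scale_config,
)


def small_config(**overrides):
    base = dict(
        n_reports=1000,
        drug_catalog=default_drug_catalog(10),
        event_catalog=default_event_catalog(0.05),
        seed=1,
    )
    base.update(overrides)
    cfg = SimulationConfig(**base)
    cfg.validate()
    return cfg


class TestValidation:
    def test_drug_probabilities_must_not_exceed_one(self):
        cfg = SimulationConfig(
            n_reports=100,
            drug_catalog=[CatalogDrug("lithium", "lithium", "N", 0.7),
                          CatalogDrug("ketamine", "ketamine", "N", 0.7)],
            event_catalog=default_event_catalog(0.05),
        )
        with pytest.raises(ValueError, match="drug_catalog"):
            cfg.validate()

    @pytest.mark.parametrize("field, value", [
        ("duplicate_rate", 1.0),
        ("duplicate_rate", -0.1),
        ("missing_date_rate", 1.5),
    ])
    def test_rates_must_lie_in_unit_interval(self, field, value):
        cfg = small_config()
        setattr(cfg, field, value)
        with pytest.raises(ValueError, match=field):
            cfg.validate()

    def test_planted_signal_must_reference_catalog(self):
        cfg = small_config()
        cfg.planted_signals = [PlantedSignal("unobtainium", TARGET_PT_CODE, 20.0)]
        with pytest.raises(ValueError, match="unobtainium"):
            cfg.validate()
        cfg.planted_signals = [PlantedSignal(cfg.drug_catalog[0].drug_id, 999, 20.0)]
        with pytest.raises(ValueError, match="999"):
            cfg.validate()

    def test_negative_rr_rejected(self):
        cfg = small_config()
        cfg.planted_signals = [PlantedSignal(cfg.drug_catalog[0].drug_id,
                                             TARGET_PT_CODE, -1.0)]
        with pytest.raises(ValueError, match="rr"):
            cfg.validate()


class TestDeterminism:
    def test_same_seed_bit_identical_after_serialization(self, tmp_path):
        cfg = small_config(n_reports=400)
        write_quarter(generate_quarter(cfg, seed=9), tmp_path / "a")
        write_quarter(generate_quarter(cfg, seed=9), tmp_path / "b")
        for kind in ("DEMO", "DRUG", "REAC", "THER", "OUTC"):
            assert (tmp_path / "a" / f"{kind}.txt").read_bytes() == \
                   (tmp_path / "b" / f"{kind}.txt").read_bytes()

    def test_different_seeds_differ(self):
        cfg = small_config(n_reports=400)
        assert not generate_quarter(cfg, seed=1).demo.equals(
            generate_quarter(cfg, seed=2).demo)


class TestExpectedCounts:
    def test_null_model_factorizes(self):
        cfg = small_config(ps_fraction=1.0)
        d = cfg.drug_catalog[3]
        e = cfg.event_catalog[0]
        t = expected_counts(cfg, d.drug_id, e.pt_code)
        assert t.a == pytest.approx(cfg.n_reports * d.p * e.p)

    def test_rr_scales_the_joint_cell_twenty_fold(self):
        # rare event so the tilted per-report probability stays below the cap
        cfg = small_config(ps_fraction=1.0,
                           event_catalog=default_event_catalog(0.002))
        d = cfg.drug_catalog[3].drug_id
        null = expected_counts(cfg, d, TARGET_PT_CODE)
        cfg.planted_signals = [PlantedSignal(d, TARGET_PT_CODE, 20.0)]
        tilted = expected_counts(cfg, d, TARGET_PT_CODE)
        assert tilted.a == pytest.approx(20.0 * null.a)
        assert tilted.n == pytest.approx(cfg.n_reports)

    def test_cells_sum_exactly_to_n_reports(self):
        cfg = small_config()
        cfg.planted_signals = [PlantedSignal(cfg.drug_catalog[0].drug_id,
                                             TARGET_PT_CODE, 50.0)]
        for d in cfg.drug_catalog:
            for e in cfg.event_catalog[:3]:
                t = expected_counts(cfg, d.drug_id, e.pt_code)
                assert t.n == pytest.approx(cfg.n_reports, rel=1e-12)
                assert min(t.a, t.b, t.c, t.d) >= 0

    def test_zero_reports_all_cells_zero(self):
        cfg = small_config(n_reports=0)
        t = expected_counts(cfg, cfg.drug_catalog[0].drug_id, TARGET_PT_CODE)
        assert (t.a, t.b, t.c, t.d) == (0.0, 0.0, 0.0, 0.0)

    def test_unknown_keys_identified(self):
        cfg = small_config()
        with pytest.raises(KeyError, match="unobtainium"):
            expected_counts(cfg, "unobtainium", TARGET_PT_CODE)
        with pytest.raises(KeyError, match="12345"):
            expected_counts(cfg, cfg.drug_catalog[0].drug_id, 12345)


class TestGeneratedStructure:
    def test_no_duplication_config_yields_distinct_caseids(self):
        cfg = small_config(duplicate_rate=0.0, missing_date_rate=0.0, seed=1)
        bundle = generate_quarter(cfg)
        assert bundle.demo["caseid"].is_unique
        assert len(bundle.demo) == 1000
        deduped, log = deduplicate(link_cases(bundle))
        assert log["n_removed"] == 0

    def test_planted_signal_count_within_four_sd_of_expectation(self, synonym_map):
        from divigil.disproportionality import build_tables
        cfg = small_config(n_reports=20_000, duplicate_rate=0.0)
        drug = cfg.drug_catalog[0].drug_id
        cfg.planted_signals = [PlantedSignal(drug, TARGET_PT_CODE, 20.0)]
        cfg.validate()
        exp = expected_counts(cfg, drug, TARGET_PT_CODE)
        bundle = generate_quarter(cfg, seed=42)
        cases, _ = deduplicate(link_cases(bundle))
        tables, _ = build_tables(cases, TARGET_PT_CODE, synonym_map)
        sd = math.sqrt(exp.a)
        assert abs(tables[drug].a - exp.a) <= 4 * sd

    def test_paper_scale_target_marginal_recovered(self):
        # the database-wide marginal: 2,189 target cases per 18,627,667 reports
        marginal = 2189 / 18627667
        cfg = SimulationConfig(
            n_reports=200_000,
            drug_catalog=default_drug_catalog(),
            event_catalog=default_event_catalog(target_p=marginal),
            duplicate_rate=0.0, seed=8,
        )
        _, truth = generate_quarter_with_truth(cfg)
        expected = 200_000 * marginal  # about 23.5
        sd = math.sqrt(expected)
        assert abs(truth.target_case_count() - expected) <= 4 * sd

    def test_duplicate_versions_share_caseid_fresh_primaryid_distinct_fda_dt(self):
        cfg = small_config(duplicate_rate=0.4, seed=13)
        bundle, truth = generate_quarter_with_truth(cfg)
        grouped = bundle.demo.groupby("caseid")
        sizes = grouped.size()
        assert sizes.max() in (2, 3)
        multi = sizes[sizes > 1].index
        assert len(multi) > 0
        for caseid in list(multi)[:50]:
            g = bundle.demo[bundle.demo["caseid"] == caseid]
            assert g["primaryid"].is_unique
            assert g["fda_dt"].is_unique
        truth_versions = truth.cases.set_index("caseid")["n_versions"]
        assert (sizes.reindex(truth_versions.index) == truth_versions).all()

    def test_date_corruption_classes_all_present(self):
        cfg = small_config(n_reports=4000, partial_date_rate=0.1,
                           missing_date_rate=0.1, malformed_date_rate=0.05, seed=2)
        bundle = generate_quarter(cfg)
        ev = bundle.demo["event_dt"]
        assert (ev == "").any()
        assert ev.str.fullmatch(r"\d{6}").any()
        assert ev.str.fullmatch(r"\d{6}XX").any()
        assert ev.str.fullmatch(r"\d{8}").any()

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = paper_scale_config(n_reports=5000, seed=3)
        p = tmp_path / "sim.yaml"
        cfg.to_yaml(p)
        back = SimulationConfig.from_yaml(p)
        assert back == cfg
        assert generate_quarter(back, seed=4).demo.equals(
            generate_quarter(cfg, seed=4).demo)
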