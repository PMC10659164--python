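import numpy as np
import pandas as pd
import pytest

from biobank_dq import synthetic as syn
from biobank_dq.engine import evaluate_catalog
from biobank_dq.errors import ConfigError, InjectionError
from biobank_dq.stats import pearson_correlation


class TestGeneratorConfig:
    def test_defaults_describe_a_16_site_network(self):
        config = syn.GeneratorConfig()
        assert config.institutions == tuple("ABCDEFGHIJKLMNOP")
        assert config.n_records("A") == 1000

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"institutions": ()},
            {"institutions": ("A", "A")},
            {"records_per_institution": -1},
            {"birth_year_range": (1800, 1990)},
            {"birth_year_range": (1990, 2025)},
            {"disease_prevalence": 1.5},
            {"sex_probs": (0.2, 0.2)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            syn.GeneratorConfig(**kwargs).validate()


class TestGenerateClean:
    def test_zero_violations_under_both_catalogs(
        self, clean_network, prereview_catalog, final_cat
    ):
        assert evaluate_catalog(prereview_catalog, clean_network).total == 0
        assert evaluate_catalog(final_cat, clean_network).total == 0

    def test_requested_record_counts(self):
        config = syn.GeneratorConfig(
            institutions=("A", "B"), records_per_institution={"A": 3, "B": 0}
        )
        a, b = syn.generate_clean(config, seed=5)
        assert len(a.tables["basic_info"]) == 3
        assert len(b.tables["basic_info"]) == 0
        assert set(b.tables) == {t for t in a.tables}

    def test_same_seed_reproduces_bitwise(self, small_config, clean_network):
        again = syn.generate_clean(small_config, seed=11)
        for ds1, ds2 in zip(clean_network, again):
            for name in ds1.tables:
                pd.testing.assert_frame_equal(ds1.tables[name], ds2.tables[name])

    def test_different_seeds_differ(self, small_config, clean_network):
        other = syn.generate_clean(small_config, seed=99)
        assert not clean_network[0].tables["measurements"].equals(
            other[0].tables["measurements"]
        )


class TestInjectErrors:
    def test_zero_rates_leave_data_unchanged(self, clean_network):
        out, ledger = syn.inject_errors(clean_network, syn.ErrorModel(), seed=3)
        assert ledger.total == 0 and ledger.counts == {}
        for ds1, ds2 in zip(clean_network, out):
            for name in ds1.tables:
                pd.testing.assert_frame_equal(ds1.tables[name], ds2.tables[name])

    def test_does_not_mutate_input(self, clean_network, mixed_model):
        before = clean_network[0].tables["basic_info"].copy()
        syn.inject_errors(clean_network, mixed_model, seed=4)
        pd.testing.assert_frame_equal(clean_network[0].tables["basic_info"], before)

    def test_null_injection_recovered_exactly(self, clean_network, final_cat):
        model = syn.ErrorModel(
            null_rate={"A": 5 / 150}, null_fields=("KBN_Donor",)
        )
        out, ledger = syn.inject_errors(clean_network, model, seed=6)
        assert ledger.counts == {("A", "CP-basic_info-KBN_Donor"): 5}
        vs = evaluate_catalog(final_cat, out)
        assert vs.per_rule_counts == {"CP-basic_info-KBN_Donor": 5}
        assert ledger.matches(vs)

    def test_unit_error_produces_gram_scale_weight(self, clean_network, final_cat):
        model = syn.ErrorModel(unit_error_rate={"A": 3 / 150})
        out, ledger = syn.inject_errors(clean_network, model, seed=7)
        weights = out[0].tables["measurements"]["weight"].astype(float)
        assert (weights > 2400).sum() == 3
        vs = evaluate_catalog(final_cat, out)
        # a gram-scale weight trips the plausibility range rule and the
        # height-vs-weight comparison; the ledger carries both
        assert vs.per_rule_counts == {
            "VR-measurements-weight": 3,
            "VR-X-height_gt_weight": 3,
        }
        assert ledger.matches(vs)

    def test_date_malformation_shapes(self, clean_network):
        model = syn.ErrorModel(date_malform_rate={"A": 10 / 150})
        out, _ = syn.inject_errors(clean_network, model, seed=8)
        bad = [
            v
            for v in out[0].tables["basic_info"]["birthdate"]
            if len(str(v)) != 8
        ]
        assert len(bad) == 10
        assert {len(str(v)) for v in bad} <= {6, 7}

    def test_logic_error_sets_type_against_no_history(self, clean_network, final_cat):
        model = syn.ErrorModel(logic_error_rate={"A": 4 / 150})
        out, ledger = syn.inject_errors(clean_network, model, seed=9)
        dh = out[0].tables["disease_history"]
        contradictions = ((dh["DHCa"] == "0") & ~dh["DHCa1"].isin(["0", "9"])).sum()
        assert contradictions == 4
        vs = evaluate_catalog(final_cat, out)
        assert vs.per_rule_counts == {"AB-REV-DHCa": 4}
        assert ledger.matches(vs)

    def test_duplicate_injection_counts(self, clean_network, final_cat):
        model = syn.ErrorModel(duplicate_rate={"A": 6 / 150})
        out, ledger = syn.inject_errors(clean_network, model, seed=10)
        vs = evaluate_catalog(final_cat, out)
        assert vs.per_rule_counts == {"UQ-basic_info-KBN_Donor": 6}
        assert ledger.matches(vs)

    def test_mixed_model_recovered_exactly(
        self, corrupted_network, violations
    ):
        _, ledger = corrupted_network
        assert ledger.total > 0
        assert ledger.matches(violations)
        assert ledger.compare(violations).empty

    def test_injection_deterministic(self, clean_network, mixed_model):
        a, la = syn.inject_errors(clean_network, mixed_model, seed=12)
        b, lb = syn.inject_errors(clean_network, mixed_model, seed=12)
        assert la.counts == lb.counts
        for ds1, ds2 in zip(a, b):
            for name in ds1.tables:
                pd.testing.assert_frame_equal(ds1.tables[name], ds2.tables[name])

    def test_rates_beyond_sites_raise(self, clean_network):
        model = syn.ErrorModel(duplicate_rate={"A": 0.9})  # needs 1.8x the rows
        with pytest.raises(InjectionError, match="institution A"):
            syn.inject_errors(clean_network, model, seed=13)

    def test_invalid_rate_rejected(self, clean_network):
        with pytest.raises(ConfigError):
            syn.inject_errors(
                clean_network, syn.ErrorModel(null_rate=1.5), seed=1
            )

    def test_ledger_csv_roundtrip(self, tmp_path, corrupted_network):
        _, ledger = corrupted_network
        p = tmp_path / "ledger.csv"
        ledger.to_csv(p)
        assert syn.GroundTruthLedger.from_csv(p).counts == ledger.counts


class TestFactors:
    def test_biospecimen_count_is_record_count(self, clean_network):
        factors = syn.generate_factors(clean_network, seed=1)
        assert factors.loc["A", "biospecimen_count"] == 150
        assert list(factors.columns)[0] == "biospecimen_count"

    def test_needs_three_institutions(self, clean_network):
        with pytest.raises(ConfigError):
            syn.generate_factors(clean_network[:2], seed=1)

    def test_noiseless_relation_gives_unit_correlation(self, final_cat):
        sizes = {inst: n for inst, n in zip("ABCDEF", (100, 160, 220, 280, 340, 400))}
        config = syn.GeneratorConfig(
            institutions=tuple(sizes), records_per_institution=sizes
        )
        clean = syn.generate_clean(config, seed=21)
        relation = syn.FactorRelation(intercept=0, slope=0.05, sigma=0)
        model = syn.error_model_from_relation(sizes, relation, seed=22)
        out, _ = syn.inject_errors(clean, model, seed=23)
        vs = evaluate_catalog(final_cat, out)
        totals = [vs.per_institution[i] for i in sizes]
        r = pearson_correlation(list(sizes.values()), totals)
        assert r == pytest.approx(1.0, abs=0.02)

    def test_theoretical_r_formula(self):
        rel = syn.FactorRelation(intercept=5, slope=2.0, sigma=0)
        assert rel.theoretical_r([1, 2, 3]) == pytest.approx(1.0)
        flat = syn.FactorRelation(intercept=5, slope=0.0, sigma=3.0)
        assert flat.theoretical_r([1, 2, 3]) == 0.0
        rel2 = syn.FactorRelation(slope=1.0, sigma=1.0)
        n = np.array([1.0, 2.0, 3.0, 4.0])
        expected = np.std(n) / np.hypot(np.std(n), 1.0)
        assert rel2.theoretical_r(n) == pytest.approx(float(expected))

    def test_relation_recorded_in_attrs(self):
        sizes = {"A": 20, "B": 40, "C": 80}
        config = syn.GeneratorConfig(
            institutions=tuple(sizes), records_per_institution=sizes
        )
        network = syn.generate_clean(config, seed=31)
        rel = syn.FactorRelation(intercept=1, slope=0.5, sigma=0)
        factors = syn.generate_factors(network, relation=rel, seed=2)
        assert factors.attrs["theoretical_r"] == pytest.approx(1.0)
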