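import numpy as np
import pandas as pd
import pytest

from reference_impl import violating_rows

from biobank_dq import catalog as cat
from biobank_dq.engine import (
    ViolationSet,
    check_unique,
    duplicate_row_indices,
    evaluate_catalog,
    evaluate_rule,
)
from biobank_dq.errors import EngineError
from biobank_dq.schema import Dataset, make_table


def _dataset(schema, table_name, rows, institution="A"):
    table = {t.name: t for t in schema}[table_name]
    return Dataset(institution, {table_name: make_table(table, rows)})


def _rule(final_cat, rule_id):
    return {r.rule_id: r for r in final_cat}[rule_id]


class TestPredicates:
    def test_not_null_flags_missing_donor_id(self, schema, final_cat):
        ds = _dataset(schema, "basic_info", [{"KBN_Donor": None}, {"KBN_Donor": "A-1"}])
        out = evaluate_rule(_rule(final_cat, "CP-basic_info-KBN_Donor"), ds)
        assert len(out) == 1
        assert out[0].observed_value is None
        assert out[0].record_key == "row:0"  # null key falls back to row index

    @pytest.mark.parametrize(
        "value,expect",
        [
            ("19620318", 0),
            ("1962318", 1),   # 7 digits
            ("660307", 1),    # 6 digits
            ("19621340", 1),  # month 13
            ("20190229", 1),  # not a leap year
            ("20160229", 0),  # leap year
            ("18991231", 1),  # before the supported year window
            ("20210101", 1),  # after the collection year
            (None, 0),        # nulls belong to completeness
        ],
    )
    def test_date_format(self, schema, final_cat, value, expect):
        ds = _dataset(schema, "basic_info", [{"KBN_Donor": "A-1", "birthdate": value}])
        rule = _rule(final_cat, "VF-basic_info-birthdate")
        assert len(evaluate_rule(rule, ds)) == expect

    @pytest.mark.parametrize(
        "height,weight,expect",
        [("170", "65", 0), ("170", "65000.0", 1), ("60", "70", 1), (None, "65", 0)],
    )
    def test_height_must_exceed_weight(self, schema, final_cat, height, weight, expect):
        ds = _dataset(
            schema, "measurements",
            [{"KBN_Donor": "A-1", "height": height, "weight": weight}],
        )
        rule = _rule(final_cat, "VR-X-height_gt_weight")
        assert len(evaluate_rule(rule, ds)) == expect

    @pytest.mark.parametrize(
        "code,expect", [("?C21.49", 1), ("N80.0-1", 1), ("C18.9", 0), (None, 0)]
    )
    def test_code_membership_on_diagnosis(self, schema, final_cat, code, expect):
        ds = _dataset(
            schema, "basic_info", [{"KBN_Donor": "A-1", "diagnosis_code": code}]
        )
        rule = _rule(final_cat, "VF-basic_info-diagnosis_code")
        assert len(evaluate_rule(rule, ds)) == expect

    def test_birthdate_after_receipt_is_flagged(self, schema, final_cat):
        rule = _rule(final_cat, "AT-birthdate_before_receipt")
        late = _dataset(
            schema, "basic_info",
            [{"KBN_Donor": "A-1", "birthdate": "20201230", "receipt_date": "20200101"}],
        )
        ok = _dataset(
            schema, "basic_info",
            [{"KBN_Donor": "A-1", "birthdate": "19620318", "receipt_date": "20200101"}],
        )
        assert len(evaluate_rule(rule, late)) == 1
        assert len(evaluate_rule(rule, ok)) == 0

    def test_cancer_history_requires_type(self, schema, final_cat):
        rule = _rule(final_cat, "AB-FWD-DHCa")
        ds = _dataset(
            schema, "disease_history",
            [
                {"KBN_Donor": "A-1", "DHCa": "1", "DHCa1": None},
                {"KBN_Donor": "A-2", "DHCa": "1", "DHCa1": "C16"},
                {"KBN_Donor": "A-3", "DHCa": "0", "DHCa1": None},
            ],
        )
        out = evaluate_rule(rule, ds)
        assert [v.record_key for v in out] == ["A-1"]
        assert out[0].observed_value is None

    def test_cancer_type_without_history_fires_reverse_rule(self, schema, final_cat):
        rule = _rule(final_cat, "AB-REV-DHCa")
        ds = _dataset(
            schema, "disease_history",
            [
                {"KBN_Donor": "A-1", "DHCa": "0", "DHCa1": "C16"},   # contradiction
                {"KBN_Donor": "A-2", "DHCa": None, "DHCa1": "C16"},  # missing flag
                {"KBN_Donor": "A-3", "DHCa": "1", "DHCa1": "C16"},   # consistent
                {"KBN_Donor": "A-4", "DHCa": "0", "DHCa1": "0"},     # sentinel: no type
                {"KBN_Donor": "A-5", "DHCa": "9", "DHCa1": "C16"},   # not investigated
            ],
        )
        out = evaluate_rule(rule, ds)
        assert sorted(v.record_key for v in out) == ["A-1", "A-2"]
        # the violation is reported on the type field, whose value exists
        assert all(v.observed_value == "C16" for v in out)

    def test_applicability_restricts_other_cancer_rule(self, schema, final_cat):
        rule = _rule(final_cat, "AB-OTHER-DHCa_other")
        ds = _dataset(
            schema, "disease_history",
            [
                {"KBN_Donor": "A-1", "DHCa": "1", "DHCa1": "C97", "DHCa_other": None},
                {"KBN_Donor": "A-2", "DHCa": "9", "DHCa1": "C97", "DHCa_other": None},
                {"KBN_Donor": "A-3", "DHCa": "1", "DHCa1": "C97", "DHCa_other": "thymoma"},
            ],
        )
        assert [v.record_key for v in evaluate_rule(rule, ds)] == ["A-1"]

    def test_unparseable_number_is_format_not_range(self, schema, final_cat):
        ds = _dataset(
            schema, "measurements", [{"KBN_Donor": "A-1", "weight": "abc"}]
        )
        parse_rule = _rule(final_cat, "VF-measurements-weight")
        range_rule = _rule(final_cat, "VR-measurements-weight")
        assert len(evaluate_rule(parse_rule, ds)) == 1
        assert len(evaluate_rule(range_rule, ds)) == 0

    def test_null_precedence_only_completeness_fires(self, schema, final_cat):
        ds = _dataset(
            schema, "measurements",
            [{
                "KBN_Donor": "A-1", "height": "170.0", "weight": None,
                "sbp": "120", "dbp": "80", "waist": "82.0",
                "measure_date": "20200105", "measure_note": "routine",
            }],
        )
        firing = [
            r.rule_id
            for r in final_cat
            if r.target_table == "measurements" and evaluate_rule(r, ds)
        ]
        assert firing == ["CP-measurements-weight"]


class TestCheckUnique:
    @pytest.mark.parametrize(
        "keys,expected",
        [
            (["x", "y", "x"], 1),
            (["x", "x", "x"], 2),
            (["x", "y", "z"], 0),
            ([None, None, "x"], 0),  # null keys never form groups
        ],
    )
    def test_all_but_first_convention(self, schema, keys, expected):
        basic = {t.name: t for t in schema}["basic_info"]
        df = make_table(basic, [{"KBN_Donor": k} for k in keys])
        assert len(check_unique(("KBN_Donor",), df)) == expected

    def test_flags_later_occurrences(self, schema):
        basic = {t.name: t for t in schema}["basic_info"]
        df = make_table(basic, [{"KBN_Donor": k} for k in ["x", "y", "x", "x"]])
        assert duplicate_row_indices(("KBN_Donor",), df) == [2, 3]


class TestEvaluateCatalog:
    def test_empty_catalog_empty_set(self, clean_network):
        vs = evaluate_catalog([], clean_network)
        assert vs.total == 0
        assert set(vs.per_institution) == {"A", "B", "C", "D"}

    def test_additivity_across_institutions(self, schema, final_cat):
        rule = _rule(final_cat, "CP-basic_info-sex")
        rows = [{"KBN_Donor": f"{i}", "sex": None} for i in range(3)]
        ds1 = _dataset(schema, "basic_info", rows, institution="A")
        ds2 = _dataset(schema, "basic_info", rows, institution="B")
        vs = evaluate_catalog([rule], [ds1, ds2])
        assert vs.per_institution == {"A": 3, "B": 3}
        assert vs.total == 6

    def test_count_views_mutually_consistent(self, violations):
        vs = violations
        assert sum(vs.per_rule_counts.values()) == vs.total
        assert sum(vs.per_institution.values()) == vs.total
        assert sum(vs.per_rule_institution().values()) == vs.total

    def test_order_invariance(self, schema, final_cat, corrupted_network):
        datasets, _ = corrupted_network
        ds = datasets[0]
        rng = np.random.default_rng(5)
        shuffled = Dataset(
            ds.institution_id,
            {
                name: df.sample(frac=1, random_state=7).reset_index(drop=True)
                for name, df in ds.tables.items()
            },
        )
        a = evaluate_catalog(final_cat, ds)
        b = evaluate_catalog(final_cat, shuffled)
        cols = ["rule_id", "field", "observed_value", "dimension", "severity"]
        # identical violations up to record-key labels of null-keyed rows
        assert a.per_rule_counts == b.per_rule_counts
        left = a.frame[cols].sort_values(cols).reset_index(drop=True)
        right = b.frame[cols].sort_values(cols).reset_index(drop=True)
        pd.testing.assert_frame_equal(left, right)

    def test_missing_table_raises_engine_error(self, schema, final_cat):
        ds = Dataset("A", {})
        with pytest.raises(EngineError, match="basic_info"):
            evaluate_catalog([_rule(final_cat, "CP-basic_info-sex")], ds)

    def test_sorted_output(self, violations):
        f = violations.frame
        keys = list(zip(f["institution_id"], f["rule_id"], f["record_key"]))
        assert keys == sorted(keys)


class TestBruteForceOracle:
    """Per-record re-checking reproduces the vectorized engine exactly."""

    def test_corrupted_fixture_matches_reference(self, final_cat, corrupted_network):
        datasets, _ = corrupted_network
        ds = datasets[0]  # <= a few hundred records per table
        for rule in final_cat:
            df = ds.tables[rule.target_table]
            expected = violating_rows(rule, ds.records(rule.target_table))
            got = evaluate_rule(rule, ds)
            assert len(got) == len(expected), rule.rule_id
            # row identity, not just counts
            keys = {r.record_key for r in got}
            donor = df["KBN_Donor"]
            for i in expected:
                key = donor.iloc[i] if pd.notna(donor.iloc[i]) else f"row:{i}"
                assert key in keys, (rule.rule_id, i)

    def test_adversarial_values_match_reference(self, schema, final_cat):
        rng = np.random.default_rng(42)
        pool = [
            None, "", "0", "1", "2", "9", "C16", "C97", "?C21.49", "N80.0-1",
            "19620318", "1962318", "660307", "20200101", "20211301", "abc",
            "65", "65000.0", "-5", "170.5", "1.2.3", "+40", "12.",
        ]
        tables = {}
        for t in schema:
            rows = [
                {f.name: rng.choice(pool) for f in t.fields} for _ in range(60)
            ]
            rows = [
                {k: (None if v in (None, "") else str(v)) for k, v in r.items()}
                for r in rows
            ]
            tables[t.name] = make_table(t, rows)
        ds = Dataset("Z", tables)
        for rule in final_cat:
            expected = violating_rows(rule, ds.records(rule.target_table))
            got = evaluate_rule(rule, ds)
            assert len(got) == len(expected), rule.rule_id
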