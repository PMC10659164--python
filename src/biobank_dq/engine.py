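"""Vectorized evaluation of a rule catalog against per-institution datasets.

Null-precedence semantics: a missing value can only ever trip a completeness
(not-null) rule — or a conditional-presence rule when the null sits in the
consequent.  Format, range, parse, code and ordering predicates silently skip
nulls, and comparison predicates additionally skip values that do not parse,
so a single defective cell is never double-counted across dimensions by one
rule; distinct rules on the same cell (e.g. a format rule and a range rule)
count separately.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import Condition, RuleSpec
from .errors import EngineError, ExportError
from .schema import Dataset, TableSpec

_NUMERIC_RE = re.compile(r"[+-]?\d+(?:\.\d+)?")

_VIOLATION_COLUMNS = (
    "rule_id",
    "institution_id",
    "table",
    "record_key",
    "field",
    "observed_value",
    "dimension",
    "severity",
)


@dataclass(frozen=True)
class ViolationRecord:
    """One rule failure on one record."""

    rule_id: str
    institution_id: str
    table: str
    record_key: str
    field: str
    observed_value: str | None
    dimension: str
    severity: str


class ViolationSet:
    """All violations of one evaluation run, with consistent count views.

    Wraps a :class:`pandas.DataFrame` (one row per violation) and remembers
    every institution that was evaluated so that zero-violation institutions
    still appear in downstream reports.
    """

    def __init__(self, frame: pd.DataFrame, institution_ids: Sequence[str] = ()):
        if frame is None or len(frame) == 0:
            frame = pd.DataFrame(columns=list(_VIOLATION_COLUMNS))
        missing = set(_VIOLATION_COLUMNS) - set(frame.columns)
        if missing:
            raise EngineError(f"violation frame missing columns {sorted(missing)}")
        self.frame = frame[list(_VIOLATION_COLUMNS)].reset_index(drop=True)
        ids = set(institution_ids) | set(self.frame["institution_id"])
        self.institution_ids = tuple(sorted(ids))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def total(self) -> int:
        return len(self.frame)

    @property
    def violations(self) -> list[ViolationRecord]:
        return [
            ViolationRecord(
                rule_id=r.rule_id,
                institution_id=r.institution_id,
                table=r.table,
                record_key=r.record_key,
                field=r.field,
                observed_value=None if pd.isna(r.observed_value) else r.observed_value,
                dimension=r.dimension,
                severity=r.severity,
            )
            for r in self.frame.itertuples(index=False)
        ]

    @property
    def per_rule_counts(self) -> dict[str, int]:
        return self.frame["rule_id"].value_counts().to_dict()

    @property
    def per_institution(self) -> dict[str, int]:
        counts = self.frame["institution_id"].value_counts().to_dict()
        return {i: int(counts.get(i, 0)) for i in self.institution_ids}

    def per_rule_institution(self) -> dict[tuple[str, str], int]:
        """``{(institution_id, rule_id): count}`` — the ledger-comparison view."""
        g = self.frame.groupby(["institution_id", "rule_id"]).size()
        return {k: int(v) for k, v in g.items()}

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, encoding="utf-8")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ViolationSet":
        df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
        df = df.astype(object).where(lambda d: d != "", None)
        return cls(df)

    @classmethod
    def from_records(
        cls, records: Iterable[ViolationRecord], institution_ids: Sequence[str] = ()
    ) -> "ViolationSet":
        rows = [r.__dict__ for r in records]
        return cls(pd.DataFrame(rows, columns=list(_VIOLATION_COLUMNS)), institution_ids)


# ---------------------------------------------------------------------------
# value-level helpers (shared by predicates)
# ---------------------------------------------------------------------------

def _notna(col: pd.Series) -> pd.Series:
    return col.notna()


def numeric_valid_mask(col: pd.Series) -> pd.Series:
    """True where the raw string is a plain decimal number.

    The accepted grammar is deliberately narrow — optional sign, digits,
    optional fractional part — because clinical capture systems emit plain
    decimals; scientific notation or stray characters count as malformed.
    """
    s = col.astype("string")
    return s.str.fullmatch(_NUMERIC_RE.pattern).fillna(False).astype(bool)


def numeric_values(col: pd.Series) -> pd.Series:
    """Parsed floats where valid, NaN elsewhere."""
    valid = numeric_valid_mask(col)
    out = pd.Series(np.nan, index=col.index, dtype=float)
    if valid.any():
        out[valid] = col[valid].astype(float)
    return out


def date_valid_mask(
    col: pd.Series, min_year: int | None = None, max_year: int | None = None
) -> pd.Series:
    """True where the raw string is a real YYYYMMDD calendar date.

    Eight digits, month 1-12, real day-of-month including leap-year February;
    optionally the year must fall inside ``[min_year, max_year]``.
    """
    s = col.astype("string")
    eight = s.str.fullmatch(r"\d{8}").fillna(False).astype(bool)
    parsed = pd.to_datetime(s.where(eight), format="%Y%m%d", errors="coerce")
    ok = eight & parsed.notna()
    if min_year is not None:
        ok &= eight & (parsed.dt.year >= min_year).fillna(False)
    if max_year is not None:
        ok &= eight & (parsed.dt.year <= max_year).fillna(False)
    return ok.astype(bool)


def eval_condition(cond: Condition, df: pd.DataFrame) -> pd.Series:
    """Boolean mask of records satisfying a condition.

    ``eq``/``ne``/``in``/``not_in`` are never satisfied by a null value.
    """
    col = df[cond.field]
    nn = col.notna()
    if cond.op == "not_null":
        return nn
    if cond.op == "is_null":
        return ~nn
    if cond.op == "eq":
        return nn & (col == cond.value)
    if cond.op == "ne":
        return nn & (col != cond.value)
    if cond.op == "in":
        return nn & col.isin(cond.value)
    if cond.op == "not_in":
        return nn & ~col.isin(cond.value)
    raise EngineError(f"unsupported condition op {cond.op!r}")


_CMP = {
    "gt": np.greater,
    "ge": np.greater_equal,
    "lt": np.less,
    "le": np.less_equal,
}


def _rule_mask(rule: RuleSpec, df: pd.DataFrame) -> tuple[pd.Series, str, pd.Series]:
    """(violation mask, reported field name, observed values) for one table."""
    kind = rule.predicate.kind
    p = rule.predicate.params
    if kind == "not_null":
        col = df[p["field"]]
        return col.isna(), p["field"], col
    if kind == "numeric_parse":
        col = df[p["field"]]
        return _notna(col) & ~numeric_valid_mask(col), p["field"], col
    if kind == "range_check":
        col = df[p["field"]]
        v = numeric_values(col)
        mask = pd.Series(False, index=df.index)
        if p.get("min") is not None:
            mask |= v < float(p["min"])
        if p.get("max") is not None:
            mask |= v > float(p["max"])
        return mask.fillna(False).astype(bool), p["field"], col
    if kind == "date_format":
        col = df[p["field"]]
        ok = date_valid_mask(col, p.get("min_year"), p.get("max_year"))
        return _notna(col) & ~ok, p["field"], col
    if kind == "code_membership":
        col = df[p["field"]]
        return _notna(col) & ~col.isin(tuple(p["codes"])), p["field"], col
    if kind == "cross_field_compare":
        left, right = df[p["left"]], df[p["right"]]
        lv, rv = numeric_values(left), numeric_values(right)
        both = lv.notna() & rv.notna()
        cmp = _CMP.get(p["op"])
        if cmp is None:
            raise EngineError(f"rule {rule.rule_id}: unknown comparator {p['op']!r}")
        with np.errstate(invalid="ignore"):
            holds = pd.Series(cmp(lv.to_numpy(), rv.to_numpy()), index=df.index)
        field = rule.target_fields[0]
        return both & ~holds, field, df[field]
    if kind == "date_order":
        earlier, later = df[p["earlier"]], df[p["later"]]
        ok = date_valid_mask(earlier) & date_valid_mask(later)
        # YYYYMMDD strings compare chronologically
        mask = ok & (earlier > later)
        return mask.fillna(False).astype(bool), p["earlier"], earlier
    if kind == "conditional_presence":
        ante = eval_condition(p["antecedent"], df)
        consequent = df[p["consequent_field"]]
        return ante & consequent.isna(), p["consequent_field"], consequent
    if kind == "conditional_valid":
        ante = eval_condition(p["antecedent"], df)
        cons_ok = eval_condition(p["consequent"], df)
        field = p["antecedent"].field
        return ante & ~cons_ok, field, df[field]
    raise EngineError(f"rule {rule.rule_id}: unsupported predicate kind {kind!r}")


def _record_keys(df: pd.DataFrame, key_fields: Sequence[str]) -> pd.Series:
    """Key-field value(s) per record, falling back to the row index."""
    fallback = pd.Series([f"row:{i}" for i in range(len(df))], index=df.index, dtype=object)
    usable = [k for k in key_fields if k in df.columns]
    if not usable:
        return fallback
    parts = df[usable].astype(object)
    complete = parts.notna().all(axis=1)
    joined = parts.fillna("").astype(str).agg("|".join, axis=1)
    return joined.where(complete, fallback)


def _key_fields_for(
    table: str, df: pd.DataFrame, schema: Sequence[TableSpec] | None
) -> tuple[str, ...]:
    if schema is not None:
        for t in schema:
            if t.name == table:
                return tuple(t.key_fields)
    return ("KBN_Donor",) if "KBN_Donor" in df.columns else ()


# ---------------------------------------------------------------------------
# public evaluation API
# ---------------------------------------------------------------------------

def duplicate_row_indices(key_fields: Sequence[str], df: pd.DataFrame) -> list[int]:
    """Positional indices of records that duplicate an earlier key.

    Within each group of records sharing a non-null key, every record after
    the first (in row order) is flagged; records with any null key component
    never form groups.
    """
    if len(df) == 0 or not key_fields:
        return []
    parts = df[list(key_fields)]
    complete = parts.notna().all(axis=1)
    dup = parts.duplicated(keep="first") & complete
    return [i for i, d in enumerate(dup.to_numpy()) if d]


def check_unique(
    key_fields: Sequence[str],
    df: pd.DataFrame,
    rule: RuleSpec | None = None,
    institution_id: str = "",
    table: str = "",
) -> list[ViolationRecord]:
    """Duplicate-key violations under the all-but-first counting convention."""
    idx = duplicate_row_indices(key_fields, df)
    keys = _record_keys(df, key_fields)
    field = key_fields[0] if key_fields else ""
    return [
        ViolationRecord(
            rule_id=rule.rule_id if rule else "unique_key",
            institution_id=institution_id,
            table=rule.target_table if rule else table,
            record_key=keys.iloc[i],
            field=field,
            observed_value=df[field].iloc[i] if field else None,
            dimension=rule.dimension if rule else "uniqueness",
            severity=rule.severity if rule else "E",
        )
        for i in idx
    ]


def _evaluate_rule_frame(
    rule: RuleSpec, dataset: Dataset, schema: Sequence[TableSpec] | None
) -> pd.DataFrame:
    if rule.target_table not in dataset.tables:
        raise EngineError(
            f"rule {rule.rule_id}: table {rule.target_table!r} absent from "
            f"dataset {dataset.institution_id!r}"
        )
    df = dataset.tables[rule.target_table]
    if len(df) == 0:
        return pd.DataFrame(columns=list(_VIOLATION_COLUMNS))
    key_fields = _key_fields_for(rule.target_table, df, schema)

    if rule.predicate.kind == "unique_key":
        records = check_unique(
            tuple(rule.predicate.params["fields"]),
            df,
            rule=rule,
            institution_id=dataset.institution_id,
        )
        return pd.DataFrame(
            [r.__dict__ for r in records], columns=list(_VIOLATION_COLUMNS)
        )

    if rule.applicability is not None:
        applicable = eval_condition(rule.applicability, df)
    else:
        applicable = pd.Series(True, index=df.index)
    mask, field, observed = _rule_mask(rule, df)
    mask = mask & applicable
    if not mask.any():
        return pd.DataFrame(columns=list(_VIOLATION_COLUMNS))
    keys = _record_keys(df, key_fields)
    sel = mask.to_numpy()
    out = pd.DataFrame(
        {
            "rule_id": rule.rule_id,
            "institution_id": dataset.institution_id,
            "table": rule.target_table,
            "record_key": keys.to_numpy()[sel],
            "field": field,
            "observed_value": observed.astype(object).to_numpy()[sel],
            "dimension": rule.dimension,
            "severity": rule.severity,
        }
    )
    return out


def evaluate_rule(
    rule: RuleSpec, dataset: Dataset, schema: Sequence[TableSpec] | None = None
) -> list[ViolationRecord]:
    """Evaluate one rule on one institution; at most one violation per record."""
    frame = _evaluate_rule_frame(rule, dataset, schema)
    return ViolationSet(frame, [dataset.institution_id]).violations


def evaluate_catalog(
    catalog: Sequence[RuleSpec],
    datasets: Sequence[Dataset] | Dataset,
    schema: Sequence[TableSpec] | None = None,
) -> ViolationSet:
    """Evaluate every rule on every institution.

    Output is sorted by (institution, rule_id, record_key) so runs are
    reproducible regardless of input record order.
    """
    if isinstance(datasets, Dataset):
        datasets = [datasets]
    frames = []
    for ds in datasets:
        for rule in catalog:
            try:
                f = _evaluate_rule_frame(rule, ds, schema)
            except EngineError:
                raise
            except Exception as exc:  # attach rule context
                raise EngineError(
                    f"rule {rule.rule_id} failed on institution "
                    f"{ds.institution_id!r}: {exc}"
                ) from exc
            if len(f):
                frames.append(f)
    if frames:
        frame = pd.concat(frames, ignore_index=True)
        frame = frame.sort_values(
            ["institution_id", "rule_id", "record_key"], kind="stable"
        ).reset_index(drop=True)
    else:
        frame = pd.DataFrame(columns=list(_VIOLATION_COLUMNS))
    return ViolationSet(frame, [d.institution_id for d in datasets])


# ---------------------------------------------------------------------------
# SQL export
# ---------------------------------------------------------------------------

def _sql_quote(v: str) -> str:
    return "'" + str(v).replace("'", "''") + "'"


def _sql_numeric_valid(c: str) -> str:
    # plain decimal grammar, mirroring numeric_valid_mask
    return (
        f"(({c} GLOB '[0-9]*' OR {c} GLOB '[+-][0-9]*') "
        f"AND NOT {c} GLOB '*[^0-9.+-]*' "
        f"AND NOT SUBSTR({c}, 2) GLOB '*[+-]*' "
        f"AND NOT {c} GLOB '*.*.*' AND NOT {c} GLOB '*.')"
    )


def _sql_date_valid(c: str, min_year: int | None = None, max_year: int | None = None) -> str:
    y = f"CAST(SUBSTR({c}, 1, 4) AS INTEGER)"
    m = f"CAST(SUBSTR({c}, 5, 2) AS INTEGER)"
    d = f"CAST(SUBSTR({c}, 7, 2) AS INTEGER)"
    day_max = (
        f"(CASE WHEN {m} IN (1,3,5,7,8,10,12) THEN 31 "
        f"WHEN {m} IN (4,6,9,11) THEN 30 "
        f"WHEN ({y} % 4 = 0 AND {y} % 100 <> 0) OR {y} % 400 = 0 THEN 29 "
        f"ELSE 28 END)"
    )
    clauses = [
        f"LENGTH({c}) = 8",
        f"{c} GLOB '[0-9][0-9][0-9][0-9][0-9][0-9][0-9][0-9]'",
        f"{m} BETWEEN 1 AND 12",
        f"{d} BETWEEN 1 AND {day_max}",
    ]
    if min_year is not None:
        clauses.append(f"{y} >= {min_year}")
    if max_year is not None:
        clauses.append(f"{y} <= {max_year}")
    return "(" + " AND ".join(clauses) + ")"


def _sql_condition(cond: Condition) -> str:
    c = cond.field
    if cond.op == "not_null":
        return f"{c} IS NOT NULL"
    if cond.op == "is_null":
        return f"{c} IS NULL"
    if cond.op == "eq":
        return f"{c} = {_sql_quote(cond.value)}"
    if cond.op == "ne":
        return f"{c} <> {_sql_quote(cond.value)}"
    if cond.op == "in":
        return f"{c} IN ({', '.join(_sql_quote(v) for v in cond.value)})"
    if cond.op == "not_in":
        return f"{c} NOT IN ({', '.join(_sql_quote(v) for v in cond.value)})"
    raise ExportError(f"condition op {cond.op!r} not expressible")


def _sql_condition_bool(cond: Condition) -> str:
    """Three-valued-logic-safe truth test (null counts as not satisfied)."""
    return f"COALESCE(({_sql_condition(cond)}), 0)"


def export_rule_sql(rule: RuleSpec) -> str:
    """Emit a SELECT retrieving exactly the records the engine flags.

    The dialect is portable (tested against SQLite); ``unique_key`` uses the
    engine's all-but-first convention via a correlated minimum-rowid test.
    """
    t = rule.target_table
    kind = rule.predicate.kind
    p = rule.predicate.params
    if kind == "unique_key":
        c = tuple(p["fields"])[0]
        where = (
            f"{c} IS NOT NULL AND rowid > "
            f"(SELECT MIN(t2.rowid) FROM {t} t2 WHERE t2.{c} = {t}.{c})"
        )
    elif kind == "not_null":
        where = f"{p['field']} IS NULL"
    elif kind == "numeric_parse":
        c = p["field"]
        where = f"{c} IS NOT NULL AND NOT {_sql_numeric_valid(c)}"
    elif kind == "range_check":
        c = p["field"]
        bounds = []
        if p.get("min") is not None:
            bounds.append(f"CAST({c} AS REAL) < {float(p['min'])}")
        if p.get("max") is not None:
            bounds.append(f"CAST({c} AS REAL) > {float(p['max'])}")
        where = (
            f"{c} IS NOT NULL AND {_sql_numeric_valid(c)} "
            f"AND ({' OR '.join(bounds)})"
        )
    elif kind == "date_format":
        c = p["field"]
        where = (
            f"{c} IS NOT NULL AND NOT "
            f"{_sql_date_valid(c, p.get('min_year'), p.get('max_year'))}"
        )
    elif kind == "code_membership":
        c = p["field"]
        codes = ", ".join(_sql_quote(v) for v in p["codes"])
        where = f"{c} IS NOT NULL AND {c} NOT IN ({codes})"
    elif kind == "cross_field_compare":
        left, right, op = p["left"], p["right"], p["op"]
        sql_op = {"gt": ">", "ge": ">=", "lt": "<", "le": "<="}.get(op)
        if sql_op is None:
            raise ExportError(f"comparator {op!r} not expressible")
        where = (
            f"{left} IS NOT NULL AND {right} IS NOT NULL "
            f"AND {_sql_numeric_valid(left)} AND {_sql_numeric_valid(right)} "
            f"AND NOT (CAST({left} AS REAL) {sql_op} CAST({right} AS REAL))"
        )
    elif kind == "date_order":
        a, b = p["earlier"], p["later"]
        where = (
            f"{a} IS NOT NULL AND {b} IS NOT NULL "
            f"AND {_sql_date_valid(a)} AND {_sql_date_valid(b)} AND {a} > {b}"
        )
    elif kind == "conditional_presence":
        where = (
            f"{_sql_condition_bool(p['antecedent'])} "
            f"AND {p['consequent_field']} IS NULL"
        )
    elif kind == "conditional_valid":
        where = (
            f"{_sql_condition_bool(p['antecedent'])} "
            f"AND NOT {_sql_condition_bool(p['consequent'])}"
        )
    else:
        raise ExportError(f"predicate kind {kind!r} not expressible as a single SELECT")
    if rule.applicability is not None and kind != "unique_key":
        where = f"{_sql_condition_bool(rule.applicability)} AND ({where})"
    return f"SELECT * FROM {t} WHERE {where};"


def export_catalog_sql(catalog: Sequence[RuleSpec], directory: str | Path) -> None:
    """Write one ``<rule_id>.sql`` file per exportable rule."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rule in catalog:
        (directory / f"{rule.rule_id}.sql").write_text(
            f"-- {rule.description or rule.rule_id}\n{export_rule_sql(rule)}\n",
            encoding="utf-8",
        )
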