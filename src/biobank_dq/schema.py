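"""Biobank data model: tables, fields, code sets, plausible ranges.

The schema deliberately carries *no* value semantics at read time: every cell
is kept as a raw string (or null for an empty cell) so that defective values —
a six-digit birthdate, a weight recorded in grams, a ``?C21.49`` diagnosis
code — survive I/O intact and can be surfaced by validation rules rather than
destroyed by eager type coercion.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .errors import SchemaError, StructureError

VALUE_CLASSES = frozenset(
    {"coded-integer", "numeric", "date-YYYYMMDD", "code-string", "free-text"}
)

#: Conventional single-letter institution labels for a 16-site network.
DEFAULT_INSTITUTIONS = tuple("ABCDEFGHIJKLMNOP")


@dataclass(frozen=True)
class FieldSpec:
    """One column of one table.

    Parameters
    ----------
    name : str
        Column identifier (unique within its table).
    value_class : str
        One of ``coded-integer``, ``numeric``, ``date-YYYYMMDD``,
        ``code-string``, ``free-text``.  This drives which validity rules a
        catalog builder attaches to the field; it never drives parsing.
    unit : str
        Measurement unit for numeric fields (``cm``, ``kg``, ``mmHg``...).
    nullable : bool
        Whether the data model tolerates a missing value.  Completeness rules
        are generated for every field regardless; nullability documents which
        ones are *essential*.
    allowed_codes : frozenset of str, optional
        Enumerated code set; only for coded-integer / code-string fields.
    plausible_range : (float, float), optional
        Inclusive clinical plausibility bounds; only for numeric fields.
    """

    name: str
    value_class: str
    unit: str = ""
    nullable: bool = True
    allowed_codes: frozenset[str] | None = None
    plausible_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.value_class not in VALUE_CLASSES:
            raise SchemaError(
                f"field {self.name!r}: unknown value_class {self.value_class!r}"
            )
        if self.allowed_codes is not None:
            if self.value_class not in ("coded-integer", "code-string"):
                raise SchemaError(
                    f"field {self.name!r}: allowed_codes only valid for coded "
                    f"fields, not {self.value_class!r}"
                )
            object.__setattr__(self, "allowed_codes", frozenset(map(str, self.allowed_codes)))
        if self.plausible_range is not None:
            if self.value_class != "numeric":
                raise SchemaError(
                    f"field {self.name!r}: plausible_range only valid for "
                    f"numeric fields"
                )
            lo, hi = self.plausible_range
            if not lo <= hi:
                raise SchemaError(f"field {self.name!r}: range min > max")
            object.__setattr__(self, "plausible_range", (float(lo), float(hi)))


@dataclass(frozen=True)
class TableSpec:
    """One table of the relational schema."""

    name: str
    fields: tuple[FieldSpec, ...]
    key_fields: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        names = [f.name for f in self.fields]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"table {self.name!r}: duplicate field names {dupes}")
        missing = [k for k in self.key_fields if k not in names]
        if missing:
            raise SchemaError(f"table {self.name!r}: key fields {missing} not defined")

    @property
    def field_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.fields)

    @property
    def field_map(self) -> dict[str, FieldSpec]:
        return {f.name: f for f in self.fields}


@dataclass
class Dataset:
    """All tables of one institution, values as raw strings.

    ``tables`` maps table name to a :class:`pandas.DataFrame` of object dtype
    whose cells are either python strings or null (``None``/``NaN``).
    """

    institution_id: str
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def n_records(self, table: str) -> int:
        return len(self.tables[table])

    def records(self, table: str) -> list[dict[str, str | None]]:
        """Row dicts with ``None`` for nulls (convenience / oracle view)."""
        df = self.tables[table]
        out = []
        for row in df.itertuples(index=False):
            out.append(
                {c: (None if pd.isna(v) else v) for c, v in zip(df.columns, row)}
            )
        return out


def _field_from_mapping(raw: Mapping, context: str) -> FieldSpec:
    try:
        rng = raw.get("plausible_range")
        return FieldSpec(
            name=str(raw["name"]),
            value_class=str(raw["value_class"]),
            unit=str(raw.get("unit", "")),
            nullable=bool(raw.get("nullable", True)),
            allowed_codes=(
                frozenset(map(str, raw["allowed_codes"]))
                if raw.get("allowed_codes") is not None
                else None
            ),
            plausible_range=tuple(rng) if rng is not None else None,
        )
    except KeyError as exc:
        raise SchemaError(f"{context}: field definition missing key {exc}") from exc


def schema_from_mapping(raw: Mapping) -> list[TableSpec]:
    """Build a schema from a parsed YAML/JSON mapping ``{"tables": [...]}``."""
    if not isinstance(raw, Mapping) or "tables" not in raw:
        raise SchemaError("schema config must be a mapping with a 'tables' list")
    tables = []
    for t in raw["tables"] or []:
        context = f"table {t.get('name', '?')!r}"
        fields = tuple(_field_from_mapping(f, context) for f in t.get("fields", []))
        tables.append(
            TableSpec(
                name=str(t["name"]),
                fields=fields,
                key_fields=tuple(t.get("key_fields", ())),
            )
        )
    names = [t.name for t in tables]
    if len(names) != len(set(names)):
        raise SchemaError("duplicate table names in schema")
    return tables


def load_schema(config_path: str | Path) -> list[TableSpec]:
    """Read a schema from a YAML file.

    Raises :class:`SchemaError` naming the offending path on malformed input.
    """
    path = Path(config_path)
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except (OSError, yaml.YAMLError) as exc:
        raise SchemaError(f"cannot parse schema config {path}: {exc}") from exc
    try:
        return schema_from_mapping(raw)
    except SchemaError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def default_schema() -> list[TableSpec]:
    """The built-in five-table biobank schema (54 fields)."""
    ref = importlib.resources.files("biobank_dq.data") / "default_schema.yaml"
    return schema_from_mapping(yaml.safe_load(ref.read_text(encoding="utf-8")))


def schema_to_mapping(schema: Iterable[TableSpec]) -> dict:
    tables = []
    for t in schema:
        fields = []
        for f in t.fields:
            d: dict = {"name": f.name, "value_class": f.value_class}
            if f.unit:
                d["unit"] = f.unit
            if not f.nullable:
                d["nullable"] = False
            if f.allowed_codes is not None:
                d["allowed_codes"] = sorted(f.allowed_codes)
            if f.plausible_range is not None:
                d["plausible_range"] = list(f.plausible_range)
            fields.append(d)
        tables.append(
            {"name": t.name, "key_fields": list(t.key_fields), "fields": fields}
        )
    return {"tables": tables}


def save_schema(schema: Iterable[TableSpec], path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(schema_to_mapping(schema), sort_keys=False), encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# dataset I/O — one CSV per table under one directory per institution
# ---------------------------------------------------------------------------

def _normalise_frame(df: pd.DataFrame, table: TableSpec) -> pd.DataFrame:
    got, want = list(df.columns), list(table.field_names)
    if set(got) != set(want):
        missing = sorted(set(want) - set(got))
        extra = sorted(set(got) - set(want))
        raise StructureError(
            f"table {table.name!r}: header mismatch "
            f"(missing columns {missing}, extra columns {extra})"
        )
    df = df[want].astype(object)
    # empty string cells are nulls; everything else stays verbatim
    return df.where(df.notna() & (df != ""), None)


def make_table(table: TableSpec, rows: Iterable[Mapping[str, str | None]]) -> pd.DataFrame:
    """Build a schema-conformant raw-string table from row mappings."""
    rows = list(rows)
    df = pd.DataFrame(rows, columns=list(table.field_names), dtype=object)
    return _normalise_frame(df, table)


def read_dataset(
    directory: str | Path,
    schema: list[TableSpec],
    institution_id: str | None = None,
) -> Dataset:
    """Read one institution's tables (``<table>.csv`` each) from a directory.

    Content is never judged here: malformed dates, impossible weights and
    unknown codes are read verbatim.  Only missing files and header
    mismatches raise.
    """
    directory = Path(directory)
    if institution_id is None:
        institution_id = directory.name
    tables: dict[str, pd.DataFrame] = {}
    for t in schema:
        path = directory / f"{t.name}.csv"
        if not path.exists():
            raise StructureError(f"missing table file for {t.name!r}: {path}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
        tables[t.name] = _normalise_frame(df, t)
    return Dataset(institution_id=institution_id, tables=tables)


def write_dataset(dataset: Dataset, directory: str | Path) -> None:
    """Write one CSV per table; nulls become empty cells."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, df in dataset.tables.items():
        out = df.fillna("")
        out.to_csv(directory / f"{name}.csv", index=False, encoding="utf-8")


def dataset_summary(dataset: Dataset) -> pd.DataFrame:
    """Per-table record and null counts (the ``inspect`` CLI surface)."""
    rows = []
    for name, df in dataset.tables.items():
        rows.append(
            {
                "table": name,
                "records": len(df),
                "fields": df.shape[1],
                "null_cells": int(df.isna().sum().sum()),
            }
        )
    return pd.DataFrame(rows, columns=["table", "records", "fields", "null_cells"])
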