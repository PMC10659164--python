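"""Synthetic multi-institution biobank data with controlled error injection.

The generator emulates the study conditions of a 16-site biobank network
submitting clinical-epidemiological tables for one collection year: a default
of 16 institutions labelled A-P with about a thousand donors each (the full
network scale of ~55k donors is reachable through configuration).  Clean data
satisfies *every* rule of both the pre-review and the final catalog by
construction, so that each injected corruption maps to a known set of rules
and the engine's detections can be compared with the injection ledger
*exactly*.

Injected error families mirror the defect types observed in real multicenter
submissions:

1. nulls in essential fields (donor ID, sex, disease-history flag, drinking
   items);
2. malformed dates (``19620318`` truncated to ``620318`` or ``1962318``) and
   undefined codes (``?C21.49``-style prefix or ``-1`` suffix on a diagnosis
   code);
3. unit errors (weight entered in grams, i.e. x1000, yielding values far
   above any plausible kilogram weight) and logical contradictions (a
   concrete cancer type recorded while the history flag says "no history");
4. duplicated donor identifiers.

Each corruption touches exactly one field of one record and no record is
corrupted twice, so ledger-vs-detection equality is exact.  A unit error is
expected to trip both the weight plausibility rule and the height-vs-weight
comparison rule; the ledger records both, keeping the equality exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import RuleSpec, final_catalog
from .engine import ViolationSet, evaluate_catalog
from .errors import ConfigError, InjectionError
from .schema import DEFAULT_INSTITUTIONS, Dataset, TableSpec, default_schema
from .stats import DEFAULT_FACTOR_NAMES, pearson_correlation

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_OCCUPATIONS = (
    "office worker", "farmer", "teacher", "retired", "self-employed",
    "healthcare worker", "student", "unemployed",
)
_FAMILY_HISTORY = (
    "none", "father: hypertension", "mother: diabetes", "sibling: cancer",
    "none reported",
)
_SPECIMEN_NOTES = ("serum", "plasma", "buffy coat", "tissue")
_MEASURE_NOTES = ("routine", "re-measured", "fasting")
_LAB_NOTES = ("normal run", "repeat run", "fasting sample")
_LIFESTYLE_NOTES = ("self-reported", "interview", "questionnaire")
_OTHER_CANCER_TEXT = ("thymoma", "soft-tissue sarcoma", "carcinoid tumour")

#: concrete cancer-type codes (excludes the sentinels 0/9 and the
#: "other cancer" code C97, which requires accompanying free text).
_CANCER_CODES = ("C16", "C18", "C21", "C22", "C34", "C50", "C61", "C73")


@dataclass(frozen=True)
class GeneratorConfig:
    """Clean-data generation parameters.

    Record counts and clinical distributions default to desk-scale study
    conditions: 16 institutions x 1000 donors, adult anthropometrics within
    the schema's plausibility ranges, one collection year (2020).
    """

    institutions: tuple[str, ...] = DEFAULT_INSTITUTIONS
    records_per_institution: int | Mapping[str, int] = 1000
    birth_year_range: tuple[int, int] = (1930, 2002)
    receipt_year: int = 2020
    sex_probs: tuple[float, float] = (0.48, 0.52)
    height_mean_sd: tuple[float, float] = (163.0, 9.0)
    weight_mean_sd: tuple[float, float] = (63.0, 11.0)
    sbp_mean_sd: tuple[float, float] = (125.0, 15.0)
    pulse_pressure_mean_sd: tuple[float, float] = (42.0, 8.0)
    waist_mean_sd: tuple[float, float] = (82.0, 10.0)
    total_protein_mean_sd: tuple[float, float] = (7.2, 0.5)
    glucose_mean_sd: tuple[float, float] = (105.0, 25.0)
    #: P(flag=1), P(flag=9 'not investigated') for each disease-history item
    disease_prevalence: float = 0.15
    not_investigated_rate: float = 0.05
    second_cancer_rate: float = 0.10
    other_cancer_rate: float = 0.08  # P(type = C97 | cancer history)
    drink_probs: tuple[float, float, float] = (0.45, 0.45, 0.10)  # codes 0/1/9

    def n_records(self, institution: str) -> int:
        if isinstance(self.records_per_institution, Mapping):
            return int(self.records_per_institution[institution])
        return int(self.records_per_institution)

    def validate(self) -> None:
        if not self.institutions:
            raise ConfigError("at least one institution required")
        if len(set(self.institutions)) != len(self.institutions):
            raise ConfigError("duplicate institution labels")
        for inst in self.institutions:
            if self.n_records(inst) < 0:
                raise ConfigError(f"negative record count for {inst!r}")
        if not 1900 <= self.birth_year_range[0] <= self.birth_year_range[1]:
            raise ConfigError("birth_year_range outside supported window")
        if self.birth_year_range[1] >= self.receipt_year:
            raise ConfigError("birth years must precede the receipt year")
        for p in (self.disease_prevalence, self.not_investigated_rate,
                  self.second_cancer_rate, self.other_cancer_rate):
            if not 0 <= p <= 1:
                raise ConfigError("probabilities must lie in [0, 1]")
        if abs(sum(self.drink_probs) - 1) > 1e-9 or abs(sum(self.sex_probs) - 1) > 1e-9:
            raise ConfigError("probability vectors must sum to 1")


# ---------------------------------------------------------------------------
# clean generation
# ---------------------------------------------------------------------------

def _date_strings(ts: pd.Series) -> np.ndarray:
    return ts.dt.strftime("%Y%m%d").to_numpy(dtype=object)


def _uniform_dates(rng, year_lo: int, year_hi: int, n: int) -> pd.Series:
    start = pd.Timestamp(year=year_lo, month=1, day=1)
    end = pd.Timestamp(year=year_hi, month=12, day=31)
    span = (end - start).days
    offs = rng.integers(0, span + 1, n)
    return pd.Series(start) .repeat(n).reset_index(drop=True) + pd.to_timedelta(offs, "D")


def _fmt(arr: np.ndarray, decimals: int) -> np.ndarray:
    return np.array([f"{v:.{decimals}f}" if decimals else f"{v:.0f}" for v in arr],
                    dtype=object)


def _generate_institution(
    inst: str, n: int, config: GeneratorConfig, rng: np.random.Generator,
    schema: Sequence[TableSpec],
) -> Dataset:
    tables: dict[str, pd.DataFrame] = {}
    donor = np.array([f"{inst}-{i:06d}" for i in range(n)], dtype=object)

    # --- basic information -------------------------------------------------
    birth = _uniform_dates(rng, *config.birth_year_range, n)
    receipt = _uniform_dates(rng, config.receipt_year, config.receipt_year, n)
    diag_off = rng.random(n)
    diagnosis = birth + pd.to_timedelta(
        np.floor(diag_off * (receipt - birth).dt.days.to_numpy()), "D"
    )
    codes = {t.name: t.field_map for t in schema}
    dx_codes = sorted(codes["basic_info"]["diagnosis_code"].allowed_codes)
    basic = pd.DataFrame(
        {
            "KBN_Donor": donor,
            "sex": rng.choice(["1", "2"], n, p=config.sex_probs),
            "birthdate": _date_strings(birth),
            "receipt_date": _date_strings(receipt),
            "residence_code": rng.integers(1, 18, n).astype(str).astype(object),
            "disease_group": rng.integers(1, 27, n).astype(str).astype(object),
            "diagnosis_code": rng.choice(dx_codes, n),
            "diagnosis_date": _date_strings(diagnosis),
            "marital_status": rng.choice(["1", "2", "3", "4", "9"], n),
            "education_level": rng.choice(["1", "2", "3", "4", "5", "9"], n),
            "insurance_type": rng.choice(["1", "2", "3", "9"], n),
            "occupation_text": rng.choice(_OCCUPATIONS, n),
            "family_history_text": rng.choice(_FAMILY_HISTORY, n),
            "specimen_note": rng.choice(_SPECIMEN_NOTES, n),
        },
        dtype=object,
    )
    tables["basic_info"] = basic

    # --- physical measurements ----------------------------------------------
    h_m, h_s = config.height_mean_sd
    w_m, w_s = config.weight_mean_sd
    s_m, s_s = config.sbp_mean_sd
    pp_m, pp_s = config.pulse_pressure_mean_sd
    wa_m, wa_s = config.waist_mean_sd
    height = np.clip(rng.normal(h_m, h_s, n), 140, 200)
    weight = np.clip(rng.normal(w_m, w_s, n), 35, 120)
    sbp = np.clip(rng.normal(s_m, s_s, n), 90, 200)
    dbp = np.clip(sbp - np.clip(rng.normal(pp_m, pp_s, n), 10, 70), 40, None)
    waist = np.clip(rng.normal(wa_m, wa_s, n), 55, 130)
    measure = receipt - pd.to_timedelta(rng.integers(0, 31, n), "D")
    tables["measurements"] = pd.DataFrame(
        {
            "KBN_Donor": donor,
            "height": _fmt(height, 1),
            "weight": _fmt(weight, 1),
            "sbp": _fmt(sbp, 0),
            "dbp": _fmt(dbp, 0),
            "waist": _fmt(waist, 1),
            "measure_date": _date_strings(measure),
            "measure_note": rng.choice(_MEASURE_NOTES, n),
        },
        dtype=object,
    )

    # --- disease history -----------------------------------------------------
    from .catalog import DISEASE_PAIRS

    dh: dict[str, np.ndarray] = {"KBN_Donor": donor}
    p1, p9 = config.disease_prevalence, config.not_investigated_rate
    flag_probs = [1 - p1 - p9, p1, p9]
    details: dict[str, np.ndarray] = {}
    for flag_name, detail_name in DISEASE_PAIRS:
        flags = rng.choice(["0", "1", "9"], n, p=flag_probs)
        detail = np.where(flags == "0", "0", "9").astype(object)
        present = flags == "1"
        k = int(present.sum())
        if detail_name == "DHCa1":
            real = rng.choice(_CANCER_CODES + ("C97",), k,
                              p=[(1 - config.other_cancer_rate) / len(_CANCER_CODES)]
                              * len(_CANCER_CODES) + [config.other_cancer_rate])
        else:
            real = rng.choice(["1", "2", "3"], k)
        detail[present] = real
        dh[flag_name] = flags
        details[detail_name] = detail
    dh["DHCa1"] = details.pop("DHCa1")
    # second cancer type: only for donors with a cancer history
    ca_present = dh["DHCa"] == "1"
    second = ca_present & (rng.random(n) < config.second_cancer_rate)
    dhca2 = np.full(n, "0", dtype=object)
    dhca2[second] = rng.choice(_CANCER_CODES, int(second.sum()))
    dh["DHCa2"] = dhca2
    for flag_name, detail_name in DISEASE_PAIRS[1:]:
        dh[detail_name] = details[detail_name]
    other = np.array(rng.choice(_OTHER_CANCER_TEXT, n), dtype=object)
    dh["DHCa_other"] = np.where(dh["DHCa1"] == "C97", other, "none").astype(object)
    order = [f.name for f in {t.name: t for t in schema}["disease_history"].fields]
    tables["disease_history"] = pd.DataFrame(dh, dtype=object)[order]

    # --- laboratory ----------------------------------------------------------
    tp = np.clip(rng.normal(*config.total_protein_mean_sd, n), 5.0, 9.0)
    glu = np.clip(rng.normal(*config.glucose_mean_sd, n), 60, 400)
    tables["lab"] = pd.DataFrame(
        {
            "KBN_Donor": donor,
            "total_protein": _fmt(tp, 1),
            "glucose": _fmt(glu, 0),
            "lab_note": rng.choice(_LAB_NOTES, n),
        },
        dtype=object,
    )

    # --- lifestyle -----------------------------------------------------------
    tables["lifestyle"] = pd.DataFrame(
        {
            "KBN_Donor": donor,
            "DR_A": rng.choice(["0", "1", "9"], n, p=config.drink_probs),
            "DR_B": rng.choice(["0", "1", "9"], n, p=config.drink_probs),
            "SM_A": rng.choice(["0", "1", "9"], n, p=config.drink_probs),
            "lifestyle_note": rng.choice(_LIFESTYLE_NOTES, n),
        },
        dtype=object,
    )
    for t in schema:
        if t.name not in tables:
            tables[t.name] = pd.DataFrame(
                {f.name: pd.Series(dtype=object) for f in t.fields}
            )
    return Dataset(institution_id=inst, tables=tables)


def generate_clean(
    config: GeneratorConfig | None = None,
    seed: int = 0,
    schema: Sequence[TableSpec] | None = None,
) -> list[Dataset]:
    """Generate rule-clean datasets, bit-reproducible from (config, seed)."""
    config = config or GeneratorConfig()
    config.validate()
    schema = schema or default_schema()
    out = []
    for i, inst in enumerate(config.institutions):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        out.append(_generate_institution(inst, config.n_records(inst), config, rng, schema))
    return out


# ---------------------------------------------------------------------------
# error injection
# ---------------------------------------------------------------------------

#: essential-field null targets: field -> (table, completeness rule id)
NULL_TARGETS: dict[str, tuple[str, str]] = {
    "KBN_Donor": ("basic_info", "CP-basic_info-KBN_Donor"),
    "sex": ("basic_info", "CP-basic_info-sex"),
    "DHCa": ("disease_history", "CP-disease_history-DHCa"),
    "DR_A": ("lifestyle", "CP-lifestyle-DR_A"),
    "DR_B": ("lifestyle", "CP-lifestyle-DR_B"),
}

RULE_DATE_MALFORM = "VF-basic_info-birthdate"
RULE_CODE_MALFORM = "VF-basic_info-diagnosis_code"
RULE_UNIT_RANGE = "VR-measurements-weight"
RULE_UNIT_CROSS = "VR-X-height_gt_weight"
RULE_LOGIC = "AB-REV-DHCa"
RULE_DUPLICATE = "UQ-basic_info-KBN_Donor"

_RATE_KINDS = (
    "null_rate",
    "date_malform_rate",
    "code_malform_rate",
    "unit_error_rate",
    "logic_error_rate",
    "duplicate_rate",
)

Rate = float | Mapping[str, float]


@dataclass(frozen=True)
class ErrorModel:
    """Per-error-type injection rates (fraction of records per institution).

    Each rate may be a scalar (applied everywhere) or a mapping from
    institution label to rate.  ``null_fields`` lists the essential fields
    eligible for null injection; each null event picks one of them at random.
    """

    null_rate: Rate = 0.0
    date_malform_rate: Rate = 0.0
    code_malform_rate: Rate = 0.0
    unit_error_rate: Rate = 0.0
    logic_error_rate: Rate = 0.0
    duplicate_rate: Rate = 0.0
    null_fields: tuple[str, ...] = tuple(NULL_TARGETS)

    def rate(self, kind: str, institution: str) -> float:
        v = getattr(self, kind)
        r = float(v.get(institution, 0.0)) if isinstance(v, Mapping) else float(v)
        if not 0 <= r <= 1:
            raise ConfigError(f"{kind} for {institution!r} outside [0, 1]")
        return r

    def validate(self, institutions: Sequence[str]) -> None:
        for kind in _RATE_KINDS:
            for inst in institutions:
                self.rate(kind, inst)
        unknown = set(self.null_fields) - set(NULL_TARGETS)
        if unknown:
            raise ConfigError(f"unsupported null-injection fields {sorted(unknown)}")


class GroundTruthLedger:
    """Per-(institution, rule) injected-violation counts.

    ``compare`` checks the central recovery property: for every institution
    and rule, the number of detected violations equals the number the
    generator injected — both directions, zero tolerance.
    """

    def __init__(self, counts: Mapping[tuple[str, str], int] | None = None):
        self.counts: dict[tuple[str, str], int] = dict(counts or {})

    def increment(self, institution: str, rule_id: str, by: int = 1) -> None:
        key = (institution, rule_id)
        self.counts[key] = self.counts.get(key, 0) + by

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def frame(self) -> pd.DataFrame:
        rows = [
            {"institution": i, "rule_id": r, "injected_count": c}
            for (i, r), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["institution", "rule_id", "injected_count"])

    def compare(self, vs: ViolationSet) -> pd.DataFrame:
        """Mismatch table between ledger and detected counts (empty = exact)."""
        detected = vs.per_rule_institution()
        keys = set(self.counts) | set(detected)
        rows = [
            {
                "institution": i,
                "rule_id": r,
                "injected": self.counts.get((i, r), 0),
                "detected": detected.get((i, r), 0),
            }
            for (i, r) in sorted(keys)
        ]
        df = pd.DataFrame(rows, columns=["institution", "rule_id", "injected", "detected"])
        return df[df["injected"] != df["detected"]].reset_index(drop=True)

    def matches(self, vs: ViolationSet) -> bool:
        return len(self.compare(vs)) == 0

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, encoding="utf-8")

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroundTruthLedger":
        df = pd.read_csv(path)
        return cls(
            {
                (str(r.institution), str(r.rule_id)): int(r.injected_count)
                for r in df.itertuples(index=False)
            }
        )


def _take_sites(
    rng: np.random.Generator,
    eligible: np.ndarray,
    used: set[int],
    count: int,
    what: str,
    inst: str,
) -> list[int]:
    pool = np.array([i for i in eligible if i not in used], dtype=int)
    if count > len(pool):
        raise InjectionError(
            f"institution {inst}: {what} needs {count} sites, only "
            f"{len(pool)} uncorrupted records available"
        )
    picked = rng.choice(pool, size=count, replace=False) if count else np.array([], int)
    used.update(int(i) for i in picked)
    return [int(i) for i in picked]


def inject_errors(
    datasets: Sequence[Dataset],
    model: ErrorModel,
    seed: int = 0,
) -> tuple[list[Dataset], GroundTruthLedger]:
    """Corrupt clean datasets according to the error model.

    Injection counts are deterministic — ``round(rate * n_records)`` per type
    and institution — while sites are drawn without replacement from records
    not yet corrupted in that table.  Raises :class:`InjectionError` when a
    rate demands more sites than remain.
    """
    model.validate([d.institution_id for d in datasets])
    ledger = GroundTruthLedger()
    corrupted: list[Dataset] = []
    for d_idx, ds in enumerate(datasets):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 104729, d_idx]))
        tables = {name: df.copy() for name, df in ds.tables.items()}
        inst = ds.institution_id
        n = len(tables["basic_info"])
        used: dict[str, set[int]] = {name: set() for name in tables}

        def count_for(kind: str) -> int:
            return int(round(model.rate(kind, inst) * n))

        # 1) nulls in essential fields
        n_null = count_for("null_rate")
        fields = rng.choice(np.array(model.null_fields, dtype=object), n_null)
        for fname, k in zip(*np.unique(fields, return_counts=True)):
            table, rule_id = NULL_TARGETS[str(fname)]
            df = tables[table]
            if fname == "DHCa":
                # restrict to records without a concrete cancer type, so the
                # null trips only the completeness rule
                eligible = np.flatnonzero(df["DHCa1"].isin(("0", "9")).to_numpy())
            else:
                eligible = np.arange(len(df))
            rows = _take_sites(rng, eligible, used[table], int(k),
                               f"null({fname})", inst)
            df.iloc[rows, df.columns.get_loc(str(fname))] = None
            ledger.increment(inst, rule_id, int(k))

        # 2a) malformed birthdates (6-digit YYMMDD or 7-digit forms)
        df = tables["basic_info"]
        rows = _take_sites(rng, np.arange(len(df)), used["basic_info"],
                           count_for("date_malform_rate"), "date_malform", inst)
        col = df.columns.get_loc("birthdate")
        for i in rows:
            s = df.iat[i, col]
            df.iat[i, col] = s[2:] if rng.random() < 0.5 else s[:4] + s[5:]
        ledger.increment(inst, RULE_DATE_MALFORM, len(rows))

        # 2b) undefined diagnosis codes (prefix '?' or suffix '-1')
        rows = _take_sites(rng, np.arange(len(df)), used["basic_info"],
                           count_for("code_malform_rate"), "code_malform", inst)
        col = df.columns.get_loc("diagnosis_code")
        for i in rows:
            s = df.iat[i, col]
            df.iat[i, col] = "?" + s if rng.random() < 0.5 else s + "-1"
        ledger.increment(inst, RULE_CODE_MALFORM, len(rows))

        # 3a) weight unit errors: kg -> g (x1000); trips the plausibility
        # range rule and the height>weight comparison rule
        mdf = tables["measurements"]
        rows = _take_sites(rng, np.arange(len(mdf)), used["measurements"],
                           count_for("unit_error_rate"), "unit_error", inst)
        col = mdf.columns.get_loc("weight")
        for i in rows:
            mdf.iat[i, col] = f"{float(mdf.iat[i, col]) * 1000:.1f}"
        ledger.increment(inst, RULE_UNIT_RANGE, len(rows))
        ledger.increment(inst, RULE_UNIT_CROSS, len(rows))

        # 3b) logical errors: concrete cancer type while the history flag
        # records no cancer history
        hdf = tables["disease_history"]
        eligible = np.flatnonzero((hdf["DHCa"] == "0").to_numpy())
        rows = _take_sites(rng, eligible, used["disease_history"],
                           count_for("logic_error_rate"), "logic_error", inst)
        col = hdf.columns.get_loc("DHCa1")
        for i in rows:
            hdf.iat[i, col] = str(rng.choice(_CANCER_CODES))
        ledger.increment(inst, RULE_LOGIC, len(rows))

        # 4) duplicate donor identifiers: copy an existing ID onto another
        # record (distinct source/target pairs, so each copy adds exactly one
        # duplicate under the all-but-first counting convention)
        n_dup = count_for("duplicate_rate")
        rows = _take_sites(rng, np.arange(len(df)), used["basic_info"],
                           2 * n_dup, "duplicate", inst)
        col = df.columns.get_loc("KBN_Donor")
        for src, tgt in zip(rows[:n_dup], rows[n_dup:]):
            df.iat[tgt, col] = df.iat[src, col]
        ledger.increment(inst, RULE_DUPLICATE, n_dup)

        corrupted.append(Dataset(institution_id=inst, tables=tables))
    # drop all-zero ledger cells (rates of zero leave no trace)
    ledger.counts = {k: v for k, v in ledger.counts.items() if v > 0}
    return corrupted, ledger


def default_error_model(institutions: Sequence[str] = DEFAULT_INSTITUTIONS) -> ErrorModel:
    """Mixed per-institution rates emulating a heterogeneous network.

    Site quality varies by an order of magnitude and one site (the 13th,
    i.e. M under default labels) submits flawless data.
    """
    scales = (0.5, 1.5, 0.2, 2.0, 1.0, 3.0, 0.1, 1.2,
              0.8, 0.3, 0.05, 0.6, 0.0, 1.8, 0.9, 0.15)
    base = {
        "null_rate": 0.010,
        "date_malform_rate": 0.008,
        "code_malform_rate": 0.006,
        "unit_error_rate": 0.004,
        "logic_error_rate": 0.004,
        "duplicate_rate": 0.002,
    }
    rates = {
        kind: {
            inst: min(b * scales[i % len(scales)], 0.2)
            for i, inst in enumerate(institutions)
        }
        for kind, b in base.items()
    }
    return ErrorModel(**rates)


# ---------------------------------------------------------------------------
# institutional factors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FactorRelation:
    """Stated linear construction of per-institution error burdens:
    ``errors_i = intercept + slope * biospecimen_count_i + N(0, sigma)``."""

    intercept: float = 0.0
    slope: float = 0.0
    sigma: float = 0.0

    def theoretical_r(self, record_counts: Sequence[int]) -> float:
        """Population correlation implied by the construction for a fixed
        design of biospecimen counts."""
        n = np.asarray(record_counts, dtype=float)
        sx = float(np.std(n))
        denom = np.hypot(self.slope * sx, self.sigma)
        if denom == 0:
            return 0.0
        return float(self.slope * sx / denom)


def error_model_from_relation(
    record_counts: Mapping[str, int],
    relation: FactorRelation,
    seed: int = 0,
) -> ErrorModel:
    """Error model whose per-institution *total* injections follow the stated
    linear function of biospecimen count (all injections as essential nulls)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 271828]))
    rates = {}
    for inst, n in record_counts.items():
        target = relation.intercept + relation.slope * n + rng.normal(0, relation.sigma)
        rates[inst] = float(np.clip(target / max(n, 1), 0.0, 0.9))
    return ErrorModel(null_rate=rates)


def generate_factors(
    datasets: Sequence[Dataset],
    ledger: GroundTruthLedger | None = None,
    relation: FactorRelation | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Institutional-factors table for the generated network.

    ``biospecimen_count`` is each institution's basic-table record count; the
    remaining factor slots are drawn from plausible survey distributions.
    When ``relation`` is given (the error burdens were constructed from the
    biospecimen counts), its implied correlation is attached as frame
    metadata under ``attrs["theoretical_r"]``.
    """
    if len(datasets) < 3:
        raise ConfigError("factors need at least 3 institutions")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 314159]))
    rows = {}
    for ds in datasets:
        n = len(ds.tables["basic_info"])
        rows[ds.institution_id] = {
            "biospecimen_count": n,
            "hospital_level": int(rng.integers(1, 4)),
            "dedicated_staff": int(rng.poisson(3)),
            "non_specialist_staff": int(rng.poisson(2)),
            "it_infrastructure_level": int(rng.integers(1, 6)),
            "data_manager_count": int(rng.poisson(1)),
            "years_in_network": int(rng.integers(1, 15)),
            "bed_count": int(rng.integers(300, 2500)),
            "collection_sites": int(rng.integers(1, 6)),
        }
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    df.index.name = "institution"
    df = df[list(DEFAULT_FACTOR_NAMES)]
    if relation is not None:
        df.attrs["theoretical_r"] = relation.theoretical_r(
            [len(d.tables["basic_info"]) for d in datasets]
        )
    return df


def recovery_run(
    seed: int = 0,
    config: GeneratorConfig | None = None,
    model: ErrorModel | None = None,
    catalog: Sequence[RuleSpec] | None = None,
) -> tuple[GroundTruthLedger, ViolationSet]:
    """One generate-inject-evaluate round trip at the default study scale
    (16 institutions x 1000 records, mixed per-site rates, final catalog)."""
    config = config or GeneratorConfig()
    model = model or default_error_model(config.institutions)
    catalog = catalog if catalog is not None else final_catalog()
    clean = generate_clean(config, seed=seed)
    corrupted, ledger = inject_errors(clean, model, seed=seed + 1)
    return ledger, evaluate_catalog(catalog, corrupted)


# ---------------------------------------------------------------------------
# correlation-recovery study
# ---------------------------------------------------------------------------

def correlation_recovery_study(
    relation: FactorRelation,
    record_counts: Mapping[str, int] | None = None,
    n_seeds: int = 50,
    seed: int = 0,
    catalog: Sequence[RuleSpec] | None = None,
) -> dict:
    """Monte-Carlo check that factor correlation is recovered end-to-end.

    For each replicate: generate clean data with a fixed spread of
    institution sizes, inject errors whose totals follow ``relation`` in the
    biospecimen count, run the final catalog, and correlate detected totals
    with the biospecimen factor.  Returns the per-seed coefficients, their
    mean, and the construction's theoretical value.
    """
    from .report import severity_table

    if record_counts is None:
        sizes = np.linspace(100, 850, 16).round().astype(int)
        record_counts = {inst: int(s) for inst, s in zip(DEFAULT_INSTITUTIONS, sizes)}
    catalog = catalog if catalog is not None else final_catalog()
    config = GeneratorConfig(
        institutions=tuple(record_counts),
        records_per_institution=dict(record_counts),
    )
    rs = []
    for s in range(n_seeds):
        clean = generate_clean(config, seed=seed * 1000003 % (2**31) + s)
        model = error_model_from_relation(record_counts, relation,
                                          seed=seed * 9176 % (2**31) + s)
        corrupted, _ = inject_errors(clean, model, seed=seed * 6271 % (2**31) + s)
        vs = evaluate_catalog(catalog, corrupted)
        totals = severity_table(vs)["total_count"]
        x = np.array([record_counts[i] for i in totals.index], dtype=float)
        rs.append(pearson_correlation(x, totals.to_numpy(dtype=float)))
    return {
        "r_values": rs,
        "mean_r": float(np.mean(rs)),
        "theoretical_r": relation.theoretical_r(list(record_counts.values())),
        "record_counts": dict(record_counts),
        "n_seeds": n_seeds,
    }
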