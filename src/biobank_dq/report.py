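"""Aggregation of violations into per-institution reporting surfaces.

Three views of one :class:`~biobank_dq.engine.ViolationSet`:

* severity table — total / error (E) / warning (W) counts per institution;
* dimension table — completeness / validity / accuracy / uniqueness counts;
* institution profiles — the Kahn-style completeness-vs-validity diagnostic
  that separates sites which tolerate wrong mappings to avoid omissions
  (validity-dominant) from sites with accurate mappings but many missing
  values (completeness-dominant).

The headline quality metric is the error rate: total violations divided by
(records x rules), i.e. the fraction of all verification cases that failed.

The module also ships the published per-institution summary counts of the
2020 Korea Biobank Network evaluation (16 sites, labels A-P) as a reference
table for arithmetic cross-checks of the reporting surfaces.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .catalog import DIMENSIONS
from .engine import ViolationSet
from .errors import StatsError

#: default dominance ratio for institution profiling: one error family must
#: exceed the other by this factor before a site is called one-sided.
DEFAULT_PROFILE_RATIO = 2.0


def severity_table(vs: ViolationSet) -> pd.DataFrame:
    """Per-institution total / error / warning counts.

    Every institution the evaluation touched gets a row, including
    zero-violation sites.
    """
    idx = pd.Index(vs.institution_ids, name="institution")
    out = pd.DataFrame(
        0, index=idx, columns=["total_count", "error_count", "warning_count"]
    )
    if len(vs.frame):
        by_sev = (
            vs.frame.groupby(["institution_id", "severity"]).size().unstack(fill_value=0)
        )
        for sev, col in (("E", "error_count"), ("W", "warning_count")):
            if sev in by_sev.columns:
                out.loc[by_sev.index, col] = by_sev[sev]
        out["total_count"] = out["error_count"] + out["warning_count"]
    return out.astype(int)


def dimension_table(vs: ViolationSet) -> pd.DataFrame:
    """Per-institution counts for the four quality dimensions."""
    idx = pd.Index(vs.institution_ids, name="institution")
    out = pd.DataFrame(0, index=idx, columns=list(DIMENSIONS))
    if len(vs.frame):
        by_dim = (
            vs.frame.groupby(["institution_id", "dimension"]).size().unstack(fill_value=0)
        )
        for dim in DIMENSIONS:
            if dim in by_dim.columns:
                out.loc[by_dim.index, dim] = by_dim[dim]
    return out.astype(int)


def error_rate(
    total_violations: int, n_records: int, n_rules: int
) -> tuple[float, str]:
    """Error rate = violations / (records x rules), with a 2-decimal percent
    string rendered round-half-up (e.g. 0.00745 -> ``"0.74%"``)."""
    if n_records <= 0 or n_rules <= 0:
        raise StatsError("error_rate needs positive record and rule counts")
    if total_violations < 0:
        raise StatsError("negative violation count")
    fraction = total_violations / (n_records * n_rules)
    pct = (
        Decimal(total_violations) * 100 / (Decimal(n_records) * Decimal(n_rules))
    ).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    return fraction, f"{pct}%"


@dataclass(frozen=True)
class InstitutionProfile:
    """Completeness-vs-validity classification of one site."""

    institution_id: str
    completeness_count: int
    validity_count: int
    label: str  # mapping-dominant | omission-dominant | balanced
    ratio_threshold: float


def profile_institution(
    completeness_count: int,
    validity_count: int,
    ratio_threshold: float = DEFAULT_PROFILE_RATIO,
    institution_id: str = "",
) -> InstitutionProfile:
    """Classify a site by which error family dominates.

    ``mapping-dominant``: validity errors exceed ``ratio_threshold`` times the
    completeness errors — the site likely forces wrong mappings to avoid
    omissions.  ``omission-dominant``: the converse — mappings are sound but
    values go missing at entry/collection.  Anything else is ``balanced``,
    including the all-zero site.
    """
    if completeness_count < 0 or validity_count < 0:
        raise StatsError("profile counts must be non-negative")
    if ratio_threshold <= 0:
        raise StatsError("ratio_threshold must be positive")
    if validity_count > ratio_threshold * completeness_count and validity_count > 0:
        label = "mapping-dominant"
    elif completeness_count > ratio_threshold * validity_count and completeness_count > 0:
        label = "omission-dominant"
    else:
        label = "balanced"
    return InstitutionProfile(
        institution_id=institution_id,
        completeness_count=int(completeness_count),
        validity_count=int(validity_count),
        label=label,
        ratio_threshold=float(ratio_threshold),
    )


def profile_table(
    dim_table: pd.DataFrame, ratio_threshold: float = DEFAULT_PROFILE_RATIO
) -> pd.DataFrame:
    """Profiles for every row of a dimension table."""
    rows = []
    for inst, row in dim_table.iterrows():
        p = profile_institution(
            row["completeness"], row["validity"], ratio_threshold, str(inst)
        )
        rows.append(
            {
                "institution": p.institution_id,
                "completeness_count": p.completeness_count,
                "validity_count": p.validity_count,
                "label": p.label,
                "ratio_threshold": p.ratio_threshold,
            }
        )
    return pd.DataFrame(rows).set_index("institution")


def write_report(
    vs: ViolationSet,
    out_dir: str | Path,
    n_records: int,
    n_rules: int,
    ratio_threshold: float = DEFAULT_PROFILE_RATIO,
) -> dict:
    """Write severity_table.csv, dimension_table.csv, profiles.csv and
    summary.json under ``out_dir``; return the summary dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sev = severity_table(vs)
    dim = dimension_table(vs)
    prof = profile_table(dim, ratio_threshold)
    sev.to_csv(out_dir / "severity_table.csv")
    dim.to_csv(out_dir / "dimension_table.csv")
    prof.to_csv(out_dir / "profiles.csv")
    fraction, pct = error_rate(vs.total, n_records, n_rules)
    summary = {
        "total_violations": int(vs.total),
        "n_records": int(n_records),
        "n_rules": int(n_rules),
        "error_rate_fraction": fraction,
        "error_rate_percent": pct,
        "profile_ratio_threshold": ratio_threshold,
        "note": (
            "A record failing several distinct rules on one field counts "
            "once per rule."
        ),
    }
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2), encoding="utf-8"
    )
    return summary


# ---------------------------------------------------------------------------
# published reference counts (2020 KBN evaluation, 16 institutions)
# ---------------------------------------------------------------------------

def load_reference_counts() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The published per-institution summary counts of the 2020 Korea Biobank
    Network quality evaluation.

    Returns ``(severity, dimension)`` frames indexed by institution label A-P:
    severity has ``total_count``/``error_count``/``warning_count`` as printed,
    dimension has one column per quality dimension.
    """
    ref = importlib.resources.files("biobank_dq.data") / "kbn2020_reference.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, index_col="institution")
    sev = df[["total_count", "error_count", "warning_count"]].copy()
    dim = df[list(DIMENSIONS)].copy()
    return sev, dim
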