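"""Statistical layer: independence tests and factor correlations.

Chi-square tests of independence are run on the per-institution severity and
dimension tables (Pearson statistic, no continuity correction); Pearson
product-moment correlations relate error counts (total and per dimension) to
surveyed institutional factors such as the number of biospecimens collected,
staffing and IT infrastructure.  The tool reports statistic / dof / p-value
and correlation coefficients raw — interpretation (and any multiplicity
adjustment) is left to the analyst.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .errors import StatsError, UndefinedCorrelationError

#: default factor slots of the institutional survey; fully config-driven —
#: any numeric columns in a factors table are correlated.
DEFAULT_FACTOR_NAMES = (
    "biospecimen_count",
    "hospital_level",
    "dedicated_staff",
    "non_specialist_staff",
    "it_infrastructure_level",
    "data_manager_count",
    "years_in_network",
    "bed_count",
    "collection_sites",
)

#: correlation targets: the total error count and each quality dimension.
CORRELATION_TARGETS = ("total", "completeness", "validity", "accuracy", "uniqueness")


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    dof: int
    p_value: float


def chi_square_independence(table: pd.DataFrame | np.ndarray) -> ChiSquareResult:
    """Pearson chi-square test of independence on a contingency table.

    Expected cell counts come from the row/column margins; the statistic is
    sum((O - E)^2 / E) with dof = (rows - 1)(cols - 1) and no continuity
    correction.  Degenerate tables (fewer than 2 rows/columns, a negative
    cell, or an all-zero margin) raise :class:`StatsError`.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise StatsError("contingency table needs at least 2 rows and 2 columns")
    if (arr < 0).any():
        raise StatsError("contingency table has negative cells")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise StatsError("contingency table has an all-zero row or column")
    res = sps.chi2_contingency(arr, correction=False)
    return ChiSquareResult(
        statistic=float(res.statistic), dof=int(res.dof), p_value=float(res.pvalue)
    )


def pearson_correlation(x, y) -> float:
    """Product-moment correlation coefficient.

    Raises :class:`UndefinedCorrelationError` on a constant input — an
    undefined correlation must never be silently reported as zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("x and y must be equal-length 1-d vectors")
    if x.size < 3:
        raise StatsError("correlation needs at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    return float(sps.pearsonr(x, y).statistic)


def spearman_correlation(x, y) -> float:
    """Rank correlation, same contract as :func:`pearson_correlation`."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("x and y must be equal-length 1-d vectors")
    if x.size < 3:
        raise StatsError("correlation needs at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    return float(sps.spearmanr(x, y).statistic)


@dataclass(frozen=True)
class CorrelationResult:
    factor: str
    target: str
    r: float | None
    n: int
    reason: str = ""  # non-empty when r is None


def correlate_factors(
    severity: pd.DataFrame,
    dimension: pd.DataFrame,
    factors: pd.DataFrame,
    method: str = "pearson",
    min_n: int = 3,
) -> list[CorrelationResult]:
    """Correlate each institutional factor with each error-count target.

    Targets are the total violation count and the four per-dimension counts;
    institutions with a missing factor value are dropped pairwise.  Pairs
    with fewer than ``min_n`` complete observations or a constant vector are
    reported with ``r=None`` and a reason rather than a number.
    """
    corr = {"pearson": pearson_correlation, "spearman": spearman_correlation}.get(method)
    if corr is None:
        raise StatsError(f"unknown correlation method {method!r}")
    targets = pd.DataFrame(index=severity.index)
    targets["total"] = severity["total_count"]
    for dim in ("completeness", "validity", "accuracy", "uniqueness"):
        targets[dim] = dimension[dim]
    results: list[CorrelationResult] = []
    common = targets.index.intersection(factors.index)
    for factor in factors.columns:
        fvals = pd.to_numeric(factors.loc[common, factor], errors="coerce")
        for target in CORRELATION_TARGETS:
            tvals = targets.loc[common, target]
            ok = fvals.notna() & tvals.notna()
            n = int(ok.sum())
            if n < min_n:
                results.append(
                    CorrelationResult(factor, target, None, n, "fewer pairs than min_n")
                )
                continue
            try:
                r = corr(fvals[ok].to_numpy(), tvals[ok].to_numpy())
            except UndefinedCorrelationError:
                results.append(
                    CorrelationResult(factor, target, None, n, "undefined-correlation")
                )
                continue
            results.append(CorrelationResult(factor, target, float(r), n))
    return results


def correlation_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Tabular view of :func:`correlate_factors` output."""
    return pd.DataFrame(
        [
            {
                "factor": r.factor,
                "target": r.target,
                "r": r.r,
                "n": r.n,
                "reason": r.reason,
            }
            for r in results
        ]
    )


def read_factors(path: str | Path) -> pd.DataFrame:
    """Read an institutional-factors table from CSV or YAML.

    CSV: one row per institution with an ``institution`` column.  YAML: a
    mapping ``{institution: {factor: value}}``.
    """
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
        df = pd.DataFrame.from_dict(raw, orient="index")
        df.index.name = "institution"
    else:
        df = pd.read_csv(path, index_col="institution")
    return df.apply(pd.to_numeric, errors="coerce")


def plot_factor_scatter(
    severity: pd.DataFrame,
    factors: pd.DataFrame,
    factor: str,
    target_column: str = "total_count",
    out_path: str | Path | None = None,
):
    """Scatter plot of one factor against an error-count column (optional;
    requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    common = severity.index.intersection(factors.index)
    x = pd.to_numeric(factors.loc[common, factor], errors="coerce")
    y = severity.loc[common, target_column]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y)
    for inst in common:
        ax.annotate(str(inst), (x.loc[inst], y.loc[inst]), fontsize=8)
    ax.set_xlabel(factor)
    ax.set_ylabel(target_column)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
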