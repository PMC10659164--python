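"""Independent brute-force reference implementations used as test oracles.

Deliberately written record-by-record in plain Python (no pandas, no scipy
shortcuts) so they share no code path with the vectorized engine and the
statistics wrappers they check.
"""

from __future__ import annotations

import math
import re
from datetime import datetime

_NUM_RE = re.compile(r"[+-]?\d+(\.\d+)?\Z")


def is_number(v) -> bool:
    return v is not None and _NUM_RE.match(str(v)) is not None


def is_date(v, min_year=None, max_year=None) -> bool:
    s = str(v) if v is not None else ""
    if len(s) != 8 or not s.isdigit():
        return False
    try:
        d = datetime.strptime(s, "%Y%m%d")
    except ValueError:
        return False
    if min_year is not None and d.year < min_year:
        return False
    if max_year is not None and d.year > max_year:
        return False
    return True


def cond_holds(cond, rec) -> bool:
    v = rec.get(cond.field)
    if cond.op == "not_null":
        return v is not None
    if cond.op == "is_null":
        return v is None
    if v is None:
        return False
    if cond.op == "eq":
        return str(v) == cond.value
    if cond.op == "ne":
        return str(v) != cond.value
    if cond.op == "in":
        return str(v) in cond.value
    if cond.op == "not_in":
        return str(v) not in cond.value
    raise ValueError(cond.op)


def _record_fails(rule, rec) -> bool:
    kind = rule.predicate.kind
    p = rule.predicate.params
    if kind == "not_null":
        return rec.get(p["field"]) is None
    if kind == "numeric_parse":
        v = rec.get(p["field"])
        return v is not None and not is_number(v)
    if kind == "range_check":
        v = rec.get(p["field"])
        if not is_number(v):
            return False
        x = float(v)
        if p.get("min") is not None and x < float(p["min"]):
            return True
        if p.get("max") is not None and x > float(p["max"]):
            return True
        return False
    if kind == "date_format":
        v = rec.get(p["field"])
        return v is not None and not is_date(v, p.get("min_year"), p.get("max_year"))
    if kind == "code_membership":
        v = rec.get(p["field"])
        return v is not None and str(v) not in p["codes"]
    if kind == "cross_field_compare":
        left, right = rec.get(p["left"]), rec.get(p["right"])
        if not (is_number(left) and is_number(right)):
            return False
        a, b = float(left), float(right)
        holds = {"gt": a > b, "ge": a >= b, "lt": a < b, "le": a <= b}[p["op"]]
        return not holds
    if kind == "date_order":
        a, b = rec.get(p["earlier"]), rec.get(p["later"])
        return is_date(a) and is_date(b) and str(a) > str(b)
    if kind == "conditional_presence":
        return cond_holds(p["antecedent"], rec) and rec.get(p["consequent_field"]) is None
    if kind == "conditional_valid":
        return cond_holds(p["antecedent"], rec) and not cond_holds(p["consequent"], rec)
    raise ValueError(kind)


def violating_rows(rule, records) -> list[int]:
    """Row indices a rule flags, by direct per-record re-checking."""
    if rule.predicate.kind == "unique_key":
        seen = set()
        out = []
        for i, rec in enumerate(records):
            key = tuple(rec.get(f) for f in rule.predicate.params["fields"])
            if any(k is None for k in key):
                continue
            if key in seen:
                out.append(i)
            else:
                seen.add(key)
        return out
    out = []
    for i, rec in enumerate(records):
        if rule.applicability is not None and not cond_holds(rule.applicability, rec):
            continue
        if _record_fails(rule, rec):
            out.append(i)
    return out


def chi_square_stat(table) -> tuple[float, int]:
    """Pearson chi-square statistic and dof from the definition."""
    rows = [list(map(float, r)) for r in table]
    total = sum(sum(r) for r in rows)
    row_sums = [sum(r) for r in rows]
    col_sums = [sum(r[j] for r in rows) for j in range(len(rows[0]))]
    stat = 0.0
    for i, r in enumerate(rows):
        for j, o in enumerate(r):
            e = row_sums[i] * col_sums[j] / total
            stat += (o - e) ** 2 / e
    dof = (len(rows) - 1) * (len(rows[0]) - 1)
    return stat, dof


def pearson_r(x, y) -> float:
    """Product-moment correlation from the summation formulas."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
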