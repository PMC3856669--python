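"""Two-group comparisons behind the benchmark tables.

Proportions are compared with Pearson's chi-square on the 2x2 table (1 df,
no continuity correction), distributions of continuous measurements with the
two-sided Mann-Whitney U test.  Probability levels strictly below 0.05 count
as significant; no multiple-testing correction is applied (none is applied
in routine network reporting either -- a deliberate, documented choice).

External reference networks only ever publish aggregate rates, so the
chi-square entry point takes (rate, n) summaries and reconstructs integer
counts by rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .records import (
    DataDictionary,
    InfantRecord,
    ItemDefinition,
    Period,
    compute_rate,
    continuous_values,
)

ALPHA = 0.05

#: exact Mann-Whitney enumeration cutoff on the combined sample size
EXACT_MW_LIMIT = 16


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    note: str | None = None


def chi_square_proportions(p1: float, n1: int, p2: float, n2: int) -> TestResult:
    """Pearson chi-square comparing two proportions given as (rate, n).

    Counts are reconstructed by rounding p*n to the nearest integer; the test
    is the uncorrected Pearson statistic on the 2x2 table with 1 df, p
    two-sided.  An expected cell below 1 is annotated but still returned.
    """
    if min(n1, n2) < 1:
        raise ValueError("sample sizes must be at least 1")
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("proportions must lie in [0, 1]")
    a = round(p1 * n1)
    c = round(p2 * n2)
    table = np.array([[a, n1 - a], [c, n2 - c]], dtype=float)
    note = None
    if table.min() == 0 and table.sum(axis=0).min() == 0:
        # a zero margin makes the statistic 0/0; report degenerate identity
        return TestResult(0.0, 1.0, "degenerate margin")
    stat, p, _, exp = _st.chi2_contingency(table, correction=False)
    if exp.min() < 1:
        note = "expected cell below 1"
    return TestResult(float(stat), float(p), note)


def chi_square_counts(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """Chi-square on raw counts (convenience wrapper)."""
    return chi_square_proportions(x1 / n1, n1, x2 / n2, n2)


def _has_ties(a: Sequence[float], b: Sequence[float]) -> bool:
    pooled = list(a) + list(b)
    return len(set(pooled)) != len(pooled)


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    The p-value is exact (full enumeration of the U null distribution) when
    the combined sample size is at most 16 and the data carry no ties;
    otherwise the normal approximation with tie correction is used.  Two
    identical constant samples give p = 1 with a degenerate-variance note.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = set(a) | set(b)
    if len(pooled) == 1:
        u = len(a) * len(b) / 2.0
        return TestResult(u, 1.0, "degenerate variance: all values identical")
    exact = len(a) + len(b) <= EXACT_MW_LIMIT and not _has_ties(a, b)
    method = "exact" if exact else "asymptotic"
    res = _st.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), None if exact else "normal approximation")


# ---------------------------------------------------------------------------
# Benchmark tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceRow:
    """Aggregate (rate, n) of an item published by an external network."""

    item: str
    rate: float
    n: int
    source: str
    year: str | None = None


@dataclass
class ExtremeRow:
    item: str
    min_unit: str | None
    min_value: float | None
    min_star: bool
    max_unit: str | None
    max_value: float | None
    max_star: bool
    skipped_units: tuple[str, ...] = ()


def unit_extremes_table(
    records: Iterable[InfantRecord],
    items: Sequence[ItemDefinition],
    period: Period | None = None,
    alpha: float = ALPHA,
    gated_out: Mapping[tuple[str, str], str] | None = None,
) -> list[ExtremeRow]:
    """Lowest and highest per-unit rate per item, starred when significant.

    A star marks an extreme whose chi-square against the rest-collective
    gives p strictly below ``alpha``.  Units gated out for an item (via
    ``gated_out`` keyed by (unit, item)) are skipped from min/max with a
    note.  Requires at least two units.
    """
    records = list(records)
    units = sorted({r.unit_id for r in records})
    if len(units) < 2:
        raise ValueError("unit extremes need at least two units")
    gated_out = gated_out or {}
    out = []
    for item in items:
        if item.continuous:
            out.append(_continuous_extremes(records, item, units, period, gated_out))
            continue
        vals: list[tuple[str, float, int, int]] = []
        skipped = []
        for u in units:
            if (u, item.name) in gated_out:
                skipped.append(u)
                continue
            r = compute_rate(records, item, unit=u, period=period)
            if r.defined:
                vals.append((u, r.proportion, r.numerator, r.denominator))
            else:
                skipped.append(u)
        if not vals:
            out.append(ExtremeRow(item.name, None, None, False, None, None, False, tuple(skipped)))
            continue
        lo = min(vals, key=lambda t: t[1])
        hi = max(vals, key=lambda t: t[1])
        row = ExtremeRow(
            item=item.name,
            min_unit=lo[0],
            min_value=lo[1],
            min_star=_star_vs_rest(records, item, lo[0], period, alpha),
            max_unit=hi[0],
            max_value=hi[1],
            max_star=_star_vs_rest(records, item, hi[0], period, alpha),
            skipped_units=tuple(skipped),
        )
        out.append(row)
    return out


def _star_vs_rest(records, item, unit, period, alpha) -> bool:
    r_unit = compute_rate(records, item, unit=unit, period=period)
    r_rest = compute_rate(records, item, exclude_unit=unit, period=period)
    if not (r_unit.defined and r_rest.defined):
        return False
    res = chi_square_counts(
        r_unit.numerator, r_unit.denominator, r_rest.numerator, r_rest.denominator
    )
    return res.p_value < alpha


def _continuous_extremes(records, item, units, period, gated_out) -> ExtremeRow:
    means: list[tuple[str, float]] = []
    skipped = []
    for u in units:
        if (u, item.name) in gated_out:
            skipped.append(u)
            continue
        vals = continuous_values(records, item, unit=u, period=period)
        if vals:
            means.append((u, float(np.mean(vals))))
        else:
            skipped.append(u)
    if not means:
        return ExtremeRow(item.name, None, None, False, None, None, False, tuple(skipped))
    lo = min(means, key=lambda t: t[1])
    hi = max(means, key=lambda t: t[1])

    def star(u: str) -> bool:
        a = continuous_values(records, item, unit=u, period=period)
        b = continuous_values(records, item, exclude_unit=u, period=period)
        if not a or not b:
            return False
        return mann_whitney_u(a, b).p_value < ALPHA

    return ExtremeRow(
        item.name, lo[0], lo[1], star(lo[0]), hi[0], hi[1], star(hi[0]), tuple(skipped)
    )


def reference_comparison_table(
    records: Iterable[InfantRecord],
    items: Sequence[ItemDefinition],
    references: Sequence[ReferenceRow],
    period: Period | None = None,
) -> pd.DataFrame:
    """Network rate vs external reference aggregates, chi-square p per row."""
    records = list(records)
    by_item: dict[str, list[ReferenceRow]] = {}
    for ref in references:
        by_item.setdefault(ref.item, []).append(ref)
    rows = []
    for item in items:
        if item.continuous or item.name not in by_item:
            continue
        r = compute_rate(records, item, period=period)
        if not r.defined:
            continue
        for ref in by_item[item.name]:
            res = chi_square_proportions(r.proportion, r.denominator, ref.rate, ref.n)
            rows.append(
                {
                    "item": item.name,
                    "network_rate": r.proportion,
                    "network_n": r.denominator,
                    "reference": ref.source,
                    "reference_rate": ref.rate,
                    "reference_n": ref.n,
                    "p_value": res.p_value,
                    "significant": res.p_value < ALPHA,
                }
            )
    return pd.DataFrame(rows)
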