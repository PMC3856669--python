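"""Gestational-age-adjusted quality indicators on the SMR model.

Each unit is compared against the *entire* collective (itself included),
whose rate is set to 1.  Two statistics are shown per unit x item:

* the **crude ratio** -- unit rate / collective rate, and
* for outcome items, the **standardized mortality/morbidity ratio** (SMR) --
  observed events O divided by the events E expected if the collective's
  stratum-specific rates applied to the unit's own gestational-age case mix
  (indirect standardization),

      E = sum_s  n_unit,s * p_collective,s

  over the six strata below 24, 24-25, 26-27, 28-29, 30-31 and above 31
  completed weeks.

Both ratios carry 95% intervals from the same Poisson machinery: O is
treated as Poisson with mean E*theta and the interval for theta uses Byar's
approximation (exact Poisson upper bound at O = 0).  A unit differs
significantly from the collective when its interval does not contain 1.
Measurement-completeness and reliability gates are applied before any ratio
is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats as _st

from .records import (
    DataDictionary,
    GestationalAge,
    InfantRecord,
    ItemDefinition,
    ItemKind,
    NOT_APPLICABLE,
    Period,
    Rate,
    compute_rate,
    completeness_by_item,
    is_eligible,
    item_value,
    select,
)
from .quality import (
    COMPLETENESS_THRESHOLD,
    ReliabilitySeries,
    completeness_gate,
    reliability_classify,
    section_split,
)

#: Ordered gestational-age strata as (label, first week, one-past-last week);
#: None marks an open end.  Strata partition the GA axis on completed weeks.
GA_STRATA: tuple[tuple[str, int | None, int | None], ...] = (
    ("below_24", None, 24),
    ("24_25", 24, 26),
    ("26_27", 26, 28),
    ("28_29", 28, 30),
    ("30_31", 30, 32),
    ("above_31", 32, None),
)

STRATUM_LABELS = tuple(s[0] for s in GA_STRATA)


def stratum_of(ga: GestationalAge | None) -> str | None:
    """Stratum label for a gestational age; None when GA is unknown."""
    if ga is None:
        return None
    w = ga.weeks
    for label, lo, hi in GA_STRATA:
        if (lo is None or w >= lo) and (hi is None or w < hi):
            return label
    raise AssertionError("strata must cover the GA axis")  # pragma: no cover


def stratify(
    records: Iterable[InfantRecord],
) -> dict[str, list[InfantRecord]]:
    """Partition records into GA strata; unknown GA goes to ``"unknown"``.

    The unknown bucket is excluded from risk adjustment and surfaces as a
    data-quality warning downstream.
    """
    groups: dict[str, list[InfantRecord]] = {lbl: [] for lbl in STRATUM_LABELS}
    groups["unknown"] = []
    for r in records:
        lbl = stratum_of(r.gestational_age)
        groups[lbl if lbl is not None else "unknown"].append(r)
    return groups


def expected_count(
    unit_stratum_n: Mapping[str, int],
    collective_stratum_rates: Mapping[str, float | None],
) -> float:
    """Expected events under indirect standardization.

    E = sum over strata of (unit denominator in stratum) x (collective rate
    in stratum).  A stratum where the unit has records but the collective
    rate is undefined is a hard error: no reference exists for that case mix.
    """
    e = 0.0
    for lbl, n in unit_stratum_n.items():
        if n == 0:
            continue
        p = collective_stratum_rates.get(lbl)
        if p is None:
            raise ValueError(
                f"collective rate undefined in stratum {lbl!r} where the unit "
                f"has {n} records"
            )
        e += n * p
    return e


# ---------------------------------------------------------------------------
# Poisson ratio intervals (Byar's approximation; exact bound at O = 0)
# ---------------------------------------------------------------------------


def byar_interval(observed: int, expected: float, level: float = 0.95) -> tuple[float, float]:
    """Byar's approximate CI for an O/E ratio.

    Treats O as Poisson with mean E*theta.  At O = 0 the lower bound is 0 and
    the upper bound uses the exact Poisson relation.  Validated against the
    exact chi-square/Poisson quantile interval.
    """
    if expected <= 0:
        raise ValueError("expected count must be positive")
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    z = _st.norm.ppf(0.5 + level / 2)
    o = observed
    if o == 0:
        lo = 0.0
    else:
        lo = (o / expected) * (1.0 - 1.0 / (9.0 * o) - z / (3.0 * math.sqrt(o))) ** 3
    if o == 0:
        # exact Poisson upper bound: solve P(X = 0 | lam) = alpha/2
        alpha = 1.0 - level
        hi = -math.log(alpha / 2.0) / expected
    else:
        op = o + 1.0
        hi = (op / expected) * (1.0 - 1.0 / (9.0 * op) + z / (3.0 * math.sqrt(op))) ** 3
    return max(0.0, lo), hi


def exact_poisson_interval(
    observed: int, expected: float, level: float = 0.95
) -> tuple[float, float]:
    """Exact Poisson CI for O/E via the chi-square quantile relation.

    Kept as the independent cross-check for :func:`byar_interval`.
    """
    if expected <= 0:
        raise ValueError("expected count must be positive")
    alpha = 1.0 - level
    lo = 0.0 if observed == 0 else _st.chi2.ppf(alpha / 2, 2 * observed) / 2 / expected
    hi = _st.chi2.ppf(1 - alpha / 2, 2 * (observed + 1)) / 2 / expected
    return lo, hi


def smr_with_ci(
    observed: int, expected: float, level: float = 0.95
) -> tuple[float, float, float]:
    """(SMR, ci_low, ci_high) with SMR = O/E and a Byar 95% interval."""
    if expected <= 0:
        raise ValueError("expected count must be positive")
    smr = observed / expected
    lo, hi = byar_interval(observed, expected, level)
    return smr, min(lo, smr), max(hi, smr)


def significance_flag(ci_low: float, ci_high: float) -> bool:
    """Significant iff the 95% interval does not contain 1 (touching = overlap)."""
    return ci_low > 1.0 or ci_high < 1.0


# ---------------------------------------------------------------------------
# QI table (model/results)
# ---------------------------------------------------------------------------


@dataclass
class QIResult:
    """One unit x item row of the quality-indicator table."""

    unit_id: str
    item: str
    kind: str  # "process" | "outcome"
    n: int = 0
    crude_rate: float | None = None
    crude_ratio: float | None = None
    crude_ci: tuple[float, float] | None = None
    observed: int | None = None
    expected: float | None = None
    smr: float | None = None
    smr_ci: tuple[float, float] | None = None
    completeness: float | None = None
    reliability: str | None = None
    significant: bool = False
    excluded: bool = False
    exclusion_reason: str | None = None  # completeness | reliability | undefined-rate


class QualityIndicatorModel:
    """GA-adjusted quality indicators for every unit x QI-eligible item.

    Parameters
    ----------
    records : cohort (must span the QI period *and* its reliability baseline)
    dictionary : active data dictionary
    period : pooled evaluation period (typically three finalized years)
    baseline : equally long period immediately before ``period`` used only
        for the reliability screen
    completeness_threshold : exclusion gate, default 0.90
    overrides : optional {(unit, item): justification} manual reliability
        overrides
    """

    def __init__(
        self,
        records: Iterable[InfantRecord],
        dictionary: DataDictionary,
        period: Period,
        baseline: Period,
        level: float = 0.95,
        completeness_threshold: float = COMPLETENESS_THRESHOLD,
        overrides: Mapping[tuple[str, str], str] | None = None,
    ):
        self.records = list(records)
        self.dictionary = dictionary
        self.period = period
        self.baseline = baseline
        self.level = level
        self.completeness_threshold = completeness_threshold
        self.overrides = dict(overrides or {})

    def fit(self, items: Sequence[ItemDefinition] | None = None) -> "QIResults":
        items = list(items) if items is not None else self.dictionary.qi_items()
        sections = section_split(self.period, self.baseline)
        units = sorted({r.unit_id for r in self.records})
        period_records = select(self.records, period=self.period)
        rows: list[QIResult] = []
        reliability: list[ReliabilitySeries] = []
        n_unknown_ga = sum(
            1 for r in period_records if r.gestational_age is None
        )
        for item in items:
            if item.continuous:
                continue
            coll = compute_rate(period_records, item)
            coll_strata = self._collective_stratum_rates(period_records, item)
            for u in units:
                rows.append(
                    self._one(
                        u, item, period_records, coll, coll_strata, sections, reliability
                    )
                )
        return QIResults(
            rows=rows,
            reliability=reliability,
            period=self.period,
            baseline=self.baseline,
            n_unknown_ga=n_unknown_ga,
        )

    # -- helpers ------------------------------------------------------------

    def _collective_stratum_rates(self, period_records, item) -> dict[str, float | None]:
        out: dict[str, float | None] = {}
        for lbl, recs in stratify(period_records).items():
            if lbl == "unknown":
                continue
            out[lbl] = compute_rate(recs, item).proportion
        return out

    def _one(
        self, unit, item, period_records, coll, coll_strata, sections, reliability_out
    ) -> QIResult:
        row = QIResult(unit_id=unit, item=item.name, kind=item.kind.value)
        row.completeness = completeness_by_item(
            self.records, unit, item, period=self.period
        )
        gate = completeness_gate(row.completeness, self.completeness_threshold)
        override = self.overrides.get((unit, item.name))
        rel = reliability_classify(
            self.records,
            unit,
            item,
            sections,
            level=self.level,
            override=override is not None,
            override_note=override,
        )
        reliability_out.append(rel)
        row.reliability = rel.classification
        if not gate.included:
            row.excluded = True
            row.exclusion_reason = "completeness"
            return row
        if rel.excluded:
            row.excluded = True
            row.exclusion_reason = "reliability"
            return row

        unit_rate = compute_rate(period_records, item, unit=unit)
        if not unit_rate.defined or not coll.defined or coll.proportion == 0:
            row.excluded = True
            row.exclusion_reason = "undefined-rate"
            return row
        row.n = unit_rate.denominator
        row.crude_rate = unit_rate.proportion
        row.crude_ratio = unit_rate.proportion / coll.proportion
        e_crude = unit_rate.denominator * coll.proportion
        lo, hi = byar_interval(unit_rate.numerator, e_crude, self.level)
        row.crude_ci = (lo, hi)

        if item.kind is ItemKind.OUTCOME:
            # indirect standardization over the unit's own GA case mix
            unit_n: dict[str, int] = {}
            observed = 0
            for lbl, recs in stratify(period_records).items():
                if lbl == "unknown":
                    continue
                r = compute_rate(recs, item, unit=unit)
                unit_n[lbl] = r.denominator
                observed += r.numerator
            try:
                expected = expected_count(unit_n, coll_strata)
            except ValueError:
                row.excluded = True
                row.exclusion_reason = "undefined-rate"
                return row
            if expected == 0:
                row.excluded = True
                row.exclusion_reason = "undefined-rate"
                return row
            row.observed = observed
            row.expected = expected
            smr, slo, shi = smr_with_ci(observed, expected, self.level)
            row.smr = smr
            row.smr_ci = (slo, shi)
            row.significant = significance_flag(slo, shi)
        else:
            row.significant = significance_flag(lo, hi)
        return row


@dataclass
class QIResults:
    """Fitted quality-indicator table plus the reliability detail behind it."""

    rows: list[QIResult]
    reliability: list[ReliabilitySeries]
    period: Period
    baseline: Period
    n_unknown_ga: int = 0

    def summary(self) -> pd.DataFrame:
        """Figure-2-style table: rate, SMR, completeness, reliability,
        significance, one row per unit x item."""
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "unit": r.unit_id,
                    "item": r.item,
                    "kind": r.kind,
                    "n": r.n,
                    "rate": r.crude_rate,
                    "crude_ratio": r.crude_ratio,
                    "crude_lo": r.crude_ci[0] if r.crude_ci else None,
                    "crude_hi": r.crude_ci[1] if r.crude_ci else None,
                    "observed": r.observed,
                    "expected": r.expected,
                    "smr": r.smr,
                    "smr_lo": r.smr_ci[0] if r.smr_ci else None,
                    "smr_hi": r.smr_ci[1] if r.smr_ci else None,
                    "completeness_pct": None
                    if r.completeness is None
                    else round(100 * r.completeness, 1),
                    "reliability": r.reliability,
                    "significant": r.significant,
                    "excluded": r.excluded,
                    "exclusion_reason": r.exclusion_reason,
                }
            )
        return pd.DataFrame(recs)

    def findings(self) -> list[QIResult]:
        """Rows flagged significant and not gated out."""
        return [r for r in self.rows if r.significant and not r.excluded]

    def plot(self, item: str, ax=None, pseudonyms: Mapping[str, str] | None = None):
        """SMR dot-and-interval chart for one item, reference line at 1."""
        if ax is None:
            import matplotlib.pyplot as plt

            _, ax = plt.subplots(figsize=(7, 4))
        rows = [r for r in self.rows if r.item == item and not r.excluded]
        labels = []
        for i, r in enumerate(rows):
            name = pseudonyms.get(r.unit_id, r.unit_id) if pseudonyms else r.unit_id
            labels.append(name)
            if r.smr is not None and r.smr_ci:
                ax.errorbar(
                    i,
                    r.smr,
                    yerr=[[r.smr - r.smr_ci[0]], [r.smr_ci[1] - r.smr]],
                    fmt="s",
                    color="C0",
                    capsize=3,
                )
            if r.crude_ratio is not None and r.crude_ci:
                ax.errorbar(
                    i + 0.2,
                    r.crude_ratio,
                    yerr=[[max(0, r.crude_ratio - r.crude_ci[0])], [r.crude_ci[1] - r.crude_ratio]],
                    fmt="D",
                    color="C1",
                    capsize=3,
                    alpha=0.7,
                )
        ax.axhline(1.0, color="k", lw=1)
        ax.set_xticks(range(len(labels)))
        ax.set_xticklabels(labels)
        ax.set_ylabel(f"{item}: ratio vs collective (=1)")
        return ax
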