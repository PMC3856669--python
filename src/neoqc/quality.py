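"""Data-quality gates for quality-indicator evaluation.

Three gates guard every unit x item evaluation:

* **Measurement completeness** -- units answering an item for fewer than 90%
  of eligible records are excluded for that item.
* **Reliability over time** -- health-care change is assumed gradual, so a
  unit x item series is screened for erratic jumps: the evaluation period plus
  an equally long baseline immediately before it are split into eight equal
  calendar sections, each section's rate gets a 95% Wald interval, and
  neighbouring intervals that fail to overlap count as erratic changes.  Zero
  changes -> reliable; exactly one -> partially reliable; two or more ->
  unreliable (excluded).  Sections sitting at exactly 0% or 100% (whose Wald
  interval has zero width) are skipped: the next section is compared against
  the last section that was away from the boundary.
* **Record completeness** -- the registry's record count is compared against
  an external national birth-registry count.

The Wald interval p-hat +/- z*sqrt(p-hat(1-p-hat)/n) is used deliberately: the
skip rule presupposes an interval that collapses to a point at 0%/100%, which
holds for Wald but not for Wilson or Clopper-Pearson.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats as _st

from .records import (
    DataDictionary,
    InfantRecord,
    ItemDefinition,
    Period,
    Rate,
    compute_rate,
)

COMPLETENESS_THRESHOLD = 0.90
DEFAULT_N_SECTIONS = 8


# ---------------------------------------------------------------------------
# Calendar sectioning
# ---------------------------------------------------------------------------


def _add_months(day: dt.date, months: int) -> dt.date:
    m = day.month - 1 + months
    return dt.date(day.year + m // 12, m % 12 + 1, day.day)


def _months_between(a: dt.date, b: dt.date) -> int:
    if a.day != 1 or b.day != 1:
        raise ValueError("section boundaries must fall on the first of a month")
    return (b.year - a.year) * 12 + (b.month - a.month)


def section_split(
    period_of_interest: Period,
    baseline: Period,
    n_sections: int = DEFAULT_N_SECTIONS,
) -> list[Period]:
    """Split baseline + period of interest into equal calendar sections.

    The baseline must end exactly where the period of interest starts, and
    the combined span must divide into ``n_sections`` whole-month sections
    (six calendar years -> eight 9-month sections).  Sections are half-open,
    contiguous and cover the combined span exactly.
    """
    if baseline.end != period_of_interest.start:
        raise ValueError(
            "baseline must immediately precede the period of interest "
            f"(baseline ends {baseline.end}, period starts {period_of_interest.start})"
        )
    total_months = _months_between(baseline.start, period_of_interest.end)
    if total_months % n_sections != 0:
        raise ValueError(
            f"combined span of {total_months} months does not divide into "
            f"{n_sections} equal whole-month sections"
        )
    step = total_months // n_sections
    bounds = [_add_months(baseline.start, k * step) for k in range(n_sections + 1)]
    return [Period(a, b) for a, b in zip(bounds[:-1], bounds[1:])]


# ---------------------------------------------------------------------------
# Wald interval and the skip-and-compare reliability walk
# ---------------------------------------------------------------------------


def wald_interval(p: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation binomial CI, clipped to [0, 1].

    Collapses to a zero-width interval at p = 0 or 1 -- the property the
    reliability skip rule relies on.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    z = _st.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(p * (1.0 - p) / n)
    return max(0.0, p - half), min(1.0, p + half)


@dataclass(frozen=True)
class Section:
    """One chronological section of a reliability series."""

    period: Period
    rate: float | None  # None when no eligible record fell in the section
    ci_low: float | None
    ci_high: float | None
    n: int

    @property
    def at_boundary(self) -> bool:
        """True for 0%/100% sections and undefined sections (both skipped)."""
        return self.rate is None or self.rate in (0.0, 1.0)


def _disjoint(a: Section, b: Section) -> bool:
    # touching endpoints count as overlap (conservative)
    return a.ci_high < b.ci_low or b.ci_high < a.ci_low


def count_nonoverlaps(sections: Sequence[Section]) -> int:
    """Skip-and-compare walk over chronological sections.

    A pointer tracks the last section whose rate was defined and away from
    0%/100%.  Every later non-boundary section is compared against the
    pointer; strictly disjoint 95% intervals count one erratic change, and
    the section then becomes the new pointer.  Boundary sections never
    trigger a change and never move the pointer.
    """
    count = 0
    pointer: Section | None = None
    for s in sections:
        if s.at_boundary:
            continue
        if pointer is not None and _disjoint(pointer, s):
            count += 1
        pointer = s
    return count


def classify(nonoverlap_count: int) -> str:
    if nonoverlap_count == 0:
        return "reliable"
    if nonoverlap_count == 1:
        return "partially_reliable"
    return "unreliable"


@dataclass
class ReliabilitySeries:
    """Reliability screening outcome for one unit x item."""

    unit_id: str
    item: str
    sections: list[Section]
    nonoverlap_count: int
    classification: str
    overridden: bool = False
    override_note: str | None = None

    @property
    def excluded(self) -> bool:
        return self.classification == "unreliable" and not self.overridden


def reliability_from_counts(
    unit_id: str,
    item: str,
    counts: Sequence[tuple[int, int]],
    periods: Sequence[Period] | None = None,
    level: float = 0.95,
    n_sections: int = DEFAULT_N_SECTIONS,
) -> ReliabilitySeries:
    """Build and classify a reliability series from (numerator, n) pairs."""
    if len(counts) != n_sections:
        raise ValueError(f"expected {n_sections} sections, got {len(counts)}")
    if periods is None:
        # placeholder year-per-section periods for count-level use
        periods = [Period.from_years(2000 + i, 2000 + i) for i in range(len(counts))]
    sections = []
    for (num, n), per in zip(counts, periods):
        if n == 0:
            sections.append(Section(per, None, None, None, 0))
        else:
            p = num / n
            lo, hi = wald_interval(p, n, level)
            sections.append(Section(per, p, lo, hi, n))
    count = count_nonoverlaps(sections)
    return ReliabilitySeries(unit_id, item, sections, count, classify(count))


def reliability_classify(
    records: Iterable[InfantRecord],
    unit: str,
    item: ItemDefinition,
    sections: Sequence[Period],
    level: float = 0.95,
    override: bool = False,
    override_note: str | None = None,
    n_sections: int = DEFAULT_N_SECTIONS,
) -> ReliabilitySeries:
    """Classify a unit x item as reliable / partially reliable / unreliable.

    ``sections`` come from :func:`section_split`.  A manual override (backed
    by review of the original case documentation) flips the effective
    exclusion off while preserving the computed classification.
    """
    if len(sections) != n_sections:
        raise ValueError(f"expected {n_sections} sections, got {len(sections)}")
    records = list(records)
    counts = []
    for per in sections:
        r: Rate = compute_rate(records, item, unit=unit, period=per)
        counts.append((r.numerator, r.denominator))
    series = reliability_from_counts(
        unit, item.name, counts, periods=list(sections), level=level,
        n_sections=n_sections,
    )
    if override:
        series.overridden = True
        series.override_note = override_note
    return series


# ---------------------------------------------------------------------------
# Completeness gate & registry coverage
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GateDecision:
    included: bool
    reason: str  # "ok" | "below_threshold" | "undefined"


def completeness_gate(
    fraction: float | None, threshold: float = COMPLETENESS_THRESHOLD
) -> GateDecision:
    """Exclude a unit x item when answered fraction is strictly below 90%."""
    if fraction is None:
        return GateDecision(False, "undefined")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("completeness fraction must lie in [0, 1]")
    if fraction < threshold:
        return GateDecision(False, "below_threshold")
    return GateDecision(True, "ok")


@dataclass(frozen=True)
class CoverageResult:
    percentage: float  # to one decimal
    network_count: int
    registry_count: int
    overcount_warning: bool


def registry_coverage(network_count: int, registry_count: int) -> CoverageResult:
    """Record completeness vs an external birth-registry count, in percent."""
    if registry_count <= 0:
        raise ValueError("registry count must be positive")
    pct = round(100.0 * network_count / registry_count, 1)
    return CoverageResult(pct, network_count, registry_count, network_count > registry_count)


def reliability_tally(series_list: Iterable[ReliabilitySeries]) -> dict[str, tuple[int, int, int]]:
    """Per-item (reliable, partially reliable, unreliable) unit counts."""
    tally: dict[str, list[int]] = {}
    order = {"reliable": 0, "partially_reliable": 1, "unreliable": 2}
    for s in series_list:
        t = tally.setdefault(s.item, [0, 0, 0])
        cls = "reliable" if s.overridden else s.classification
        t[order[cls]] += 1
    return {k: tuple(v) for k, v in tally.items()}
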