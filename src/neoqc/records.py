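"""Patient-level domain model for a multi-unit VLBW quality registry.

One :class:`InfantRecord` per live-born infant (delivery-room deaths
included).  Care items are tri-state: ``True``/``False`` for answered binary
items, ``None`` for a missing answer, and the :data:`NOT_APPLICABLE` sentinel
for items that are structurally inapplicable to a record (e.g. NICU-course
items for an infant who died in the delivery room).  Continuous items carry a
float or one of the two missing markers.

The data dictionary (:class:`ItemDefinition`) attaches to each item a
process/outcome class, a denominator rule and its benchmarking /
quality-indicator eligibility.  Rates, completeness fractions and record
validation all honour the denominator rules so that the same machinery serves
every downstream stage (control charts, SMR indicators, benchmark tables).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Iterable, Mapping, Sequence


class _NotApplicable:
    """Singleton marker for structurally-missing (inapplicable) item values."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NOT_APPLICABLE"

    def __bool__(self) -> bool:
        raise TypeError("structurally-missing value has no truth value")


#: Structurally-missing sentinel: the item does not apply to the record and is
#: excluded from completeness denominators (unlike ``None`` = missing answer).
NOT_APPLICABLE = _NotApplicable()


class ItemKind(str, Enum):
    PROCESS = "process"
    OUTCOME = "outcome"


class Denominator(str, Enum):
    """Which records enter an item's denominator."""

    ALL_LIVEBIRTHS = "all_livebirths"
    ADMITTED = "admitted"  # admitted alive to the NICU (no delivery-room death)
    SURVIVORS = "survivors"  # survived to first discharge home
    SURVIVORS_AT_36W = "survivors_at_36w"


@dataclass(frozen=True)
class GestationalAge:
    """Gestational age in completed weeks plus days (obstetric convention).

    ``GestationalAge(27, 3)`` prints as ``27+3``; "below 24 weeks" means
    strictly less than 24+0.
    """

    weeks: int
    days: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.days <= 6:
            raise ValueError(f"days component must be 0-6, got {self.days}")
        if self.weeks < 0:
            raise ValueError("weeks must be non-negative")

    @property
    def total_days(self) -> int:
        return self.weeks * 7 + self.days

    @classmethod
    def parse(cls, text: str) -> "GestationalAge":
        """Parse ``"27+3"`` (or plain ``"27"``) into a GestationalAge."""
        text = text.strip()
        if "+" in text:
            w, _, d = text.partition("+")
            return cls(int(w), int(d))
        return cls(int(text), 0)

    def __str__(self) -> str:
        return f"{self.weeks}+{self.days}"

    def __lt__(self, other: "GestationalAge") -> bool:
        return self.total_days < other.total_days

    def __le__(self, other: "GestationalAge") -> bool:
        return self.total_days <= other.total_days


@dataclass(frozen=True)
class ItemDefinition:
    """Dictionary entry for one collected item."""

    name: str
    kind: ItemKind
    denominator: Denominator = Denominator.ALL_LIVEBIRTHS
    qi_eligible: bool = False
    benchmark_eligible: bool = True
    continuous: bool = False


class DataDictionary:
    """Ordered, name-unique collection of :class:`ItemDefinition`."""

    def __init__(self, items: Iterable[ItemDefinition]):
        self._items = list(items)
        self._by_name = {it.name: it for it in self._items}
        if len(self._by_name) != len(self._items):
            raise ValueError("duplicate item names in data dictionary")

    def __iter__(self):
        return iter(self._items)

    def __len__(self) -> int:
        return len(self._items)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> ItemDefinition:
        return self._by_name[name]

    def get(self, name: str) -> ItemDefinition | None:
        return self._by_name.get(name)

    @property
    def names(self) -> list[str]:
        return [it.name for it in self._items]

    def binary_items(self) -> list[ItemDefinition]:
        return [it for it in self._items if not it.continuous]

    def qi_items(self) -> list[ItemDefinition]:
        return [it for it in self._items if it.qi_eligible]

    def benchmark_items(self) -> list[ItemDefinition]:
        return [it for it in self._items if it.benchmark_eligible]


@dataclass
class InfantRecord:
    """One live-born infant of the 501-1500 g collective.

    ``items`` maps item name to ``True``/``False``/float/``None``/
    :data:`NOT_APPLICABLE`.  Demographics live in dedicated fields; the
    virtual item names ``sex_male`` and ``multiples`` expose them to the
    rate machinery.
    """

    record_id: str
    unit_id: str
    birth_date: dt.date
    gestational_age: GestationalAge | None
    birth_weight: float | None
    sex: str | None  # "male" / "female" / None
    multiple_birth: bool | None
    delivery_room_death: bool
    items: dict = field(default_factory=dict)

    @property
    def died(self) -> bool | None:
        """Death before first discharge (the mortality item), tri-state."""
        v = self.items.get("mortality")
        if v is NOT_APPLICABLE:
            return None
        return v


#: Virtual items backed by record fields rather than the items map.
VIRTUAL_ITEMS = ("sex_male", "multiples")


def item_value(record: InfantRecord, item_name: str):
    """Value of an item on a record, resolving virtual demographic items."""
    if item_name == "sex_male":
        if record.sex is None:
            return None
        return record.sex == "male"
    if item_name == "multiples":
        return record.multiple_birth
    return record.items.get(item_name)


def is_eligible(record: InfantRecord, item: ItemDefinition) -> bool:
    """Does the record enter the item's denominator?

    Records whose survival status is unknown are excluded from
    survivor-based denominators.
    """
    d = item.denominator
    if d is Denominator.ALL_LIVEBIRTHS:
        return True
    if d is Denominator.ADMITTED:
        return not record.delivery_room_death
    # survivor rules: death before discharge disqualifies; unknown excluded
    return record.died is False


# ---------------------------------------------------------------------------
# Periods and selectors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Period:
    """Half-open calendar interval [start, end)."""

    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("period start must precede end")

    def __contains__(self, day: dt.date) -> bool:
        return self.start <= day < self.end

    @classmethod
    def from_years(cls, first_year: int, last_year: int) -> "Period":
        """Inclusive year range -> half-open date interval."""
        return cls(dt.date(first_year, 1, 1), dt.date(last_year + 1, 1, 1))

    @classmethod
    def year(cls, y: int) -> "Period":
        return cls.from_years(y, y)


def select(
    records: Iterable[InfantRecord],
    unit: str | None = None,
    exclude_unit: str | None = None,
    period: Period | None = None,
) -> list[InfantRecord]:
    """Filter records by unit membership and birth-date period."""
    out = []
    for r in records:
        if unit is not None and r.unit_id != unit:
            continue
        if exclude_unit is not None and r.unit_id == exclude_unit:
            continue
        if period is not None and r.birth_date not in period:
            continue
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# Rates and completeness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Rate:
    """A proportion with its counts; ``proportion`` is None when undefined."""

    numerator: int
    denominator: int

    @property
    def proportion(self) -> float | None:
        if self.denominator == 0:
            return None
        return self.numerator / self.denominator

    @property
    def defined(self) -> bool:
        return self.denominator > 0


def compute_rate(
    records: Iterable[InfantRecord],
    item: ItemDefinition,
    unit: str | None = None,
    exclude_unit: str | None = None,
    period: Period | None = None,
) -> Rate:
    """Numerator / denominator / proportion of a binary item.

    Denominator = records admitted by the item's denominator rule with a
    non-missing answer; numerator = those answered ``True``.  A zero
    denominator yields an undefined rate, not a crash.
    """
    if item.continuous:
        raise ValueError(f"item {item.name!r} is continuous; rates need a binary item")
    num = den = 0
    for r in select(records, unit=unit, exclude_unit=exclude_unit, period=period):
        if not is_eligible(r, item):
            continue
        v = item_value(r, item.name)
        if v is None or v is NOT_APPLICABLE:
            continue
        den += 1
        if v:
            num += 1
    return Rate(num, den)


def continuous_values(
    records: Iterable[InfantRecord],
    item: ItemDefinition,
    unit: str | None = None,
    exclude_unit: str | None = None,
    period: Period | None = None,
) -> list[float]:
    """Non-missing values of a continuous item under its denominator rule."""
    out = []
    for r in select(records, unit=unit, exclude_unit=exclude_unit, period=period):
        if not is_eligible(r, item):
            continue
        v = item_value(r, item.name)
        if v is None or v is NOT_APPLICABLE:
            continue
        out.append(float(v))
    return out


def completeness_by_item(
    records: Iterable[InfantRecord],
    unit: str | None,
    item: ItemDefinition,
    period: Period | None = None,
) -> float | None:
    """Fraction of denominator-eligible records with an answered value.

    Structurally-missing (inapplicable) values are excluded from the
    denominator.  Returns None (undefined) when no record is eligible --
    deliberately distinct from 0.0.
    """
    answered = eligible = 0
    for r in select(records, unit=unit, period=period):
        if not is_eligible(r, item):
            continue
        v = item_value(r, item.name)
        if v is NOT_APPLICABLE:
            continue
        eligible += 1
        if v is not None:
            answered += 1
    if eligible == 0:
        return None
    return answered / eligible


# ---------------------------------------------------------------------------
# Plausibility validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    rule_id: str
    field: str
    message: str
    severity: str = "error"  # "error" | "warning"


@dataclass
class PlausibilityRules:
    """Configurable plausibility catalogue.

    Defaults target the 501-1500 g live-birth collective; other collectives
    swap in their own ranges without touching the record schema.
    """

    weight_range: tuple[float, float] = (501.0, 1500.0)
    ga_range: tuple[GestationalAge, GestationalAge] = (
        GestationalAge(22, 0),
        GestationalAge(36, 6),
    )
    uaph_range: tuple[float, float] = (6.5, 7.6)
    check_logical: bool = True


def validate_record(
    record: InfantRecord,
    dictionary: DataDictionary,
    rules: PlausibilityRules | None = None,
) -> list[Violation]:
    """Completeness and plausibility checks for a single record.

    Returns the violated rules; never mutates the record.  Severity "error"
    marks the record as erroneous and due for correction at the source unit.
    """
    if len(dictionary) == 0:
        raise ValueError("data dictionary must be non-empty")
    rules = rules or PlausibilityRules()
    out: list[Violation] = []

    for name in record.items:
        if name not in dictionary:
            out.append(
                Violation("unknown_item", name, f"item {name!r} not in data dictionary")
            )

    bw = record.birth_weight
    if bw is not None:
        lo, hi = rules.weight_range
        if not lo <= bw <= hi:
            out.append(
                Violation(
                    "weight_range",
                    "birth_weight",
                    f"birth weight {bw:g} g outside collective range {lo:g}-{hi:g} g",
                )
            )
    ga = record.gestational_age
    if ga is not None:
        lo_ga, hi_ga = rules.ga_range
        if not lo_ga <= ga <= hi_ga:
            out.append(
                Violation(
                    "ga_range",
                    "gestational_age",
                    f"gestational age {ga} outside {lo_ga}-{hi_ga}",
                )
            )

    uaph = record.items.get("uaph_value")
    if isinstance(uaph, (int, float)):
        lo_p, hi_p = rules.uaph_range
        if not lo_p <= uaph <= hi_p:
            out.append(
                Violation(
                    "uaph_range", "uaph_value", f"umbilical artery pH {uaph:g} implausible"
                )
            )

    if rules.check_logical:
        cpap_wo = record.items.get("cpap_without_mv")
        cpap = record.items.get("cpap")
        mv = record.items.get("mechanical_ventilation")
        if cpap_wo is True and (cpap is False or mv is True):
            out.append(
                Violation(
                    "cpap_without_mv_consistency",
                    "cpap_without_mv",
                    "CPAP-without-MV requires CPAP and no mechanical ventilation",
                )
            )
        if record.items.get("surfactant") is True and record.delivery_room_death:
            out.append(
                Violation(
                    "surfactant_implies_admitted",
                    "surfactant",
                    "surfactant recorded for a delivery-room death",
                )
            )
        if record.delivery_room_death:
            for it in dictionary:
                if it.denominator is Denominator.ALL_LIVEBIRTHS:
                    continue
                v = record.items.get(it.name)
                if v is not None and v is not NOT_APPLICABLE:
                    out.append(
                        Violation(
                            "delivery_room_reduced_set",
                            it.name,
                            "NICU-course item answered for a delivery-room death",
                        )
                    )
    return out


@dataclass
class ValidationReport:
    """Cohort-level validation outcome.

    ``violations`` maps record_id -> list of violations; ``completeness``
    maps (unit_id, item name) -> fraction (None = undefined).
    """

    violations: dict[str, list[Violation]]
    completeness: dict[tuple[str, str], float | None]

    @property
    def n_erroneous(self) -> int:
        return sum(
            1
            for v in self.violations.values()
            if any(x.severity == "error" for x in v)
        )

    def is_plausible(self, record_id: str) -> bool:
        return not self.violations.get(record_id)


def validate_cohort(
    records: Sequence[InfantRecord],
    dictionary: DataDictionary,
    rules: PlausibilityRules | None = None,
    period: Period | None = None,
) -> ValidationReport:
    """Validate every record and tabulate per-unit, per-item completeness."""
    violations: dict[str, list[Violation]] = {}
    for r in records:
        v = validate_record(r, dictionary, rules)
        if v:
            violations[r.record_id] = v
    units = sorted({r.unit_id for r in records})
    completeness: dict[tuple[str, str], float | None] = {}
    for u in units:
        for it in dictionary:
            completeness[(u, it.name)] = completeness_by_item(
                records, u, it, period=period
            )
    return ValidationReport(violations=violations, completeness=completeness)


# ---------------------------------------------------------------------------
# Default data dictionary (24 benchmark items of the VLBW collective)
# ---------------------------------------------------------------------------

_P = ItemKind.PROCESS
_O = ItemKind.OUTCOME
_ALL = Denominator.ALL_LIVEBIRTHS
_ADM = Denominator.ADMITTED
_SURV = Denominator.SURVIVORS
_S36 = Denominator.SURVIVORS_AT_36W


def default_dictionary() -> DataDictionary:
    """The 24-item VLBW benchmark dictionary.

    Five process and fifteen outcome quality indicators, plus four
    benchmark-only items.  Umbilical-artery-pH measurement is the one
    QI-eligible item excluded from benchmarking diagrams.
    """
    return DataDictionary(
        [
            ItemDefinition("inborn", _P, _ALL, qi_eligible=True),
            ItemDefinition("uaph_measured", _P, _ALL, qi_eligible=True, benchmark_eligible=False),
            ItemDefinition("caesarean_section", _P, _ALL, qi_eligible=True),
            ItemDefinition("full_prenatal_steroids", _P, _ALL, qi_eligible=True),
            ItemDefinition("any_prenatal_steroids", _P, _ALL, qi_eligible=True),
            ItemDefinition("major_birth_defects", _O, _ALL),
            ItemDefinition("mortality", _O, _ALL, qi_eligible=True),
            ItemDefinition("pda", _O, _ADM, qi_eligible=True),
            ItemDefinition("pph", _O, _ADM, qi_eligible=True),
            ItemDefinition("nec", _O, _ADM, qi_eligible=True),
            ItemDefinition("early_onset_sepsis", _O, _ADM, qi_eligible=True),
            ItemDefinition("late_onset_sepsis", _O, _ADM, qi_eligible=True),
            ItemDefinition("o2_at_36w", _O, _S36, qi_eligible=True),
            ItemDefinition("mechanical_ventilation", _O, _ADM, qi_eligible=True),
            ItemDefinition("cpap", _O, _ADM, qi_eligible=True),
            ItemDefinition("cpap_without_mv", _O, _ADM, qi_eligible=True),
            ItemDefinition("surfactant", _O, _ADM, qi_eligible=True),
            ItemDefinition("rop_3_4", _O, _ADM, qi_eligible=True),
            ItemDefinition("pih_3_4", _O, _ADM, qi_eligible=True),
            ItemDefinition("cpvl", _O, _ADM, qi_eligible=True),
            ItemDefinition("growth_restriction", _O, _ADM, qi_eligible=True),
            ItemDefinition("surgery", _O, _ADM),
            ItemDefinition("length_of_stay", _O, _ADM, continuous=True),
            ItemDefinition("length_of_stay_survivors", _O, _SURV, continuous=True),
            # raw pH value behind the uaph_measured process item; collected,
            # plausibility-checked, but never benchmarked directly
            ItemDefinition("uaph_value", _P, _ALL, benchmark_eligible=False, continuous=True),
        ]
    )
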