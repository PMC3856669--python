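"""Synthetic multi-unit VLBW cohorts with the structure the analyses assume.

No VLBW registry dataset is publicly deposited (patient-level neonatal data
is confidential), so this module generates cohorts that emulate a nine-unit,
multi-year national network: each infant draws a gestational-age stratum,
then each care item independently from a per-stratum (optionally per-unit)
Bernoulli rate, then per-item missingness masks answers.  Items whose
denominators exclude delivery-room deaths or non-survivors are marked
structurally missing on ineligible records.

The default configuration is calibrated to the published scale of a Swiss-
style network: nine level-III units totalling 2025 live-births over a pooled
three-year period (unit sizes 96-387), overall mortality ~13.6%, 52.2% male,
36.0% multiples, and stratum gradients that make mortality, ventilation,
surfactant and oxygen-dependence strongly gestational-age dependent.

Items are generated independently given the stratum -- except CPAP-without-
mechanical-ventilation, which is derived from the CPAP and ventilation draws
so the generated records never violate their own logical-consistency rule.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .records import (
    NOT_APPLICABLE,
    DataDictionary,
    GestationalAge,
    InfantRecord,
    default_dictionary,
)
from .qi import GA_STRATA, STRATUM_LABELS

#: Inclusive completed-week spans used to draw a GA inside each stratum.
_STRATUM_WEEKS = {
    "below_24": (22, 23),
    "24_25": (24, 25),
    "26_27": (26, 27),
    "28_29": (28, 29),
    "30_31": (30, 31),
    "above_31": (32, 35),
}

RateSpec = float | Mapping[str, float]


@dataclass
class SimulationConfig:
    """Cohort generator settings.

    ``item_rates`` maps item name to either a flat probability or a
    per-stratum map; ``unit_rate_overrides`` overlays unit-specific rates.
    ``missingness`` maps item name to a flat missing probability or a
    per-unit map.  ``shifts`` lists (unit, item, effective ISO date, new
    rate) step changes applied after generation.
    """

    units: list[tuple[str, int]]  # (unit_id, annual live-births)
    years: tuple[int, int]  # inclusive
    ga_distribution: dict[str, float]
    item_rates: dict[str, RateSpec]
    missingness: dict[str, RateSpec] = field(default_factory=dict)
    shifts: list[tuple[str, str, str, float]] = field(default_factory=list)
    unit_rate_overrides: dict[str, dict[str, RateSpec]] = field(default_factory=dict)
    p_male: float = 0.522
    p_multiple: float = 0.360
    p_delivery_room_death_given_death: float = 0.30
    los_median_days: float = 49.0
    los_sigma: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not self.units:
            raise ValueError("at least one unit required")
        for uid, n in self.units:
            if n <= 0:
                raise ValueError(f"unit {uid!r} has non-positive annual size {n}")
        if set(self.ga_distribution) != set(STRATUM_LABELS):
            raise ValueError("ga_distribution must cover exactly the six GA strata")
        total = sum(self.ga_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"ga_distribution sums to {total!r}, not 1")
        for lbl, p in self.ga_distribution.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"stratum probability out of [0,1]: {lbl}={p}")
        for item, spec in self.item_rates.items():
            for p in (spec.values() if isinstance(spec, Mapping) else [spec]):
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"rate out of [0,1] for item {item!r}")
        for item, spec in self.missingness.items():
            for p in (spec.values() if isinstance(spec, Mapping) else [spec]):
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"missingness out of [0,1] for item {item!r}")
        for p in (self.p_male, self.p_multiple, self.p_delivery_room_death_given_death):
            if not 0.0 <= p <= 1.0:
                raise ValueError("demographic probabilities must lie in [0,1]")

    def rate(self, unit: str, item: str, stratum: str) -> float:
        spec = self.unit_rate_overrides.get(unit, {}).get(item)
        if spec is None:
            spec = self.item_rates[item]
        if isinstance(spec, Mapping):
            return float(spec[stratum])
        return float(spec)

    def missing_prob(self, unit: str, item: str) -> float:
        spec = self.missingness.get(item, 0.0)
        if isinstance(spec, Mapping):
            return float(spec.get(unit, 0.0))
        return float(spec)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["units"] = [list(u) for u in self.units]
        d["years"] = list(self.years)
        d["shifts"] = [list(s) for s in self.shifts]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        d["units"] = [tuple(u) for u in d["units"]]
        d["years"] = tuple(d["years"])
        d["shifts"] = [tuple(s) for s in d.get("shifts", [])]
        return cls(**d)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def default_config(seed: int = 0) -> SimulationConfig:
    """Nine-unit network at published national scale (2025 infants / 3 y)."""
    units = [
        ("U1", 32), ("U2", 45), ("U3", 55), ("U4", 62), ("U5", 70),
        ("U6", 78), ("U7", 92), ("U8", 112), ("U9", 129),
    ]
    ga = {
        "below_24": 0.04, "24_25": 0.13, "26_27": 0.20,
        "28_29": 0.27, "30_31": 0.24, "above_31": 0.12,
    }
    rates: dict[str, RateSpec] = {
        "inborn": 0.950,
        "uaph_measured": 0.827,
        "caesarean_section": 0.772,
        "full_prenatal_steroids": 0.711,
        "any_prenatal_steroids": 0.879,
        "major_birth_defects": 0.050,
        "mortality": {
            "below_24": 0.85, "24_25": 0.35, "26_27": 0.15,
            "28_29": 0.07, "30_31": 0.04, "above_31": 0.03,
        },
        "pda": {
            "below_24": 0.65, "24_25": 0.55, "26_27": 0.42,
            "28_29": 0.28, "30_31": 0.14, "above_31": 0.07,
        },
        "pph": 0.054,
        "nec": 0.020,
        "early_onset_sepsis": 0.020,
        "late_onset_sepsis": {
            "below_24": 0.25, "24_25": 0.18, "26_27": 0.11,
            "28_29": 0.06, "30_31": 0.03, "above_31": 0.02,
        },
        "o2_at_36w": {
            "below_24": 0.55, "24_25": 0.30, "26_27": 0.15,
            "28_29": 0.07, "30_31": 0.03, "above_31": 0.02,
        },
        "mechanical_ventilation": {
            "below_24": 0.95, "24_25": 0.85, "26_27": 0.70,
            "28_29": 0.50, "30_31": 0.35, "above_31": 0.25,
        },
        "cpap": 0.784,
        "surfactant": {
            "below_24": 0.90, "24_25": 0.80, "26_27": 0.65,
            "28_29": 0.45, "30_31": 0.28, "above_31": 0.18,
        },
        "rop_3_4": {
            "below_24": 0.15, "24_25": 0.08, "26_27": 0.03,
            "28_29": 0.01, "30_31": 0.003, "above_31": 0.001,
        },
        "pih_3_4": {
            "below_24": 0.25, "24_25": 0.15, "26_27": 0.08,
            "28_29": 0.04, "30_31": 0.02, "above_31": 0.01,
        },
        "cpvl": 0.023,
        "growth_restriction": 0.094,
        "surgery": 0.103,
    }
    missingness = {
        "rop_3_4": 0.15,
        "o2_at_36w": 0.02,
        "full_prenatal_steroids": 0.03,
        "any_prenatal_steroids": 0.03,
        "growth_restriction": 0.02,
        "length_of_stay": 0.013,
        "length_of_stay_survivors": 0.013,
        "pih_3_4": 0.01,
        "cpvl": 0.01,
    }
    return SimulationConfig(
        units=units,
        years=(2006, 2011),
        ga_distribution=ga,
        item_rates=rates,
        missingness=missingness,
        seed=seed,
    )


def _draw_ga(rng: np.random.Generator, stratum: str) -> GestationalAge:
    lo, hi = _STRATUM_WEEKS[stratum]
    weeks = int(rng.integers(lo, hi + 1))
    days = int(rng.integers(0, 7))
    return GestationalAge(weeks, days)


def _draw_birth_weight(rng: np.random.Generator, ga: GestationalAge) -> float:
    mean = 500.0 + 62.0 * (ga.weeks - 23) + 9.0 * ga.days
    bw = rng.normal(mean, 120.0)
    return float(min(1500.0, max(501.0, round(bw))))


def generate_cohort(
    config: SimulationConfig,
    dictionary: DataDictionary | None = None,
) -> tuple[list[InfantRecord], dict]:
    """Generate a reproducible cohort; returns (records, metadata).

    A single pseudo-random stream seeded from ``config.seed`` drives every
    draw, so identical configs give identical cohorts.  Step changes listed
    in ``config.shifts`` are applied afterwards via :func:`inject_shift`
    with seeds derived from the same stream.
    """
    config.validate()
    dictionary = dictionary or default_dictionary()
    rng = np.random.default_rng(config.seed)
    labels = list(STRATUM_LABELS)
    probs = np.array([config.ga_distribution[l] for l in labels])
    y0, y1 = config.years
    records: list[InfantRecord] = []
    for unit_id, annual_n in config.units:
        for year in range(y0, y1 + 1):
            year_start = dt.date(year, 1, 1)
            days_in_year = (dt.date(year + 1, 1, 1) - year_start).days
            for i in range(annual_n):
                stratum = labels[int(rng.choice(len(labels), p=probs))]
                ga = _draw_ga(rng, stratum)
                bw = _draw_birth_weight(rng, ga)
                birth_date = year_start + dt.timedelta(days=int(rng.integers(days_in_year)))
                sex = "male" if rng.random() < config.p_male else "female"
                multiple = bool(rng.random() < config.p_multiple)
                died = rng.random() < config.rate(unit_id, "mortality", stratum)
                drd = bool(died and rng.random() < config.p_delivery_room_death_given_death)
                items: dict = {"mortality": bool(died)}

                def bern(name: str) -> bool:
                    return bool(rng.random() < config.rate(unit_id, name, stratum))

                # all-livebirth items
                for name in (
                    "inborn", "caesarean_section", "full_prenatal_steroids",
                    "any_prenatal_steroids", "major_birth_defects", "uaph_measured",
                ):
                    items[name] = bern(name)
                items["uaph_value"] = (
                    float(round(rng.normal(7.27, 0.08), 2))
                    if items["uaph_measured"]
                    else NOT_APPLICABLE
                )
                # NICU-course items: inapplicable for delivery-room deaths
                admitted_items = (
                    "pda", "pph", "nec", "early_onset_sepsis", "late_onset_sepsis",
                    "mechanical_ventilation", "cpap", "surfactant", "rop_3_4",
                    "pih_3_4", "cpvl", "growth_restriction", "surgery",
                )
                if drd:
                    for name in admitted_items:
                        items[name] = NOT_APPLICABLE
                    items["cpap_without_mv"] = NOT_APPLICABLE
                    items["length_of_stay"] = NOT_APPLICABLE
                else:
                    for name in admitted_items:
                        items[name] = bern(name)
                    # derived so the record satisfies its own logic rule
                    items["cpap_without_mv"] = bool(
                        items["cpap"] and not items["mechanical_ventilation"]
                    )
                    los = float(
                        round(config.los_median_days * math.exp(rng.normal(0.0, config.los_sigma)), 1)
                    )
                    items["length_of_stay"] = los
                # survivor-only items
                if died:
                    items["o2_at_36w"] = NOT_APPLICABLE
                    items["length_of_stay_survivors"] = NOT_APPLICABLE
                else:
                    items["o2_at_36w"] = bern("o2_at_36w")
                    items["length_of_stay_survivors"] = items["length_of_stay"]

                # mask answers per-item missingness (values only; eligibility
                # and counts of eligible records are untouched)
                for name in config.missingness:
                    p_miss = config.missing_prob(unit_id, name)
                    if p_miss <= 0.0 or name not in items:
                        continue
                    if items[name] is NOT_APPLICABLE:
                        continue
                    if rng.random() < p_miss:
                        items[name] = None

                records.append(
                    InfantRecord(
                        record_id=f"{unit_id}-{year}-{i:04d}",
                        unit_id=unit_id,
                        birth_date=birth_date,
                        gestational_age=ga,
                        birth_weight=bw,
                        sex=sex,
                        multiple_birth=multiple,
                        delivery_room_death=drd,
                        items=items,
                    )
                )
    for unit, item, date_str, new_rate in config.shifts:
        shift_seed = int(rng.integers(0, 2**31 - 1))
        records = inject_shift(
            records, unit, item, dt.date.fromisoformat(date_str), new_rate, shift_seed
        )
    meta = {
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "n_records": len(records),
        "units": [u for u, _ in config.units],
        "years": list(config.years),
    }
    return records, meta


def inject_shift(
    records: Sequence[InfantRecord],
    unit: str,
    item: str,
    effective_date: dt.date,
    new_rate: float,
    seed: int,
) -> list[InfantRecord]:
    """Re-draw a binary item at ``new_rate`` for one unit from a date onward.

    Returns a new record list; records outside the (unit, date) window are
    the same objects, untouched.  Missing and structurally-missing values
    keep their markers -- only answered values are re-drawn.
    """
    if not 0.0 <= new_rate <= 1.0:
        raise ValueError("new_rate must lie in [0, 1]")
    known_units = {r.unit_id for r in records}
    if unit not in known_units:
        raise ValueError(f"unknown unit {unit!r}")
    if not any(item in r.items for r in records):
        raise ValueError(f"unknown item {item!r}")
    rng = np.random.default_rng(seed)
    out: list[InfantRecord] = []
    for r in records:
        if r.unit_id != unit or r.birth_date < effective_date:
            out.append(r)
            continue
        v = r.items.get(item)
        if v is None or v is NOT_APPLICABLE or not isinstance(v, bool):
            out.append(r)
            continue
        new_items = dict(r.items)
        new_items[item] = bool(rng.random() < new_rate)
        out.append(dataclasses.replace(r, items=new_items))
    return out
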