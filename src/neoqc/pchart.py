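"""Plsek p-charts: one chart per item per unit versus the rest-collective.

The chart plots one dot per calendar year: the unit's annual proportion next
to the pooled proportion of all *other* units (the rest-collective).  Flat
horizontal lines mark each series' pooled mean over the charted period and
the unit's +/-1, +/-2 and +/-3 standard-deviation bands, with

    SD = sqrt( mean * (1 - mean) / sample_size )

where ``sample_size`` is the unit's mean annual denominator -- the size of a
single plotted dot.  Control limits sit by convention at mean +/- 3 SD
(clipped to [0, 1]); a year whose unit proportion falls strictly outside the
limits is a signal.  Because the limits are calibrated to the sampling noise
of one year's dot, a unit at a stable rate signals in roughly 0.27% of
unit-years, the two-sided normal tail beyond three sigma.

Usage follows the model/results idiom::

    res = PChartModel(records, unit="U3", item=d["mortality"],
                      years=range(2009, 2012)).fit()
    res.signals        # years flagged
    res.summary()      # per-year table
    res.plot()         # the rendered chart
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .records import (
    InfantRecord,
    ItemDefinition,
    Period,
    Rate,
    compute_rate,
)


@dataclass(frozen=True)
class PChartLimits:
    """SD and control limits for a pooled mean proportion.

    ``ucl``/``lcl`` are clipped to [0, 1]; the raw (unclipped) values retain
    the exact symmetry ucl_raw - mean = mean - lcl_raw = 3 SD.
    """

    mean: float
    sample_size: float
    sd: float
    ucl: float
    lcl: float
    ucl_raw: float
    lcl_raw: float
    bands: dict[int, tuple[float, float]]  # k -> (lower, upper), clipped
    clipped: bool


def pchart_limits(mean_proportion: float, sample_size: float) -> PChartLimits:
    """Control limits from the p-chart SD formula.

    ``sample_size`` is the denominator behind one plotted dot (for a chart,
    the unit's mean annual denominator).  Degenerate means of exactly 0 or 1
    give SD = 0 and coincident limits.
    """
    if not 0.0 <= mean_proportion <= 1.0:
        raise ValueError("mean proportion must lie in [0, 1]")
    if sample_size < 1:
        raise ValueError("sample size must be at least 1")
    sd = math.sqrt(mean_proportion * (1.0 - mean_proportion) / sample_size)
    ucl_raw = mean_proportion + 3.0 * sd
    lcl_raw = mean_proportion - 3.0 * sd
    bands = {}
    for k in (1, 2, 3):
        bands[k] = (max(0.0, mean_proportion - k * sd), min(1.0, mean_proportion + k * sd))
    ucl = min(1.0, ucl_raw)
    lcl = max(0.0, lcl_raw)
    return PChartLimits(
        mean=mean_proportion,
        sample_size=sample_size,
        sd=sd,
        ucl=ucl,
        lcl=lcl,
        ucl_raw=ucl_raw,
        lcl_raw=lcl_raw,
        bands=bands,
        clipped=(ucl != ucl_raw) or (lcl != lcl_raw),
    )


@dataclass(frozen=True)
class YearPoint:
    year: int
    unit_rate: Rate
    rest_rate: Rate

    @property
    def unit_p(self) -> float | None:
        return self.unit_rate.proportion

    @property
    def rest_p(self) -> float | None:
        return self.rest_rate.proportion


def annual_series(
    records: Iterable[InfantRecord],
    unit: str,
    item: ItemDefinition,
    years: Sequence[int],
) -> list[YearPoint]:
    """Per-year unit and rest-collective proportions.

    The rest-collective pools every other unit's records.  Years with no
    eligible answered record are carried as undefined rates (gaps), never as
    zeros.
    """
    if not years:
        raise ValueError("years must be non-empty")
    records = list(records)
    if not any(r.unit_id == unit for r in records):
        raise ValueError(f"unit {unit!r} has no records")
    pts = []
    for y in years:
        per = Period.year(y)
        pts.append(
            YearPoint(
                year=y,
                unit_rate=compute_rate(records, item, unit=unit, period=per),
                rest_rate=compute_rate(records, item, exclude_unit=unit, period=per),
            )
        )
    return pts


def detect_signals(points: Sequence[YearPoint], limits: PChartLimits) -> list[int]:
    """Years whose unit proportion lies strictly outside [lcl, ucl].

    A point exactly on a limit does not signal; undefined years are skipped.
    """
    out = []
    for pt in points:
        p = pt.unit_p
        if p is None:
            continue
        if p > limits.ucl or p < limits.lcl:
            out.append(pt.year)
    return out


class PChartModel:
    """p-chart for one unit x item over a span of calendar years."""

    def __init__(
        self,
        records: Iterable[InfantRecord],
        unit: str,
        item: ItemDefinition,
        years: Sequence[int],
    ):
        self.records = list(records)
        self.unit = unit
        self.item = item
        self.years = list(years)

    def fit(self) -> "PChartResults":
        pts = annual_series(self.records, self.unit, self.item, self.years)
        period = Period.from_years(self.years[0], self.years[-1])
        unit_pooled = compute_rate(self.records, self.item, unit=self.unit, period=period)
        rest_pooled = compute_rate(
            self.records, self.item, exclude_unit=self.unit, period=period
        )
        limits = None
        signals: list[int] = []
        if unit_pooled.defined:
            years_with_data = sum(1 for p in pts if p.unit_rate.defined)
            mean_annual_n = unit_pooled.denominator / max(years_with_data, 1)
            limits = pchart_limits(unit_pooled.proportion, mean_annual_n)
            signals = detect_signals(pts, limits)
        return PChartResults(
            unit=self.unit,
            item=self.item.name,
            points=pts,
            unit_pooled=unit_pooled,
            rest_pooled=rest_pooled,
            limits=limits,
            signals=signals,
        )


@dataclass
class PChartResults:
    unit: str
    item: str
    points: list[YearPoint]
    unit_pooled: Rate
    rest_pooled: Rate
    limits: PChartLimits | None
    signals: list[int]

    @property
    def unit_mean(self) -> float | None:
        return self.unit_pooled.proportion

    @property
    def rest_mean(self) -> float | None:
        return self.rest_pooled.proportion

    def summary(self) -> pd.DataFrame:
        """One row per charted year with rates, counts and signal flags."""
        rows = []
        for pt in self.points:
            rows.append(
                {
                    "year": pt.year,
                    "unit_n": pt.unit_rate.denominator,
                    "unit_p": pt.unit_p,
                    "rest_n": pt.rest_rate.denominator,
                    "rest_p": pt.rest_p,
                    "signal": pt.year in self.signals,
                }
            )
        df = pd.DataFrame(rows)
        df.attrs.update(
            unit=self.unit,
            item=self.item,
            unit_mean=self.unit_mean,
            rest_mean=self.rest_mean,
            sd=self.limits.sd if self.limits else None,
            ucl=self.limits.ucl if self.limits else None,
            lcl=self.limits.lcl if self.limits else None,
        )
        return df

    def to_dict(self) -> dict:
        d = {
            "unit": self.unit,
            "item": self.item,
            "unit_mean": self.unit_mean,
            "rest_mean": self.rest_mean,
            "sd": self.limits.sd if self.limits else None,
            "ucl": self.limits.ucl if self.limits else None,
            "lcl": self.limits.lcl if self.limits else None,
            "signals": list(self.signals),
            "years": [
                {
                    "year": pt.year,
                    "unit_n": pt.unit_rate.denominator,
                    "unit_p": pt.unit_p,
                    "rest_n": pt.rest_rate.denominator,
                    "rest_p": pt.rest_p,
                }
                for pt in self.points
            ],
        }
        return d

    def plot(self, ax=None):
        """Render the chart: both series, mean lines, dotted +/-1/2 SD and
        dashed +/-3 SD bands."""
        import matplotlib

        if ax is None:
            import matplotlib.pyplot as plt

            _, ax = plt.subplots(figsize=(7, 4))
        ys = [pt.year for pt in self.points]
        ax.plot(ys, [pt.unit_p for pt in self.points], "o-", label=f"unit {self.unit}")
        ax.plot(ys, [pt.rest_p for pt in self.points], "s--", color="gray", label="rest")
        if self.unit_mean is not None:
            ax.axhline(self.unit_mean, color="C0", lw=1)
        if self.rest_mean is not None:
            ax.axhline(self.rest_mean, color="gray", lw=1)
        if self.limits is not None:
            for k in (1, 2):
                lo, hi = self.limits.bands[k]
                ax.axhline(lo, ls=":", color="C0", lw=0.8)
                ax.axhline(hi, ls=":", color="C0", lw=0.8)
            ax.axhline(self.limits.ucl, ls="--", color="C3", lw=1.2)
            ax.axhline(self.limits.lcl, ls="--", color="C3", lw=1.2)
        ax.set_xlabel("year")
        ax.set_ylabel(self.item)
        ax.set_ylim(-0.02, 1.02)
        ax.legend(loc="best", fontsize=8)
        return ax
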