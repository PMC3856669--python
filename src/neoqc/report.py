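"""The quality cycle as one reproducible report run.

``run_cycle`` chains the stages guideline -> perform -> falsify -> reform as
they appear in data form: ingest and validate the cohort, apply the three
data-quality gates, draw p-charts for every benchmark-eligible item x unit,
compute the GA-adjusted quality indicators, assemble the benchmark tables,
and finish with a findings list -- every (unit, item) showing a p-chart
signal or a significant SMR that survived the gates.  Identical inputs give
a byte-identical JSON bundle (timestamps are deliberately externalized).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .benchmarks import reference_comparison_table, unit_extremes_table
from .config import RunConfig
from .io import read_cohort, write_cohort
from .pchart import PChartModel
from .qi import QualityIndicatorModel
from .quality import registry_coverage, reliability_tally
from .records import (
    DataDictionary,
    InfantRecord,
    Period,
    default_dictionary,
    select,
    validate_cohort,
)

log = logging.getLogger("neoqc")


def load_cohort(path, dictionary: DataDictionary | None = None):
    """Read a cohort CSV; returns (records, row_errors)."""
    return read_cohort(path, dictionary)


def run_cycle(
    records: Sequence[InfantRecord],
    config: RunConfig | None = None,
    dictionary: DataDictionary | None = None,
) -> dict:
    """Execute the full cycle and return the report bundle (pure data)."""
    config = config or RunConfig()
    dictionary = dictionary or default_dictionary()
    records = list(records)
    period = Period.from_years(*config.period)
    baseline = Period.from_years(*config.baseline)
    chart_years = list(range(config.baseline[0], config.period[1] + 1))
    units = sorted({r.unit_id for r in records})

    bundle: dict = {
        "config": config.to_dict(),
        "n_records": len(records),
        "units": units,
    }

    # -- validate -----------------------------------------------------------
    vrep = validate_cohort(records, dictionary, period=period)
    bundle["validation"] = {
        "n_erroneous_records": vrep.n_erroneous,
        "violations": {
            rid: [
                {"rule": v.rule_id, "field": v.field, "severity": v.severity}
                for v in vs
            ]
            for rid, vs in sorted(vrep.violations.items())
        },
        "completeness_pct": {
            f"{u}:{item}": None if frac is None else round(100 * frac, 1)
            for (u, item), frac in sorted(vrep.completeness.items())
        },
    }

    # -- registry record completeness --------------------------------------
    coverage = {}
    for year, reg_n in sorted(config.registry_counts.items()):
        net_n = len(select(records, period=Period.year(year)))
        cov = registry_coverage(net_n, reg_n)
        log.info("registry coverage %s: %.1f%%", year, cov.percentage)
        coverage[str(year)] = {
            "network": cov.network_count,
            "registry": cov.registry_count,
            "coverage_pct": cov.percentage,
            "overcount_warning": cov.overcount_warning,
        }
    bundle["registry_coverage"] = coverage

    # -- p-charts (benchmark-eligible binary items) -------------------------
    pcharts = []
    findings: list[dict] = []
    for item in dictionary.benchmark_items():
        if item.continuous:
            continue
        for u in units:
            try:
                res = PChartModel(records, u, item, chart_years).fit()
            except Exception as exc:  # item skipped, run continues
                log.warning("p-chart %s/%s skipped: %s", u, item.name, exc)
                continue
            pcharts.append(res.to_dict())
            for year in res.signals:
                findings.append(
                    {"unit": u, "item": item.name, "kind": "pchart_signal", "year": year}
                )
    bundle["pcharts"] = pcharts

    # -- quality indicators (gates + SMR) -----------------------------------
    qi_res = QualityIndicatorModel(
        records,
        dictionary,
        period,
        baseline,
        level=config.ci_level,
        completeness_threshold=config.completeness_threshold,
        overrides=config.reliability_overrides,
    ).fit()
    qi_df = qi_res.summary()
    bundle["qi_table"] = json.loads(qi_df.to_json(orient="records"))
    bundle["qi_unknown_ga"] = qi_res.n_unknown_ga
    for row in qi_res.findings():
        findings.append(
            {"unit": row.unit_id, "item": row.item, "kind": "qi_significant"}
        )
    for series in qi_res.reliability:
        if series.excluded:
            log.info("gate reliability: %s/%s unreliable", series.unit_id, series.item)
    tally = reliability_tally(qi_res.reliability)
    bundle["reliability_tally"] = {
        item: {"reliable": t[0], "partially_reliable": t[1], "unreliable": t[2]}
        for item, t in sorted(tally.items())
    }

    # -- benchmark tables ----------------------------------------------------
    gated = {
        (r.unit_id, r.item): r.exclusion_reason for r in qi_res.rows if r.excluded
    }
    extremes = unit_extremes_table(
        records,
        dictionary.benchmark_items(),
        period=period,
        alpha=config.alpha,
        gated_out=gated,
    )
    bundle["unit_extremes"] = [
        {
            "item": e.item,
            "min_unit": e.min_unit,
            "min_value": e.min_value,
            "min_star": e.min_star,
            "max_unit": e.max_unit,
            "max_value": e.max_value,
            "max_star": e.max_star,
            "skipped_units": list(e.skipped_units),
        }
        for e in extremes
    ]
    if config.references:
        ref_df = reference_comparison_table(
            select(records, period=period), dictionary.benchmark_items(), config.references
        )
        bundle["reference_comparison"] = json.loads(ref_df.to_json(orient="records"))

    findings.sort(key=lambda f: (f["unit"], f["item"], f["kind"], f.get("year", 0)))
    bundle["findings"] = findings
    return bundle


def write_report(bundle: dict, out_dir, charts: bool = False, records=None,
                 dictionary: DataDictionary | None = None) -> list[Path]:
    """Write the bundle: JSON summary plus CSV tables (optionally charts)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    p = out / "report.json"
    p.write_text(json.dumps(bundle, indent=2, sort_keys=True, allow_nan=False,
                            default=_json_default) + "\n")
    written.append(p)

    for key, name in (
        ("qi_table", "qi_table.csv"),
        ("unit_extremes", "unit_extremes.csv"),
        ("findings", "findings.csv"),
        ("reference_comparison", "reference_comparison.csv"),
    ):
        if key in bundle and bundle[key]:
            df = pd.DataFrame(bundle[key])
            fp = out / name
            df.to_csv(fp, index=False)
            written.append(fp)
    if bundle.get("reliability_tally"):
        rows = [
            {"item": item, **counts} for item, counts in bundle["reliability_tally"].items()
        ]
        fp = out / "reliability_tally.csv"
        pd.DataFrame(rows).to_csv(fp, index=False)
        written.append(fp)

    if charts and records is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        dictionary = dictionary or default_dictionary()
        chart_dir = out / "charts"
        chart_dir.mkdir(exist_ok=True)
        for chart in bundle.get("pcharts", []):
            u, item = chart["unit"], chart["item"]
            years = [y["year"] for y in chart["years"]]
            res = PChartModel(records, u, dictionary[item], years).fit()
            ax = res.plot()
            fp = chart_dir / f"pchart_{item}_{u}.svg"
            ax.figure.savefig(fp)
            plt.close(ax.figure)
            written.append(fp)
    return written


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
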