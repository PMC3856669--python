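"""Run configuration: periods, thresholds, pseudonyms, overrides, references.

Serialized as YAML (or JSON -- YAML is a superset) so a whole report run is
reproducible from one file plus the cohort CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .benchmarks import ReferenceRow
from .quality import COMPLETENESS_THRESHOLD


@dataclass
class RunConfig:
    """Settings for one quality-cycle report run."""

    period: tuple[int, int] = (2009, 2011)  # inclusive years, pooled
    baseline: tuple[int, int] = (2006, 2008)
    completeness_threshold: float = COMPLETENESS_THRESHOLD
    ci_level: float = 0.95
    alpha: float = 0.05
    pseudonyms: dict[str, str] = field(default_factory=dict)
    #: {(unit, item) -> justification} manual reliability overrides
    reliability_overrides: dict[tuple[str, str], str] = field(default_factory=dict)
    #: external aggregate rows for the reference comparison table
    references: list[ReferenceRow] = field(default_factory=list)
    #: {year -> registry live-birth count} for record-completeness checks
    registry_counts: dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "period": list(self.period),
            "baseline": list(self.baseline),
            "completeness_threshold": self.completeness_threshold,
            "ci_level": self.ci_level,
            "alpha": self.alpha,
            "pseudonyms": dict(self.pseudonyms),
            "reliability_overrides": [
                {"unit": u, "item": i, "justification": j}
                for (u, i), j in self.reliability_overrides.items()
            ],
            "references": [
                {"item": r.item, "rate": r.rate, "n": r.n, "source": r.source, "year": r.year}
                for r in self.references
            ],
            "registry_counts": {str(k): v for k, v in self.registry_counts.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        overrides = {
            (o["unit"], o["item"]): o.get("justification", "")
            for o in d.get("reliability_overrides", [])
        }
        refs = [
            ReferenceRow(r["item"], float(r["rate"]), int(r["n"]), r.get("source", "?"), r.get("year"))
            for r in d.get("references", [])
        ]
        return cls(
            period=tuple(d.get("period", (2009, 2011))),
            baseline=tuple(d.get("baseline", (2006, 2008))),
            completeness_threshold=float(d.get("completeness_threshold", COMPLETENESS_THRESHOLD)),
            ci_level=float(d.get("ci_level", 0.95)),
            alpha=float(d.get("alpha", 0.05)),
            pseudonyms=dict(d.get("pseudonyms", {})),
            reliability_overrides=overrides,
            references=refs,
            registry_counts={int(k): int(v) for k, v in d.get("registry_counts", {}).items()},
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
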