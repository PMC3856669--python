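"""Data-quality gates: sectioning, reliability walk, thresholds, coverage."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoqc import (
    Period,
    completeness_gate,
    registry_coverage,
    section_split,
    wald_interval,
)
from neoqc.quality import (
    Section,
    classify,
    count_nonoverlaps,
    reliability_from_counts,
)


# ---------------------------------------------------------------------------
# independent oracle for the skip-and-compare walk
# ---------------------------------------------------------------------------


def oracle_nonoverlaps(series):
    """Brute-force re-statement of the rule from its text.

    ``series`` is a list of (rate, lo, hi) with rate None for empty sections.
    Enumerate the informative sections (defined rate, not 0%/100%) in order;
    count chronologically consecutive informative pairs whose intervals are
    strictly disjoint.
    """
    informative = [
        (r, lo, hi)
        for r, lo, hi in series
        if r is not None and 0.0 < r < 1.0
    ]
    count = 0
    for (r1, lo1, hi1), (r2, lo2, hi2) in zip(informative, informative[1:]):
        if hi1 < lo2 or hi2 < lo1:
            count += 1
    return count


def build_sections(counts, level=0.95):
    out = []
    for i, (num, n) in enumerate(counts):
        per = Period.from_years(2000 + i, 2000 + i)
        if n == 0:
            out.append(Section(per, None, None, None, 0))
        else:
            p = num / n
            lo, hi = wald_interval(p, n, level)
            out.append(Section(per, p, lo, hi, n))
    return out


class TestSectionSplit:
    def test_six_years_gives_eight_nine_month_sections(self):
        secs = section_split(Period.from_years(2009, 2011), Period.from_years(2006, 2008))
        assert len(secs) == 8
        assert secs[0].start == dt.date(2006, 1, 1)
        assert secs[0].end == dt.date(2006, 10, 1)
        for s in secs:
            months = (s.end.year - s.start.year) * 12 + s.end.month - s.start.month
            assert months == 9

    def test_union_covers_combined_period_contiguously(self):
        secs = section_split(Period.from_years(2009, 2011), Period.from_years(2006, 2008))
        assert secs[0].start == dt.date(2006, 1, 1)
        assert secs[-1].end == dt.date(2012, 1, 1)
        for a, b in zip(secs, secs[1:]):
            assert a.end == b.start

    def test_every_date_falls_in_exactly_one_section(self):
        secs = section_split(Period.from_years(2009, 2011), Period.from_years(2006, 2008))
        day = dt.date(2006, 1, 1)
        while day < dt.date(2012, 1, 1):
            assert sum(day in s for s in secs) == 1
            day += dt.timedelta(days=17)

    def test_non_adjacent_periods_rejected(self):
        with pytest.raises(ValueError):
            section_split(Period.from_years(2010, 2012), Period.from_years(2006, 2008))

    def test_indivisible_span_rejected(self):
        with pytest.raises(ValueError):
            section_split(
                Period.from_years(2009, 2011),
                Period.from_years(2007, 2008),
                n_sections=7,
            )


class TestWaldInterval:
    def test_zero_width_at_boundary_rates(self):
        assert wald_interval(0.0, 50) == (0.0, 0.0)
        assert wald_interval(1.0, 50) == (1.0, 1.0)

    def test_contains_point_estimate(self):
        lo, hi = wald_interval(0.3, 60)
        assert lo < 0.3 < hi


class TestReliabilityWalk:
    def test_constant_rate_is_reliable(self):
        series = reliability_from_counts("A", "pda", [(25, 50)] * 8)
        assert series.nonoverlap_count == 0
        assert series.classification == "reliable"

    def test_single_step_is_partially_reliable(self):
        counts = [(10, 100)] * 4 + [(60, 100)] * 4
        series = reliability_from_counts("A", "pda", counts)
        assert series.nonoverlap_count == 1
        assert series.classification == "partially_reliable"

    def test_two_steps_is_unreliable_and_excluded(self):
        counts = [(10, 100)] * 3 + [(60, 100)] * 3 + [(5, 100)] * 2
        series = reliability_from_counts("A", "pda", counts)
        assert series.nonoverlap_count == 2
        assert series.classification == "unreliable"
        assert series.excluded

    def test_boundary_sections_skipped_via_pointer(self):
        # 0.30, 0.00, 0.00, 0.31, then constant: 0.31 compares with 0.30
        counts = [(30, 100), (0, 100), (0, 100)] + [(31, 100)] * 5
        series = reliability_from_counts("A", "pda", counts)
        assert series.nonoverlap_count == 0
        assert series.classification == "reliable"

    def test_boundary_skip_still_detects_real_jump(self):
        counts = [(30, 100), (100, 100), (70, 100)] + [(70, 100)] * 5
        series = reliability_from_counts("A", "pda", counts)
        assert series.nonoverlap_count == 1

    def test_zero_denominator_sections_treated_as_skips(self):
        counts = [(30, 100), (0, 0), (0, 0)] + [(31, 100)] * 5
        series = reliability_from_counts("A", "pda", counts)
        assert series.nonoverlap_count == 0

    def test_wrong_section_count_rejected(self):
        with pytest.raises(ValueError):
            reliability_from_counts("A", "pda", [(1, 10)] * 7)

    def test_manual_override_unexcludes_but_keeps_class(self):
        counts = [(10, 100)] * 3 + [(60, 100)] * 3 + [(5, 100)] * 2
        series = reliability_from_counts("A", "pda", counts)
        series.overridden = True
        assert series.classification == "unreliable"
        assert not series.excluded

    def test_matches_bruteforce_oracle_on_randomized_series(self):
        # >= 10,000 randomized 8-section series incl. 0%/100% and empty ones
        rng = np.random.default_rng(1234)
        for _ in range(10_000):
            counts = []
            for _ in range(8):
                n = int(rng.choice([0, 5, 20, 60, 150]))
                if n == 0:
                    counts.append((0, 0))
                    continue
                kind = rng.random()
                if kind < 0.15:
                    num = 0
                elif kind < 0.30:
                    num = n
                else:
                    num = int(rng.binomial(n, rng.uniform(0.02, 0.98)))
                counts.append((num, n))
            sections = build_sections(counts)
            got = count_nonoverlaps(sections)
            want = oracle_nonoverlaps(
                [(s.rate, s.ci_low, s.ci_high) for s in sections]
            )
            assert got == want, counts

    def test_false_alarm_rate_small_units(self):
        # constant p = 0.3, n = 60 per section: non-reliable fraction < 15%
        rng = np.random.default_rng(7)
        bad = 0
        reps = 3000
        for _ in range(reps):
            counts = [(int(rng.binomial(60, 0.3)), 60) for _ in range(8)]
            s = reliability_from_counts("A", "x", counts)
            bad += s.classification != "reliable"
        assert bad / reps < 0.15

    def test_step_change_detected(self):
        # 0.1 -> 0.7 at the midpoint, n = 100 per section: non-reliable >= 95%
        rng = np.random.default_rng(8)
        detected = 0
        reps = 1000
        for _ in range(reps):
            counts = [(int(rng.binomial(100, 0.1)), 100) for _ in range(4)]
            counts += [(int(rng.binomial(100, 0.7)), 100) for _ in range(4)]
            s = reliability_from_counts("A", "x", counts)
            detected += s.classification != "reliable"
        assert detected / reps >= 0.95


class TestCompletenessGate:
    @pytest.mark.parametrize(
        "fraction,included",
        [(0.899, False), (0.90, True), (1.0, True), (0.0, False)],
    )
    def test_strict_ninety_percent_boundary(self, fraction, included):
        assert completeness_gate(fraction).included is included

    def test_undefined_completeness_excluded_with_distinct_reason(self):
        d = completeness_gate(None)
        assert not d.included
        assert d.reason == "undefined"
        assert completeness_gate(0.5).reason == "below_threshold"

    @settings(max_examples=100, derandomize=True)
    @given(
        st.floats(0, 1, allow_nan=False),
        st.floats(0, 1, allow_nan=False),
    )
    def test_gate_monotone(self, a, b):
        a, b = max(a, b), min(a, b)
        if completeness_gate(b).included:
            assert completeness_gate(a).included


class TestRegistryCoverage:
    @pytest.mark.parametrize(
        "net,reg,pct",
        [(50, 100, 50.0), (2025, 2025, 100.0), (961, 1000, 96.1)],
    )
    def test_percentage_to_one_decimal(self, net, reg, pct):
        assert registry_coverage(net, reg).percentage == pct

    def test_overcount_flagged_but_computed(self):
        cov = registry_coverage(105, 100)
        assert cov.overcount_warning
        assert cov.percentage == 105.0

    def test_zero_registry_rejected(self):
        with pytest.raises(ValueError):
            registry_coverage(10, 0)
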