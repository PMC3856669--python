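# Methods

This note documents the statistical procedures, the synthetic-data model and
the numerical choices behind `neoqc`, in the package's own terms.

## Cohort model and denominators

One record per live-born infant of the 501–1500 g collective, delivery-room
deaths included. Collective membership is a *selector*, not a schema
constraint, so the same record type can serve other collectives (e.g. very
preterm by gestational age). Every care item carries one of four states:
`True`/`False` (answered), `None` (missing answer) or a structurally-missing
marker (`NOT_APPLICABLE`) for items that cannot apply — NICU-course items for
infants who died in the delivery room, survivor items for infants who died
before discharge. Structurally-missing values are excluded from completeness
denominators; missing answers are not.

Each item's denominator rule is part of the data dictionary: all live-births,
admitted alive, survivors to discharge, or survivors at 36 weeks
postmenstrual age. The last is operationalised as survivors to discharge
because the generator does not model time of death; for a cohort where death
timing is recorded the rule can be given its exact predicate. Records whose
survival status is unknown are excluded from survivor denominators.

Period membership uses half-open calendar intervals `[start, end)` on the
birth date, which makes annual series and section splits exact partitions.

Plausibility checking ships a configurable default catalogue (birth weight
within the collective's range, gestational age 22+0–36+6, umbilical-artery pH
in [6.5, 7.6], CPAP-without-ventilation implying CPAP and no ventilation,
delivery-room deaths carrying the reduced item set). Registries differ in
their plausibility rules; the catalogue is a starting point, not a standard.

## Reliability screen

Health-care change is assumed gradual; erratic jumps indicate measurement
problems rather than care changes. The evaluation period and an equally long
baseline immediately before it are split into eight equal whole-month
sections (six years → eight 9-month sections). Each section's item rate gets
a 95% **Wald** interval. Wald is a deliberate choice: the screen's special
rule for 0%/100% sections presupposes an interval that collapses to a point
at the boundary, which holds for Wald and fails for Wilson or
Clopper–Pearson.

The walk keeps a pointer to the last section whose rate was defined and away
from 0%/100%. Each later non-boundary section is compared with the pointer;
strictly disjoint intervals (touching endpoints count as overlap —
conservative) add one erratic change, and the section becomes the new
pointer. Sections at 0%/100%, and sections with an empty denominator, are
skipped without moving the pointer; the empty-denominator case is not covered
by the rule's text and skipping avoids spurious flags for tiny units. Zero
changes ⇒ reliable, one ⇒ partially reliable, two or more ⇒ unreliable
(excluded from evaluation). A manual override — justified by review of
source documentation — removes the exclusion while preserving the computed
class, and is logged.

With small units the screen is deliberately lenient: at a constant rate of
0.3 and 60 infants per section the false-alarm rate measures around 5%
(reported by the acceptance script), and a genuine 0.1→0.7 step with 100 per
section is caught essentially always.

## p-charts

One chart per item per unit versus the rest-collective (all other units'
pooled records — distinct from the full collective used by the SMR
indicators; the asymmetry is intentional and mirrors how each display is
read). Means are pooled proportions (Σ numerators / Σ denominators), never
means of annual rates. The SD formula `sqrt(p̄(1−p̄)/n)` uses the unit's
**mean annual denominator** — the sample size behind a single plotted dot.
This calibrates the ±3 SD limits to the sampling noise of one year's
proportion, so a stable unit signals in ≈0.27% of unit-years (the two-sided
three-sigma tail), which is the property that makes the 3-SD rule a usable
alarm. Using the pooled multi-year denominator instead would shrink the
limits by √(years) and alarm on noise.

Limits are clipped to [0, 1] with the clipping recorded; raw limits keep the
exact symmetry UCL − mean = mean − LCL = 3·SD. "Crossing" is strict: a year
exactly on a limit does not signal, and undefined years (no eligible record)
are gaps, never zeros. Only the 3-SD rule is implemented — no run rules —
matching the display's design goal of being simple enough to generate
automatically for every item × unit.

## Quality indicators

The collective reference **includes** the unit under comparison and its rate
is set to 1. Process items report the crude ratio only; outcome items add
the gestational-age-adjusted SMR by indirect standardization over the six
strata. Records with unknown gestational age go to an `unknown` bucket that
is excluded from adjustment and surfaced as a warning count.

Both ratio intervals treat the observed count as Poisson with mean E·θ and
use **Byar's approximation**, the standard closed-form SMR interval; at
O = 0 the exact Poisson upper bound −ln(α/2)/E is used. Byar is validated in
the tests against the exact chi-square/Poisson quantile interval (agreement
within 0.02–0.03 across the count range used). The crude ratio uses the same
machinery with E = n·p_collective, so diamonds (crude) and squares
(adjusted) in the display are read identically. Whether a binomial interval
would fit the crude ratio better is an open modelling question; the choice
is isolated in one function (`byar_interval`) so it can be swapped.

Significance is strict non-overlap of 1. Under the Poisson model the flag
rate at SMR = 1 is nominal (≈4.4–5% at E = 20, coverage ≈95.6% — Byar is
slightly conservative at moderate counts). On *binomial* cohort data with
the unit inside the collective the test is more conservative still (≈2%
flags in the package's null simulations): the Poisson variance overstates
binomial variance by 1/(1−p), and the shared reference shrinks deviations.
For a screening tool this errs in the safe direction — fewer false alarms —
and is documented rather than corrected.

Gates run before any ratio is reported: completeness strictly below 90% ⇒
excluded (`completeness`), unreliable series ⇒ excluded (`reliability`),
undefined or zero collective rate ⇒ excluded (`undefined-rate`). Every
excluded row keeps its machine-readable reason.

## Benchmark statistics

Pearson chi-square on the 2×2 table, 1 df, **no** continuity correction:
recomputing published comparisons from rounded aggregate (rate, n) pairs
reproduces the printed p-values (0.29 for sex, 0.185→0.193 for mortality,
within the ±0.01 tolerance that count rounding allows) only without the
correction. Comparisons against external networks consume aggregate rows
(item, rate, n, source) because only aggregates are ever published.
Mann–Whitney U is exact by enumeration for combined samples ≤16 without
ties, otherwise normal approximation with tie correction. Significance is
strict two-sided α = 0.05. No multiple-testing correction is applied across
the item table; the tool flags candidates for discussion, it does not make
confirmatory claims — the omission is deliberate and should be kept in mind
when reading star columns.

## Synthetic cohort generator

The generator emulates the statistical structure the analyses assume, not
clinical reality. Defaults define the study conditions: nine units with
annual sizes 32–129 (2025 live-births over the pooled 2009–2011 period,
per-unit three-year sizes 96–387), years 2006–2011 so the reliability screen
has its baseline, stratum distribution (0.04, 0.13, 0.20, 0.27, 0.24, 0.12)
over the six GA strata, and item rates seeded from published all-unit VLBW
rates (mortality 13.6% overall with stratum rates 0.85/0.35/0.15/0.07/0.04/
0.03, ventilation 51.8%, CPAP 78.4%, late-onset sepsis 7.4%, …). Within a
stratum, items are independent Bernoulli draws — sufficient for rate-based
machinery, since every downstream analysis is univariate per item — with two
exceptions that keep records self-consistent: CPAP-without-ventilation is
derived from the CPAP and ventilation draws, and survivor/delivery-room
structural missingness follows the drawn mortality status (30% of deaths
occur in the delivery room). Length of stay is log-normal (median 49 d,
σ = 0.5), giving the right-skewed positive distribution the Mann–Whitney
comparisons need. Missingness masks answers only, per item (optionally per
unit), leaving eligibility untouched.

One seeded generator stream drives everything; the seed and a config hash
land in the metadata sidecar. What the generator does **not** model — and
what passing tests therefore cannot show — includes cross-item clinical
correlation (beyond the two consistency couplings), death timing,
within-unit secular trends, seasonal patterns, and transfer between units.
Step changes for testing the reliability screen are injected explicitly
(`inject_shift`), re-drawing answered values from the effective date onward
and touching nothing else.

## Problem sizes and numerical choices

Null-calibration runs use 100,000 replicates (SMR coverage at E = 20;
p-chart signals as 1,000 charts × 100 years at n = 1,000, p = 0.3 — many
years per chart so the estimated centre line is close to truth and the
three-sigma tail is the dominant term; binomial discreteness and centre-line
estimation shift the measured rate by a few hundredths of a percent, hence
the ±0.1 pp allowance around 0.27%). Oracle-equivalence checks use 10,000
randomized eight-section series including empty and 0%/100% sections.
Detection runs use the default nine-unit cohort with one unit's late-onset
sepsis elevated three-fold in every stratum; because the collective
reference includes the elevated unit, the attainable ratio is ≈2.7 rather
than 3.0 for a unit carrying ~5% of the collective, and the measured SMR
lands in that vicinity with ~20% sampling variability at ≈25 events.

Ties in interval comparisons always resolve conservatively: touching
confidence intervals overlap (no erratic change, not significant), a point
exactly on a control limit does not signal, p exactly at α earns no star.
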