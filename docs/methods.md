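# Methods

This note documents the statistical models, conventions and design choices
behind the package, and what the synthetic-data tests do and do not
demonstrate about real spontaneous-report data.

## Data model and cohort rules

A case is the join of one DEMO row (sex; decade age band such as "20s";
reporting year) with its DRUG rows (name, involvement category, route,
start date) and REAC rows (MedDRA Preferred Term, onset date, outcome).
Dates may be complete, partial (year-month, retained but flagged) or absent;
duration arithmetic treats partial dates as unknown because time-to-onset
needs day resolution. Drug/reaction rows whose case id is absent from DEMO
are reported as orphans, never silently dropped; duplicate DEMO case ids are
rejected (the package assumes the ingested release is already deduplicated
to one row per case — real report streams contain follow-up versions of the
same case, and deduplication policy is release-specific).

Inclusion flow: cases with unknown sex or age band are removed first, then
patients younger than 20 (NSAIDs are generally not given to children in the
source population). "Elderly" means an age-band lower bound ≥ 70 — bands are
the only age granularity available.

Exposure classification is an exact match of the normalized drug name
(NFKC, trim, case-fold) against configurable class lists; no fuzzy matching,
so classification stays deterministic and auditable, and brand-name mapping
is delegated to the lists. Three deliberate rules:

* all involvement categories (suspect / concomitant / interaction) count as
  exposure;
* aspirin is excluded from the NSAID class at list construction (it is
  typically given at antiplatelet doses), so it can never set the NSAID flag;
* a case whose only NSAID exposures are topical is NSAID-naive. Unknown
  route counts as systemic: only confirmed topical-only use is excluded.

The combination pattern is a pure function of the three class booleans;
every case has exactly one of the eight patterns.

## Disproportionality

The reporting odds ratio compares the odds of an AKI report in an index
pattern against the no-TW-drug reference stratum. The CI is a Wald interval
on the log scale with z = 1.959964 at α = 0.05 (the standard construction in
the disproportionality literature); a signal is declared when the CI lower
bound exceeds 1. Zero cells raise an error by default; the
Haldane–Anscombe +0.5 correction is an explicit option
(`zero_policy="haldane"`), flagged on the result, never silent.

Adjusted RORs come from a maximum-likelihood binomial logistic regression
(Newton iterations, analytic-gradient convergence check) of the AKI
indicator on the seven pattern indicators (or pooled single/double/triple
indicators — both term sets are supported since pooled rows require their
own fit) plus male sex, age ≥ 70, any AKI-risk drug, and the reporting year.
The year enters centred as a continuous covariate by default (one-hot per
year available): a linear reporting-trend adjustment is the parsimonious
reading of "year as covariate". Quasi-complete separation is detected via a
diverging exposure coefficient (|log-OR| > 15) and raised, not reported.
Pearson chi-square for 2×2 tables is uncorrected by default (large-sample
setting); Yates correction is a flag.

## Time-to-onset

**Duration.** Days from the start of the last-started TW class to the first
AKI onset date. Two day-counting conventions coexist in this analysis
tradition — onset on the start day counted as 0 days, or the start day
counted as day 1 — so the convention is an explicit flag (`day0` default,
`day1` available) rather than a hidden assumption, and reproduction runs
against deposited durations try both. Onset before the last start is
implausible and excludes the record (counted and logged). When a drug
appears several times in a case, its class keeps the earliest complete start
date; which re-start a "last start" should mean is genuinely ambiguous in
report data, and the earliest-start rule is the conservative, deterministic
choice.

**Order strata.** The involved classes are ranked by their start dates.
Any tie makes the case "simultaneous": it cannot be placed in
which-drug-came-last strata and is excluded from order-stratified rows and
ordered-group comparisons, but retained in pattern-level totals (this
reconciles ordered-row counts that sum to less than their pattern total).

**Weibull shape test.** The two-parameter Weibull is fitted by maximum
likelihood: the shape β solves the profile score equation

    1/β + mean(ln x) − Σ x^β ln x / Σ x^β = 0

by bracketed root-finding (bracket grown geometrically, Brent's method,
xtol 1e−12; power sums computed with a max-shift to avoid overflow), and
the scale is then closed-form, η = (mean x^β)^{1/β}. The CI for β is a Wald
interval on log β from the observed information (central-difference Hessian
of the log-likelihood in (log β, log η), step 1e−4), so it is always
positive. The published analysis was run in commercial software whose CI
construction is not stated; point estimates are comparable, CIs may differ
slightly. β < 1 is "early failure" (decreasing hazard), β > 1 "wear-out";
by default the classification only commits when the whole CI is on one side
of 1, with a strict point-estimate mode available. Day-resolution data
contain exact zeros, outside the Weibull support; the zero policy is
explicit: replace 0 with 0.5 days (default), exclude zeros, or shift the
whole sample by +1. Fits require ≥ 3 positive durations with non-zero
spread. The fit is cross-checked in tests against an independent MLE
(scipy's) and against score stationarity and a likelihood grid.

**Cumulative incidence.** Every analyzable record is an event (cases are
selected for having an onset), so the Kaplan–Meier estimator reduces to the
empirical CDF; ties merge into one step and the curve ends at 1. The group
median is the first event time at which the curve reaches 50% — on discrete
day data this is the published convention ("the day the cumulative failure
rate reached 50%"), not an interpolated quantile.

**Generalized Wilcoxon (Gehan–Breslow).** For groups a, b the statistic is
W = Σ over all cross-pairs of sign(b_j − a_i), ties scoring 0; equivalently
the sum over group b of the pooled Gehan scores h_k = #(x < x_k) − #(x > x_k).
The normal approximation uses the exact permutation variance conditional on
the pooled sample, Var W = mn/(N(N−1)) · Σ h². For small pooled samples
(n ≤ 12 by default in `auto` mode) an exhaustive permutation is run instead,
reporting both the inclusive two-sided p (P(|W| ≥ |w|)) and the Lancaster
mid-p (half weight on the observed atom). The mid-p is the quantity a
continuous approximation of a discrete null estimates; agreement between the
normal p and the exact mid-p is within 0.05 at pooled sizes around 10–12,
but below a pooled n of about 10 the permutation distribution is too
discrete for any normal-type approximation to track exact p-values that
closely — use the exact method there. Pairwise comparisons across strata are
unadjusted by default, matching the reporting tradition of pairwise
generalized Wilcoxon tables at α = 0.05; Holm adjustment is available.
Peto–Prentice and other weightings are out of scope: one well-defined,
oracle-testable variant.

## Synthetic generator

The generator emulates the features of a spontaneous-report database this
pipeline is sensitive to: decade age bands with a small unknown/under-20
fraction, reporting years, a pattern prevalence vector, an independent
AKI-risk-drug indicator, an AKI outcome drawn from a logistic model
(baseline log-odds + pattern log-odds-multiplier + male/elderly/risk/year
effects — the configured multiplier is therefore the true
covariate-conditional odds ratio versus NONE), per-pattern Weibull onset
durations added to the last TW start and floored to whole days, drug rows
with class-list names and involvement categories, missing dates, and
simultaneous starts. Defaults mimic the study conditions: prevalences
(74% no-TW down to 0.5% triple) and odds multipliers (1.18–2.44) echo the
real database's combination table, onset shapes ≈ 0.5–0.6 with medians of
8–120 days echo its shape table, 35% date missingness matches the low
completeness of real reports, and 10% of multi-class cases start
simultaneously. Analytic medians are η·(ln 2)^{1/β}.

It deliberately does **not** emulate: correlated co-prescription (classes
are drawn jointly as a pattern but risk drugs are independent), duplicate /
follow-up reports, brand-name variation, MedDRA coding noise, or
informative missingness (dates are missing completely at random). Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated generative model, not robustness to reporting biases — the ROR
remains a disproportionality measure, not a risk estimate.

## Problem sizes and numerical conventions

Test and demonstration runs are scaled so the whole suite and the
acceptance script each finish in minutes on one CPU: pipeline smoke tests at
1,500–2,000 cases, prevalence/median recovery at 10,000–40,000, crude-ROR
recovery at 200,000, adjusted-ROR recovery at 50,000, Weibull recovery at
n = 2,000 × 20 seeds per true shape, and the acceptance pipeline at 100,000
cases. At these sizes the triple-pattern time-to-onset stratum holds only
~10 analyzable cases — matching, proportionally, how thin that stratum is
in the real database — so its median and shape are reported but noisy.
All randomness flows from a single integer seed; same config + seed gives
byte-identical tables and bundles (no stage reads the clock). Tables are
written with fixed column order; formatted columns round estimates to two
decimals while full-precision columns are kept alongside.

## Known limitations

* Exact-name matching means real-release coverage is only as good as the
  supplied drug lists; the bundled defaults are compact generic-name lists
  for synthetic data and testing.
* The shape-parameter CI construction of the published tables is unknown;
  two-decimal agreement of β point estimates is the right comparison, CI
  bounds may differ in the second decimal.
* Without the deposited per-case durations the published medians can only
  be approached statistically through the generator, not reproduced exactly;
  the reproduction driver (`analysis/05_reproduce_deposited.py`) exists for
  when that file is available.
* The Gehan normal approximation should not be trusted below a pooled
  sample of about 10; the exact permutation method exists for that regime.
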