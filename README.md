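# triplewhammy

Signal detection and time-to-onset analysis for "Triple Whammy" acute kidney
injury (AKI) in spontaneous adverse-event report databases.

Concurrent use of a renin-angiotensin-system inhibitor (RASI), a diuretic and
an NSAID — the "Triple Whammy" (TW) — is a well-known pharmacological risk
factor for AKI. This package implements, as a tested and reusable pipeline,
the kind of analysis pharmacovigilance groups run against JADER-style report
databases (DEMO/DRUG/REAC tables) to characterise that risk:

* **Cohort construction** — inclusion flow (known sex and age band, age ≥ 20),
  AKI case flagging by MedDRA Preferred Term lists, and classification of each
  case into one of the eight TW combination patterns
  {NONE, R, D, N, RD, RN, DN, RDN}. All involvement categories (suspect,
  concomitant, interaction) count as exposure; aspirin never counts as an
  NSAID; topical-only NSAID use is NSAID-naive.
* **Disproportionality** — the reporting odds ratio for each pattern versus
  the no-TW-drug stratum,

      ROR = (a/b) / (c/d),
      95% CI = exp( ln ROR ± 1.96 · √(1/a + 1/b + 1/c + 1/d) ),

  with the signal rule CI-lower-bound > 1, plus covariate-adjusted RORs from
  a binomial logistic regression (male sex, age ≥ 70, AKI-risk drugs,
  reporting year) and chi-square comparisons.
* **Time-to-onset** — days from the *last*-started TW class to AKI onset;
  two-parameter Weibull maximum-likelihood fits whose shape β classifies the
  hazard trend (β < 1 early failure, β ≈ 1 random, β > 1 wear-out);
  Kaplan–Meier cumulative incidence (with no censoring, the empirical CDF)
  with medians at the 50% crossing; and Gehan–Breslow generalized Wilcoxon
  comparisons between combination/order strata, with an exact permutation
  option for small groups.
* **Synthetic data** — a generator of JADER-shaped databases with known
  ground truth (pattern prevalences, conditional odds ratios, per-pattern
  Weibull onset distributions, date missingness, simultaneous starts), so
  every stage is testable without access to a real release.

## Worked example

Simulate a 50,000-case database and run the three analysis stages:

```bash
python analysis/01_simulate.py --n 50000 --seed 1
python analysis/02_cohort.py
python analysis/03_signal.py
python analysis/04_onset.py
```

The signal stage prints (seed 1):

```
   row  aki_n  other_n  crude_ror  adjusted_ror  signal
     R    278     3116       1.52          1.55    True
     D    155     1514       1.75          1.79    True
     N    335     4361       1.31          1.33    True
    RD    201     1296       2.65          2.69    True
    RN     55      610       1.54          1.55    True
    DN     31      315       1.68          1.76    True
   RDN     29      211       2.35          2.32    True
single    768     8991       1.46          1.48    True
double    287     2221       2.21          2.25    True
triple     29      211       2.35          2.32    True
```

Each row is one combination pattern (plus pooled single/double/triple rows):
AKI and other-event report counts, the crude ROR versus the no-TW stratum,
the covariate-adjusted ROR, and the signal flag. The generator's true odds
multipliers for this run ranged from 1.18 (N) to 2.44 (RDN), and the
adjusted estimates recover them within sampling error. The onset stage then
reports, for example, a single-drug-total Weibull shape of 0.55 ("early
failure": the AKI hazard is highest right after the start of the last drug)
and a median of 8 days for NSAID monotherapy cases, against a generator
ground-truth median of 9 days.

The same stages run on real exported tables via the `triplewhammy` console
script (`simulate`, `cohort`, `ror`, `onset`, `run` subcommands); delimiter,
encoding and column naming of a release are described by a `TableDialect`,
and drug-class/PT membership lists are supplied as YAML.

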