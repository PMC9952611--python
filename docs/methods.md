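# Methods

This note records the models, conventions and design choices behind
`pvsignal`, in the spirit of a statistical software appendix: what is
computed, under which assumptions, and where the genuinely open choices
were resolved.

## Disproportionality on drug–event pairs

The counting unit throughout is the **drug–event pair**, not the report:
a report listing *k* distinct retained drugs and *m* distinct reaction
preferred terms contributes *k·m* pairs (identical (drug, PT) repeats
within a report collapse to one). Pair-level counting is what the
reference screens' denominators imply — the study drug's 9,829 reports
yield 36,207 pairs — and it makes every 2×2 table a partition of one pair
universe. The comparator universe is either all pairs ("all other drugs")
or the pairs of a configured drug list (the within-class screen); building
a table commutes with restricting the universe, a property the tests
assert.

### Indices

With cells *a, b, c, d* and *N = a+b+c+d*:

- **PRR** = [a/(a+b)] / [c/(c+d)].
- **ROR** = (a/b)/(c/d); Wald interval on the log scale with
  SE = √(1/a+1/b+1/c+1/d) and z = 1.96 everywhere.
- **Yates χ²** = N·(max(0, |ad−bc| − N/2))² / [(a+b)(c+d)(a+c)(b+d)].
  The correction is clamped: when the continuity adjustment overshoots
  (|ad−bc| ≤ N/2) the statistic is exactly 0. The implementation is
  verified against an independent cell-wise route,
  Σ (max(0, |O−E|−½))²/E over the four cells, on 1,000 random tables
  (agreement < 10⁻⁹).
- **BCPNN information component.** Among the several published BCPNN
  variants the package pins the closed-form posterior with Beta(1,1)
  marginal priors and joint prior balanced for independence (γ₁₁ = 1):

      γ     = (N+2)² / ((c_x+1)(c_y+1)),          c_x = a+b, c_y = a+c
      E(IC) = log₂[(a+1)(N+2)² / ((N+γ)(c_x+1)(c_y+1))]
      V(IC) = (1/ln2)²·[(N−a+γ−1)/((a+1)(1+N+γ))
                        + (N−c_x+1)/((c_x+1)(3+N))
                        + (N−c_y+1)/((c_y+1)(3+N))]
      IC025 = E(IC) − 1.96·√V(IC)

  This variant reproduces the reference screens' verifiable IC lower
  bounds (0.26 for the study drug within the penicillin class; −0.01 for
  hypernatremia against all drugs) and the published sign pattern — the
  IC-starred rows of all three screens have IC025 > 0 under it, the
  unstarred rows do not. Several other printed IC bounds (1.11, 2.51,
  3.34, …) are not reproducible under this or any standard closed-form
  variant we evaluated from the printed cells; they are carried in the
  fixture files flagged `inconsistent` and excluded from exact
  comparison. The formula is not tuned toward them.

### Signal rules

- PRR rule: a ≥ 3 ∧ PRR ≥ 2 ∧ χ² ≥ 4.
- ROR rule: a ≥ 3 ∧ ROR ≥ 2 ∧ χ² ≥ 4 ∧ ROR 95% lower bound > 1.
- IC rule: IC025 > 0.
- A pair is a signal when any rule fires.

Zero cells make PRR/ROR/χ² undefined; the package reports `nan` and the
corresponding flag is false. No Haldane/continuity correction is applied
to zero cells: the frequency ≥ 3 requirement already prevents such tables
from signalling on the frequentist rules, and the IC priors regularize
a = 0 on the Bayesian one. Arithmetic is full precision; rounding (half
away from zero, 2 dp) happens only at display/comparison time.

## ETL and cleaning conventions

- **Dialects.** Legacy (`ISR`/`CASE`) and current (`primaryid`/`caseid`)
  headers are auto-detected and harmonized to one vocabulary; downstream
  code never sees the dialect.
- **Age.** Unit conversions use calendar constants: decade ×10, year ×1,
  month ÷12, week ÷52.1775, day ÷365.25, hour ÷8766. A value with a
  missing unit is read as years (the dominant FAERS convention). Negative
  or > 150-year results become missing and are counted. Age groups
  (≤18 / 19–64 / ≥65 / unknown) floor the age before comparison, so 18.9
  years is ≤18; the grouping convention is inclusive at the printed
  boundaries.
- **Version selection.** Per case, the greatest (quarter, numeric report
  id) wins; within a quarter the larger id is the later submission (ids
  increase over time). Ties cannot survive this ordering.
- **Exclusion cascade and precedence.** A latest-version report is dropped
  (and tallied exactly once, in this order) if: deletion-listed → blank
  case key → no non-blank drug name → all usable drug rows concomitant →
  no non-blank reaction. Concomitant drug rows are then removed from
  survivors; interacting and suspect roles are kept. The deletion list is
  an optional plain-text file of case ids (the regulator's list is not
  packaged); absent list = no-op. Cleaning is idempotent and conserving:
  input = retained + Σ exclusions, asserted at run time.
- **Drug matching** is exact after normalization (lowercase, whitespace
  collapse, trailing dosage tokens like "4.5 g" stripped) against an
  editable synonym dictionary covering the twelve penicillins; no fuzzy
  or substring matching. Unmatched names keep their normalized verbatim
  form, so "all other drugs" pair counts are preserved drug by drug.
- **Event queries**: each of the ten electrolyte disorders maps to exactly
  two preferred terms (clinical + laboratory); the "increased/decreased"
  laboratory terms belong to exactly one disorder each.

## Synthetic data generator

The generator emulates the structure and hazards of quarterly extracts,
not pharmacology. Per report: drugs are drawn first (without replacement,
catalog marginals), then events with probability proportional to
baseline(e) × max over the report's drugs of λ(drug, e). λ = 1 everywhere
gives independence; a planted λ multiplies the odds of the event being
selected for reports carrying that drug. The max-mechanism means
co-reported drugs inherit part of a planted association, so a planted
λ = 4 realizes a pair-level ROR nearer 2.5–3 — the recovery tests assert
detection, and a separate minimal configuration (one drug, one event per
report, two-point catalogs) where the population ROR equals λ exactly is
used for the CI-coverage check (95% ± 4 points over 200 replicates).

Default condition parameters, chosen once as plausible for a mid-sized
quarter: 5,000 reports; 1–3 drugs and 1–3 events per report; 5% of cases
re-versioned; 15% of drug rows concomitant; 10% missing age, 5% missing
sex; age units 85% years with the remainder across decades, months,
weeks, days; ages gamma-distributed around a mean of ~58 years. One
random stream per run, seeded once; identical configuration gives
byte-identical files.

`PlantedTruth` records the *clean* realized pair counts (latest version,
non-concomitant rows) — the exact quantity a correct pipeline must
recover, which the end-to-end tests assert to equality on 50,000-report
quarters. What the generator does **not** emulate: drug-name misspellings
beyond case/whitespace jitter, cross-case duplicates with different ids,
correlated demographics, therapy dates, reporting-trend (Weber) effects.
Passing recovery tests therefore show the pipeline's mechanics are exact
under the stated rules, not that the rules suffice for raw regulatory
data, whose manual curation is out of scope.

## Risk-factor stage

- Case-control rows are the target drug's reports with known sex and age;
  the outcome is "report carries the signalled event (with that drug)".
  Reference categories: male, age ≤ 18.
- Logistic regression is fitted by Newton/IRLS from β = 0, converged when
  max |score| < 10⁻⁸, capped at 50 iterations; all terms entered
  simultaneously. Wald intervals (exp(β ± 1.96·SE)) match the reported
  convention of mainstream statistical packages. Separation is detected —
  all fitted probabilities within 10⁻⁶ of the 0/1 boundary, or divergence
  without score convergence — and raised, never returned silently. The
  fit agrees with an independent implementation (statsmodels `Logit`) to
  10⁻⁶ in the tests, and for a single binary covariate exp(β) equals the
  closed-form 2×2 odds ratio exactly.
- Hosmer–Lemeshow: groups are deciles of fitted risk; tied fitted values
  go to the lower group and duplicate quantile edges are merged, so ties
  stay in one group; the statistic Σ (O−E)²/(n·p̄·(1−p̄)) is referred to
  χ² with (groups − 2) df. With a continuous covariate the test holds its
  nominal size (5% ± 2 points over 400 null replicates, n = 50,000) and
  rejects a linear fit to quadratic truth in > 90% of replicates. With
  only a handful of discrete covariate patterns (e.g. sex × age group)
  the grouped statistic is conservative — a known property of the test,
  not an implementation artifact — so the size simulation uses the
  continuous design.
- The published multivariate odds ratio (1.94) and Hosmer–Lemeshow p
  (0.847) for the reference analysis require the unpublished joint
  sex × age × outcome cross-tabulation and are deliberately not numeric
  targets; the univariate odds ratios (1.93, 0.77, 1.02) are reproduced
  from the published marginal counts, and the multivariate machinery is
  pinned by the oracle identity and the simulations above.

## Reference fixtures and known inconsistencies

The packaged reference tables carry the published cells and printed
statistics of the three screens plus the risk-factor marginals. Recomputing
every statistic from the cells reproduces the printed 2-dp values except
for a short list of internally inconsistent entries (flagged per row in
the fixtures): three ROR confidence limits and four χ² values differ in
the last digit or appear transposed (e.g. one CI printed 1.21–2.32 where
the cells give 2.31–5.00), and most IC lower bounds differ as discussed
above. Inconsistent entries are excluded from exact comparison; all
signal-pattern assertions hold on the recomputed values.

## Problem sizes used in the test suite

End-to-end recovery and false-positive screens run on two 50,000-report
synthetic quarters; CI coverage uses 200 replicates of 1,200 reports;
logistic parameter recovery uses n = 20,000; the Hosmer–Lemeshow size and
power simulations use 400 × n = 50,000 and 100 × n = 20,000 replicates
respectively. These sizes give stable Monte-Carlo estimates for the
asserted tolerances while keeping the suite quick to run.

## Command-line interface

`pvsignal` exposes `simulate`, `screen`, `fixtures` and `characteristics`
subcommands as thin wrappers over the library; `--fixtures` accepts raw
(a,b,c,d) quadruples so published tables are exercisable with no report
data. Outputs are TSV; identical inputs and configuration produce
byte-identical artifacts. Seriousness categories in the characteristics
summary are made mutually exclusive by clinical precedence
(fatal > life-threatening > hospitalization > other serious), and report
sources map physician/pharmacist/other-health-professional codes to
"Health professional", the consumer code to "Consumer", and the rest to
"Other"/"Unknown".
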