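# Methods

## Study design the package implements

`comoscreen` implements a retrospective matched-cohort screen over
claims-shaped data. Two arms are built from diagnosis-code rules; each case
is paired with one control on the propensity score; every recorded diagnosis
code is then treated as a candidate comorbidity and scored by the ratio of
one-year period prevalences between the arms. The design is
hypothesis-generating: the ranked output is a map of associations, not a set
of causal or multiplicity-adjusted tests.

### Cohort eligibility

A person enters an arm iff (a) they have ≥ `min_claims` (default 2) claims of
an eligible kind matching the arm's code patterns, (b) an enrollment spell
covers the reference date (default 2007-06-30; the closed check
`start ≤ date ≤ end`), (c) at least one matching eligible claim falls
*strictly before* the pre-cutoff date (default 2006-07-01), and (d) they are
at least `min_age` (default 16) at the index date. The index date is the
earliest matching eligible claim. Only encounter-kind claims define cohorts —
lab/radiology service lines repeat codes without asserting a diagnosis — but
*all* claim kinds count toward comorbidity prevalence.

Ages are computed at calendar-year resolution, `age = year(date) −
birth_year`: de-identified claims carry birth year only, and a single fixed
convention keeps results deterministic. A person qualifying for both arms is
assigned to the case arm and removed from the control pool, keeping the arms
disjoint for matching.

### Propensity model and digit matching

The propensity score is P(case | age, sex, plan) from a logistic regression
(age linear in years, indicator for female sex and Medicare plan; no
interactions), fitted by Newton/IRLS to convergence tolerance 1e-10 within
100 iterations. Constant covariates are dropped with a warning (an
intercept-only model legitimately scores everyone at the case fraction);
complete separation and collinearity raise errors naming the covariate. The
numerical optimizer behind the model object is statsmodels' `Logit`; an
independent brute-force likelihood grid serves as the test oracle.

Matching is the greedy digit-agreement algorithm of the classic SAS macro
family: for d = 8 down to 0, unmatched cases (seeded-random order) are paired
with an unused control whose score agrees on the first d decimal digits.
Digits are *truncated*, not rounded, and truncation is performed on a fixed
12-decimal string rendering of the score, because float tricks like
`floor(x·10^d)` misrepresent decimal digits (e.g. `0.29·100 → 28.999…`).
Scores lie strictly in (0, 1), so the d = 0 pass pairs every leftover case
while controls remain; with equal pool sizes no case stays unmatched. The
within-pass order is a seeded shuffle — the multiset of digit levels used is
invariant to input order (a tested property); only tie-level assignments
move. Balance is reported as standardized mean differences, with the pooled
SD taken from the pre-match arms so before/after are on one scale.

### Screen statistics

For each code: each person counts once, the window is the closed interval
[window_start, window_end] (defaults 2006-07-01 .. 2007-06-30), and

* RR = (n₁/N₁)/(n₀/N₀), computed as the cross-product n₁N₀/(n₀N₁) so equal
  denominators cancel exactly;
* 95% CI by the Katz log method, z = 1.959964 — the standard Wald interval
  for a prevalence ratio in a 2×2 table. The method behind the printed
  intervals we mirror is not documented, so the Katz choice is recorded here
  for users wanting to compare alternatives;
* OR by the cross product with the Woolf log interval; zero cells flag the
  row as undefined rather than receiving a continuity correction.

Filters: codes with 3-digit stem 710–729 or prefix 9964 are excluded as
index-condition related; codes with < 20 affected controls are dropped as
unstable (the two filters commute). Note the source literature for this
design states the ≥ 20 rule once against the control group and once against
the case group; the control-group rule is implemented. Ranking is by
descending RR with ties broken by larger n_case, then code. Display rounding
is half-up to one decimal; internal values are never rounded. No
multiple-testing adjustment is applied, by design.

## Synthetic data generator

The generator emulates the statistical skeleton the screen assumes, with
defaults mirroring a rheumatoid-arthritis-style study population: age
truncated-normal (mean 59, SD 15, bounds 16–100), 73.8% female, 35% Medicare,
case condition 714.0, control condition 692.0. Sex and plan are independent
Bernoulli draws — in reality Medicare is an age threshold; the independence
keeps the propensity model full-rank and is irrelevant to the quantities
tested. Every person gets two defining-condition encounter claims (one
pre-cutoff, one in-window) and an enrollment spell covering the reference
date; comorbidity codes are person-level Bernoulli events (p₀ in controls,
min(RR·p₀, 1) in cases), dated uniformly in the window, at most one claim per
person — the analysis counts persons, so richer within-person repetition
would be invisible to it. Age confounding enters on the log-odds scale
(`confounder_slope` per decade of age, paired with `case_age_shift`), which
is the structure a logistic propensity model can remove.

The default code book plants ~23 codes: high-RR entries use the observed
case prevalences and prevalence ratios of conditions strongly associated
with rheumatoid arthritis (baseline p₀ = p_case/RR), common chronic codes get
modest RRs of 1.1–2.0 (chosen as plausible; no published anchor), one skin
code is control-associated (RR 0.4, matching the reported value for pruritic
disorder), and two locomotor-chapter codes exist only to exercise the
exclusion filter. What the generator does **not** emulate: code correlation
structure, visit clustering, enrollment churn, miscoding, or the 6,000+-code
breadth of real data — so passing tests demonstrate the pipeline's
statistical correctness under its assumed sampling model, not robustness to
real-world coding behaviour.

## Validation studies and problem sizes

The guarantees are phrased as computations on planted truth, at sizes chosen
to give informative sampling distributions while keeping the default test run
fast: interval coverage over 500 replicate screens (n = 5,000/arm, one code
at p₀ = 0.005, RR = 3; band 0.93–0.97), null calibration over 200 RR = 1
codes on one screen (band 0.03–0.07 — note this fraction has sampling SD
≈ 0.015, so the band is ~±1.3 SD), confounding removal over 100 replicates
(1,500 cases / 4,000 controls, slope 1 per decade, case arm shifted +10 y),
and byte-level determinism of two full pipeline runs. The demographic and
worked-example anchors use 50,000 simulated persons and printed count/
denominator pairs respectively.

## Known limitations

* Rates and codes are stationary within the window; no incidence or
  time-to-event semantics.
* The Katz and Woolf intervals are asymptotic; with < ~5 expected events they
  under-cover, which is exactly why the ≥ 20-control stability filter exists.
* Greedy digit matching is not optimal matching; it can leave avoidable
  score distance at low digit levels, and at d = 0 pairs arbitrarily.
* V/E-codes are accepted and screened like any code but receive no special
  semantics.
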