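# comoscreen

Hypothesis-free comorbidity screening of administrative-claims data.

Given claims-shaped tables (persons, diagnosis claims, enrollment spells),
`comoscreen` builds a chronic-disease **case cohort** and a comparator
**control cohort** by code-pattern rules, pairs each case 1:1 with a control by
greedy propensity-score digit matching, and then rank-orders *every* recorded
ICD-9 diagnosis code by the ratio of one-year period prevalences between the
arms. The output is a ranked table of relative risks — a quick, data-driven
map of the conditions that travel with a disease of interest (for example
rheumatoid arthritis screened against an eczema/dermatitis comparator), useful
in pharmacoepidemiology and drug-safety risk management.

Because research claims databases are proprietary, the package ships a
synthetic claims generator with planted ground truth, so the entire pipeline
is testable end to end: planted relative risks must be recovered, nominal
intervals must cover, and matching must remove planted age confounding.

## The statistic

For each level-5 ICD-9 code *k*, with `n` = persons having ≥1 in-window claim
of *k* and `N` = arm size,

```
RR_k = (n_case/N_case) / (n_control/N_control)
95% CI: exp( ln RR_k ± 1.959964 · √(1/n_case − 1/N_case + 1/n_control − 1/N_control) )   (Katz log method)
OR_k = n_case·(N_control−n_control) / ( n_control·(N_case−n_case) ),  Woolf log CI
```

Each person counts once per code. Codes in the index-condition chapters
(stems 710–729, 996.4x) are excluded; codes with fewer than 20 affected
controls are dropped as unstable; survivors are ranked by descending RR.

The propensity score is P(case | age, sex, plan) from a logistic regression;
matching requires agreement of the first *d* decimal digits of the score,
relaxing *d* from 8 to 0, each control used at most once.

## Worked example (CLI)

```yaml
# example.yaml
seed: 42
outdir: example_out
simulate:
  n_cases: 20000
  n_controls: 25000
```

```
$ comoscreen screen --config example.yaml
$ comoscreen report example_out/ranked.csv --top-k 5
 rank  icd9                                           description  n_case   pct   rr    ci_95
    1  6960                                 Psoriatic arthropathy     533  2.7% 12.7 9.3-17.4
    2 73309                                      Osteoporosis NEC     162  0.8%  4.9  3.4-7.1
    3  9952 Unspecified adverse effect drug properly administered     256  1.3%  3.7  2.8-4.8
    4  7955         Tuberculin test reaction abnormal or positive      79  0.4%  3.6  2.2-5.8
    5   515                   Postinflammatory pulmonary fibrosis     431  2.2%  3.5  2.8-4.2
```

Reading the first row: 533 of the 19,991 matched cases (2.7%) had a psoriatic
arthropathy claim in the one-year window, 12.7× the matched-control
prevalence (95% CI 9.3–17.4). The default synthetic scenario plants this code
at RR 12.3, so the screen ranks it first and recovers the planted effect
within sampling error. `run_manifest.json` records the cohort funnel
(45,000 persons → 19,991 matched pairs → 25 codes recorded → 18 ranked) and
the seed; rerunning with the same config and seed reproduces every output
byte for byte.

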