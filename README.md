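# itemharmony

Pre-statistical harmonization of item-level behavioral and psychometric
survey data.

When the same underlying construct — say, dementia-related behavioral
symptoms — is measured by different instruments across clinical cohorts,
national surveys, and trials, the item-level data cannot simply be pooled:
studies disagree on response coding (`0 = No, 1 = Yes` vs `1 = Yes, 5 = No`),
polarity (higher = better vs higher = worse), scale origin (0-based vs
1-based), numeric missing-data sentinels (96–99, −5), skip patterns
(severity items asked only when a screener fires), and scale granularity
(binary vs 4-point). Pooling without resolving these defects manufactures
spurious between-study variance and breaks any downstream latent-variable
co-calibration.

`itemharmony` makes that pre-statistical stage explicit, auditable, and
testable:

- **crosswalk** — a validated table mapping each harmonized construct to
  every study's source variable, response options, missing codes, gate
  (skip-pattern) variable, and a declarative recode rule in a compact
  grammar (`"1->1;5->0;6,96,97,98,99->NA"`);
- **standardize** — deterministic transforms: missing-code masking,
  polarity reversal (`v -> max − v`), one-based shift, dichotomization,
  sparse-cell collapsing, all logged to a machine-readable audit trail;
- **qc** — an automated comparability battery: sentinel-code detection,
  no-variability items, cross-study min/max discrepancies, reverse-coding
  candidates (any within-study Pearson correlation `r < −0.2`), and
  conditional-item exclusion;
- **irt** — per-study two-parameter logistic (2PL) IRT as a
  configural-invariance check, with limited-information fit statistics
  and local-dependence diagnostics;
- **synthetic** — a multi-study generator with planted defects and a
  truth record, so every rule above is validated against known ground
  truth.

## The model

The 2PL models the probability that a respondent with latent severity
θ ~ N(0, 1) endorses item *j* as

```
P_j(θ) = 1 / (1 + exp(−a_j (θ − b_j)))
```

with discrimination *a_j* (analogous to a factor loading) and difficulty
*b_j* (the severity at which endorsement probability is 50%). Estimation
is marginal maximum likelihood via EM on a 41-node Gauss–Hermite grid;
missing responses simply drop out of the likelihood. Model fit per study
is summarized by an M2-type quadratic form in the univariate and
bivariate margin residuals, from which RMSEA and CFI are derived
(independence model with free thresholds as the CFI baseline), plus SRMR
over residual inter-item correlations. Item pairs with
|residual correlation| > 0.3 or |bivariate standardized residual| > 3
are flagged as local-dependence "couplets". Cutoffs: RMSEA < 0.05
excellent, 0.05–0.08 mediocre, > 0.08 poor; CFI ≥ 0.90 good;
SRMR < 0.08 good.

## Worked example

Simulate a three-study bank (n = 500/study) planting every defect class —
four reversed items in S2, 96–99 sentinels in S1, a −5 sentinel and
one-based coding in S3, two gated severity items and one local-dependence
couplet in S1, one constant item in S2 — then run the full checklist:

```sh
itemharmony simulate --seed 11 --n 500 --out bank
itemharmony run-all --crosswalk bank/crosswalk.tsv \
    --data S1=bank/S1.tsv --data S2=bank/S2.tsv --data S3=bank/S3.tsv \
    --out run --seed 11
```

`run/flag_digest.tsv`:

```
study_id  kind               count  constructs
S1        conditional_item   2      sev00,sev01
S1        missing_code       15     itm00,...,sev01
S2        no_variability     1      itm11
S2        reverse_candidate  12     itm00,...,ord01
S3        missing_code       14     itm00,...,ord01
pooled    scale_discrepancy  14     itm00,...,ord01
```

Both gated severity items are excluded, every sentinel-bearing item in S1
and S3 is caught, the constant item is removed, and the raw-range
cross-tabulation flags all 14 constructs shared with the one-based study.
The reverse-candidate list contains the four planted reversals
(itm01, itm04, itm07, itm10) plus their correctly-coded partners — a
negative correlation implicates a pair, not a side; use
`itemharmony.qc.suggest_reversals` to partition polarity groups (it
returns exactly the planted four here), then authorize the reversal in
the crosswalk.

`run/fit_report.tsv` (per-study 2PL after all exclusions):

```
study_id  n    n_items  converged  rmsea     cfi       srmr      rmsea_label  cfi_label  srmr_label
S1        500  13       True       0.063611  0.9578    0.051923  mediocre     good       good
S2        500  12       True       0.0       1.0       0.028388  excellent    good       good
S3        500  14       True       0.024096  0.993591  0.032913  excellent    good       good
```

S1's mediocre RMSEA is the planted couplet (itm05, itm06) — its items
share variance beyond the single trait, and the pair shows up in the
flagged local-dependence pairs of the residual report. S2 and S3, whose
defects were coding dialects rather than structural, fit cleanly once
recoded.

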