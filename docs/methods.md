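# Methods

This note documents the statistical procedures, the defaults and why
they were chosen, the numerical details, and what the synthetic
validation does and does not establish.

## Scope and data model

The package operates on the *pre-statistical* stage of item
harmonization: everything needed to make item-level data from multiple
studies comparable before any pooled latent-variable model is fit.
Pooled co-calibration itself (linking, factor-score estimation,
differential item functioning) is deliberately out of scope; the
per-study 2PL stage here establishes configural invariance — the same
unidimensional structure holding in each study fit separately — which is
the precondition for that later work.

Missingness is represented in memory exclusively as IEEE NaN in float
vectors. Numeric missing sentinels (96–99, −5 and similar) exist only in
raw files and are masked at recode time; no downstream API accepts or
emits a magic number for "missing". This makes the most insidious
pathology of pooled survey data — a sentinel surviving into analysis as
a score — unrepresentable after the standardize stage.

Harmonized scores are non-negative integers with 0 as the floor, and the
direction convention is fixed: higher = worse/more severe. Reversal is
applied per study so the pooled construct obeys the convention.

## Standardization

Transforms compose in a fixed order: mask missing codes → shift
one-based scales to zero → reverse polarity (only when the crosswalk
authorizes it) → dichotomize / collapse sparse categories. The order
matters — reversal is defined on 0-based values, and the guard in
`shift_to_zero` (no-op with a warning when the minimum is already 0)
makes double-shifting impossible. Every applied transform is appended to
a JSONL audit log keyed by (study, construct, operation, parameters).

Sparse-cell collapsing: an ordinal item with three or more observed
levels is truncated to binary when any observed level's count falls
below `min_cell` (default 5, the conventional small-cell criterion; the
threshold is configurable). Binary items are never altered by this rule.
We treat *any* sparse cell — including an extreme one — as grounds for
collapsing, since a thin top category is precisely the situation that
destabilizes ordinal models.

## The QC battery

- **Sentinel detection** runs on raw codes only: flag when the observed
  maximum lies in [90, 100] or any value is negative. After recoding,
  harmonized ranges are small by construction and the rule would be
  meaningless, so it is never re-applied.
- **No variability**: min = max over non-missing values (all-missing
  items are flagged too). For binary items this coincides with 0%/100%
  endorsement, which is also the precondition the IRT stage enforces.
- **Range cross-tabulation**: a construct carried by ≥ 2 studies is
  flagged when its observed (min, max) differs across them. Run on raw
  codes it surfaces coding dialects (one-based scales, sentinels);
  the same function applies to harmonized data.
- **Reverse candidates**: within-study Pearson correlations on
  pairwise-complete observations (pairs with fewer than `min_overlap`
  = 20 joint observations are skipped — conditional items create
  blockwise missingness). Any item with a correlation below −0.2 against
  any other item is flagged, with the most negative partner and the pair
  count as evidence. This rule deliberately over-triggers: a negative
  correlation implicates a *pair*. The companion `suggest_reversals`
  resolves the ambiguity by the sign of each item's loading on the
  leading eigenvector of the correlation matrix (oriented so the
  majority is positive); the negative-loading minority is the suggested
  reversal set. Neither function mutates data — reversal requires an
  explicit crosswalk edit, because an anti-correlated item can be
  substantively rather than artifactually reversed.
- **Conditional items** are excluded purely from crosswalk metadata
  (`gate_variable`), not inferred from correlation structure; gate
  cycles are a structural error. Summary-score exclusion is likewise
  metadata-driven (`is_summary_score`).

Every check is a pure function of its inputs, and each flag carries the
numeric evidence needed to recompute it independently.

## 2PL estimation

Marginal maximum likelihood with EM (Bock–Aitkin). The latent trait has
a standard-normal prior integrated on a 41-node Gauss–Hermite grid
(probabilists' nodes, weights normalized to sum to 1); 41 nodes keep the
quadrature error orders of magnitude below the convergence tolerance —
the acceptance suite verifies the converged log-likelihood against
brute-force 1001-node integration over ±6 to better than 1e−4 per
respondent. The E-step computes each respondent's posterior over nodes
from the observed responses only (missing entries contribute nothing);
the M-step is a per-item weighted Bernoulli regression in
slope–intercept form (logit = aθ + c), solved by Newton iterations with
step-halving so the expected complete-data objective never decreases —
this preserves the EM monotonicity guarantee, which is recorded in the
log-likelihood trace and asserted in tests at tolerance 1e−10.

Numerical choices:

- convergence: absolute change in marginal log-likelihood < 1e−6,
  max 500 iterations; non-convergence is reported (`converged=False`),
  not raised;
- slopes are bounded at |a| ≤ 5. Near-duplicate items would otherwise
  drive their slopes toward infinity, letting the unidimensional model
  partially absorb local dependence and hiding it from the residual
  diagnostics; bounding keeps such pairs visible. Item parameters near
  the bound are themselves a red flag;
- sign identification: the trait is oriented so the mean slope is
  positive. Genuinely reversed items then estimate negative
  discriminations — faithful to the data, and the directionality check
  is the stage responsible for catching them;
- difficulty is recovered as b = −c/a; standard errors come from the
  per-item expected information on the quadrature grid with a delta-
  method transform. These SEs ignore cross-item information and
  uncertainty in the trait distribution, so they understate sampling
  variability somewhat; they are reported for screening, not inference;
- items reaching this stage must be binary. Ordinal input raises rather
  than silently dichotomizing: upstream truncation is a logged pipeline
  decision, and silent conversion here would mask a stage-ordering bug.
  Items with 0% or 100% endorsement raise and point to the QC filters.

## Fit statistics

Full-information chi-square tests are degenerate for binary item banks
at realistic sizes (2^J sparse cells), so fit is assessed from
univariate and bivariate margins. With m = J + J(J−1)/2 margin
residuals e = p − π(θ̂), the statistic is the quadratic form

    M2 = N · e' C e,   C = Σ⁻¹ − Σ⁻¹Δ(Δ'Σ⁻¹Δ)⁻¹Δ'Σ⁻¹

where Σ is the model-implied covariance of the margin indicators
(entries π_{A∪B} − π_A π_B, with up-to-4-item joint probabilities
integrated over the trait) and Δ = ∂π/∂(a, b). Degrees of freedom:
m − 2J. Derived indices:

- RMSEA = sqrt(max(M2 − df, 0) / (df · N));
- CFI = 1 − max(M2 − df, 0) / max(M2_base − df_base, 0), baseline =
  mutual independence with thresholds fixed at the sample margins
  (df_base = m − J). When the baseline itself fits (no inter-item
  association), numerator and denominator both vanish and CFI is
  reported as not computable;
- SRMR = root mean square of (observed − model-implied) inter-item
  Pearson correlations.

Sample margins use pairwise-complete proportions with N = number of
respondents; under blockwise missingness the statistic is approximate,
which is acceptable for its screening role.

Classification follows the conventional cutoffs: RMSEA < 0.05 excellent,
0.05–0.08 (boundaries inclusive) mediocre, > 0.08 poor; CFI ≥ 0.90 good;
SRMR < 0.08 good. The common verbal conventions for the RMSEA bands are
not fully consistent across the literature; we adopt the reading above
and keep the boundaries inclusive on the mediocre side.

## Residual (local-dependence) diagnostics

Two per-pair diagnostics feed the "couplet" flag:

- **residual correlation**: observed minus model-implied inter-item
  correlation, threshold |.| > 0.3;
- **bivariate standardized residual**: the joint-endorsement residual
  p₁₁ − π₁₁ divided by its asymptotic standard error *after the
  parameter-estimation correction*, i.e. the square root of the
  corresponding diagonal of (Σ − Δ(Δ'Σ⁻¹Δ)⁻¹Δ')/n. Threshold |.| > 3.

The estimation correction matters: the naive binomial standard error
sqrt(E(1−E/n)) overstates the residual's variability (margins were used
to fit the parameters), deflating the z-scores by roughly 30–50% in our
simulations and hiding genuine local dependence at the flag threshold.
With the correction the statistic is approximately standard normal when
the model holds — across null replicates (n = 1000, 15 items) its
standard deviation is ≈ 1 and flags are rare — while a planted couplet
(specific-factor loading 0.6, n = 1000) yields z ≈ 5 and is flagged
reliably. Flagged pairs are reported for analyst action (drop one item,
or merge); models with residual covariances or group factors are out of
scope.

Tetrachoric correlations (for optional inspection, and as an independent
check on pairwise association) use two-step ML: thresholds from the 2×2
margins, correlation maximizing the table's multinomial likelihood under
the bivariate normal, with a 0.5 continuity correction on all cells when
any cell is zero. Degenerate tables yield NaN, never a fabricated value.

## Synthetic banks

The generator emulates the documented pathologies of multi-study
behavioral item banks: binary responses from the 2PL; ordinal responses
from a cumulative-logit mechanism (thresholds centered on the item's
difficulty, spacing 0.8); reversed raw coding; one-based scales;
sentinel codes (defaults 96–99 and −5, the dialects of common survey
instruments) injected into 5% of responses; gated severity follow-ups
that are missing whenever their screener is 0 and at least 1 when it
fires; constant items; and couplet pairs sharing a specific factor,
whose factor-analytic loading λ is converted to a logit slope
1.702·λ/√(1−λ²). Study sizes default to 1000 per study for desk-scale
validation (the generator accepts any sizes; validation problem sizes
were chosen so each QC rule operates far from its detection boundary).
Everything is reproducible from a single integer seed, and every planted
defect is emitted in a truth record for scoring.

The emitted crosswalk skeleton undoes coding dialects (sentinels,
one-based shift) but *not* reversals — that is the state an analyst is
in before the directionality review; `corrected_crosswalk()` provides
the post-review rules, and the round-trip test (generate → recode with
corrected rules → fit) recovers the planted (a, b).

What passing these tests does not show: the generator draws from the
very model family the estimator assumes, with clean unidimensional
structure, independent respondents, and missingness that is either
planted-at-random (sentinels) or purely structural (gates). Real
instruments add informative missingness, acquiescence and other response
styles, cross-study population differences, and semantic non-equivalence
of items that no automated rule can detect — the package surfaces
statistical symptoms, while mapping items to constructs remains expert
judgment recorded in the crosswalk.

## Design decisions

- Correlations for the directionality check are Pearson on item scores:
  defined for mixed binary/ordinal data and matching the screening
  intent; tetrachorics are available separately for the binary stage.
- The crosswalk is delimited text with a declarative recode mini-grammar
  rather than executable snippets: portable, diffable, and safe to
  validate.
- Raw codes are integers by contract; non-integer codes fail at parse
  time rather than being coerced.
- The pipeline's stage order is fixed and recorded in the manifest; no
  stage reads a later stage's output, inputs are never mutated, and
  reports round floats before serialization so equal manifests imply
  byte-identical outputs.
- Monte-Carlo property checks that compare estimation error across
  sample sizes average over several seeds: at desk scale a single
  replicate's RMSE ordering can invert by luck even when the property
  holds.

## Known limitations

- Standard errors understate uncertainty (block-diagonal information).
- M2 margins use pairwise-complete proportions with a single N; heavy
  non-structural missingness would bias the statistic.
- The CFI baseline fixes thresholds at sample margins rather than
  maximizing the independence likelihood under missingness.
- No bifactor/multidimensional estimation, no cross-study linking, no
  DIF testing — the toolkit stops where pooled calibration begins.
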