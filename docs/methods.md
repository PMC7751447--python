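# Methods

This note records the models, algorithms, defaults and design choices
behind realmkit, in the order the pipeline applies them.

## Scoring model and data layout

A word-recognition administration yields one mark per presented word:
correct, incorrect, skipped (the respondent exceeded the interviewer's
time allowance — a protocol fact recorded upstream, never computed here)
or not attempted.  Only "correct" scores 1; the sum of 1s is the raw
score and is reported on a 0–100 percent scale so that forms of different
lengths are comparable.  Response matrices are wide (persons × items)
with values 0/1/NA; NA means *not administered* and is distinct from a
scored 0.  Statistics use pairwise-complete data per item; Cronbach's
alpha uses listwise-complete rows because its variance decomposition
requires them.  When a respondent is asked to attempt only known words,
unattempted words are coded 0 (an assumption: the marking protocol treats
not-attempted and mispronounced alike).

## Content validity

Lynn's item CVI is the proportion of experts rating an item 3 or 4 on the
4-point relevance scale; items are retained when I-CVI exceeds the
threshold (default .80, strict inequality).  The scale CVI reported is the
mean of item CVIs.  An alternative reading of the retention rule — mean
rating ≥ 3 — exists in the field; the proportion-based rule is implemented
because it is Lynn's method, and the threshold is a parameter.  Difficulty
votes (1/2/3) map to strata by the modal category, ties resolving to
medium (the least selection-distorting default); a mean-binned rule
(thirds of [1, 3]) is available.  Optional trimming of items with extreme
mean difficulty ratings is off by default since no principled cutoff
exists.

## Classical test theory

Percent correct is the difficulty index; the **corrected** item-total
correlation (item vs total-minus-item) is the discrimination index —
the uncorrected variant is available but self-inflates, noticeably for
short forms.  Alpha is computed by the variance formula with sample
(n−1) variances; on 0/1 data it equals KR-20, so there is no separate
code path.  Undefined statistics (zero variance) are reported as NaN
rather than raised.  Note that duplicating every item does *not* follow
the Spearman–Brown doubling formula exactly: literal copies correlate 1,
so alpha rises to (2k/(2k−1))(1 − S/(2V)), at or above the
Spearman–Brown prediction; the test suite asserts the exact closed form.

## 2PL estimation

The 2PL is parameterised as a(θ − b) (not slope–intercept) because
equating operates on b directly; conversion helpers are provided.
Estimation is Bock–Aitkin MML-EM:

- **Quadrature**: 61 equally spaced nodes on [−6, 6] with standard-normal
  weights renormalised to sum to 1 (resolution configurable).  The latent
  scale is identified by fixing θ ~ N(0, 1).
- **E-step**: per-person posterior node weights; expected per-node counts
  of administered and correct responses per item.
- **M-step**: each item's expected complete-data log-likelihood is
  maximised by a damped Newton ascent using the Fisher-form 2×2 Hessian,
  vectorised across items, with per-item step halving that never lets the
  objective decrease — which is what makes the EM marginal log-likelihood
  provably non-decreasing (asserted to 1e−8 in tests).
- **Bounds**: a ∈ [0.05, 6], b ∈ [−6, 6]; estimates at a bound are flagged
  `boundary`.  Items with all-correct or all-incorrect observed responses
  have unbounded likelihood and are excluded with flag
  `excluded_degenerate`.
- **Convergence**: max |parameter change| < 1e−4 *and* relative
  log-likelihood change < 1e−7, capped at 500 cycles; hitting the cap
  flags the result rather than raising.
- **Standard errors**: per-item 2×2 cross-product (BHHH) of per-person
  marginal score vectors — a block-diagonal approximation to the observed
  information; cross-item information is ignored.  SEs shrink as 1/√n as
  expected (tested) but are approximations, not full-information SEs.
- **Start values**: a = 1, b = −logit(p̂) clipped inside the bounds.
- An optional log-normal penalty on a (off by default) stabilises tiny
  samples; pure MML is the default.

EAP person scores are posterior means/sds on the same grid; a person with
no administered items gets the prior (0, 1) back with a flag.  At the
default 61 nodes, EAPs agree with a 601-node oracle to 1e−4.

## Multi-group fitting, equating and DIF

The multi-group fitter shares item parameters across groups (pooling
expected counts in the M-step) with selected items freed per group; the
reference group's latent density is fixed N(0, 1) and each focal group's
mean and sd are estimated by EM moment updates.  The DIF test for item j
compares the fully constrained model with the model freeing (a_j, b_j) in
the focal group — all other items anchor the scale — giving a 2-df
likelihood-ratio statistic.  The free fit warm-starts from the constrained
solution.  Benjamini–Hochberg adjustment at α = .05 across tested items is
the default (82 simultaneous tests otherwise inflate discoveries); raw p
is always reported.  Anchor purification (one pass, freeing first-sweep
flags) is available but off by default — at a few hundred persons per
group it adds instability without clear benefit.  Items degenerate in
either group are reported not-testable.

Monte Carlo calibration (test suite and acceptance script) studies one
designated item per replicate — a constrained fit plus one freed fit —
which measures the per-item test's operating characteristics directly at
a fraction of the cost of sweeping all items.  At J = 20 items,
n = 300/group, a focal ability shift of 0.2 and 500 replicates, the
empirical type-I error sits near .05 (band [.03, .08] asserted); power
for a 1.0-logit difficulty shift at n = 500/group exceeds .8 over 200
replicates.

Mean/sigma equating uses item difficulties only (the moment matching is
the definition of the procedure): A = sd(b_ref)/sd(b_foc),
B = mean(b_ref) − A·mean(b_foc), b′ = Ab + B, a′ = a/A, with standard
errors rescaled accordingly.  Moment matching is exact by construction
(asserted to 1e−8); self-equating is the identity; transforms compose.
Characteristic-curve equating methods are out of scope.

The difficulty-separation index, (mean b_high − mean b_low+medium) /
pooled sd, quantifies how much harder the hardest stratum is than the
rest — large for orthographically deep forms (irregular spelling makes
rare words hard to pronounce), smaller for shallow-orthography forms.

## Short-form selection

The mean curve is a cubic smoothing spline of item-total correlation on
percent correct (scipy's penalised B-spline).  Smoothing is chosen by
generalised cross-validation when at least 15 distinct abscissae exist;
below that, the penalty is tuned by bisection so the smoother's effective
degrees of freedom (trace of the hat matrix, computed column-wise) equal
4.  Tied percent-correct values are merged into weighted means, which is
equivalent for penalised least squares; at least 5 distinct values are
required.  Because linear functions lie in the penalty's null space,
exactly collinear scatters are interpolated to machine precision
regardless of the penalty.

Quotas are largest-remainder apportionments of the target length over the
*original* bank's stratum sizes, so every nested form preserves the full
scale's difficulty distribution; ties in fractional remainders break
low → medium → high.  Within each stratum candidates are ranked by
above-curve residual (descending), ties by higher item-total correlation
and then input order; items with percent correct outside the acceptance
window (default 5–95%, relaxed automatically rather than making a quota
unfillable) are excluded.  If above-curve items cannot fill a quota the
best below-curve residuals top it up and the form is flagged.  Nested
selection restricts candidates to the parent form but recomputes nothing.
Selection statistics come from the reference language only; other
languages enter through an advisory review listing each selected item's
residual in every other language, with below-curve entries marked for
review — no automatic swaps.  Greedy-by-residual within strata is the
whole algorithm; no combinatorial short-form search is attempted.

## Validity and sensitivity

Pearson correlations use pairwise-complete observations with two-sided
p-values from t = r√((n−2)/(1−r²)) on n−2 df.  The sensitivity table
reports per-arm cell means with SE = sd/√n, and for each follow-up the
between-arm difference in mean change from baseline with a Welch
two-sample test on per-person change scores (stars at p < .05 / p < .01).
The baseline "difference" row is the raw between-arm gap.  The estimates,
not the p-values, are the primary surface: the inferential model real
studies use for such tables (possibly repeated-measures) is generally
unstated, and Welch-on-changes is a transparent default.  No mixed-effects
longitudinal modelling is attempted.

## Synthetic data generator

The generator emulates the structure the pipeline assumes, with all
effect sizes as configuration defaults, not estimates:

- **Bank**: strata 29/28/25 (82 items).  True difficulties: low/medium
  ~ N(−0.7, 0.5²), high ~ N(+1.3, 0.4²) in "separated" mode; "compressed"
  mode shrinks stratum means toward the size-weighted grand mean by
  λ (default 0.5; λ = 1 reproduces the separated structure exactly).  One
  standardised difficulty draw per item is shared across languages, so
  language forms differ only through their stratum structure and any
  planted DIF shifts (Δa, Δb per item/language).  Discriminations
  ~ U(0.8, 2.0), shared across languages.
- **Samples**: defaults n = 261 (en, separated), 128 (es, compressed),
  245 (ko, compressed) — the language-group sizes typical of the
  multi-site studies this design mirrors.
- **Responses**: θ ~ N(μ, σ²), X ~ Bernoulli(2PL); empirical item
  proportions match quadrature-integrated marginal probabilities within
  Monte Carlo error (tested).
- **Longitudinal**: two arms × four timepoints (baseline/3/6/12 months),
  θ_i(t) = θ_i(0) + δ_arm(t) + ε_it with occasion noise τ = 0.3; default
  intervention drift 0.40/0.35/0.50 logits (roughly a 9–14 point percent
  gain), control flat, 120 persons per arm.
- **Covariates**: ρ·θ + √(1−ρ²)·noise with defaults ρ = .50 (NVS-like,
  7 levels), .45 (education, 4 levels), .35 (disease knowledge,
  continuous), discretised by normal quantiles.

What the generator does **not** emulate: pronunciation phonetics, rater
error in +/− marking, item-order or fatigue effects, planned missingness,
and attrition (every simulated person completes every wave).  Passing
tests therefore demonstrate correctness of the statistical machinery
under the assumed response process, not robustness of real-instrument
conclusions to violations of it.

## Problem sizes used in checks

Parameter recovery: J = 40, n = 1000 (corr(b, b̂) > .95, RMSE(b) < .25).
DIF: 500 null and 200 power replicates in the test suite (200/100 in the
acceptance script, which also recomputes everything else at the default
study sizes).  Sensitivity recovery: 500 persons/arm with a 0.5-logit
month-12 drift.  Alpha oracle: 100 random fixtures at machine precision.

## Known limitations

- Single-factor 2PL only; no 1PL/3PL, graded models, or MCMC.
- BHHH block-diagonal SEs understate cross-item uncertainty slightly.
- LR-DIF only; no Mantel–Haenszel/logistic-regression variants, and no
  uniform/nonuniform decomposition beyond the joint 2-df test.
- The equating transform is estimated from the same items it rescales
  (no external anchor design).
- Alpha on pooled multi-language data is not meaningful; the package
  computes it per language and leaves pooling to the analyst.
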