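# Methods

## Scope and conventions

`varcal` evaluates a predictor score s(x) against ground truth on a test set
D = {(x_i, y_i)}. Scores are normalized at load so that higher always means
more likely pathogenic; a `lower_is_positive` input is negated once and the
flag is carried so thresholds can be reported on the original scale. Binary
decisions use the rule *predict positive iff s ≥ τ*. All randomness
(bootstrap resampling, permutation nulls, synthetic generation) flows from
explicit integer seeds through `numpy.random.default_rng`, so every result
is bit-reproducible given the seed.

## Metric suite

Continuous targets: R² = 1 − SS_res/SS_tot measures calibrated agreement
(negative when worse than predicting the mean; it is *not* the square of
Pearson's r), RMSE is reported in assay units, Pearson's r captures linear
association, Spearman's ρ is Pearson on mid-ranks, and Kendall's τ-b is the
concordant-minus-discordant sign sum normalized by the geometric mean of
tie-corrected pair counts on each side. The correlation coefficients are
delegated to `scipy.stats`; the test suite holds them to an O(n²)
literal-definition oracle at 1e−12.

Binary targets: the ROC has one vertex per distinct score, so a tie group
appears as a single vertex and the segment across it is a diagonal chord.
That convention is chosen deliberately: the trapezoidal area under the curve
then equals the tie-aware Mann-Whitney statistic
P(s(X₊) > s(X₋)) + ½P(s(X₊) = s(X₋)) exactly, which is how `auc` is
computed (via mid-ranks, O(n log n)). The truncated AUC integrates the
curve over FPR ∈ [0, cap] with linear interpolation at the cap (consistent
with trapezoidal integration) and normalizes by the cap — the maximum
achievable area in the strip — rather than by the best area for the given
class mix. MCC is the Pearson correlation of the binarized prediction and
label vectors, computed from the confusion matrix; a degenerate matrix
(zero row or column) returns 0 with a warning rather than raising, keeping
reports total. LR⁺ = TPR/FPR, LR⁻ = (1−TPR)/(1−FPR) and DOR = LR⁺/LR⁻
return +inf (flagged) on zero denominators. DOR deliberately has no local
version and is never prior-corrected: a local negative likelihood ratio is
not definable.

## Local calibration

The local posterior P(Y=1 | s(X)=s) is estimated as the pathogenic fraction
in a window [s−ε, s+ε]:

- ε = 5% of the score range, the range taken as the 5th–95th percentile
  interval so that outliers do not inflate it (`window_fraction`, default
  0.05);
- each window must hold at least min(⌈0.10·n⌉, 50) items
  (`window_min_fraction` = 0.10, `window_max_count` = 50). The requirement
  is read as *capped at 50*: for large sets the 10% rule would oversmooth,
  and 50 items bound the binomial standard error of the window proportion at
  ≤ 0.071. Short windows are grown outward one nearest neighbor at a time
  (by absolute score distance, ties toward the lower score) — the minimal
  symmetric reading of an adaptive window.

The evaluation grid defaults to the sorted distinct observed scores, so the
evidence thresholds derived later always land on reachable score values; an
arbitrary grid can be passed. lr⁺(s) follows from the posterior-odds
identity lr⁺ = [P/(1−P)]·[(1−α_D)/α_D]; a saturated window (P = 1) maps to
+inf. lr⁺ is class-prior independent even though the posterior is not,
which the tests verify by subsampling one class.

Smoothing (`smooth_curve`) is display-side only and never feeds the
threshold computation: `isotonic` runs weighted pool-adjacent-violators
(window counts as weights) to enforce a non-decreasing lr⁺, `moving_average`
a centered 5-point mean; the posterior is recomputed from the smoothed lr⁺
to keep the pair pointwise consistent. A bootstrap-lower-bound stringency
option is intentionally not implemented.

Estimator error has two parts: binomial noise per window (per-point relative
error on lr⁺ of a few percent at n = 10⁵ in the central score region, far
larger in the tails where windows hit the 50-item floor) and smoothing bias
of order ε² where the posterior curves. The acceptance test therefore
checks the mean absolute relative lr⁺ error (< 5% over the central 90% of
scores at n = 10⁵) and the pointwise posterior error (< 0.05 on the same
region), plus the exact integral identity that the item-averaged posterior
equals α_D.

## Evidence model

The exponential evidence-combination model assigns one Very Strong line of
evidence the likelihood ratio c and scales lower levels as c^(1/2) (Strong),
c^(1/4) (Moderate), c^(1/8) (Supporting), so combined evidence multiplies:
LR_T = c^(n_su/8 + n_mo/4 + n_st/2 + n_vs). Posteriors follow the odds-form
Bayes update P = LR·α/((LR−1)α + 1). Defaults are c = 351 at target prior
α = 0.10 and c = 8511 at α = 0.01 (351 rather than 350 because the integer
solution avoids rounding error at the 0.9/0.99 posterior targets; the
rounded per-level requirements at c = 350 are 2.08, 4.33 and 18.7).

`solve_c` finds the smallest integer c for which every caller-supplied
combining rule (an evidence-count tuple asserting "pathogenic" or "likely
pathogenic") reaches posterior 0.99 / 0.90: the posterior is monotone in c,
so a bisection to 1e−6 followed by an integer scan-down is exact. The full
qualitative rule catalog is not bundled — callers supply the rule set they
operate under — and smaller priors provably demand larger c.

Score thresholds per level use the universal quantifier: τ_level =
min{τ on the grid : lr⁺(s) ≥ requirement for all grid s ≥ τ}, implemented
as a suffix-minimum scan. This is stricter than first-crossing: an interior
dip in the estimated lr⁺ invalidates every lower candidate threshold. A
level with no qualifying score is reported as absent, not an error.
Thresholds are computed on the normalized orientation and reported on both
scales. Mirrored benign-direction thresholds (requirements c^(−1/8), ...)
are not enabled by default.

## Prior transfer

Measures that depend only on the class-conditional score distributions
(TPR, FPR, ROC, AUC, LR±, DOR, lr⁺) transfer between populations unchanged.
Prior-dependent measures are recomputed at the target prior α from the
class-conditional terms: PPP = α·TPR + (1−α)·FPR, PPV = α·TPR/PPP,
ρ(s) = α·lr⁺/(α(lr⁺−1)+1), RR(s) = ρ(s)/α (exact identity, asserted in
tests). The correction is exact when test set and target population share
class-conditional distributions and differ only in prior; α_D defaults to
the observed positive fraction and can be overridden.

## Uncertainty

Bootstrap CIs are percentile intervals from case resampling with
replacement, n out of n, 1000 iterations by default — the minimal standard
reading; BCa is deliberately not implemented, stratified (within-class)
resampling is available by flag. Plain resamples of binary data that lose a
class are redrawn (capped; counted; > 50% degenerate raises with advice to
stratify). Percentile intervals can rarely exclude the point estimate; that
is flagged as a warning, not an error. p-values use permutation nulls —
labels shuffled for binary data, observed values for continuous — because
the natural "random model" baselines (AUC = 0.5, r = τ = 0) are exactly
permutation nulls; p = (1 + #{null ≥ observed})/(B + 1).

## Synthetic generators

The binormal generator (labels Bernoulli(α), scores N(μ_y, σ_y²)) is the
canonical fixture because everything the toolkit estimates is closed-form
there: AUC = Φ((μ₁−μ₀)/√(σ₀²+σ₁²)), lr⁺(s) = φ₁(s)/φ₀(s) (log-linear in s
when σ₀ = σ₁, slope Δμ/σ²), and the posterior at any prior. Defaults
μ₀ = 0, μ₁ = √2, σ₀ = σ₁ = 1, α = 0.5 give AUC = Φ(1) ≈ 0.841, a
separation typical of current well-performing pathogenicity predictors. A
beta-mixture generator covers bounded [0,1] scores (metapredictor-like
output; its AUC is obtained by quadrature of f₁·F₀), the bivariate-normal
generator provides continuous pairs with Pearson r = ρ and Kendall
τ = (2/π)·arcsin(ρ), optionally warped by a strictly monotone transform,
and `generate_tied` quantizes scores to bin midpoints to exercise every tie
correction.

What the synthetic models do *not* emulate: heteroscedastic assay noise,
replicate structure in observed values, label noise in curated databases,
score distributions with point masses at 0/1, and covariate structure.
Passing the closed-form recovery tests shows the estimators are correct
under the stated sampling model, not that any particular real predictor is
calibrated.

## Problem sizes and numerical choices

Oracle-equivalence tests run 1000 random instances at n ≤ 60 against O(n²)
brute-force references at 1e−12; closed-form recovery uses n = 10⁵ draws;
prior-transfer consistency compares two independent n = 10⁵ populations at
3 standard errors; bootstrap coverage uses 500 replicate experiments of
n = 200 with 300 iterations each, accepting 92–98% coverage of the analytic
AUC. Window expansion uses exact two-pointer growth; ROC construction and
the windowed estimator are O(n log n) via sorting, prefix sums and
`searchsorted`, comfortable at saturation-mutagenesis scale (~10⁴–10⁵
variants).

## Known limitations

- The windowed lr⁺ estimator is noisy in the score tails (window floor 50
  items) exactly where Very Strong evidence would be declared; thresholds
  derived from raw curves are conservative there because of the ∀-rule, but
  tail lr⁺ point values should be read with their window counts.
- The ε and 10%/50 window constants are heuristics inherited from practice;
  no data-driven bandwidth selection is attempted.
- Prior transfer assumes identical class-conditional score distributions
  across populations; covariate shift between databases and clinic violates
  this and is out of scope.
- Labels are taken as ground truth; no allowance for label error.
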