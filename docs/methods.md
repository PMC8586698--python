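# Methods

This note documents the statistical models implemented in `circumfit`,
the numerical choices behind them, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## The bi-factor circumplex model

The measurement model for the eight octant scales is

    x = Λ f + e,    f ~ N(0, Φ),    e ~ N(0, Θ),

with three orthogonal factors (Dominance, Love, Distress),
Φ = diag(φ_D, φ_L, 1), and Θ diagonal unless residual covariances are
explicitly freed.  The 8×2 circumplex block of Λ holds the ideal pattern
(sin θᵢ, cos θᵢ) at the octant angles 0°, 45°, …, 315°; the diagonal
octants are stored as ±0.71 exactly, matching the conventional printed
pattern rather than 1/√2 (`ideal_circumplex_pattern(exact_diagonals=True)`
switches to the exact value; the difference is 0.0029 per loading and
propagates to fourth-decimal changes in congruence statistics).  The
loadings of PA on Dominance and LM on Love are fixed to 1 and the
Distress variance to 1 for identification; all analyses run on
z-standardized scales (N−1 variance estimator).

### Maximum-likelihood estimation

`fit_mcfa` minimizes the normal-theory discrepancy
F = ln|Σ(θ)| + tr(SΣ(θ)⁻¹) − ln|S| − p with analytic gradients under an
unconstrained reparameterization: free loadings in natural units,
log factor variances, log uniquenesses (so Heywood cases cannot go
negative; a uniqueness below 1e−4 is reported as a boundary warning), and
freed residual covariances in natural units.  L-BFGS with gradient
∞-norm tolerance 1e−7 and up to three jittered restarts.  χ² = (n−1)·F̂.

Two properties worth knowing:

- ML stationarity zeroes diag(Σ⁻¹(S−Σ)Σ⁻¹), not diag(S−Σ): the implied
  diagonal matches the sample diagonal exactly only at perfect fit and to
  sampling accuracy otherwise.  Constraining uniquenesses to
  1 − communality would force an exact unit diagonal but changes the
  degrees of freedom from 18 to 26; the conventional free-uniqueness
  model is kept.
- With every circumplex cell freed, the fixed-at-1 scaling cells are
  absorbed by the free factor variances and the model becomes rotation
  invariant across all three standardized factor columns — it is an
  exploratory three-factor solution in disguise (32 parameters minus a
  3-dimensional rotation ridge reproduces the EFA df of 7).  This is the
  mathematical reason small-variance priors are needed to study "almost
  circumplex" patterns confirmatorily.

Fit indices: CFI against the independence baseline Σ_b = diag(S); SRMR as
the root mean square of the p(p+1)/2 standardized residuals; RMSEA
√(max(χ²−df,0)/(df(n−1))) with the 90 % interval by noncentral-χ²
inversion; GFI by the standard ML formula; BIC as χ² − df·ln n (the
difference against the saturated model — only BIC *differences* are ever
consumed, for which the additive convention cancels).  Standard errors
come from the inverse observed information (delta method for
log-parameterized entries) and feed two-tailed normal tests; no
robustness (sandwich) correction is applied — that would rescale standard
errors and χ², not point estimates.

Modification indices are univariate score tests: with g and H the
gradient and (finite-difference) Hessian of F over the fitted parameters
extended by one candidate constraint c,
MI = (n−1)/2 · g_c² / (H_cc − H_cθH_θθ⁻¹H_θc) and EPC = −g_c / (·).
Candidates are all fixed circumplex cells except the two scaling cells,
plus every unfreed residual covariance.

### Bayesian estimation

`fit_bcfa` samples the same model by blocked Gibbs: (i) factor scores
jointly per observation; (ii) all free/prior loading cells as one
multivariate normal block (precision (Θ⁻¹)_jk(F′F)_fg plus prior
precision — exact also when Θ has freed off-diagonals); (iii)
uniquenesses by conjugate inverse-gamma (IG(0.001, 0.001) prior) when Θ
is diagonal, otherwise a random-walk Metropolis sweep over the diagonal
and the freed covariances (normal N(0, 0.01) priors, positive
definiteness enforced); (iv) φ_D, φ_L by conjugate inverse-gamma.
Circumplex cells carry N(ideal, σ²) priors (default σ² = 0.01, the
alternative 0.1 is one config field away); free loadings N(0, 100).

The Distress column is identified only up to a joint sign flip (its
variance is fixed, its loadings all free); draws are relabeled onto the
positive-sum mode, which is valid because the posterior is symmetric
under (Λ₃, f₃) → (−Λ₃, −f₃).  Chains start overdispersed (dispersion
grows with the chain index); convergence is monitored by the
Gelman–Rubin PSR computed on the second half of each chain, with the
reported value floored at 1 (the pooled-variance estimator undershoots 1
when chains coincide).  Burn-in is the first half; the default target is
max PSR ≤ 1.001 with a 100 000-iteration cap and checks every 1 000–2 000
iterations.  An optional warm start initializes chains at a fitted ML
solution; it exists for diffuse-prior configurations, where the posterior
concentrates at the ML solution but Gibbs mixing along the soft rotation
ridge is far too slow from overdispersed starts to be useful.

Posterior predictive checking recomputes, per retained draw, the
likelihood-ratio discrepancy (n−1)·F of the observed covariance matrix
and of one replicated dataset of the same size; p is the proportion of
draws with replicated ≥ observed, and the bracketed "χ² interval" is the
central 95 % interval of the observed-minus-replicated differences.
Bayesian CFI/RMSEA analogues treat the positive part of that difference
as a noncentrality estimate per draw and are summarized by the median and
a 90 % interval.  Credible-interval significance flags a loading or
residual covariance when its central 95 % interval excludes zero.

## Circular stochastic process model

The SPMC represents octant correlations as rᵢⱼ = vᵢvⱼ ρ_c(θᵢ−θⱼ) with
ρ_c(d) = Σ_{k=0}^m βₖ cos(kd), βₖ ≥ 0, Σβₖ = 1 (so ρ_c(0) = 1 and
|ρ_c| ≤ 1), unit implied diagonal, and uniqueness 1 − vᵢ².  Fourier order
m = 3 by default (configurable).  β is parameterized by a softmax with
the first logit pinned, communality roots by a logistic transform, angles
as unconstrained reals wrapped mod 360 with LM fixed at 0; estimation
minimizes the same ML discrepancy with multi-start L-BFGS.  Degrees of
freedom equal the p(p−1)/2 non-redundant correlations minus the free
parameters.  The reflection indeterminacy is resolved by orienting NO
into (0°, 180°).  The minimum of ρ_c over [0°, 180°] is located by a
0.1° grid plus bounded local refinement.  When the input is a
scoring-model reproduced matrix, its communality diagonal is replaced by
unities (keeping it positive definite) before fitting.

## Target-rotated EFA

The unrotated ML solution comes from `statsmodels.multivariate.Factor`
(method `"ml"`); fit statistics use the standard EFA degrees of freedom
((p−m)² − (p+m))/2 = 7 for p = 8, m = 3.  (Published applications
sometimes print other df conventions for the same layout — e.g. 5 — but
no alternative bookkeeping is implemented.)  The orthogonal *partial*
target rotation minimizes ‖M ∘ (ΛT − H)‖² over orthogonal T by gradient
projection with step-halving and multi-start, where H is the ideal 8×2
circumplex and the mask M zeroes the untargeted Distress column — that
column participates in the transform but contributes nothing to the
criterion.  Reflections (det T = −1) are allowed.  Congruence reports
optionally Kaiser-normalize the circumplex rows of both patterns first.

## Scoring and reliability

Weighted-sum scores apply the fixed circumplex weights to z-standardized
scales (a raw-scale variant sits behind `standardize_first=False`);
Distress is the octant mean (the printed /8 divisor).  Regression scores
are standardized data times W = Σ(θ̂)⁻¹Λ̂Φ̂.  The scoring model computes
Λ* (octant–score correlations), C (score intercorrelations), Λ = Λ*C⁻¹
and Σᵣ = ΛCΛ′, with B re-derived by multiple regression of the scores on
the octants (for linear scores this reproduces the generating weights
with R² = 1 exactly).

One algebraic fact shapes the reliability interface: with Σ₁₂ = Σᵣ the
parallel-forms formula is *identically 1* for any full-rank linear
scoring of the same sample, because Σᵣ = SB(B′SB)⁻¹B′S is the projection
of S onto the score space and therefore B′ΣᵣB = B′SB.
`ScoringModel.reliabilities` implements that literal reading (and
documents it); the scientifically informative estimate is
`cfa_score_reliability`, which uses the fitted factor model's common part
Λ̂Φ̂Λ̂′ as the cross-block — two parallel octant sets sharing the common
factors with independent uniquenesses — and yields the conventional
0.85–0.95-range factor-score reliabilities.  The pipeline reports both.
Significance flags for score–criterion correlations use the Fisher-z
normal approximation; at n in the hundreds the difference from exact
t-tests is negligible.

## Synthetic-data generator

`default_population` places the octants at the exact ideal angles with a
common circumplex radius of 0.6 — i.e. standardized circumplex loadings
0.6·(sin θ, cos θ) — and Distress loadings
(0.64, 0.65, 0.66, 0.49, 0.47, 0.59, 0.64, 0.73) in circular order, the
values estimated for a large non-clinical sample.  Uniquenesses are the
complements, so the implied matrix is exactly a correlation matrix.  The
radius 0.6 is a package choice (the reference analysis does not report
raw descriptive moments): it gives communalities 0.58–0.89 and
uniquenesses 0.11–0.42, consistent with scale-score reliabilities in the
low-0.7 to mid-0.8 range.  Data are generated as X = FΛ′ + E from normal
factors and errors; the generator can return the latent factor scores for
score-validity oracles, and a scaled-t option exists for robustness
experiments only.  Item-level data use a one-parameter common-factor item
model (default standardized item loading 0.58, eight items per scale)
discretized to five Likert categories at equal-probability normal
thresholds; the Spearman-Brown value for these settings is α ≈ 0.80,
attenuated a few hundredths by discretization — matching the 0.71–0.85
range typical of octant scales.  External criteria are single indicators
with specified loadings on the three factors (defaults shaped like
Extraversion, Agreeableness, Neuroticism, and grandiose narcissism).

What the generator does **not** emulate: non-normal or heavy-tailed
response distributions (real questionnaire data typically violate
multivariate normality), missingness, demographic heterogeneity, or
method factors.  Passing recovery tests therefore demonstrate estimator
correctness under the stated model, not robustness to those features.

## Problem sizes and tolerances used by the test suite

Recovery tests run at the study sample size n = 822; large-sample
algebra checks at n = 10⁵–2·10⁵; the diffuse-prior limit at n = 10⁴.
Per-loading ML sampling error at n = 822 is about 0.032, so dataset-level
recovery is summarized as RMSE (< 0.05) or as the median over
replications of the per-dataset maximum error (≤ 0.05) — a biased
estimator would still fail both.  Reduced sampler settings
(a few thousand iterations, PSR targets of 1.05–1.1) are used where a
test exercises structure rather than convergence precision; the
convergence test itself runs the full two-chain sampler to
max PSR ≤ 1.001.

## Known limitations

- Plain ML only: no sandwich/scaled test statistics, no FIML for missing
  data, no mean structure.
- The Gibbs sampler mixes slowly for diffuse loading priors (the
  rotation ridge); use the warm start there, or small-variance priors as
  intended.
- No plausible-value factor scores from the Bayesian posterior (their
  bias in individual scoring is the reason the regression and
  weighted-sum scores exist).
- The SPMC implementation covers the standard correlation-structure
  variant; no embedded external variables and no Bayesian SPMC.
- Oblique target rotation is out of scope; the rotation is orthogonal by
  construction.
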