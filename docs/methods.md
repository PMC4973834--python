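# Methods

## Data model

An analysis *level* is a cut-point value, a measurement-method label, or a
method-at-cut-point combination. Each `EffectRecord` holds one log odds
ratio or log hazard ratio `y` with standard error `se > 0` for one level in
one study; sampling variances are treated as known, the standard
meta-analysis convention. The direction convention is that estimates compare
subjects with factor ≤ cut-point against those above it; sources using the
opposite convention are negated on load (`flip_sign`). Mixing log odds and
log hazard ratios in one dataset is refused rather than silently pooled —
there is no defensible automatic conversion between the two scales.

Within-study dependence between two estimates from the same cohort is stored
as either a covariance or a correlation, with the other derived as
cov = ρ·se_a·se_b. Correlations within 1e-9 of ±1 are clipped to the
interior so assembled covariance matrices stay positive semi-definite.
Pairs with no stated value default to covariance 0 with a warning; a global
imputed correlation can be supplied instead, and the sensitivity helper can
additionally *override* stated values with a grid value — without the
override a sensitivity grid touches only unknown pairs, which is a no-op on
datasets where every multi-level study has a stated correlation.

## Univariate synthesis

`fit_univariate` estimates the two-level normal hierarchy by REML (default)
or DerSimonian–Laird moments. The restricted likelihood is profiled over the
mean and maximised over log τ² with bounded Brent searches from dispersed
starts plus an explicit comparison against the τ² = 0 boundary; convergence
tolerance 1e-8. The summary is the inverse-variance weighted mean at τ̂²,
with a Wald confidence interval using the normal quantile. Heterogeneity is
reported as Cochran's Q (fixed-effect weights) and I² = max(0, (Q−(k−1))/Q).

Prediction intervals for the effect in a new population use
β̂ ± t_{N−2}·√(τ̂² + Var β̂) with N the number of studies in the analysis;
the t quantile (rather than normal) partially accounts for the uncertainty
in τ̂. At least three studies are required (df > 0). Confidence intervals
deliberately stay on normal quantiles so that the prediction interval's
extra width isolates the heterogeneity-plus-t contribution.

`fit_meta_regression` shares the same REML engine with an arbitrary design
matrix (intercept always prepended), giving the cut-point meta-regression
with predicted effect α̂ + γ̂₁x and delta-method variance.

## Multivariate synthesis

`fit_mv` maximises the restricted likelihood of the multi-level hierarchy
with per-study dimension reduction: study *i* contributes the normal
log-density of its observed sub-vector with covariance (sub-Ω + S_i), and
the REML adjustment −½ log |Σ X_i′V_i⁻¹X_i| accounts for estimating the
level means. Missing levels therefore drop out under a missing-at-random
assumption; studies reporting a single level enter as 1×1 blocks and still
inform that level's mean and variance.

Ω parameterisations, all unconstrained so quasi-Newton search (L-BFGS-B
with finite-difference gradients, ftol 1e-8, three dispersed starts:
per-level moment variances, shrunken, and inflated, each at zero
correlation) needs no explicit constraints:

* `unstructured` — log-Cholesky: T log-diagonal entries plus T(T−1)/2
  free sub-diagonal entries of the Cholesky factor (T variances and
  T(T−1)/2 covariances);
* `common_var_common_corr` — one log-SD plus one logistic-transformed
  correlation mapped into (−1/(T−1), 1), the positive-definite range of a
  compound-symmetric correlation matrix;
* `ar1` — one log-SD plus tanh-transformed ρ, with τ_jk = τ²ρ^|j−k| over
  the ordered level index (ordering by cut-point value, not spacing).

Between-study correlations may legitimately reach the ±1 boundary with few
studies; the log-Cholesky parameterisation approaches the boundary smoothly
(bounded at |ρ| ≈ 1 − 1e-11 by the parameter box), and fits with
|ρ̂| > 1 − 1e-6 are flagged in the result (`boundary`) rather than rejected.
Summary effects are generalised-least-squares at Ω̂ with Wald z confidence
intervals; per-level prediction intervals reuse the univariate construction
with τ̂_j² and df = (total studies in the joint fit) − 2 — the convention
that reproduces the published worked example.

The univariate and multivariate REML engines were cross-checked during
development against an independent mixed-model implementation and agree to
five decimal places on the packaged datasets; the test suite freezes those
values together with brute-force grid-search and dense-likelihood oracles.

## Cut-point trend

`fit_trend` replaces the T free level means with α + γ·f(x) and a
study-level random intercept: marginal covariance τ_α²·J + S_i (J the
all-ones matrix), REML-profiled over the fixed effects and maximised over
log τ_α. Random slopes are available (`random_slope=True`, diagonal G) but
off by default: with one or two cut-points per study the slope heterogeneity
is rarely identifiable, and where estimable it tends to zero. A
method-stratified variant fits a separate fixed intercept and slope per
measurement method, optionally with method-specific intercept variances and
a between-method intercept correlation (tanh-parameterised).

Transforms are linear or one-term fractional polynomials with powers
{−2, −1, −0.5, 0 (log), 0.5, 1, 2, 3}. A shift is added before negative/log
powers; `shift="auto"` resolves to +1 exactly when some cut-point is ≤ 0,
which keeps the transform defined at a zero cut-point and matches the
internal consistency of the published inverse-quadratic analysis.

Model selection across transforms uses AIC from **full ML** refits with the
identical random-effects structure — REML likelihoods are not comparable
across mean structures — while reported estimates come from REML. Ties keep
input order; candidates undefined on the data's cut-point range are skipped
with a warning. Prediction at a cut-point outside the observed range is a
hard error (`allow_extrapolation=True` to override): the fitted function has
no support outside the studied range. Trend prediction intervals add τ̂_α²
under the root with df = k − 2, mirroring the univariate convention; this is
a declared convention, not derivable from first principles.

## Within-study correlations from published tables

When a cohort publishes the 2×2 table at each of several ordered cut-points,
the participant data are exactly recoverable: successive differencing of the
≤-side margins yields event/non-event counts per inter-cut-point interval
(validated for consistent totals and monotone margins, with the offending
cut-point pair named on failure). `bootstrap_within_corr` resamples whole
subjects (multinomial over interval × event status), computes the log odds
ratio at every cut-point per replicate, and returns the empirical
correlation and covariance matrices plus per-cut-point means and SEs.
Replicates in which some cut-point leaves an empty ≤ or > group are redrawn,
capped at 10× the requested replicates (default n_boot = 1000; the cap is a
declared convention for extreme cut-points). Zero cells are handled by the
opposite-group-reciprocal continuity correction — add 1/(size of the other
group) to every cell of each group — applied only when a zero cell is
present, never silently to clean tables. The covariance handed to the
multivariate model is by default the bootstrap covariance itself;
`use_cov=False` passes the correlation to be combined with analytic SEs as a
sensitivity route.

Where reconstruction is impossible (adjusted effects, hazard ratios), the
patient-level correlation between measurement methods serves as an
approximation: cov = ρ_patient·se_a·se_b, tagged with its provenance.

## Synthetic data

`simulate_from_model` draws directly from the fitted hierarchy: θ_i ~
N(β, Ω), per-study SEs log-uniform over (0.15, 0.45) by default — matching
the spread of precision in the packaged cohort data — and observed vectors
y_i ~ N(θ_i, S_i) with a common within-study correlation (default 0.5, the
typical bootstrap value in the Apgar cohorts). `simulate_trend_model` does
the same for the random-intercept trend. `simulate_cohorts` generates
participant-level data — standard-normal factor, Bernoulli outcome with
logit(p) = intercept + slope·factor (defaults −1 and −1, i.e. ~27% baseline
risk and a risky low range) — and emits the per-cut-point 2×2 tables, the
reconstructed intervals and the derived log-odds-ratio dataset, exercising
the bootstrap machinery end to end. Under this generator the true log odds
ratio is **U-shaped** in the cut-point (verified by numerical integration
over the factor distribution), decreasing through the risky low range and
rising again in the far upper tail; tests compare against that analytic
curve rather than assuming monotonicity.

`apply_missingness` implements MCAR, MAR (deletion probability logistic in
the study's *observed* estimate at a reference level) and
MNAR-by-significance (non-significant level results deleted with probability
p, significant ones always kept — the selective-reporting pattern).
Deleted records take their covariance rows with them; a level losing every
study triggers a warning. All generators take explicit seeds and never touch
global random state.

What the synthetic experiments do and do not show: parameter recovery and
the borrowing-of-strength / selective-reporting comparisons are run under
correctly specified hierarchies with known within-study covariances. Real
data add transcription error, non-normal random effects, correlated
cut-point selection and unknown within-study correlations, so passing these
experiments demonstrates correctness of the estimators, not robustness to
every field condition.

## Numerical conventions and problem sizes

Tolerances: REML convergence 1e-8; PSD checks at −1e-10 relative;
correlation boundary reporting at 1e-6. Replicated experiments in the test
suite use 2-level hierarchies at k = 12 with 500 replicates (missingness
comparisons) and the k = 40, T = 6 trend hierarchy with 600 replicates —
sizes at which the Monte-Carlo SEs are small enough for two-SE recovery
bands to be informative while the full suite runs in about two minutes.

## Known limitations

* Method-of-moments multivariate estimators and the reparameterised
  "overall correlation" model are not implemented; REML only.
* Two-term fractional polynomials and restricted cubic splines are out of
  scope; the one-term family covers the published use cases.
* No Knapp–Hartung adjustment and no publication-bias machinery.
* Survival-time participant data are consumed as log hazard ratio estimates,
  never re-fitted; bootstrap reconstruction applies only to unadjusted odds
  ratios from 2×2 tables.
* With T levels and few studies, the unstructured Ω is weakly identified;
  boundary correlations are expected and structured forms or the trend model
  are the practical alternatives.
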