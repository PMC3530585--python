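# Methods

## Model and estimation

The bud-fate model treats the fraction of a tree-year's buds that develop
into long shoots, P_LS, as a logistic function of pruning intensity PI,
previous-season growth L_W1 (meters of 1-yr-old wood before pruning) and
their product:

    P_LS = 1 / (1 + a · exp(η)),   η = b·PI + c·L_W1 + e·PI·L_W1

with a = exp(log a) > 0, so 1/(1+a) is the bud-fate probability when all
covariate terms vanish. The exponent carries a positive sign; this is the
convention under which the calibrated signs (c > 0, e < 0) make P_LS
monotonically increasing in PI and make the L_W1 effect flip from negative
to positive at PI* = −c/e. The mirrored convention (exp(−η)) would reverse
both statements and is deliberately not implemented.

Estimation linearizes with y = log((1 − P_LS)/P_LS), giving
y = log a + b·PI + c·L_W1 + e·PI·L_W1, and fits by ordinary least squares.
A binomial GLM would be the textbook alternative, but the data are
tree-level fractions without bud counts, so binomial weights are
unavailable; OLS on the logit scale is the estimator the linearization
defines, and the synthetic-data generator's `LogitNormalNoise` matches its
error assumption exactly.

Model selection is backward stepwise by AIC starting from
{PI, L_W1, PI×L_W1}: at each step the single term whose deletion lowers AIC
most is dropped; selection stops when no deletion lowers AIC. There is no
marginality constraint — the interaction may outlive the PI main effect,
and on the bundled data it does. AIC uses the Gaussian profile-likelihood
form n·log(rss/n) + 2(p+1) with additive constants dropped; only
differences within one response vector are meaningful. Stepwise ties within
1e-9 are broken by dropping the interaction last, in the fixed order PI,
L_W1, PI×L_W1. R² is reported primarily on the logit scale (1 − rss/tss on
y); the back-transformed P_LS-scale R² is also exposed because the two can
differ for skewed fractions and it is not knowable which scale a given
published figure used.

Residual diagnostics are advisory only: Shapiro–Wilk for normality and the
Breusch–Pagan LM statistic from regressing squared residuals on fitted
values for heteroscedasticity, each with a pass flag at α = 0.05.

## Data

The bundled calibration data are 20 peach trees (cv Suncrest/GF677)
observed in 2005 and 2006 (40 tree-year rows): L_W1 ∈ [101, 357] m,
PI ∈ [0.10, 0.77], P_LS tree-level fractions. Seven P_LS cells are printed
with one decimal (0.9, 0.8, 0.7) in a table that otherwise uses two, and
the model predicts 0.08–0.21 at those covariates; the `corrected` variant
reads them as 0.09, 0.08, 0.07 (dropped leading zero), the `raw` variant
keeps them verbatim. The correction is a hypothesis and is therefore
explicit, never silent. Its residual ambiguity matters: on the corrected
data the fit gives log a = 1.17, c = 7.12×10⁻³, e = −1.48×10⁻², logit-scale
R² = 0.62 (P_LS-scale 0.63), whereas the reference calibration for this
orchard reports bootstrap means log a = 1.01, c = 7.85×10⁻³,
e = −1.51×10⁻² and 68% variability explained. c and e agree to within
9%/2%, but the intercept is ~16% high and R² ~0.06 low — consistent with
one or more of the corrupted cells having had a true value not recoverable
by the leading-zero rule. The package reports what the bundled data yield;
it does not adjust them further to match the reference numbers.

`REFERENCE_PARAMS` (log a = 1.01, c = 7.85×10⁻³ m⁻¹, e = −1.51×10⁻² m⁻¹)
is that published calibration, used for the analytic results (PI*, onset
threshold, maximum recommended PI) and as simulation truth.

## Bootstrap

Uncertainty is assessed by a nonparametric case bootstrap: the 40 tree-year
rows (years pooled, no blocking by tree) are resampled with replacement,
and the model is refit per replicate with the term set fixed to the
selected model — re-running selection inside the bootstrap would mix
selection variability into coefficient distributions that are meant to
describe the selected model. Default 10,000 replicates. Replicate r of a
run with seed s draws from `numpy.random.default_rng([s, r])`, so single
replicates are reproducible in isolation and whole runs are bit-identical.
Rank-deficient resamples are discarded and redrawn; more than 1% of them
aborts the run. Summaries are mean, sd (ddof = 1), median and the 5th/95th
percentiles by linear interpolation of order statistics, plus the Pearson
correlation matrix of the replicate vectors; the intercept correlation is
also available on the a = exp(log a) scale, since either scale may be
wanted when comparing with published scatter plots.

## Prediction and optimization

Expected long-shoot count: N_LS = N_S · L_W1 · (1 − PI) · P_LS, with
N_S = 45.55 shoots per meter of wood left after pruning (overridable).
N_LS is kept continuous — it is a rate model, not a count draw.

`optimal_pruning_intensity` finds the minimal PI in [0, 1] maximizing N_LS
at a given L_W1: a dense grid (step 10⁻³) locates the maximizer, bounded
golden-section refinement sharpens it to 10⁻⁶, and any plateau within 10⁻⁹
of the maximum resolves to the smallest PI ("minimal maximizer" — prune no
harder than needed). The onset threshold, the smallest L_W1 at which the
optimum becomes positive, is located as the root of the marginal-gain
condition at PI = 0, (1 − P_LS(L_W1, 0))·(−e)·L_W1 = 1, bracketed on a
coarse scan and solved by Brent's method to 0.01 m; tests cross-check it
against direct bisection of the optimizer's indicator. It is reported raw
(79.18 m for the reference calibration) and rounded to the nearest 10 m
(80 m), since the published recommendation is a round number. The maximum
recommended PI is the supremum of the optimal curve over a 1 m grid of
L_W1 up to 600 m (0.6943 for the reference calibration). At resolution
below ~10⁻⁵ the optimal-PI curve is not exactly monotone: it peaks near
L_W1 ≈ 595 m and declines very slowly for larger trees; tests assert
monotonicity and the end-point supremum at 10⁻⁵ tolerance.

## Synthetic data

The generator emulates the study design: L_W1 ~ Uniform(100, 360) m and
PI ~ Uniform(0, 0.8) (the observed spans), P_LS from the true model plus
either Gaussian logit-scale noise (`LogitNormalNoise`, recovery guarantees)
or binomial bud-count sampling (`BinomialNoise`: n_buds =
round(N_S·(1−PI)·L_W1) and the empirical-logit adjustment
(x + 0.5)/(n_buds + 1) keeping fractions inside (0, 1); robustness checks).
Records whose bud count rounds to zero are redrawn. Not emulated: tree
identity across years, year effects, covariate correlation, measurement
error in L_W1 or PI. Passing recovery tests therefore show the estimator is
correct under its own assumptions and under binomial sampling — not that
real orchard data satisfy those assumptions.

Default simulation sizes in the test suite (n = 500 records, noise sd 0.3,
100 replicates for recovery; 100 datasets × 1000 replicates for bootstrap
coverage) were chosen as the smallest designs at which the asserted
properties are stable across seeds.

## Known limitations

- The correction of the seven corrupted P_LS cells is a documented
  hypothesis; intercept-dependent quantities inherit its ~15% uncertainty.
- Tree/year structure is pooled, as in the original analysis; a mixed model
  might shrink the intercept differently.
- No uncertainty propagation from the bootstrap into the optimal-pruning
  curve (exposed building blocks make this straightforward downstream).
- Single cultivar, two seasons: the calibration is not a peach-wide claim.
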