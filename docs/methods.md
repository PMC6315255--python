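# Methods

This note records the models, conventions, and numerical choices the
package implements, and what its synthetic-data tests do and do not
establish.

## Wear-time rule

A candidate nonwear run starts at a zero-count minute and extends
through zeros and *interruptions*: 1–2 consecutive minutes with counts
in [1, 100). A count of 100 or more, or a third consecutive nonzero
minute, terminates the run; the run's span ends at its last zero, so
trailing interruption minutes stay wear. A run is flagged nonwear iff
its span strictly exceeds 90 minutes; interruption minutes inside a
flagged span are excluded along with the zeros (the source rule is
silent on them; excluding is our reading, since retaining 1–2-minute
wear islands inside a 90-minute gap has no analytic value). Runs may
contain any number of interruptions — the rule bounds each
interruption's length, not their count — and runs touching the day's
edges are flagged like any other, device-off before first wear being
the canonical case. Runs never bridge calendar days. A day is valid
with ≥ 600 wear minutes. Missing minutes in an epoch file are treated
as gaps (no record), not zeros.

## Segmentation

Within each wear bout (never across excised nonwear gaps, which would
manufacture distribution changes at the splice) we run divisive
change-point detection with the sample energy divergence

Q(τ) = (n_l n_r / (n_l + n_r)) · (2 E|X−Y|^α − E|X−X′|^α − E|Y−Y′|^α),

estimated by U-statistics over all pairs, α = 1 by default. At each
recursion node the split maximizing Q over admissible points
(min segment size 5 min) is tested by permutation: R shuffles of the
node's values, p = (r+1)/(R+1) with r the number of shuffles whose own
best split reaches the observed Q; the split is kept iff p < 0.05 and
the recursion descends into both children. Segments are summarized by
the sample mean and SD (denominator n−1; SD of a single minute is 0).

Numerics: for α = 1 the full split scan runs in O(n log n) by keeping
the left block's pairwise-distance sums in a Fenwick tree over value
ranks and recovering the right block's sums from static prefix sums;
other α use an O(n²) incremental scan. The default permutation count
is R = 39: under the add-one convention the smallest attainable
p-value is 1/40 = 0.025 < 0.05, so a split is kept only when no
shuffle reaches the observed divergence. This is deliberately the
cheapest valid test at the 5% level — it is slightly conservative
(weak changes are missed a little more often than with R in the
hundreds), which only strengthens false-split control; on bench data
it changes mean segments per day by under 10%. Raise
`n_permutations` when finer p-values are wanted. Each recursion node
draws its shuffles from a stream seeded by (master seed, node offset,
node length), so decisions are reproducible, independent of
processing order, and monotone in the significance level. The
permutation loop stops as soon as rejection has become impossible;
the decision equals full enumeration.

## Pattern classes and profiles

The grid is built on a reference (training) segment set: M and S are
the maximal segment mean and SD, bins are [i·w, (i+1)·w) from origin 0
with floor(M/w)+1 mean bins (so M lands in the top bin, closed above),
and likewise for SD. Held-out segments beyond M or S clip to the edge
bins — building the grid on training segments only avoids leaking the
test partition into the feature definition. With w = 700 the cell
holding (3150, 350) is [2800, 3500) × [0, 700); its midinterval values
µ = 3150, σ = 350 give Chebyshev endpoints µ ± 1.8σ = (2520, 3780)
with probability bound 1 − 1/1.8² ≈ 0.69, and the cell [2800, 3500) ×
[1400, 2100) gives upper endpoint 6300.

Profiles are exact bookkeeping: every wear minute of a valid day lies
in exactly one segment and every segment in exactly one class, so
Σ_j a_ij equals subject i's mean daily wear minutes to floating-point
precision — this conservation is asserted in the tests. Profile
columns with fewer than 10 subjects of nonzero time are dropped before
modeling (smooths need support); the threshold is configurable.

## Ordinal additive model

Cumulative logit with estimated thresholds θ₁ < θ₂ (generalizing to
C−1 thresholds): P(Y ≤ c) = logistic(θ_c − η), η = Σ_p f_p(X_p).
Continuous predictors get cubic B-spline smooths (basis dimension 6,
second-order curvature penalty, from `statsmodels` smooth bases),
column-centered over the training data; the intercept is absorbed
into the thresholds; categorical predictors are unpenalized level
offsets with vocabularies taken from the categorical dtype, so rare
levels unseen in a training split still predict. A continuous
predictor with fewer than 8 distinct values falls back to a linear
term. Basis dimension 6 (rather than a larger basis) reflects the
package's working scale of ~100–150 training subjects against up to
~20 simultaneous smooths. Held-out values outside a smooth's training
range are clipped to it for basis evaluation; `partial_effect` flags
such points as extrapolation and widens the band in proportion to the
distance outside.

Each smooth's penalty carries a double penalty — curvature plus its
null-space projector scaled to the mean curvature eigenvalue — so a
large smoothing parameter shrinks a noise smooth all the way to zero
instead of leaving a free linear slope. Smoothing parameters are
shared within term groups (the evaluation layer puts clinical
covariates in one group and profile columns in another) and selected
by a coordinate sweep over a log-spaced grid, warm-started from the
heaviest smoothing, scoring each candidate by 2·NLL + log(n)·edf with
edf = tr[(H + S_λ)⁻¹H]. The BIC-type penalty is deliberate: with many
candidate profile smooths near n, an AIC score retains spurious
structure that measurably degrades held-out rank correlation, while
the heavier penalty lets pure-noise groups collapse. Observations are
weighted by inverse class prevalence, w_i = N/(C·n_c(i)) (mean 1),
reading "weighted by its class prevalence" through its stated purpose
of countering the 1:2:1 quartile imbalance.

Optimization is damped Newton with the analytic gradient and Hessian
of the weighted NLL — the cumulative-logit log-likelihood is concave,
so Newton with step-halving (rejecting steps that disorder the
thresholds) converges globally; tolerance 1e−8 on the penalized
objective. The linear-smooth, penalty-off configuration coincides
with unpenalized proportional-odds regression and is tested against
`statsmodels` OrderedModel. The fit is deterministic; the `seed`
argument exists only for interface uniformity.

## Evaluation protocol

Quartile cutoffs use linear-interpolation empirical quantiles
(NumPy's default, R type 7) of the *training* values only; values
exactly at Q1 or Q3 fall in category 2 ("lowest quartile" read as
strictly below the cutoff). Gamma excludes tied pairs and is flagged
NaN when all pairs tie. Width tuning rebuilds grid, profiles, cutoffs
and fit inside each fold of repeated stratified 5-fold CV and selects
the argmax mean Gamma, ties to the smaller width. The holdout design
is a stratified 80/20 split (stratified on provisional full-sample
quartile categories; all *fitted* quantities still derive from the
training side alone) comparing the full descriptor against
covariates-only, reported as both Gammas and their difference.

## Synthetic cohorts

Each subject has a latent function score φ ~ N(0,1). Days are
semi-Markov: bout class ~ softmax(base weight + β·φ·rank) with
centered class ranks in [−1, 1] following template order, geometric
bout lengths (mean 20 min, min 2), within-bout counts i.i.d.
Normal(mean, SD²) rounded and clipped at 0 — matching the mean/SD
segment summary the pipeline assumes; within-segment autocorrelation
is deliberately not emulated. The six default classes span means
50–4500 counts/min (including a low-SD moderate class at 3150),
weighted toward sedentary behavior. Wear time is uniform on 10–14 h;
nonwear is inserted as all-zero blocks > 90 min (leading, optional
midday, and trailing), with an adversarial preset salting blocks with
1–2-minute sub-100 interruptions to exercise the wear rule. Capacity
measures are linear in φ — 400-m time decreasing, pace and sit-stand
rate increasing — plus age, BMI and sex effects and Gaussian noise,
clipped positive. The covariate effects matter: a baseline model with
nothing real to find produces held-out Gammas that are pure noise,
whereas published cohort baselines carry clear covariate signal; with
them, the covariates-only Gamma is a stable reference and the
with/without-profile difference is interpretable. Covariate
distributions echo a knee-osteoarthritis cohort (BMI 28.52 ± 4.87,
44.5% male, incidence-heavy subcohort mix) and are independent of φ.

The width-tuning scenario (`width_scaled_config`) needs care: with a
single latent score and a rank-monotone tilt, merging adjacent mean
classes costs almost no information, so cross-validation prefers the
coarsest grid that separates mean levels. The scenario therefore
puts the scale-w* information on the SD axis: two tied-mean levels,
each with a low-SD and a high-SD class (SDs 0.21·w* and 1.21·w*),
ranks by template order, and base weights (0, ln 3, ln 3, 0) chosen
to cancel each level's first-order dwell response to φ. Aggregates
available to coarser grids are then nearly uninformative while a
width-w* grid resolves the informative within-level split; finer
grids pay fragmentation noise. Bouts average 30 min here so
segment-SD estimates stay inside their bins.

What passing tests show — and don't: the synthetic cohorts have
exactly the bout/class structure the segmentation assumes,
conditionally independent counts, clean monotone capacity links, and
no missing data, nonadherence, circadian structure, or device
artifacts. Green tests demonstrate that the pipeline recovers
structure it is designed for and stays honest under a null; they do
not certify performance on real actigraphy.

## Problem sizes and determinism

The acceptance-scale studies run 20-seed batches of 150-subject,
7-day cohorts for the holdout comparison (per-seed effect averaged
over the three measures and three split seeds to tame the variance of
a 30-subject held-out Gamma) and 100-subject, 4-day cohorts for width
tuning with one CV repeat — sizes chosen so the whole suite runs on a
single CPU at desk scale. Every stochastic step (simulation,
segmentation permutations, CV splits, holdout splits) draws from
seeds derived deterministically from a master seed via seed
sequences; identical configuration and seed reproduce every artifact
byte for byte.

## Known limitations

- Temporal structure within segments and the ordering of class
  instances across the day are ignored by design.
- The energy statistic is O(n log n) per scan only for α = 1.
- A single smoothing parameter per term group, not per smooth.
- Gamma is undefined (flagged NaN) when a degenerate model predicts
  one category for all held-out subjects.
- The generator's capacity links are linear in φ; nonlinear
  dose-response shapes are only exercised indirectly through the
  spline machinery's own tests.
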