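# Methods

This note documents the statistical models implemented in `relimap`, the
choices made where the design was genuinely open, and what the synthetic
phantoms do and do not establish about real data.

## Data model

All analyses operate on a `MapStack`: per-subject, per-session,
per-condition 3-D volumes restricted to a user-supplied binary analysis
mask. All volumes of one analysis must share a grid (shape and affine,
affine compared with absolute tolerance 1e-4); 4-D multi-volume files are
rejected rather than disambiguated. Cells absent from the manifest are
flagged missing, and subjects incomplete for a given analysis are excluded
*pairwise per analysis* (with a log message), not globally — an 11-subject
longitudinal study cannot afford listwise deletion across every analysis at
once. The analysis mask is a required input: whether a whole-brain EPI mask
or a grey-matter mask is appropriate is a study-level decision the package
does not make.

## Overlap of thresholded activation

A statistic map is treated as voxel-wise t-values and binarized at the
critical t for a voxel-wise threshold (default p < 0.001, uncorrected,
one-sided positive — the usual convention for an activation contrast such
as food > neutral; a two-sided option splits alpha equally, and a direct
t-threshold is accepted for maps without a known df). Cluster-extent
thresholds and FWE/FDR corrections are out of scope. For super-threshold
sets A and B of the same subject in two sessions:

    Jaccard(A, B) = |A ∩ B| / |A ∪ B|
    Dice(A, B)    = 2|A ∩ B| / (|A| + |B|)

Dice = 2J/(1 + J) identically; both lie in [0, 1] with Dice ≥ Jaccard.
When the union is empty the coefficient is undefined: it is reported as NaN
and tallied, never forced to 0 or 1, because either convention would bias
the across-subject means. Per-subject first-level maps are the unit of
analysis — the mean/SD summary across subjects requires a per-subject
distribution of coefficients.

The summary table (session pair × contrast) feeds a classical two-way
repeated-measures ANOVA (factors: contrast and session pair; sphericity
assumed, with an optional Greenhouse–Geisser epsilon correction) via
`statsmodels.stats.anova.AnovaRM`, plus Bonferroni-corrected paired t-tests
of a designated difference contrast against each constituent condition.
With literally constant input (zero variance everywhere) the F ratio is the
indeterminate 0/0; it is reported as F = 0, p = 1 — a zero effect, not
numerical noise.

## ICC(3,1)

Reliability of continuous measurements uses the consistency intraclass
correlation from the two-way mixed model (subjects random, sessions fixed,
single measurement):

    ICC(3,1) = (BMS − EMS) / (BMS + (k − 1) · EMS)

with BMS the between-subject mean square and EMS the residual after
removing subject and session main effects. For k = 2 this reduces exactly
to (σ²_between − σ²_within)/(σ²_between + σ²_within); the general form is
implemented so that pairwise (k = 2) and all-session (k = 3) maps use one
consistent definition. Session-wise constant shifts do not affect it,
which is the property wanted for longitudinal data where global signal
level may drift between scans.

Choices:

- **Negative ICCs are reported, not truncated at 0.** Truncation would
  bias atlas-region means upward.
- **Voxel exclusion is per-voxel**: a non-finite value in any subject or
  session makes that voxel NaN in the output; other voxels are unaffected.
- Degenerate denominators (zero variance) give NaN, with a warning.
- Thresholded ICC maps use a strict inequality (ICC > cutoff, default
  0.75); NaN voxels are inactive.
- Atlas summaries average finite in-mask voxels per region and attach the
  Fleiss qualitative bands (poor < 0.4 ≤ fair < 0.6 ≤ good ≤ 0.75 <
  excellent). Confidence intervals for voxel-wise ICC maps and the
  absolute-agreement variants are out of scope; the ratings module exposes
  the F = BMS/EMS significance test and an average-measure ICC(3,k) option,
  since standard statistical packages report both.

The voxel-wise implementation is a vectorised two-way ANOVA over the voxel
axis; the scalar version is the same code path, and the ratings module
calls it directly — one implementation, no drift between modules. Its
correctness is checked against an explicit-loop sums-of-squares oracle and
against `pingouin.intraclass_corr` in the test suite.

## Similarity and re-identification

S[i, j] is the correlation (Pearson by default — the common choice for
spatial map similarity; Spearman available) across in-mask voxels finite
in both maps, between subject i's map in session A and subject j's map in
session B. S is not symmetric because the sessions differ; swapping
sessions transposes it. Constant maps yield NaN entries rather than an
arbitrary value.

Subject i is re-identified iff S[i, i] > S[i, j] for all j ≠ i — row-wise
and strict, so ties count as failures. The rate is 100 × identified /
scored, with NaN-containing rows excluded and logged. Group means of
correlations are plain arithmetic means (a Fisher-z option exists). The
within- vs between-subject comparison uses Welch's unequal-variance t-test:
the group sizes (n vs n² − n) and variances differ by construction, so the
pooled-variance test would be inappropriate. ECDF curves are standard
right-continuous empirical CDFs; when within-subject similarity
stochastically dominates, its curve sits pointwise below (right of) the
between-subject curve.

## Cross-condition correlation and difference scores

Per subject, the spatial Spearman correlation (average-rank ties) between
each food-category map and the neutral map is computed per session,
averaged within subject, then summarised across subjects as mean, SD, and
R² = (mean rho)² — the squared mean, not the mean of squares, and both a
pooled value and the per-session breakdown are emitted, since either
pooling order is defensible. The closed-form reliability of a difference
score D = X − Y,

    r_DD = (r_xx σ_x² + r_yy σ_y² − 2 r_xy σ_x σ_y)
           / (σ_x² + σ_y² − 2 r_xy σ_x σ_y),

quantifies the attenuation mechanism: positively correlated constituents
lose shared true variance under subtraction while errors add. The package
treats this as a validation utility — the phantom supplies r_xx, r_yy,
r_xy from its generating parameters; estimating them from real maps is out
of scope.

## Ratings

The craving contrast per subject and session is mean(food-block ratings) −
mean(neutral-block ratings), mirroring the imaging contrast. Subjects
missing either condition in any session are excluded listwise (the ICC and
RM-ANOVA need complete rows) and the analysed n is reported explicitly.
The one-way repeated-measures ANOVA of the session factor tests the
session effect against the subject × session residual with
(k − 1, (n − 1)(k − 1)) degrees of freedom.

## The phantom generator

`generate_stack` draws

    Y[i, s, v] = μ[v] + b[i, v] + ε[i, s, v],
    b ~ N(0, σ²_between[v]),  ε ~ N(0, σ²_within[v]),

so the true consistency ICC at voxel v is σ²_B/(σ²_B + σ²_W), recorded in
a `PhantomTruth` alongside the generating maps. σ²_W = 0 is rejected
(degenerate ICC). Optional box/sphere regions carry their own amplitude
and variance components; a toy atlas with one label per region is emitted
with on-disk bundles.

`generate_condition_stack` adds the condition-sharing structure. A single
coefficient λ applies to the *stable* part of the signal — both the fixed
mean pattern and the per-subject effect field:

    μ_c    = pattern_scale · (√λ · C + √(1−λ) · U_c)
    b_i,c  = σ_B · (√λ · G_i + √(1−λ) · H_i,c)

with C, U_c, G_i, H_i,c independent unit-variance white fields, and
condition-independent session noise. Writing P = pattern_scale², B =
σ²_between, W = σ²_within, the analytic expectations recorded in the truth
are:

- per-condition spatial test–retest r: (P + B)/(P + B + W)
- same-session cross-condition Pearson r: λ(P + B)/(P + B + W)
- difference-map test–retest r: (1−λ)(P + B)/((1−λ)(P + B) + W)
- voxel-wise true ICC: B/(B + W) per condition and
  (1−λ)B/((1−λ)B + W) for a difference condition.

The expected Spearman rho is derived from the Pearson value via the
bivariate-normal relation ρ_s = (6/π)·asin(ρ/2). Sharing must live in the
stable component: if subject effects were condition-independent,
subtraction would leave voxel-wise ICC unchanged and no attenuation could
occur — the model encodes the mechanism it is meant to exhibit, and the
acceptance experiment verifies the closed-form prediction against the
empirical retest correlation of the generated difference maps.

Further properties:

- **Seeding.** One master seed; every (subject, session, condition) draw
  uses its own SeedSequence-derived substream, so runs are bit-reproducible
  and adding a subject leaves existing subjects' data untouched.
- **Smoothing** is an optional isotropic Gaussian kernel (nearest-edge
  handling, hence mean-preserving on constants) applied identically to all
  maps. It induces spatial dependence, so the stated recovery tolerances
  apply to the unsmoothed default.
- **Pseudo-t mode** divides maps by a nominal standard error and records a
  df, producing statistic-like maps for the overlap module.
- **Ratings.** Per subject: a baseline shift common to both conditions
  (cancels in the contrast), a stable subject-level contrast effect
  (default SD 15 on the 0–100 scale), per-block rating noise (default SD
  5), and fixed per-session contrast effects (default 45.2 → 18.6 → 32.5:
  a strong craving contrast at baseline, a post-intervention drop, partial
  rebound). 18 food and 12 neutral blocks per session mirror a typical
  block design. Ratings are clipped to [0, 100]; with the default
  parameters clipping is rare.

What the phantom does *not* emulate: activation topography and anatomy,
spatially structured (non-white) noise, hemodynamic time series, motion or
scanner drift, and non-Gaussian heavy-tailed subject effects. Passing
recovery tests therefore establishes the correctness of the estimators
under the stated variance-component model, not the reliability of any real
paradigm.

## Problem sizes and numerical choices

The test suite and acceptance script run at sizes chosen to make sampling
error comfortably smaller than the asserted tolerances while staying
desk-scale: ICC recovery at n = 50 subjects × 3 sessions × ~5,000 voxels
(tolerance ±0.05) and n = 100 across true ICC ∈ {0.2, 0.5, 0.9}; the
attenuation experiment at n = 200 subjects on a 12³ grid; fingerprinting
ladders at n = 20. Two-way mean squares are computed vectorised in float64;
tiny negative residual sums of squares from cancellation are clamped at
zero. Formula identities (Dice vs Jaccard) are asserted to 1e-12, oracle
equivalences to 1e-8, invariances to 1e-10.

## Known limitations

- Overlap coefficients depend strongly on the chosen threshold; the
  package reports the threshold in every output but offers no principled
  threshold selection.
- The RM-ANOVA assumes sphericity by default (Greenhouse–Geisser optional)
  and complete designs; unbalanced data are rejected, not imputed.
- Re-identification rates on small n have large sampling variance; no
  permutation p-value is provided (noted as a possible extension).
- The atlas summary averages ICC point estimates; it does not propagate
  voxel-level uncertainty.
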