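# Methods

This note documents the statistical models, defaults and numerical choices
behind `diaq`, and what the synthetic-data tests do and do not demonstrate.

## Data model and stage order

The atomic feature is the **precursor** (modified sequence + charge); a
long report holds one row per (run, precursor) with intensity, q-value and
apex retention time. Internally matrices are runs × precursors; statistics
run on log2 intensities except CVs, which are computed on the linear scale
(the field's precision currency). Zero intensities denote non-detection and
become missing on log transform, never −∞.

The pipeline applies, in fixed order: q-value filter → pivot/log →
robust-sum normalization → RT stability (side channel) → batch correction →
peptide selection → geometric rollup → QC metrics. Filtering precedes
normalization so the reference pool is built from confidently identified
precursors; correction operates on log2 data where batch effects are
additive/multiplicative.

An open representational question is whether post-processing should operate
on precursors or on charge-collapsed peptides; the precursor is the
canonical unit here (it is what extraction software scores), and mappings
may collapse charges upstream if desired.

## Q-value filtering

A precursor-level decision at cutoff c (default 0.01): *sparse* keeps a
precursor with ≥1 passing run; *complete* requires a measurement passing in
every run; *percentile(p)* requires a passing fraction ≥ p; *median*
requires the median q across runs ≤ c. Missing q-values count as failing.
The median is the **lower order statistic** (no interpolation): this makes
median filtering exactly the percentile policy at p = 0.5 and guarantees
the nesting complete ⊆ median ⊆ percentile(p ≤ 0.5) ⊆ sparse, which the
property suite asserts on randomized fixtures. Filtering never blanks
individual cells of a kept precursor — completeness of the matrix is the
point of the policy comparison.

## Robust-sum normalization

Per-run injection differences are corrected by scaling each run to a
trimmed-sum reference: precursors are ranked, the top and bottom 10% are
excluded, the pool is restricted to precursors present in every run (so
each run sums identical members), and run r is multiplied by
f_r = median_r'(S_r')/S_r.

The ranking statistic is the cross-run median of **run-median-scaled**
intensities. A ranking on raw medians would change under per-run scale
shifts — the very thing being corrected — so the selected pool would not
commute with normalization and the procedure would be neither idempotent
nor stable. With the scale-invariant ranking, applying the normalizer twice
is exactly a no-op, and rescaling any single run leaves all run-to-run
ratios exactly unchanged. The absolute output level is pinned to the median
pool sum and therefore, like any data-driven location, can shift by one
common factor when a rescaled run crosses the median; relative
quantification is unaffected. Ties at pool boundaries break on precursor
id; the tail count is ⌊n·fraction⌋ per side.

## Empirical-Bayes batch correction

For feature g in run j of batch i, with design matrix X of biological
covariates,

    y_ijg = α_g + X_j β_g + γ_ig + δ_ig ε_ijg,   ε ~ N(0, σ_g²).

Fitting proceeds feature-wise: (1) least squares on [batch indicators | X]
with the identifiability constraint Σ_i n_i γ_ig = 0, giving α̂_g (the
batch-size-weighted grand mean), β̂_g and pooled σ̂_g² (mean squared
residual); (2) standardization z = (y − α̂ − Xβ̂)/σ̂; (3) per-batch feature
estimates γ̂_ig (mean of z) and δ̂²_ig (sample variance, n−1); (4)
moment-matched hyperpriors per batch — normal (γ̄_i, τ̄²_i) across features
for γ, inverse-gamma for δ² with λ̄ = (m² + 2s²)/s², θ̄ = (m³ + m·s²)/s²
from the mean m and variance s² of the δ̂²; (5) fixed-point iteration of
the conditional posterior means

    γ* = (n τ̄² γ̂ + δ²* γ̄)/(n τ̄² + δ²*),
    δ²* = (θ̄ + ½ Σ_j (z − γ*)²)/(n/2 + λ̄ − 1),

to tolerance 1e-4 (max |Δγ*|, max relative Δδ²*), max 100 iterations, error
on non-convergence. Correction restores location and scale:
y* = (σ̂/δ*)(z − γ*) + α̂ + Xβ̂, so covariate contrasts (genotype effects)
are preserved by construction. With `shrink=False` the raw γ̂, δ̂² are used
instead, which reduces to "standardize each feature within batch, restore
pooled location/scale" — the brute-force oracle the tests compare against
on small instances. One test additionally cross-checks the shrunk estimator
against the Bioconductor reference implementation on a tiny fixture; they
agree to ~1e-6.

**QC anchoring.** Pooled QC injections enter the condition covariate as
their own level, so every batch contains a common reference profile that
informs γ̂ without QC being treated as a biological group.

Choices worth stating: a single batch yields the identity correction (no
contrast to estimate); features with fewer than 2 observed values in some
batch, or with zero residual variance, pass through uncorrected and are
flagged; missing cells stay missing; per-feature regressions group
identical missingness patterns and solve them with one pseudoinverse each.
Only the parametric (normal/inverse-gamma) variant is implemented — no
non-parametric density estimate, no reference-batch mode, no continuous
time-trend correction.

## Supervised surrogate variables

Features are ranked by variance across runs (log2 scale; ties on feature
id); the least-variable 50% form the control set, assumed to carry
technical but negligible biological variation. The control submatrix is
row-centred and decomposed by SVD; the top k right-singular vectors
(orthonormal, run-dimension) are the surrogates, regressed out of **all**
features with the intercept retained. k defaults to 1 (one dominant
acquisition-date axis); `k="auto"` keeps components whose singular value
exceeds the 95th percentile of the matching singular value under row-wise
permutation of the controls (19 permutations, seeded). Residual
missingness inside the control submatrix is mean-imputed for the SVD only.
The empirical-Bayes and surrogate modes are alternatives, not a chain: one
correction per pipeline run.

## Peptide selection and protein rollup

Within each protein group, every member's score is its mean pairwise
Pearson correlation with the other members, computed on shared runs (≥6 by
default; pairs with less overlap contribute no score). While the worst
score is below ρ_min = 0.5 and more than two members remain, the worst
member is removed and scores are recomputed (greedy backward elimination —
one-shot thresholding would mis-rank members whose scores are dragged down
by an outlier). Proteins with ≤2 members keep all members and are flagged
rather than dropped; the removal trace is persisted so any threshold can be
audited. ρ_min has no canonical literature value; 0.5 excludes
anti-correlated and uncorrelated members while tolerating noisy but
consistent ones, and is exposed in configuration. Spearman is available
where monotone-but-nonlinear behaviour is expected.

Protein quantities are geometric means of the selected members (on linear
scale; arithmetically averaged log2 values, identical to 1e-12), per run,
provided at least half the selected members are present in that run.

## QC metrics

CV = sample SD / mean × 100 on linear intensities, per feature per group;
groups with fewer than two present values yield a missing CV, never 0.
Intra-batch precision uses each batch's QC injections; cross-batch
precision pools all QCs. The variability-reduction summary is
100 × (median_before − median_after)/median_before on the cross-batch
median CV; a negative value (correction made things worse) is reported,
not raised. Batch structure is diagnosed by feature-wise one-way batch R²
and by the silhouette of batch labels in the first two principal components
of the complete-case, feature-centred matrix — deliberately minimal,
diagnostic machinery, not inference.

## Acquisition-scheme arithmetic

Isolation windows tile [mz_low, mz_high] gaplessly (n = ⌈span/width⌉, the
last window may overshoot; zero overlap by default — the printed counts
34 × 25 Th over 400–1250 and 29 × 16 Th over 400–850 are consistent only
with no overlap, though an overlap parameter exists). Cycle time is
n·t_acc + t_survey; published cycle times are approximations that no single
survey overhead reproduces for every scheme, so t_survey (default 0.1 s) is
configuration, not a fitted constant. Peak sampling uses the Gaussian 4σ
base width, 4/(2√(2 ln 2)) ≈ 1.699 × FWHM: points per peak =
base width / cycle time; peak capacity = 1 + gradient/(FWHM × 1.699). Other
base-width conventions are parameterized rather than reverse-engineered.

## Synthetic campaigns: scope and honesty

The generator emulates the structure of a 3-batch, ≈330-run yeast
campaign on the log2 scale:

    y = base_g + effect_{g,s} + inj_j + a_{i,g} + d_{i,g}·ε_jg

with protein base abundances N(13, 2.5²) log2 a.u. plus N(0,1) peptide
offsets, protein-level strain effects N(0, 0.30²) shared by sibling
peptides, per-run injection offsets N(0, 0.15²), additive batch offsets
a ~ N(0, 0.18²) and multiplicative factors d² inverse-gamma with mean 1
(shape 40) — the same family the corrector assumes, enabling exact
parameter-recovery tests. Technical noise is set by a linear CV of 7.5%
(σ_log2 = √(ln(1 + cv²))/ln 2). QC runs carry the pooled mean of all
strain profiles. Dropout is logistic in abundance (midpoint 9 log2 a.u.,
slope 0.8 per log2 unit); 1% of rows are false identifications with
q-values above 0.01 (true rows below). These settings give ≈7% intra-batch
and ≈17% cross-batch QC CV and 327–340 total runs with ≥30 QCs: 38 strains
× 8 replicates balanced over 3 batches, a QC opening and closing each
batch and after every 10–12 study runs.

Retention times come from per-run linear maps of reference iRT (11
standards shipped) with slope multiplier N(1, 0.002²), intercept shift
N(0, 5 s²) and 17.7 s apex jitter on a 60-min gradient. The drift SDs are
kept small relative to the jitter so the planted jitter dominates the
observed apex SD and is recoverable from the data; larger calibration
drift would be absorbed into the apex SD and make the planted value
unidentifiable from raw RTs.

The closed-form CV oracle (`truth_cv`) converts planted log2 SDs to linear
CVs via CV = √(exp((σ ln 2)²) − 1), excluding injection offsets (removed
by normalization before CVs are read).

**What passing tests do not show.** The generator is linear-Gaussian per
feature with independent batch effects; real campaigns have drifts within
batches, correlated feature-wise batch responses, interference-driven
(not purely abundance-driven) missingness, and q-values whose errors
correlate with intensity. Recovery correlations near 0.99 here therefore
certify the estimator's correctness under its own model, not field
performance; the real-data headline figures (protein counts, exact CV
levels) depend on the original raw runs and are emulated as generator
defaults, not reproduced.

## Numerical and determinism choices

All randomness flows from explicit integer seeds (numpy `default_rng`);
pipelines rerun byte-identically. Matrices are written with %.17g so text
round trips are bit-exact (reads use round-trip float parsing). Ties —
pool boundaries, control sets, selection scores — break on feature id.
Degenerate inputs are defined, not accidental: constant matrices give k=0
surrogates; a single batch corrects to identity; empty reference pools and
rank-deficient designs raise errors naming the offending columns.

## Problem sizes used in the test suite

Property suites run on ≤10-feature × ≤20-run instances (exhaustively
random-seeded); recovery tests run on the full default campaign
(≈330 runs × ≈1200 precursors), which fits comfortably in a couple of
seconds per pipeline pass on one CPU.
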