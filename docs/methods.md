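# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic generators do and do not emulate,
and the numerical choices made where the design was open.

## Data model

All stages operate on an `IntensityMatrix`: proteins × samples log2
abundances with an explicit boolean mask (True = observed). Values at
unobserved cells are never read. Identifiers live in one canonical
namespace — the upper-cased first whitespace token — because Fisher-exact
overlap arithmetic requires a single key space; a mapping hook
(`normalize_id`) is the place to plug in a real symbol↔accession map.
Duplicate protein rows in input tables collapse to the row with the highest
total observed intensity (a declared convention; search engines do not
specify a collapse rule for shared gene symbols).

## Missingness filter and imputation

Label-free AP-MS intensities are missing not at random: censoring
concentrates at low abundance. The filter drops a protein when its missing
fraction is ≥ `max_frac` (default 0.5) over all samples (`global`), or keeps
it if at least one group stays under the threshold (`groupwise`); the
boundary case (exactly 50%) is removed. Imputation is the Perseus
down-shift convention: per sample, missing values are drawn
i.i.d. from N(μ_s − shift·σ_s, (width·σ_s)²) with shift = 1.8 and
width = 0.3 in observed-SD units. The "±0.3 SD band around the noise level"
phrasing is read as a Gaussian of SD 0.3·σ_s centered at the noise level,
not a truncated distribution — this matches the down-shift semantics of the
program the convention comes from; a truncated reading cannot be excluded
from the description alone. Order is filter → impute. Samples with fewer
than 3 observed values cannot support the per-sample moments and are a hard
error.

## Bait normalization

For comparisons between bait-carrying conditions, per-sample log2 values are
shifted so the mean of the bait-fragment rows is constant across samples
(grand mean re-added to stay on the original scale). This assumes equal
bait expression is the right loading control; it is inappropriate when bait
expression itself differs biologically.

## GIS median-polish normalization

Cohort batches are anchored to global-internal-standard (GIS) samples:
iterate (a) subtract, per protein and batch, the batch's GIS-sample median
log2 ratio to the global GIS central tendency, and (b) subtract the
per-sample median; stop when the largest adjustment is < `tol`
(default 1e−8, `max_iter` 100; non-convergence is a warning, not fatal).
The output is relative log2 abundance with the GIS central tendency at 0.
Batches without a GIS sample fall back to the batch median as pseudo-GIS
(logged). This is a simplified two-step polish, not the full published
ratio-polish algorithm with its tunable options.

A consequence worth knowing: subtracting the per-sample median leaves a
faint negative image of any dominant co-expression signal in every other
protein (a composition effect common to all median/ratio normalizations).
On synthetic data this occasionally lets a chance branch of noise proteins
pass module detection with an eigengene anti-correlated to the largest
module.

## Bootstrap covariate regression

Per protein, abundance is regressed on covariates to remove (age, sex, PMI)
plus protected variables (diagnosis/group) that are modeled but not
removed. Coefficients are the medians over `n_boot` (default 1000)
bootstrap resamples of samples; the returned abundance subtracts only the
removed covariates' centered contributions. Categorical covariates are
one-hot encoded against the first level. Rank-deficient resamples are
redrawn (bounded), then skipped with a log line. GIS samples are excluded
from fitting and passed through.

## Differential enrichment

Two-group comparisons use the equal-variance two-sample t (Welch by flag);
log2FC = mean(A) − mean(B). Zero pooled variance resolves to p = 1 (equal
means) or the smallest positive double (unequal), flagged. Multi-group
designs use one-way ANOVA with Tukey HSD pairwise p from the
studentized-range distribution; a Tukey estimate below 10^−8.5 is replaced
by the Bonferroni-corrected pooled-t p for that pair (recorded per row) to
avoid the precision ceiling of extreme studentized-range tails. Candidate
selection uses unadjusted p < 0.05 (strict; the −log10 = 1.3 volcano line),
with BH-adjusted values always reported alongside. Some figure-style
summaries in the field describe two-group volcanoes via ANOVA; with two
groups the ANOVA p equals the t-test p exactly, so the distinction is moot.

## Enrichment (FET)

One-tailed over-representation only: p = P(X ≥ k) for
X ~ Hypergeometric(N, K, n). Fold enrichment = (k/n)/(K/N). The default
background is the quantified proteome of the experiment at hand (post
filter), not the GMT universe — the choice is recorded in output metadata
and both options exist because published pipelines are silent on it. BH is
applied across all sets for single-list runs and within each query row for
grids; grid stars at 0.05/0.01/0.001; an unadjusted-p variant exists for
barplot-style outputs.

## Co-expression network

Correlation is Tukey biweight midcorrelation (bicor): center = median,
scale = 9·MAD, weights (1 − u²)² for |u| < 1. Vectors with zero MAD fall
back to Pearson (logged); constant vectors are an error. Signed adjacency
a_ij = ((1 + r_ij)/2)^β with β = 9; topological overlap
TOM_ij = (l_ij + a_ij)/((k_i + k_j)/2 − a_ij + 1) (mean denominator; min
variant available).

Module detection clusters 1 − TOM with average linkage and decomposes the
tree adaptively:

1. an initial cut at a height quantile modulated by `deep_split`
   (0 → 0.95, 2 → 0.80, 4 → 0.65, linear in between);
2. recursive splitting at internal junctions: a branch splits when both
   children could hold a module (≥ `min_module_size` = 25) and their
   eigengenes differ by at least the merge cut height; chained side twigs
   are detached only when a genuine junction exists beneath them.
   Over-splitting is safe because the merge stage rejoins fragments of one
   module;
3. a coherence filter: a candidate module must achieve split-half
   cross-validated coherence ≥ `min_module_coherence` (0.3) — eigengene
   loadings estimated on half the samples, mean |leave-self-out correlation|
   of members' held-out profiles with the projected factor. This removes
   most (not all) chance-correlation branches: a branch selected for high
   empirical correlation across all samples is genuinely correlated in any
   subset, so no data-driven filter can fully distinguish a weak chance
   module from a weak real one;
4. PAM stage: an unassigned protein joins its closest module when its mean
   TOM-dissimilarity to the module does not exceed the module's own mean
   within-module dissimilarity (a member-likeness rule; comparing against
   the protein's background dissimilarity instead proved useless in signed
   β = 9 networks, where all dissimilarities crowd within ~10⁻³ of 1);
5. eigengene reassignment: a protein moves to the module where its kME is
   highest if that kME is significant (bicor p < 0.05), and is released to
   M0 when its own-module kME falls below 0.3 (the `minKMEtoStay`
   convention);
6. modules under the size floor dissolve to M0; labels M1… by size
   descending;
7. merging: iteratively merge the module pair with the smallest eigengene
   dissimilarity 1 − cor while it is below `merge_cut_height` = 0.07,
   recomputing eigengenes each time.

The module eigengene is the first principal component of the
member-standardized profiles, unit sample variance, oriented to correlate
positively with the mean member profile. kME(i, M) = bicor(profile_i,
ME_M); module–trait association is bicor of eigengenes with traits (ordinal
traits as numeric ranks), two-sided p by the t approximation with n − 2 df.

This is a simplified re-implementation of the dynamic hybrid tree cut, not
a bug-compatible replica: it aims at correct modules on well-separated
data. Blockwise decomposition is not implemented (single-block only).

## Braak-stage trends and integration

Per-protein staging trends use the tie-corrected Kruskal–Wallis test across
stages and two-sided rank-sum tests per stage pair — exact enumeration of
rank configurations when both groups have ≤ 8 samples, the tie-corrected
normal approximation otherwise; pairwise p unadjusted by default (a
family-wise flag exists). Module composition reports exclusive class counts
under an explicit precedence ordering (a member matching several annotation
lists counts once, under the first match), percentages to 2 d.p. summing to
100. Insoluble-proteome mapping reports per-module one-tailed FET with
unadjusted −log10 p (barplot convention).

## Synthetic generators

`simulate_apms` plants: two bait rows (+8 log2FC in the bait group,
mirroring the strong self-enrichment of a ligase-fragment bait), `n_true`
interactors (+2 by default), equal-mean "endogenously biotinylated"
background rows, per-batch offsets, and logistic MNAR censoring
P(missing) = expit(slope·(midpoint − intensity)) with midpoint 17.5 and
slope 1 against a background of N(20, 2²) protein means and 0.5 sample
noise — roughly 15–20% missingness concentrated at low abundance. The
censoring mechanism is an assumption (no published statement of the true
mechanism exists); it is exactly the assumption the down-shift imputation
encodes.

`simulate_cohort` plants modules as loading·seed + unit noise with loading
√(r/(1−r)) so expected pairwise within-module correlation equals
`within_module_cor` (default 0.9); defaults use 1000 proteins, module sizes
150/100/60/30, CTL/AD/PSP group sizes 46/49/26 (the cohort composition the
pipeline targets), age/sex/PMI covariate effects on all proteins, per-batch
offsets, and one noiseless GIS copy of the grand central tendency per batch
(noiseless so the median-polish target is exactly recoverable). Braak and
CERAD are quantile-discretized latent Gaussians (0–6 and 0–3); diagnosis
effects shift module seeds by group. `simulate_genesets` emits per-module
marker sets at a chosen overlap fraction plus uniform decoys.

What the generators do **not** emulate: peptide-level structure, shared
peptides/protein-group ambiguity, intensity-dependent variance, non-Gaussian
tails, correlated covariates (age vs diagnosis), or hub-heavy scale-free
degree structure within modules (loadings are equal within a module unless
constructed otherwise). Passing tests therefore demonstrate correctness of
the statistical machinery under its own assumptions, not robustness to
every pathology of real MS data.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale data (≈1000–2000 proteins, ≈10–120
samples, 20 replicate cohorts), sizes at which every stage completes in
seconds while leaving the planted structure statistically unambiguous.
Median-polish tolerance 1e−8; BH via the standard step-up with
monotonicity; hypergeometric tails via the survival function (never 1 − cdf);
p-values clamped to (0, 1]; eigengene sign fixed by the mean-profile rule;
ties in module size ordering broken by label. All randomness flows from
explicit integer seeds; identical configurations reproduce outputs
byte-for-byte.

## Known limitations

- The tree-cut is simplified; on data with nested or weakly separated
  modules it will differ from the reference dynamic hybrid cut.
- Chance-correlation modules (typically 25–55 proteins) occasionally
  survive on data with many unstructured proteins; inspect small modules'
  coherence and trait correlations before interpreting them.
- The GIS polish assumes GIS samples are representative mixtures; it cannot
  fix batch × protein interactions.
- Bootstrap regression assumes linear covariate effects and exchangeable
  samples; strongly confounded designs (diagnosis collinear with age) will
  leak protected signal into removed terms.
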