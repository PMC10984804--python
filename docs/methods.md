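# Methods

`xtissue` implements a cross-tissue transcriptome analysis: it builds a
co-expression network shared by skeletal muscle (SM) and subcutaneous adipose
tissue (SAT), partitions it into gene communities, tests each community's
eigengene for tissue-discordant regulation by an exercise intervention, and
models community expression against clinical traits.  Because the underlying
study designs (a large cross-sectional two-tissue biobank and a small paired
pre/post intervention cohort) involve controlled-access data, the package
ships a synthetic-cohort generator with known ground truth; every statistical
claim made by the test suite is a claim about recovery of that truth.

## Preprocessing

Counts are normalized with trimmed-mean-of-M-values (TMM) scaling factors.
The reference sample is the one whose upper-quartile/library-size ratio is
closest to the mean of that ratio.  Against the reference, each sample's
per-gene log2 ratio of count fractions (M) and average log2 abundance (A) are
computed over genes expressed in both samples, doubly trimmed (30% on M, 5%
on A, rank-based two-sided), and averaged with precision weights equal to the
inverse approximate binomial variance of M.  Factors are rescaled to
geometric mean 1.  The implementation reproduces `edgeR::calcNormFactors`
exactly (verified during development to all printed digits on random count
matrices); the shipped test oracle is an independent step-by-step Python
transcription of the same published recipe.

Expression is `log2cpm = log2((count + 0.5) / (libsize * factor) * 1e6)`.
The prior count of 0.5 is the common convention.  Gene filtering keeps genes
with row-mean log2CPM >= 4 — the threshold is applied inclusively, per tissue
per dataset (the strictest reading of "expressed in both tissues in both
datasets") — and, when a protein-evidence list is supplied, restricts to it.
Candidates are the intersection of surviving genes across all four
cohort x tissue slices.

## Network construction

For each tissue, every unordered candidate pair is scored with Pearson r;
two-sided p-values come from the t transform `t = r*sqrt((n-2)/(1-r^2))`;
Benjamini–Hochberg adjustment runs across all pairs tested within the tissue.
Edges require r > 0.30 (signed, consistent with a reported positive mean
network correlation; `use_abs_r` switches to |r|) and BH FDR < 1%.  The
shared network is the *intersection* of the two tissues' edge sets — the only
reading that yields a single edge set "representing both tissues" — with sign
concordance required by default.  Louvain modularity optimization (seeded,
via networkx) partitions the unweighted shared graph at resolution 1.0;
communities below `min_size = 10` nodes are relabeled "unassigned" (id 0).
The floor sits below the smallest planted community (19 genes) and above
singleton noise.

## Eigengenes and the exercise analysis

A community eigengene is the first right singular vector, over samples, of
the community's gene-standardized expression (unit norm; sign aligned with
the community mean profile, tie-broken toward a positive loading on the
first gene).  `variance_explained` is the first squared singular value over
the total.

The exercise statistic is a fully within-subject 2x2 repeated-measures ANOVA
(Time, Tissue, Time x Tissue), computed by the exact sums-of-squares
decomposition with each effect tested against its own subject x effect error
stratum on (1, n-1) degrees of freedom.  For a 2x2 within design this is
algebraically identical to one-sample t-tests on per-subject contrasts, so
the implementation admits an exact internal oracle: F_interaction equals the
squared paired t statistic on the difference-of-differences
`(post-pre)_SM - (post-pre)_SAT` (asserted to 1e-8 in the tests, and
cross-checked against `pingouin.rm_anova`).  A community's "fold change"
per tissue is the mean paired eigengene change (post - pre); per-tissue
paired t-tests accompany the interaction.  Following the source analysis, no
multiplicity correction is applied across the eight communities (a BH option
exists, off by default).  Trait association is plain Pearson correlation of
eigengenes against the trait table on one tissue x timepoint slice
(default: pre-intervention SAT, the slice where discordant adipose signal is
expected); missing traits are dropped pairwise.

## OPLS / OPLS-DA

The trait models use orthogonal projections to latent structures with one
predictive component and (by default) one orthogonal component.  X is
centered and unit-variance scaled, y centered.  The predictive weight is
`w ∝ X'y` (unit norm); each orthogonal component takes the predictive
loading `p* = X't/(t't)`, removes its projection on w, normalizes to get
`w_o`, and deflates `X <- X - t_o p_o'`.  With `n_ortho = 0` the model is
exactly single-component PLS1 (asserted against scikit-learn's
`PLSRegression` to 1e-8).  VIP is computed on the predictive component only,
`VIP_j = sqrt(p)*|w_j|/||w||`, so mean(VIP^2) = 1 exactly — the conventional
form for single-predictive-component OPLS, and the reason VIP > 1 marks
above-average contributors.  OPLS-DA encodes a binary class as a 0/1 dummy
response and classifies by the predictive score; performance is summarized
by AUROC via the Mann–Whitney identity (ties count 1/2).

Model validation is Monte-Carlo cross-validation: `n_repeats` random
holdouts of 1/7 of the samples (a 7-fold-like scheme; the published phrase
"cross-validated 1000 times" does not specify one), aggregating
`Q2 = 1 - PRESS/TSS` over repeats.  The model-level "q-value" is an
add-one-smoothed permutation p-value: the fraction of label permutations
whose Q2, under the *same* holdout splits, reaches the observed Q2.  For
`n_ortho <= 1` the permutation ensemble is evaluated by a vectorized
closed-form batch (algebraically identical to per-permutation fits; asserted
in the tests), which keeps 1000 x 1000 validation affordable.

## Synthetic cohorts

Each community k has a latent factor f_k (one value per sample).  On the
log2CPM scale, member genes follow `x_g = baseline_g + sqrt(rho)*f_k + eps`,
with `eps ~ N(0, 1-rho)`, so the expected within-community pairwise
correlation is exactly `rho` (default 0.5); background genes are independent
N(baseline, 1); baselines are uniform on [4.5, 9] log2CPM.  Counts are
negative-binomial, `NB(mu = 2^x * libsize/1e6, dispersion 0.1)` via the
gamma–Poisson mixture, with library sizes uniform on [5e6, 2e7] — the exact
inverse of the count -> log2CPM path, at a dispersion typical of human
cohort RNA-seq.  Default community sizes are 233/147/178/41/106/32/19 plus
an eighth community of 50 genes (its size is not pinned by the source
material) inside a 5000-gene universe, keeping the communities ~16% of the
filtered transcriptome.  That proportion matters: community-level expression
shifts must not dominate the count composition, since between-sample
normalization is blind to a majority shift; at realistic proportions the
compositional distortion of eigengenes is negligible.

The intervention cohort is a complete paired design (default 16 subjects,
both tissues, pre/post).  The community factor becomes
`f = u_subject + delta_tissue*1{post} + e`, with the per-tissue shifts
`delta` configured per community (defaults plant one discordant community,
+0.8/-0.8 in units of the baseline factor SD, several SM-only shifts of
+-0.5, and null communities).  The subject intercept variance is 25% of the
occasion-level residual variance, and the pre-timepoint total variance is
fixed at 1 so the intervention factor lives on the same scale as the
reference cohort: Var(u) = 0.2, Var(e) = 0.8.  Under these conditions the
planted discordant effect gives a difference-of-differences noncentrality of
1.6/(2*sqrt(0.8))*sqrt(16) ~ 3.6, i.e. ~92% power at alpha = 0.05 with 16
subjects — the detection checks operate close to their own power boundary by
design.  Traits derive from the pre-timepoint SAT factors: a continuous
BMI-like trait (27 + slope*f + N(0,1), default slope -1.0, population
R ~ -0.7), a correlated fat-mass-like trait, and a binary T2D-like trait
through a logistic link (default log-odds slope +2.0, intercept -1.1,
~25% prevalence).  Everything planted is returned in a `truth` record.

What the generator does *not* emulate: batch effects, sex chromosomes,
gene-length bias, isoform structure, heavy-tailed outlier samples, missing
biopsies, and microarray intensity scales (a validation cohort is
represented by the same log-scale generator).  Passing tests therefore
certify the statistical machinery and its calibration under a clean
factor-model world, not robustness to those artifacts.

## Numerical choices and degenerate inputs

Constant genes are excluded from correlation testing and eigengenes (with a
logged count); constant predictors are dropped from OPLS; a zero-variance
response is an error.  Paired tests with zero-variance nonzero differences
return p = 0 with an infinite t (flagged degenerate); all-zero differences
return t = 0, p = 1.  An empty shared network, an empty candidate
intersection, or fewer than 3 complete subjects are errors that name the
failing stage.  Holdouts that leave the training response constant are
resampled and counted.  Pipeline runs are deterministic for a fixed
config + seed (all child seeds derive from one `SeedSequence`); the JSON
report carries a config hash instead of timestamps so reruns are
byte-identical, and is checked against `docs/report.schema.json` by a
minimal structural validator.

## Problem sizes used by the shipped checks

The acceptance-style checks run the default-scale reference cohort (5000
genes, 400 samples per tissue, ~10 s per network build), 100 intervention
cohort replicates for detection and trait-sign recovery, 10 simulation seeds
for community recovery, 2000 null replicates for ANOVA calibration, and 200
null replicates at reduced cross-validation depth (100 repeats, 200
permutations) for permutation calibration.  The analysis drivers under
`analysis/` use the full default configuration with 1000 x 1000
cross-validation.
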