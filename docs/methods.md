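# Methods

`dimoshift` implements the statistical pipeline for asking whether the two
sexes of a cold-adapted fly respond to cold acclimation in the same way —
at the whole-organism level (chill-coma onset temperature, CTmin) and at
the transcriptome level (bulk RNA-seq of a 2 sexes x 2 temperatures x 3
replicates design) — and, centrally, whether cold *reduces sexually
dimorphic expression*: male-biased genes moving down and female-biased
genes up in males is a net "feminization" of the male transcriptome.

## Expression model and differential testing

**Filtering.** A gene is kept only if no sex x temperature group has two or
more libraries with CPM < 0.5, with CPM computed on raw library sums
(filtering precedes normalization). "Condition" is read as the four
factorial groups — the strictest well-defined reading with three libraries
per group; `grouping="temperature"` and `"all"` are available because the
phrase is genuinely ambiguous at two-or-more-per-condition.

**TMM.** Between-library scaling factors come from a doubly trimmed
(30% on M-values, 5% on A-values), inverse-variance-weighted mean of
per-gene log2 ratios against a reference library (the one whose
upper-quartile count rate is closest to the mean upper-quartile). Genes
with a zero count in either member of a pair are excluded; factors are
rescaled to geometric mean 1, and effective library sizes are raw sums
times factors. This is the standard TMM construction; it is validated
against a hand-stepped evaluation of the definition, not against any
specific package's binary output.

**Log-CPM.** log2((count + p_j) / (N_j + 2 p_j) * 1e6) with a
library-size-scaled prior p_j = prior_count * N_j / mean(N) (default
prior_count = 2), so zeros map to finite values and the prior means the
same thing at every depth. These display values feed the filter, MDS,
clustering and correlation stages; the GLM works on raw counts.

**NB GLM.** Per gene, counts follow NB(mu, phi) with variance
mu + phi mu^2 and log link; the linear predictor is a group-means
parameterization of the 2 x 2 design plus a log effective-library-size
offset. Fitting is IRLS, vectorized across genes (one shared design, a
stack of 4 x 4 normal equations). Dispersion phi is estimated on a fixed
log-spaced grid (1e-4 to 10, 41 points) by Cox-Reid adjusted profile
likelihood; the common value maximizes the mean APL over genes, and
tagwise values maximize each gene's APL plus `dispersion_prior_df / df_res`
pseudo-genes of the common curve (default prior df 10 at residual df 8,
i.e. 1.25 pseudo-genes), shrinking noisy estimates toward the common one.
A grid argmax rather than a spline-interpolated Cox-Reid trend is a
deliberate simplification: the quasi-dispersion layer absorbs residual
quantization, and the design is validated by its operating characteristics
(type-I error, effect recovery) rather than bit-level agreement with any
reference implementation.

**Quasi-F contrasts.** Five named contrasts cover the model terms: cold
effect in each sex, sex effect in each condition, and the interaction.
For each, the reduced model (design projected onto the contrast's null
space) is refitted at the same dispersions and the deviance drop is
divided by a moderated quasi-dispersion, s2_mod = (d0 * s2_trend +
df_res * s2_g) / (d0 + df_res), where s2_g = residual deviance / df_res,
s2_trend is a binned running mean of s2 against average log-CPM, and
d0 = 10 by default. p comes from F(1, df_res + d0). On effect-free
simulations every contrast's rejection rate at alpha = 0.05 sits within
0.05 +/- 0.015 (2000 genes), and with 50 replicates per group the
estimated log2FC of a 2-log2FC effect is unbiased to within 0.05.

**Multiple testing.** Benjamini-Hochberg step-up within each contrast
(statsmodels' implementation behind a validating wrapper); genes with
non-converged fits get NaN statistics and are excluded from the number of
tests so the FDR is not deflated.

## Sex-bias classification and the feminization estimate

A gene is *male-biased* iff the male-vs-female contrast has FDR < 0.05 and
log2FC >= +1 in **both** temperature conditions (female-biased with <= -1;
log2FC is male minus female throughout). Genes significant and large in
both conditions but with opposite signs are labelled unbiased and counted
in a `discordant` diagnostic — such genes are empirically negligible, and
excluding them from the biased classes is the conservative choice. An
optional conservative label set keeps a call only when an external
relative's sex-bias table agrees in direction.

Each bias class's cold response is then summarized per sex:

1. **Wilcoxon rank-sum** of the class's cold log2FC against unbiased
   genes' cold log2FC (exact enumeration when both groups have <= 50
   values and no ties; normal approximation with tie correction
   otherwise), BH-corrected across the four sex x class tests.
2. **Normalized shift**: the unbiased genes' median cold log2FC (per sex)
   is subtracted from every biased gene's cold log2FC, and the class is
   summarized by the Hodges-Lehmann pseudomedian — the median of all
   Walsh averages (x_i + x_j)/2, i <= j — with a distribution-free
   signed-rank 95% CI (order statistics of the sorted Walsh averages at a
   depth given by the exact signed-rank null distribution for n <= 50,
   its normal approximation above).

With the default generator settings the chain recovers the simulated
deltas: pseudomedian ~ -0.46 for male-biased genes in males (truth -0.5)
and ~ -0.13 in females (truth -0.1), the male shift exceeding the female
shift in magnitude in effectively every replicate.

Two caveats the CI does not capture, both properties of the published
procedure rather than of this implementation: (i) classifying genes by
thresholded estimates and then measuring their shift on the same data
biases the shift slightly toward zero in males and away in females
(winner's-curse selection through the shared group mean); (ii) the
subtracted unbiased median is itself an estimate whose sampling error is
a common offset to the whole class. Together they push single-replicate
CI coverage of the true delta to roughly 80-90% rather than the nominal
95%. The sign structure and sex asymmetry — the findings the estimator
exists to detect — are unaffected.

## Concordance analyses

* **Multi-set overlap.** For two DE sets the intersection's significance
  is the hypergeometric upper tail. For k > 2 the exact intersection-size
  distribution is built by successive conditioning (the running
  intersection of uniform random subsets is itself uniform given its
  size, so each step is hypergeometric), matching the multi-set exact
  construction; a seeded Monte-Carlo chain (1e5 draws) replaces the
  convolution for very large instances (universe > 5000 and k > 3).
* **Response correlation.** Spearman's rho with midrank ties between the
  sexes' cold log2FC, over all genes or a subset (e.g. the DE union).
* **Dimorphism correlation by condition.** Spearman correlation of mean
  male vs mean female log2 CPM within each temperature, compared by a
  Fisher z-test for independent correlations. The two coefficients in
  fact share genes, so the z-test's independence assumption is wrong in a
  known direction (conservative for positively dependent estimates); the
  dependent-correlation variant is a flagged extension, and the
  independent form is kept because that is the test named in the
  workflow this package reimplements.
* **Leading-log-FC MDS.** The distance between two libraries is the RMS
  of their `top` (default 500) largest absolute log2-CPM differences,
  selected per pair; classical Torgerson double-centering embeds the
  distance matrix. Pairwise (not common) top-gene selection is used.
* **Bootstrap clustering.** Average-linkage hierarchical clustering of
  libraries on Euclidean log2-CPM distance; support of a node is the
  percentage of gene-resampled bootstrap dendrograms containing a node
  with exactly the same library set (cluster-wise recovery). Linkage and
  metric are configurable since the modelled workflow does not state
  them. Under the default simulation the libraries split first by sex
  (support ~ 100) with temperature subclusters inside each sex.

## Enrichment

Per-term significance is a one-tailed hypergeometric (Fisher) test on the
set x term 2 x 2 table against a background of the filtered (expressed)
genes — not the whole genome — with BH correction across terms. An
optional EASE variant removes one gene from the overlap cell before
taking the tail. Term *clusters* are accepted as given groupings (no
kappa-based fuzzy clustering is performed; that heuristic is
tool-internal and version-dependent); a cluster's enrichment score is
-log10 of the geometric mean of its members' p-values, significant above
1.3 (geometric-mean p < 0.05). A direction summary counts significant
member genes moving up vs down and flags direction-pure terms.

## CTmin phenotype model

CTmin (degC at chill-coma onset) is shifted by +5 and log-transformed
(natural log by default, base-10 by flag) so values a few degrees below
zero are admissible; the model on the transformed scale is a linear mixed
model — fixed effects sex, treatment, sex x treatment and body weight,
random intercept per assay batch — fitted by REML (statsmodels MixedLM,
with derivative-free optimizer fallbacks at the zero-variance boundary).
Although the source workflow says "generalized linear mixed model", the
stated log transform of the response makes a Gaussian LMM on the
transformed scale the only consistent reading, and that is what is
implemented (recorded in the output metadata). Each fixed term is tested
by a 1-df Wald chi-square, (estimate/SE)^2 against chi2(1); the batch
variance may legitimately sit at 0, where the fixed-effect estimates
agree with OLS. A single-batch table falls back to a fixed-effects model
with a loud warning. Weight enters uncentered, as supplied.

## Synthetic data

`simulate_counts` draws the 2 x 2 x n_reps design with NB counts.  Group
means live on log2 scale: per-gene baseline ~ N(0, 2); a +/-2 log2 sex
effect on sex-biased genes (18% female-, 21% male-biased — mirroring the
modelled study's 1682 and 2023 of 9338 expressed genes); a shared cold
log2FC ~ N(0, 1) on 15% of genes (the study saw a little over 10% DE per
sex); an extra male-only cold term on 1% of genes (64/9338 interactions);
and the feminization delta (default -0.5 in males, -0.1 in females) added
to sex-biased genes' cold response in the named sex, sign-flipped for
female-biased genes. Labels are drawn in exact configured numbers;
cold-responsiveness and interaction are independent draws, so categories
overlap as they do in real data. Library sizes are log-normal
(mean 2e7, CV 0.2 — conventional bulk RNA-seq values; the study reports
neither depth nor dispersion, and phi = 0.1 is a typical bulk estimate).
All groups share the baseline profile's normalizing constant, making
every configured effect exact on the expected-count scale; groups with
net up-regulation consequently sequence slightly deeper, which is
precisely the composition effect TMM corrects. Genes are independent —
sufficient for every statistic computed here, but it means the generator
does not exercise co-expression, batch artefacts, or length/GC biases,
so passing tests certify the statistics, not robustness to those
real-data features.

`simulate_ctmin` draws ~34 flies per sex x treatment group (the modelled
assay ran 32-37, 137 total) in 6 cyclically assigned batches (batches of
at most 24 flies), CTmin = -3 degC intercept - 1 degC cold-acclimation
effect + weight slope x weight (~2 +/- 0.3 mg) + batch deviate
(sd 0.3 degC) + residual (sd 0.7 degC), with residuals redrawn so every
value exceeds the -5 degC transform boundary. Configurations whose group
means approach -5 are therefore truncated — intentional, since the
transform must be defined, but worth knowing when choosing extreme
effects.

## Numerical choices and degenerate inputs

* IRLS: linear predictor clipped at +/-40 (offset-free), ridge 1e-10 on
  the normal equations, convergence when the deviance change falls below
  1e-8 relative; non-converged genes are flagged, get NaN statistics,
  and are excluded from BH.
* Saturated designs (one replicate per group) are refused outright —
  no silent p-values at zero residual df. All-zero genes reaching the
  GLM are an error (the filter removes them).
* Deviance drops are clipped at 0; a zero drop gives F = 0, p = 1.
* Exact vs approximate switches (Wilcoxon enumeration, signed-rank CI)
  sit at n = 50, configurable.
* Empty bias classes yield NaN with a warning and are excluded from the
  BH family; singleton classes get a point estimate with NaN CI.
* Wherever randomness enters a stage (bootstrap, Monte-Carlo overlap),
  the seed is derived from the single pipeline seed via SeedSequence
  streams, so a whole run is reproducible from one integer.

## Problem sizes used in the validation suite

The test suite and `scripts/acceptance.py` run the chain at 1200-9338
genes, 100 recovery replicates, 500-1000 null replicates and 500
bootstrap draws — sizes chosen so every operating characteristic
(type-I error within binomial error, recovery bias well inside the CI,
bootstrap support saturation) is measured with comfortable resolution
while the whole validation remains a desk-scale computation.
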