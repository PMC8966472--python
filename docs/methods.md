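# Methods

This note records the statistical model, the synthetic-data generator's
assumptions, the numerical choices, and the limitations a user should
know before trusting the outputs.

## The site test and its reduction

Each CpG is tested per pollutant in two contrasts sharing one filtered
universe: curtox vs the six pooled water controls, and switch vs the same
controls. The model is a binomial GLM with logit link and a two-level
group factor on the per-sample (methylated, total) counts; the test is
the likelihood ratio against the intercept-only model with p from χ²₁.
Because the group MLE is the pooled group proportion, the LRT collapses
algebraically to the G-test on the group-pooled 2×2 table, independent of
whether observations enter per sample or pooled. The implementation uses
that closed form (`pooled_lrt`), and the tests verify equality both
against scipy's log-likelihood chi-square and against an explicitly
fitted statsmodels GLM to 1e-8.

The per-site binomial model deliberately ignores replicate
overdispersion; that is the analysis being reproduced, and under
overdispersed (beta-binomial) replicates it is anti-conservative. A
quasibinomial per-site F-test (`method="quasi"` in `run_contrast`) is
available behind a flag but is not the default.

Filter order is coverage (cells with <10 reads become missing) →
missingness (≤2 of 6 controls, ≤1 of 3 curtox, ≤1 of 3 switch) →
extremes (pooled methylation across the pollutant's 12 samples within
[1%, 99%]; the removal rule is strict-< / strict->, so both bounds are
kept inclusively). The order matters because the extremes percentage is
computed over the cells that survive the coverage mask; it is recorded in
every run's filter funnel.

BH correction is applied within one family per (pollutant × contrast).
Classification at q < 0.05 is strict: a q exactly equal to α is not
significant. Delta methylation is the difference of *read-pooled* group
percentages, not the mean of per-sample percentages; the two differ under
unequal coverage, and the pooled reading matches how the effect sizes
the pipeline mirrors were tabulated.

## Characterization choices

- Heaviness is pooled-control methylation strictly >50%. Feature
  odds ratios divide the feature's heavy odds by the whole-genome odds
  (genome including the feature); that convention reproduces the
  published 2.40 (exon) and 2.64 (promoter) worked examples from the
  printed counts. The printed intron odds ratio (1.09) is not
  reproducible from the printed counts under either convention (both
  give ≈1.08); it is stored as printed and excluded from arithmetic
  checks rather than silently corrected.
- The overrepresentation p-value is, by default, a paired t-test across
  the control samples of the per-sample heavy fraction in the feature
  vs the genome; a pooled Fisher-exact alternative sits behind
  `test="fisher"`. The published method names t-tests while tabulating
  odds ratios; the odds-ratio column here is computed independently of
  whichever test is selected.
- Promoter = 2 kb upstream of the first exon, strand-aware, clipped at
  contig edges; downstream = 2 kb past the last exon. Landscape bins are
  20 bp with features truncated at 2 kb, exon/intron ordinals counted in
  transcription direction and pooled at 11+; the optional smoother is
  lowess with span 0.3. Bin width and span are conventions chosen to
  resolve metagene-scale structure, recorded in `RunConfig`.
- Repeatability uses the Gaussian one-way ANOVA intraclass correlation
  on per-sample methylation fractions grouped by site (the estimator
  family behind rptR's default), with unbalanced group-size correction
  and a null that permutes site labels within each sample;
  p = (1 + #{R_perm ≥ R_obs}) / (n_perm + 1).

## Enrichment and gene-level models

Expected DM counts scale the class size by the feature's share of the
tested universe. Fisher tests are two-sided under the minimum-likelihood
convention (the convention of `fisher.test`/scipy), BH-corrected within
each pollutant's 3×3 table of rows. Gene aggregation attributes promoter
and downstream CpGs to the owning gene, so a promoter-only DM CpG can
create a DM gene; intergenic DM CpGs attribute to none.

The effect-direction model is OLS of delta on response type × feature
with one observation per (DM CpG, feature label); persistent CpGs
contribute one observation per treatment (curtox-persistent and
switch-persistent groups). Marginal means average the factor grid with
equal weights over the other factor's estimable levels, with t-based
CIs from the residual variance; empty cells are dropped from the grid
and flagged. The baseline-methylation model is a binomial-family logit
GLM (additive factors) on pooled-control counts with dispersion
estimated as Pearson χ²/df — computed directly with the binomial trial
counts folded in, because statsmodels' built-in X2 scale omits them for
two-column endog — and all Wald covariances scaled by it. Groups with
all-zero or all-one pooled counts are flagged inestimable rather than
reported.

Classical MDS is the Torgerson construction (double-centered squared
Euclidean distances, top-k eigenpairs, coordinates scaled by √λ), run on
DM sites with no missing cells across all samples. Coordinates are
defined only up to rotation/reflection; tests therefore compare
inter-point distances, not raw coordinates.

## The synthetic generator

The generator emulates the study conditions, not any particular dataset:

- **Design**: 6 water controls shared across pollutants; 3 curtox + 3
  switch replicates for each of Cd, Gly, Np (24 samples).
- **Genome**: one 1.5 Mb contig, 120 non-overlapping genes (~5 exons
  each), 20,000 CpGs placed uniformly. Promoters of tightly spaced genes
  legitimately overlap neighbours' exons, so multi-label sites exist by
  construction.
- **Baselines**: two-component Beta mixture — a low mode with mean 1.31%
  and a heavy mode with mean 80% occupied by 0.71% of sites — tuned so
  pooled controls show ≈1.87% global methylation. Heavy-site probability
  is assigned on the odds scale with 2.4-fold exon and 2.64-fold promoter
  enrichment; the off-feature probability is solved so the genome-wide
  expected heavy fraction is hit exactly. Sites in both an exon and a
  promoter take the promoter fold, which slightly inflates the realized
  exon enrichment at dense gene spacing.
- **Effects**: a single logit-scale shift of 2.75, chosen once so the
  mean planted |Δ| is ≈25 percentage points. Persistent sites are drawn
  with weight ∝ baseline (hence preferentially from the heavy mode) and
  shifted down in both treatments; legacy sites with weight ∝ 1−baseline
  and shifted up in switch only; direct sites uniformly with a random
  sign in curtox only. A single shared shift makes decreases larger than
  increases — the asymmetry the studied system shows — rather than
  equalizing the classes.
- **Counts**: negative-binomial coverage (mean 26.5, dispersion 0.15)
  and beta-binomial methylated counts with ρ = 0.01. The replicate
  overdispersion level is a declared assumption (the emulated study does
  not report one), kept mild so the binomial site test remains usable
  while replicate noise is not literally binomial.
- **Determinism**: one seeded `numpy` Generator drives annotation,
  baselines, effect placement and counts in a fixed order; identical
  configs give byte-identical fixtures.

What the generator does *not* emulate: read-level artefacts (FASTQ,
bisulfite conversion error), SNP/allele-specific methylation,
chromosome-scale heterogeneity, and CpG density structure beyond an
optional thinning of CpGs near heavy sites (off by default). Passing
tests therefore demonstrate the pipeline's statistical behaviour under
the declared model, not robustness to alignment or conversion artefacts.

## Calibration checks and their scope

Null calibration runs on a 5,000-site methylome with no planted effects
and pure binomial noise. FDR control (fraction of q < 0.05 sites ≤ 5%)
is checked on the realistic bimodal mixture. The Kolmogorov–Smirnov
uniformity check of raw p-values runs on a broad-baseline null
(Beta mean 0.45) instead: at near-zero methylation the pooled counts are
tiny, the G-test is discrete and conservative, and a KS test against the
uniform would flag exactly that conservatism. Conservatism does not
threaten FDR control, which is why the two checks are split across the
two regimes.

Class-recovery floors (sensitivity/precision per response class) were
fixed by a pre-build calibration run — three seeds × three pollutants at
the study regime (20k CpGs, 300 planted sites/class, 25× coverage) — and
are stored in `tests/data/recovery_thresholds.json`. Persistent
sensitivity is limited by its low-baseline tail (small absolute deltas
at small baselines under a fixed logit shift), and direct precision by
persistent sites whose switch contrast narrowly misses significance.

The repeatability monotonicity check (widening the variable-site band
never raises R) holds when the sites added at the band edges are pure
sampling noise *and* dominate numerically, as near-zero sites do in a
sparsely methylated genome; the test constructs exactly that regime.

Problem sizes throughout (20k CpGs, 5k null sites, 199–499 permutations)
are the package's desk-scale defaults: large enough for the Monte-Carlo
tolerances asserted, small enough to iterate on.

## Known limitations

- The site test inherits the anti-conservatism of ignoring replicate
  overdispersion; the quasibinomial flag exists for sensitivity
  analyses.
- Destranding (merging symmetric CpG pairs) is off by default and the
  emulated analysis is silent on it; both behaviours are supported.
- Multiple transcripts per gene collapse to the first (longest if tied);
  region-level (DMR) calling and covariate adjustment are out of scope.
- Gene-ontology overrepresentation requires external databases; the
  pipeline only exports per-class gene lists suitable for such tools.
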