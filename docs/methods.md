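# Methods

`metadiet` re-implements, as a tested library, a complete analysis chain
linking habitual diet measured by a food frequency questionnaire (FFQ), the
faecal metabolome, and gut-microbiome composition, in a two-cohort
(discovery + replication) twin design. Because real cohort data of this
kind are access-controlled, the package ships a synthetic-data generator
that emulates the statistical structure every downstream stage assumes and
records all planted effects, so that the whole chain can be validated by
recovery experiments rather than by re-deriving cohort-specific findings.

## Synthetic cohorts (`metadiet.synthio`)

Each cohort consists of:

* **Participants** with twin-family structure. Family effects are the
  minimal additive-genetics analogue: monozygotic (MZ) pairs share the full
  family effect, dizygotic (DZ) pairs share half (effect correlation 0.5),
  singletons none. Default composition — roughly 45% of individuals in MZ
  pairs, 29% in DZ pairs — mirrors a large adult twin registry. Covariates
  are age (normal, mean 58, SD 13, truncated 20–95 so the under-80
  cardiovascular eligibility rule has work to do), sex (15% male,
  reflecting the female-dominated registries this design emulates), height,
  weight and BMI.
* **Diet.** Twenty food and beverage groups with right-skewed (log-normal)
  gram intakes whose log-scale latents load, with group-specific signs and
  magnitudes, on one latent plant-vs-animal axis (`latent_scale` rescales
  the loadings; 0 gives independent groups). Group medians and dispersions
  are set to population-plausible values (e.g. vegetables ~200 g/day,
  alcohol median ~8 g/day with the largest dispersion). Each group is split
  over its 6–7 FFQ line items (131 items total) with fixed Dirichlet
  weights, so aggregation recovers the group exactly. A small fraction of
  line items per participant is blanked ("unanswered"), with ~3% of
  participants exceeding the 10-item completeness gate, and ~1.5% of
  participants are planted over- or under-reporters (all reported intakes
  scaled by 3.0 or 0.25) so the energy/BMR plausibility filter has true
  positives to remove. Energy and macronutrient totals are weighted sums of
  the group intakes with multiplicative noise; sodium is included because
  the DASH score consumes it.
* **Metabolites.** On a latent inverse-normal scale, an informative
  metabolite linked to food group *g* is
  `m = beta * x_g + sqrt(1 - beta^2) * (sqrt(icc) * u_family + sqrt(1 - icc) * e)`,
  where `x_g` is the standardized log-intake latent; `beta`
  (`effect_size_beta`) is therefore exactly the standardized slope a
  correctly specified model should recover, and `family_icc` is the
  family share of the residual variance. Observed intensities are
  `exp(m/2)` times a per-(run-day, metabolite) log-normal drift factor
  (8 pseudo run-days assigned round-robin; drift SD 0.3), with
  per-metabolite MCAR missingness drawn from `missing_rate_range`
  (default 0–30%, deliberately straddling the 20% exclusion bound so both
  the imputation and exclusion paths are exercised).
* **Species.** Log-normal log-abundances with planted linear links to
  informative metabolites, a rare tail (for the prevalence filter), then
  closure to relative abundances and Poisson counts at ~50k depth.
* **Mediation trios.** Designated (food group → metabolite → species)
  triples generated from the explicit linear system
  `m = a x + ...`, `y = b m + c' x + ...`, with the true proportion
  mediated `a b / (a b + c')` recorded. Defaults: three trios with
  a = 0.5, b = 0.4, c' = 0.3 (proportion 0.4). Planted mediator
  metabolites are exempt from MCAR missingness: minimum-imputation ties
  would attenuate the planted indirect path and make the planted
  proportion unidentifiable at the precision the recovery experiments
  target. Note the default trios are *real* diet–metabolome–microbiome
  effects: a global-null experiment must pass `mediation_trios=[]`.

What the generator does **not** emulate: compositional count noise beyond
Poisson sampling, batch structure other than multiplicative run-day drift,
nutrient measurement error correlated with misreporting, selective (MNAR)
missingness, and any real metabolite identities or taxonomies. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated model, not robustness to every artefact of real data.

## FFQ preparation (`metadiet.dietprep`)

Fixed order: (1) drop records with more than 10 unanswered line items
(strictly more; remaining blanks count as zero intake); (2) drop records
whose energy-to-BMR ratio is more than 2 SD from the cohort mean, with BMR
from the original (1919-coefficient) Harris–Benedict equations — the ratio
is used directly, with a `log_ratio` switch since the convention is
ambiguous; statistics are computed on completeness survivors only;
(3) aggregate line items into the 20 groups; (4) energy-adjust each group
by the residual method (residual of intake on energy, plus the mean
intake, leaving adjusted values exactly uncorrelated with energy and on an
interpretable scale); (5) where a rank-normal exposure is needed, the
rank-based inverse-normal transform with Blom offset 3/8 and average ranks
for ties.

## Dietary indices and ASCVD risk (`metadiet.dietscore`)

Seven a priori indices, component memberships in JSON config rather than
code: the plant-based diet index family (PDI/hPDI/uPDI; 18 components
quintile-scored 1–5 within cohort, reversed per variant, range 18–90),
DASH (5 encouraged + 3 discouraged components, range 8–40; sodium comes
from the nutrient table), aMED (strict above/below-median points, red and
processed meat reversed, and an alcohol moderate-intake window — 5–15
g/day for women, 10–25 g/day for men, a literature convention, range 0–9),
and the percentage of dietary grams from plant and from meat groups
(computed on unadjusted grams, since residual-adjusted values can be
negative). Quintile ties go to the lower quintile; with many zero intakes
(alcohol) this choice is consequential and is pinned by tests.

Ten-year risk of a first hard atherosclerotic event uses the pooled cohort
equations: sex- and race-specific coefficients on log-transformed terms,
`risk = 1 - S0^exp(L - mean_L)`, eligibility below age 80. The published
coefficient sets ship as JSON config; a test pins the four standard worked
example profiles (55-year-old, TC 213 mg/dL, HDL 50 mg/dL, untreated SBP
120 mmHg → 2.1/3.0/5.4/6.1% by stratum).

## Omics processing (`metadiet.omicsprep`)

Canonical metabolite order: run-day block normalization (each metabolite
divided by its within-day median; exactly removes multiplicative day
drift), then minimum imputation for metabolites with missingness strictly
below 20% and exclusion at or above it (the boundary itself is excluded —
the strict-imputation reading of an ambiguous rule), then per-metabolite
inverse-normal transformation. Microbiome: species kept when present in
strictly more than 10% of samples; centred log-ratio transform with a
pseudocount of half the smallest non-zero relative abundance (zeros only;
config-overridable); Shannon entropy in nats; Bray–Curtis dissimilarity;
and an "ecologically abnormal" flag from DBSCAN (min_pts 5, eps from the
k-distance elbow unless given) on the first two principal coordinates,
with negative eigenvalues dropped. Flags are reported; exclusion is a
pipeline switch (off by default).

## Mixed-model association engine (`metadiet.assoc`, `metadiet._lmm`)

Association models are linear mixed models with a random intercept per
twin family, fitted by REML. Because scans fit thousands of models on the
same family structure, the engine profiles the single variance ratio
`theta = s2_family / s2_residual`: for fixed theta the covariance inverts
block-wise in closed form, and all REML cross-products assemble from
per-family column sums, so one design matrix is scanned against an entire
outcome matrix over a theta grid (61 points, 0 to ICC ≈ 0.98) at once.
Single fits polish theta by bounded scalar search; scans may stay on the
grid (`refine=False`), whose resolution affects standard errors at well
below test tolerance. The engine agrees with `statsmodels` MixedLM to
~1e-5 in tests, and reduces exactly to OLS when every family is a
singleton. Inference on the exposure slope is a Wald z test; at the
sample sizes used the difference from Satterthwaite-style t inference is
negligible.

Multiplicity uses the effective number of tests from the eigenvalue
variance of a correlation matrix, `Meff = 1 + (M-1)(1 - Var(lambda)/M)`
(sample variance, denominator M−1), with the Bonferroni threshold
`alpha / (Meff_exposures * Meff_outcomes)` computed in the discovery
cohort. Per-pair cohort results with consistent effect directions are
pooled by inverse-variance fixed-effects meta-analysis (inconsistent pairs
are retained but flagged and not pooled); Benjamini–Hochberg FDR is
applied where the analysis calls for it (food–species at 0.1,
metabolite–species at 0.01); association-strength comparisons between two
result collections use a two-sided Wilcoxon rank-sum test on −log10 p.

## Prediction stack (`metadiet.predict`)

Twin-aware splitting assigns whole families to the 80% train / 20% test
sides; for classifiers the majority class is first randomly down-sampled
and each side is then trimmed to exactly equal class counts. Quartile
classification uses cohort-wide top/bottom quartiles with stable-sort tie
handling.

Feature selection is Boruta with progressive elimination: each iteration
appends a column-permuted shadow copy of every still-active feature, fits
a forest, and scores a hit when a real feature's impurity importance
exceeds the maximum shadow importance; after every 40 iterations a
Bonferroni-corrected two-sided binomial test against 0.5 rejects (and
removes from subsequent forests) features with significantly few hits and
confirms those with significantly many. Elimination matters: with
hundreds of permanent noise features and their shadows, importance is so
diluted that weak-but-real features cannot beat the shadow maximum.

Tuning is a repeated stratified 5-fold CV grid search (mtry = sqrt and
10–50% of features; minimum node size 5/10/15; split rules gini/entropy
for classification and variance for regression — the exotic rules of some
R ecosystems are not natively available and the split rule is an explicit
grid field), selected by accuracy or RMSE with ties to the earlier grid
cell, then refit on the full training set. Identical resampling seeds are
used across cells so equal cells score identically.

Evaluation reports AUC (classification) or Spearman rho (regression) with
1000-resample paired bootstrap percentile intervals; paired DeLong tests
compare correlated classifiers. The cross-cohort comparison resamples
both evaluation sets 1000 times and takes twice the smaller tail mass of
the AUC-difference distribution at zero as the two-sided p value —
identical sets give exactly p = 1, and a genuine difference pushes the
distribution off zero.

Permutation importance is computed per tree on its out-of-bag samples
(error increase after permuting one column, averaged over 10 permutation
repeats and all trees). Mean-masking recursive feature elimination then
cumulatively fixes features, least important first, at their *training*
means — the model is never refit — recording the metric on the held-out
test set and the validation cohort at every step; the selected subset is
the smallest retained set staying within 0.05 of the unmasked metric on
both sets, with at least one feature retained. Panels are unions of the
minimal subsets with covariates (age, sex, BMI) excluded.

An intrinsic property of mean-mask RFE worth knowing: for a model built on
k exchangeable, individually weak features, the marginal correlation of
each feature and the achievable model R² are tied (R² ≈ k·r²), so
whenever individual features are strong enough for shadow-based selection
to find them, the model operates at an AUC where a fixed 0.05 tolerance
allows a substantial minority (~25–40%) of the features to be masked
before the criterion binds. Minimal subsets should therefore be read as
"sufficient panels", not as exhaustive lists of informative features.

## Community-level analyses (`metadiet.multivar`)

PERMANOVA uses sequential (order-dependent) sums of squares of the
Gower-centred squared-dissimilarity matrix, covariates (age, sex, BMI)
entered before the term of interest; the permutation null shuffles the
term only, covariates fixed, and single-column terms are permuted in a
vectorised batch. p values are `(1 + #exceedances)/(1 + n_perm)`. One twin
per family is randomly removed (seeded) before PERMANOVA. Cohort R² values
pool as the sample-size-weighted average. Pathway overrepresentation is
the exact hypergeometric upper tail with Bonferroni correction.
Association-profile clustering uses the sign-aware Adjusted Coefficient of
Commonality: over the union of categories where either profile is
non-zero, ACC = (same-sign − opposite-sign)/|union|, distance
(1 − ACC)/2; this particular normalisation is isolated behind one function
and pinned by tests as the package's definition. Items significant
nowhere are excluded before clustering. Ward linkage runs on the distance
matrix with the cluster number chosen by maximum silhouette (ties and
degenerate geometries resolve to the smallest k).

## Mediation screen (`metadiet.mediate`)

Trios are triples whose three edges all pass their thresholds
(food–metabolite at the Meff-Bonferroni bound, food–species at FDR < 0.1,
metabolite–species at FDR < 0.01); both causal orderings are emitted.
For each trio, a mediator model `m ~ x + covariates` and an outcome model
`y ~ x + m + covariates`, both with family random intercepts, feed a
quasi-Bayesian summary: 1000 joint draws of (a, b, c') from the normal
sampling distributions give per-draw ACME = a·b, ADE = c', total =
ACME + ADE (additive by construction in every draw), percentile intervals
and sign-crossing p values. The proportion mediated is clipped to [−1, 2]
for reporting near zero totals; the raw value is retained. Only the
continuous–continuous linear case without exposure–mediator interaction
is implemented, and significance indicates statistical compatibility with
mediation, not causality.

## Validation experiment design and problem sizes

The statistical acceptance tests run at deliberately chosen scales:

* **Oracle equivalence** — the eight core statistics against brute-force
  loop/enumeration oracles on 100 random small instances each, at 1e-9.
* **Null calibration** — 50 replicate cohort pairs (n = 400 each, 200
  metabolites, 20 food groups, no planted effects, no trios): familywise
  Meff-Bonferroni rate, null RF AUC per index (judged by the mean across
  replicates — a single null AUC on an 80-sample test set has SD ≈ 0.08,
  so per-draw bounds would be uninformative), and PERMANOVA p uniformity
  over 200 runs at 999 permutations.
* **Effect recovery** — 100 replicate pairs (n = 600 each, slope 0.25,
  ICC 0.3): the exposures are inverse-rank transforms of the *QC-filtered,
  unadjusted* group intakes and metabolite missingness is zero, because
  energy residualisation and minimum imputation deliberately alter the
  data and would attenuate the planted truth by several percent — the
  experiment targets the estimator, not the preprocessing.
* **Panel recovery** — one cohort pair at n = 800 with 20 markers among
  200 metabolites driving a 20-component index. The per-marker slope is
  0.95 and the groups are decoupled (`latent_scale=0`), the operating
  point implied by requiring shadow-based selection to find 18/20
  individually necessary markers (r ≈ 0.21 per marker); marker
  missingness stays below the exclusion bound so the planted panel
  survives processing.
* **Bootstrap comparison** — 100 repeats of equal (0.80/0.80) and forced
  (0.95/0.55) binormal evaluation sets at n = 500.
* **Mediation** — 30 planted trios at n = 474 plus 30 null-path (b = 0)
  replicates.
* **Leakage guard** — 20 label-permutation seeds through the full stack
  (selection, tuning, RFE) at n = 300 with a 40-iteration screen.

## Known limitations

* The LMM assumes a single within-family correlation; DZ pairs truly share
  half the family effect, so the random-intercept model is mildly
  misspecified by design — calibration tests show the impact is nil at
  these scales.
* Quartile labels are computed cohort-wide before splitting; the
  alternative (train-only quartiles) is not implemented.
* PERMANOVA supports free permutation of the term only; restricted
  permutation schemes for structured designs are out of scope, which is
  why twins are de-duplicated first.
* The hypergeometric ORA tests enrichment only; depletion is not tested.
* Mediation offers no sensitivity analysis for sequential ignorability.
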