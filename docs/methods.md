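# Methods

## Unit of analysis

Every statistic in the pipeline lives at the **cancer-type level**. A cohort
of tumor samples per cancer type is reduced to one row of descriptors
(medians of expression, loads, frequencies), and one irAE reporting odds
ratio per type is estimated from adverse-event report counts. With ~19
cancer types passing the report-count filter, all downstream inference is
small-n: rank-based correlation, models of at most 3–4 predictors, and
leave-one-out cross-validation.

## Reporting odds ratio

For a cancer type with `a`/`b` ICI reports with/without an irAE and `c`/`d`
comparator reports, `ROR = (a/b)/(c/d)`. The comparator is the rest of the
reporting database (non-ICI reports), i.e. the convention that avoids
self-comparison when "the entire database" is the reference. Inference uses
the log-normal approximation `se(log ROR) = sqrt(1/a+1/b+1/c+1/d)` with
z = 1.96 for the 95% CI. Any zero cell triggers the Haldane–Anscombe 0.5
correction on all four cells, flagged `corrected` in the output rather than
silently applied. Cancer types with fewer than 1,000 ICI reports are
dropped (boundary inclusive). The regression response is the ROR on its
natural scale by default, with a log-ROR option.

## Splicing descriptors

- **Expression classes** (splicing factors, genes, isoforms): features are
  kept when max TPM > 10 **and** median TPM > 2 (strict); the per-type
  median of *raw* TPM is taken first and then transformed to
  log2(median + 0.001). Filtering and median on the raw scale match the
  thresholds' TPM units; medians commute with the monotone log only
  pointwise, so the order is fixed and documented rather than left to
  chance.
- **AS-event filter**: events detected (non-missing PSI) in strictly more
  than 10 samples are kept, then observations with PSI < 0.05 or > 0.95 are
  masked per observation (not per event), since loads are per-sample counts.
  Events left with no retained observation are dropped. Missing PSI means
  "not quantified in that sample"; it is never imputed as 0.
- **Splicing load**: per-sample count of retained observations — total, per
  mode (AS3, AS5, EX, MEX, RI) and per PSI category. Category boundaries are
  closed on the upper end (psi ≤ 0.20 highly excluded; ≤ 0.40 mid-excluded;
  ≤ 0.80 mid-included; > 0.80 highly included) so the four categories
  partition the retained observations — the conservation invariant
  `total = Σ modes = Σ categories` is asserted in tests.
- **Splicing frequency**: per (cancer type, gene), the fraction of samples
  with ≥1 retained observation in any event of the gene (set union over
  events).
- **Neojunction / autoantigen loads**: per-type medians of per-sample
  counts; neojunction counts are a pipeline input, autoantigen load is the
  splicing load restricted to a gene list.
- Even-length medians use the midpoint convention throughout.

## Correlation screen

Tie-aware Spearman *Rs* (Pearson on average ranks) with the t approximation
`t = Rs·sqrt((n−2)/(1−Rs²))` on n−2 df; an exact permutation p is available
for n ≤ 9. Missing values are deleted pairwise per feature and a feature is
screened only with ≥ 8 complete pairs (about 40% of 19 types — enough to
make a rank correlation meaningful). Constant features are skipped with a
warning instead of being reported as Rs = 0. Selection uses raw p < 0.05;
Benjamini–Hochberg q-values are reported alongside, adjusted within one
family per descriptor class so a handful of load descriptors is not
penalized by thousands of gene features.

## Model building

OLS with intercept via statsmodels; the log-likelihood is Gaussian at the ML
variance σ̂² = RSS/n, so nested models can be compared by
`LRT = 2·Δloglik ~ χ²(Δk)`. Predictive accuracy is LOOCV: each type is
predicted from a fit on the other n−1; the *pooled* vector of n held-out
predictions is correlated with the observations by Spearman (not averaged
per fold, which would be undefined for single-observation folds), and
summarized as unexplained variance 1 − Rs² (an exact identity in the
output). VIF_j = 1/(1−R²_j) from regressing predictor j on the rest with
intercept; VIF > 4 is flagged, perfect collinearity yields `inf` rather
than an exception. The combination search evaluates every 2- and 3-subset
of the candidate list, ranks by LOOCV Rs (ties: fewer variables, then
lexicographic ids — deterministic), and reports BH q-values over the search
family. Designs with ≥ 5 predictors are refused: with n ≈ 19 they are not
estimable in any honest sense.

A property worth knowing: under the null (response unrelated to the
predictors) the LOOCV predicted-vs-observed correlation is *negatively*
biased at small n (≈ −0.2 at n = 12–60 for 2 predictors), because leaving
observation i out moves the fit away from y_i. Model selection on LOOCV Rs
is therefore conservative, never optimistic; the test suite freezes this
measured behavior.

## Enrichment

- **Hypergeometric over-representation**: upper-tail P(X ≥ overlap) with the
  universe = all features that survived screening eligibility.
- **Preranked GSEA**: classic weighted running sum (weight 1): in-set genes
  add |score|^w normalized over the set, others subtract 1/(N−K); ES is the
  maximum-magnitude excursion, NES and p come from seeded gene-label
  permutations (phenotype permutation is impossible with one ranked list).
- **Per-sample set activity**: mean within-sample rank of set genes,
  centered/scaled by the exact mean and SD of a mean of K ranks drawn
  without replacement. This is a deliberately simple rank statistic —
  monotone-transform invariant, approximately standard normal under
  exchangeability — not the GSVA kernel estimator; it preserves the
  high-vs-low group contrast the pipeline tests with the two-sided Wilcoxon
  rank-sum (exact for combined n ≤ 20 without ties).
- High/low ROR groups come from a median split; ties and the odd middle
  element go to "low".

## Synthetic study generator

The generator emulates the study's inputs, not real biology. Defaults are
the study conditions: 19 cancer types × 40 samples, ~1,100 descriptors
after filtering, 5,000 ICI reports per type with a 0.2 base irAE report
rate, true log-ROR ~ N(0, 0.6) (RORs roughly 0.3–3), 10% of features
planted with random sign and `effect_size = 1.0` — one log2-TPM unit (or
one logit of detection probability) per SD of log-ROR, which puts planted
type-level signal well above the within-type median noise at 40
samples/type.

Signal is injected at the cancer-type location (the screen's unit):
expression features shift their per-type log2-TPM mean; frequency-planted
genes get two dedicated events whose detection probability is logit-shifted;
PSI values are Beta(mκ, (1−m)κ) with per-event mean m ~ U(0.15, 0.85) and
concentration κ = 20; reports are binomial with the irAE log-odds shifted by
the true log-ROR against one shared comparator, making the estimated
log-ROR consistent (slope ≈ 1 vs truth). Covariates emulate PD-L1 protein
(negative direction), fPD1 (positive) and TMB (null); neojunction counts
are Poisson with a weak positive link. With `effect_size = 0` every feature
is exchangeable across types, which is how the pipeline's type-I error is
calibrated (selection rate within the 99% binomial band of 0.05 over 50
null cohorts).

What the generator does **not** emulate: correlated gene programs,
mode-specific PSI distributions, batch effects, report-count heterogeneity
between types, or any real FAERS/TCGA structure. Passing tests demonstrate
the statistical machinery is correct and calibrated under the stated model;
they do not validate biological claims on real data.

Randomness: a single integer seed feeds named, independent substreams (one
per generator), so outputs are byte-identical under a fixed seed and adding
draws to one generator never perturbs another.

## Problem sizes and numerical choices

The default synthetic cohort (19 × 40, 300 events, 920 expression features)
keeps a full pipeline run under a second; the calibration and recovery
properties use 50 and 1 replicates respectively, and the acceptance script
completes in well under a minute. Exact permutation p-values are limited to
n ≤ 9 (enumeration of n! permutations); GSEA permutations default to
1,000–10,000 seeded draws. p-values are clipped into (0, 1] before BH
adjustment; Spearman with |Rs| = 1 reports the smallest positive float
rather than 0.

## Known limitations

- Descriptor↔ROR noise in the generator is a modeling choice, not an
  estimate from TCGA/FAERS.
- The t approximation for Spearman p is slightly miscalibrated at n = 19
  (the calibration test bounds the effect); the exact permutation option is
  limited to very small n.
- The LRT is asymptotic; at n ≈ 19 its null p-values are only approximately
  uniform (verified within generous bands in tests).
- The per-sample set score is not GSVA; results for a single sample are a
  rank summary, not a distribution-adjusted enrichment.
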