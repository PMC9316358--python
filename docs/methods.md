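# Methods

This note documents the statistical models implemented in `coralfront`,
the defaults and why they were chosen, what the synthetic-data generators
do and do not emulate, and the numerical decisions a maintainer should
know about. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Study design being modelled

Colonies of two *entities* (chimera / nonchimera), descending from seven
*mother colonies* (A–G), acclimated at 10 m depth, with a subset
translocated to 2 m for 48 h — a 2x2 entity x depth design with a
family batch factor. Four standard contrasts are run, each as a
two-group fit on the relevant sample subset with the mother covariate:
entity within each depth, and depth within each entity. Positive log2
fold change always means higher in the first-named level (chimera over
nonchimera; 2 m over 10 m); every output header repeats this convention.

## Differential expression

Counts are modelled as NB(mu_gj, alpha_g) with
log mu_gj = x_j' beta_g + log s_j.

* **Size factors** are plain median-of-ratios over genes with all-positive
  counts. They are defined relative to the per-gene geometric-mean
  reference, so only factor *ratios* are meaningful; scaling one sample by
  c scales its factor relative to every other sample's by exactly c.
  Note that planted (or real) asymmetric expression shifts are partially
  absorbed as apparent sequencing depth — the usual composition effect of
  ratio normalization — which is why recovered fold changes sit slightly
  below the planted values (about 1.9 for a planted 2.0 in the shipped
  preset).
* **Dispersions** are method-of-moments estimates made design-aware:
  normalized counts are projected onto the design, and the dispersion is
  solved from residual second moments around the *fitted* means
  (`alpha = (RSS_corrected - sum fitted_j / s_j) / sum fitted_j^2`), with
  two corrections — the residual sum of squares is inflated by n/df for
  the variance absorbed by the projection, and the squared-fitted
  denominator is deflated by its leverage bias (bounded at half its naive
  value for stability). Without the design projection, real treatment and
  mother effects masquerade as biological dispersion and destroy power.
  Raw estimates are then averaged with a fitted mean-dispersion trend
  `a1/mu + a0`; the trend weight defaults to 0.7. All-zero genes are
  floored at 1e-8 and flagged.
* **Wald test**: one IRLS pass per contrast, vectorized over genes
  (shared design matrix, batched normal equations), statistic
  `beta_c / se(beta_c)` referred to the standard normal. The
  normal-vs-Student-t choice and the trend weight were fixed by a null
  calibration experiment (uniform p-values by Kolmogorov–Smirnov, type-I
  rate at alpha = 0.05) at the shipped design size of five replicates per
  cell; with weakly shrunk dispersions the normal reference is
  anticonservative and a t with residual df is badly conservative, while
  the shipped combination holds the 5% level to within Monte-Carlo error
  (recomputed on every run of `scripts/acceptance.py`). A `df_reference="t"`
  option remains for users who prefer the conservative reference.
* **FDR** is Benjamini–Hochberg step-up with monotone enforcement,
  NaN-aware (untestable genes are excluded from the adjustment but kept
  as NaN rows so all contrasts share one gene universe).
* **Batch removal** fits, per gene, the retained design plus sum-contrast
  batch columns and subtracts only the fitted batch component (the limma
  `removeBatchEffect` recipe); with pure additive offsets the batch means
  are equalized to the grand mean and retained effects are untouched.
  The log expression used there and for ordination/DAPC is
  `log2(count/s + 1)` — monotone and variance-damping; exact
  regularized-log parity is a non-goal.

This engine is deliberately *not* a DESeq2 port: no Cook's outlier
filtering, no independent filtering, no LFC shrinkage. The downstream
science depends on contrasts and FDR thresholds, not those refinements.

## Frontloading classification

Only genes with `fdr < alpha` (default 0.05) on the non-chimera response
contrast enter. For each entering gene:

* frontloaded flag: basal contrast (chimera vs nonchimera at 10 m)
  significant at alpha *and* log2fc > 0;
* higher-plasticity flag: chimera response significant at alpha *and*
  `|chimera lfc| > |nonchimera lfc|` *and* same sign.

Both flags → FRONTLOADED_AND_HIGHER_PLASTICITY; one → the respective
category; neither (or an opposite-direction response) → UNCLASSIFIED.
Each sub-condition is individually switchable
(`require_basal_significance`, `require_magnitude`,
`require_sign_concordance`) so the rule is auditable.

A consequence worth knowing: for a gene whose true response is *equal* in
both entities, the strict magnitude inequality is satisfied about half
the time under sampling noise, so equal responders split roughly evenly
between HIGHER_PLASTICITY and UNCLASSIFIED. A margin parameter could
suppress this at the price of sensitivity to genuine amplification; the
default keeps the plain rule because the planted-archetype recovery (the
quantity the acceptance run reports) is unaffected.

## DAPC

PCA by SVD of the centered training matrix; the number of retained PCs
defaults to the smallest number explaining 80% of variance, capped at
n_train - 3 (never more than n_train - 2, keeping the within-group
covariance invertible in practice; a pseudo-inverse is used regardless).
The two-group discriminant direction is `pinv(Sw) (m1 - m2)` on PC
scores, scaled to unit pooled within-group variance of the training
coordinates and sign-fixed by making the largest-magnitude gene-space
loading positive (determinism). Projection of new samples uses the stored
center, loadings and discriminant only. At full PC rank this equals
ordinary LDA up to sign and scale (asserted to 1e-8 in the tests).

Plasticity metrics on the discriminant axis, per entity: **shift**
(absolute difference of condition means — transcriptomic plasticity),
**overlap** (symmetric fraction of each condition's coordinates inside
the other's range; a kernel-based alternative was considered and dropped
as needless machinery at n = 5 per cell), and **diversity**
(within-condition pooled variance).

## GO enrichment

Annotation terms are optionally closed under is_a ancestors, then
filtered (fewer than `smallest = 10` members, or more than
`largest = 0.1` of the universe, dropped). Redundant categories merge by
complete-linkage clustering on `1 - |A n B| / min(|A|, |B|)` cut at
`cut_height = 0.5`; overlap-over-smaller-set is the default (Jaccard
available) because it sends *nested* near-duplicates to zero distance,
which is the redundancy that actually occurs in GO; merged unions are
re-checked against the `largest` cap. The filter → cluster → re-filter
order is fixed and tested.

The rank test per category is a two-sided Mann-Whitney U of member vs
non-member genes on the continuous measure, tie-corrected normal
approximation (category sizes after the smallest filter make the exact
distribution unnecessary); the reported effect is the delta-rank (mean
member rank minus mean non-member rank). Being rank-based, results are
invariant under monotone transforms of the measure. The Fisher mode
tests the member x flagged 2x2 table two-sided (scipy's exact routine,
cross-checked against an independent hypergeometric tail summation to
1e-10). `n_strong` (members with |log2fc| > 2) is a display statistic
only and never enters a test. BH runs across the tested categories of
one analysis. Delta-rank comparison pairs categories by member-set
identity (name as fallback) and reports Pearson r over >= 3 shared
categories.

## Chimerism

Microsatellite rule: chimeric iff any locus carries more than two
distinct alleles (duplicates collapsed; one diploid genome explains at
most two). The same ">2" threshold is the default for MNP records —
where an MNP record is one whose REF spans >= 2 bases with all ALT
alleles of equal length — counting the distinct alleles carried by the
sample's genotype field (REF plus called ALTs; site-only files fall back
to all ALTs). The threshold is a required, logged parameter rather than
a constant because reasonable analyses may prefer a stricter ">3" rule.
The per-sample statistic is the fraction of MNP records that are
multiallelic; entities are compared with a Mann-Whitney U test (exact
null distribution by the counting recurrence when n1*n2 <= 400 and no
ties; otherwise tie-corrected normal approximation with continuity
correction; exact mode refuses ties). Two-sided by default, one-sided
"chimera greater" exposed.

## Microbiome

OTUs below 1% of total tags, and singletons, are removed before any
diversity computation (the order matters and is fixed). Chao1 uses the
bias-corrected estimator `S_obs + F1(F1-1) / (2(F2+1))`, defined when
doubletons are absent; Shannon uses the natural log (base-2 by flag).
Bray-Curtis is computed on raw counts and is therefore deliberately
library-size sensitive; no rarefaction is applied by default (optional
seeded subsampling exists). PCoA is classical scaling (double-centering
+ eigendecomposition); negative-eigenvalue axes are dropped with a
logged count, and on Euclidean-embeddable inputs the coordinates
reproduce the distances to 1e-9. Group tests are one-way ANOVAs per
index across the entity x depth groups with BH across the three indices —
a pragmatic reading of a "MANOVA" on three highly correlated indices;
a true multivariate test is out of scope.

## Field statistics

Logger summaries are computed per depth over all records: min/mean/max
temperature, CV as sample sd over mean on raw Celsius (configurable to
Kelvin — a ratio on an interval scale is unit-dependent and the
convention must be stated), mean light, and the maximum light among
records whose local clock time falls in the inclusive 10:00–16:00
diurnal window. Survival comparisons are per-timepoint independent 2x2
chi-square tests (Yates correction off by default, flag exposed) with
Clopper–Pearson exact intervals from Beta quantiles; no longitudinal
survival model is fitted.

## Synthetic data

The generators define the study conditions for all recovery and
calibration runs:

* **Counts**: NB via a gamma–Poisson mixture; per-gene baselines
  N(5, 1.5^2) on the natural-log scale (median mean ~150 counts),
  common dispersion 0.1, mother effects N(0, 0.5^2) drawn independently
  per (gene, mother). Planted archetypes (log2 units, converted
  internally; response sign random per gene): frontloaded genes get a +2
  basal shift in chimeras at both depths and no chimera response;
  higher-plasticity genes respond 2 in non-chimeras and 2*(1+1) in
  chimeras; both-category genes combine the two; responsive-only genes
  respond 2 in both entities; null genes carry nothing. The `paper-like`
  preset plants 60/60/60/200 of these in 2000 genes with five replicates
  per cell; `frontload-dominant` (300 frontloaded, 100 responsive-only)
  creates the regime where chimeras respond less overall, used for the
  DAPC comparisons; `null` plants nothing. Mother labels rotate
  identically within every cell so the covariate is balanced within
  every pairwise contrast (with five replicates per cell, five of the
  seven labels are in use).
* **Variant tables**: every sample gets one MNP record per locus;
  records are multiallelic (3–4 distinct alleles at ploidy 4, the
  two-genomes calling convention) with probability 0.1 in non-chimeras
  plus a configurable excess (default 0.3) in chimeras. The default
  cohort is 11 validated chimeras vs 9 others — the per-group sizes for
  this comparison are not published, so this is a documented choice, not
  a reproduction target.
* **Logger**: temperature `mean + amplitude*sin(2pi(h-8)/24)` plus
  Gaussian noise; light a truncated sinusoid, zero outside 06:00–18:00,
  scaled by the peak. The shipped depth profiles reproduce the published
  temperature ranges and window maxima of the two platforms; because the
  waveforms are identical up to scale, the mean-light ratio between
  depths equals the peak ratio exactly — unlike the real record, where
  weather makes the waveforms differ, so mean-light values are not
  comparable to the field numbers.
* **OTU tables**: Dirichlet-multinomial (total concentration 200,
  library 20k) around random or supplied base proportions; a group
  effect perturbs chimera proportions by `exp(+-effect)` on alternating
  OTUs. **Survival**: chained binomials per census, monotone by
  construction.

What passing the synthetic recovery tests shows — and does not: the
pipeline recovers planted structure under NB noise, batch effects and
the design's sample sizes; it does not establish robustness to real-data
features the generators omit (gene–gene correlation, dispersion
heterogeneity beyond the trend, GC/length biases, mapping artifacts,
phylogenetic OTU structure, logger sensor drift).

## Problem sizes and determinism

Every stochastic test and the acceptance script derive all randomness
from explicit integer seeds; identical inputs reproduce byte-identical
outputs. The acceptance script runs 3 recovery cohorts, 20+20
calibration replicates, 300 enrichment universes, 40 DAPC simulations
and 100 variant cohorts — sizes chosen so the whole recomputation stays
in the tens of seconds on one CPU while keeping Monte-Carlo error well
below the decision margins; the test suite uses 50+50 calibration
replicates and 100-replicate power checks at the same design sizes.

## Known limitations

* The DE engine's finite-sample calibration was tuned at the shipped
  design size (n = 5 per cell, ~2000 genes); very small gene universes
  weaken the dispersion trend and the calibration claim.
* `classify_frontloading` treats the three DE tables as independent
  inputs; genes missing from the basal/chimera tables raise rather than
  being imputed.
* The VCF writer emits minimal single-sample v4.2 files (GT only);
  reading arbitrary caller output relies on pysam and uses the genotype
  field when present.
* PCoA returns only positive-eigenvalue axes; no Cailliez/Lingoes
  correction is applied for strongly non-Euclidean dissimilarities.
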