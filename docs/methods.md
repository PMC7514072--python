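# Methods

## The analysis in brief

The pipeline quantifies how much of effector-triggered transcriptional
reprogramming in Arabidopsis depends on the two helper-NLR (RNL)
families, ADR1s and NRG1s. Its molecular input is a gene × sample
count matrix from a factorial design: four genotypes (Col-0 wild type,
the *adr1 triple* mutant, the *nrg1.1 nrg1.2* double mutant, and the
*helperless* pentuple mutant lacking both families), four treatments
(*Pf0-1* with an empty vector, or delivering AvrRps4, AvrRpt2 or
AvrRpm1), and four timepoints (0, 0.5, 4, 8 hpi). Replication is
organised as samples within independent experiments; the default
design uses 2 samples × 3 experiments = 6 replicates per condition,
312 samples in total.

Two contrast families drive everything. *PTI induction* is the
empty-vector treatment against the pre-treatment baseline within a
genotype (bacterial perception without effector delivery).
*ETI regulation* is an effector treatment against the empty-vector
control at the matched timepoint within a genotype, defined at 4 and
8 hpi only — NLR-driven expression changes are not yet visible at
0.5 hpi. "ETI-regulated" genes are the wild-type DEGs of that second
contrast; each is then classified by whether it remains differentially
expressed in each mutant (same contrast, same thresholds, same
direction): DE in *helperless* ⇒ RNL-independent; otherwise lost in
both single-family mutants ⇒ synergistic, kept in both ⇒ redundant,
kept only in one ⇒ specific to the other family. Up- and
down-regulated genes are classified separately and never merged.

Two readings of "ETI-regulated" are defensible — the direct
effector-vs-EV contrast, or the set difference of two vs-time-0 DEG
lists. The direct contrast is implemented as the default
(`Denominator.EV_SAME_TIME`) because it tests the quantity of interest
in one model rather than differencing two thresholded lists; the
vs-time-0 contrast remains available through `ContrastSpec`.

"Not DE in a mutant" means absence from that mutant's DEG set at the
same thresholds; no equivalence test is performed, so genes near the
threshold can flip category with sampling noise (visible in the
synthetic benchmark as the residual misclassification at weakened
effect sizes). A gene DE in a mutant with the opposite sign to the
wild type is counted as not DE for that direction and logged.

## Differential expression model

Counts are modelled as NB(μ = s_j·q_g, variance μ + α_g μ²).

- **Size factors** s_j: median-of-ratios over reference genes with
  nonzero counts in every sample; an optional pseudo-reference
  (genes nonzero in ≥ half the samples, geometric mean over nonzero
  entries) covers sparse matrices. Size factors are meaningful up to a
  common scale; only their ratios are identifiable.
- **Dispersion** α_g: method-of-moments (s² − μ̄)/μ̄², pooled across
  all within-condition replicate groups weighted by degrees of
  freedom, clipped at 0, then shrunk toward a fitted mean–dispersion
  trend α(μ) = a₀ + a₁/μ by a configurable weight (default 0.5).
  The trend is an ordinary least-squares fit over genes with μ̄ > 1
  and positive raw estimates. With 6-vs-6 designs the raw per-gene
  estimate is noisy; the trend carries most of the information, which
  is why the default weight is even.
- **Testing**: per-group NB mean q̂ by Newton iteration on β = log q
  (score Σ(K−μ)/(1+αμ), expected information Σ μ/(1+αμ), size factors
  as offsets), log2 fold change log2((q̂_num+0.5)/(q̂_den+0.5)) — the
  +0.5 normalized-count moderation keeps ratios finite at zero counts
  and is propagated into the delta-method standard error — and a
  two-sided Wald test against the normal reference. Wald is known to
  be conservative relative to the likelihood ratio at large effects;
  for DEG calling at |log2FC| > 1 this is immaterial.
- **Independent filtering**: genes with mean normalized count below
  `min_count_filter` (default 5) across the two contrasted groups are
  excluded from testing and from the BH family.
- **DEG thresholds**: BH-adjusted p < 0.05 and fold change > 2, both
  strict inequalities, applied to the moderated estimate (no posterior
  shrinkage).
- **Batch handling**: experiments are blocks of the simulation, not
  covariates of the test; contrasts compare matched condition groups
  that span the same experiments, so a multiplicative per-experiment
  factor cancels through the size factors. A batch-covariate GLM is
  deliberately out of scope.

The z-score view applies t = log2(count/s_j + 1) and standardizes each
gene across samples (constant genes map to zero rows); PCA QC runs on
the 2,000 highest-dynamic-range rows of that matrix.

## Fraction accounting

Category fractions are reported per effector × timepoint × direction:
the RNL-dependent fraction is over the ETI set; synergistic,
redundant, shared (= syn + red) and specific (= ADR1- + NRG1-specific)
fractions are over the RNL-dependent count; the two family-specific
fractions are over the specific count. Percentages are rounded
half-up to one decimal, matching the precision convention of published
tables of this kind; an empty base yields an undefined (None/dash)
percentage, never 0.0. Counts always satisfy
syn + red + adr1 + nrg1 = n_dependent and
n_dependent + n_independent = n_ETI, enforced at construction.

## Synthetic data generator

The generator emulates the study design, not any particular dataset.
Each gene is background (75%), PTI-induced (10%) or ETI (15%); the
five-way category mix among ETI genes echoes the observed AvrRps4
8-hpi split (3.1% RNL-independent; 35.3% synergistic, 22.8% redundant,
28.1% ADR1-specific, 10.7% NRG1-specific). Effects:

- PTI genes respond to every bacterial treatment (including the empty
  vector) in all four genotypes from 0.5 hpi, with a log2 effect drawn
  uniformly from [2, 4] and a small extra boost (default 0.5 log2,
  below the fold-change threshold) under effector delivery, emulating
  the over-induction of PTI genes during ETI without converting them
  into nominal ETI calls.
- ETI genes respond to the effectors in their scope (1–3 effectors,
  biased toward one) from their onset (4 hpi with probability 0.6,
  else 8 hpi), in exactly the genotype set implied by their category.
  That genotype map (`CATEGORY_GENOTYPES`) is the single shared
  definition the classifier inverts; a test enforces the consistency.
- Counts are gamma-Poisson (NB with variance μ + αμ²) with dispersion
  α(μ) = 0.05 + 1/μ, per-sample library factors uniform in [0.7, 1.3],
  and a per-experiment log-normal batch factor (sd 0.1). Signal genes
  draw baselines log-uniformly from [50, 500]; background baselines
  are log-normal (ln-mean 3.5, ln-sd 1.2), so the low-count filter is
  exercised.
- 80% of planted effects are up-regulation; direction is part of the
  truth record and of the benchmark.

Defaults are test-scale (2,000 genes); the full-scale design
(27,206 protein-coding genes, ~5M reads/sample) is reachable through
`SimParams(n_genes=...)` and larger baselines. The generator does not
emulate: gene–gene correlation, count outliers, partial effects
(a gene weakly retained in a mutant below threshold), per-gene batch
interactions, or annotation structure. Passing the recovery benchmark
therefore shows the pipeline's logic and statistics are sound under
the stated noise model — not that real data of this design would
classify with the same accuracy, since real effect sizes straddle the
threshold far more than the planted [2, 4]-log2 effects do.

## Benchmarks the package computes about itself

- **Null calibration**: on a 5,000-gene null (6 vs 6, dispersion
  0.05), the raw Wald rejection rate at p < 0.05 is ≈ 0.054–0.059 and
  the BH-corrected DEG set at the study thresholds is empty — slight
  anticonservatism from plug-in dispersions, well inside the FDR
  control margin.
- **Planted-truth recovery**: on the default fixture the pipeline
  recovers 100% of eligible planted ETI genes and assigns every
  recovered gene its planted five-way category; halving effect sizes
  (to [1, 2] log2, straddling the fold-change threshold) lowers recall
  and never improves recovery, the expected monotone degradation.

## Enrichment and phenotype statistics

Over-representation uses the upper-tail hypergeometric probability
P(X ≥ k) per term (equivalently one-sided Fisher), BH across all terms
within the size filter (default 3–500 genes), ranked by adjusted p
with ties broken by fold enrichment then term id; the top 25 terms per
set is the default report. The annotation is taken as already
propagated up the ontology; no GO graph handling is performed. The
universe defaults to all genes in the counts table and is
configurable.

Phenotypes: the disease index is DI = Σ i·nᵢ over symptom categories
1–6 with nᵢ the *percentage* of leaves in category i (range 100–600);
a fraction-based 1–6 scale is available behind `scale="fraction"`.
Sporangiophore counts bin into {0}, [1,5], [6,10], [11,15], (15, ∞)
with inclusive integer bounds. cfu/cm² requires the plating constants
(dilution, plated and extract volumes, disc area) as explicit inputs.
Total ROS is the trapezoidal integral of the luminescence time
course. Group comparisons use one-way ANOVA plus Tukey's HSD
(equal-variance studentized-range test, via statsmodels) summarized as
a compact letter display built by the sweep-and-absorb construction;
two-way ANOVA is out of scope.

## Numerical choices and degenerate inputs

- Newton iterations on log-mean are step-clipped at ±5 and converge in
  < 25 iterations for all tested inputs; all-zero groups land on the
  moderated fold change toward 0 with a vanishing statistic.
- Percentages use decimal ROUND_HALF_UP; Python's round() (banker's
  rounding) would print 63.5 where 63.6 is correct.
- Empty DEG sets, empty queries and zero-count categories are valid
  results, not errors; empty universes, zero leaves, single-replicate
  designs and malformed files raise typed `ValidationError`s.
- Determinism: every stochastic stage consumes a `numpy` Generator
  seeded from the run seed; fixtures regenerate byte-identically.

## Known limitations

- Dispersion shrinkage is a fixed-weight blend, not an empirical-Bayes
  posterior; at very small replicate numbers the Wald test runs a few
  tenths of a percent anticonservative.
- The classifier's set-membership logic inherits threshold effects:
  a gene at 1.9-fold in a mutant is "lost" there. The package reports
  normalized-expression matrices so users can inspect such genes, but
  no quantitative partial-dependence analysis is implemented.
- No multi-factor GLM: time courses and genotype × treatment
  interactions are handled by matched two-condition contrasts only.
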