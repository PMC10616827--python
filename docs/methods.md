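# Methods

## The collapsing model

For gene *g*, model *m* and analyzed sample *i*, the carrier indicator is

    s_i(g, m) = 1  iff sample i carries >= 1 qualifying variant of m in g
                      (dominant models), or
                iff sample i carries >= 2 distinct heterozygous qualifying
                      variants or one homozygous qualifying variant in g
                      (compound-het model, unphased approximation),

and the per-gene statistic is the two-tailed Fisher's exact test on the
2×2 table of carrier counts in cases vs controls.  Two-sided p-values use
the minimum-likelihood definition — the sum of hypergeometric probabilities
of all same-margin tables no more probable than the observed one — which is
what reproduces the published values; the doubling definition does not.
The effect estimate is the unadjusted cross-product odds ratio; zero-cell
tables return infinity (carriers only in cases) or undefined (no carriers),
and a Haldane–Anscombe-corrected OR is available for display only.  Genes
with no carriers anywhere are reported with p = 1 rather than dropped, so
the output schema is stable.

A variant qualifies for sample *i* under model *m* when all of the
following hold:

1. functional class: synonymous models accept only synonymous variants;
   PTV models only protein-truncating ones; "all functional" accepts
   missense, inframe indel and PTV, with the PolyPhen and REVEL gates
   applied **to missense only** (truncating and inframe variants pass the
   deleteriousness gates outright).  A missense lacking a required score
   fails silently rather than erroring.
2. external frequency: max(gnomAD AF, ExAC AF) <= the model ceiling; a
   ceiling of 0 means "absent from both databases"; a missing external
   frequency counts as 0 (absent).
3. internal frequency: the leave-one-out allele frequency
   (AC − dose_i)/(AN − 2) <= the model ceiling.  AC/AN are computed on the
   analyzed (post-pruning) samples, with missing genotypes excluded from
   AN.  The leave-one-out construction matters: a genuine singleton
   carrier sees frequency 0 while a non-carrier at the same site sees
   AC/(AN−2), so borderline sites filter asymmetrically by design.  With
   fewer than two genotyped samples the leave-one-out cohort is empty and
   the filter is vacuous.

Carrier status is anti-monotone in filter stringency (tightening any
ceiling or adding a gate can only switch carriers to non-carriers); the
test suite checks this property directly, plus exact equivalence of the
vectorized carrier-matrix computation against a per-sample brute-force
re-derivation for every built-in model.

Nine built-in models form the grid: a synonymous negative control and an
ultra-rare model (LOO <= 5e-4, externally absent), two "rare damaging"
models (LOO <= 5e-4, external <= 5e-5, REVEL- or PolyPhen-gated), three
flexible models (LOO and external <= 1e-3; REVEL-, PolyPhen-, or ungated),
a PTV model (<= 1e-3) and a compound-het recessive model (<= 1e-2).
The REVEL gate is strict (> 0.5).  The X chromosome is out of scope: the
simulator emits autosomes only, and all analyses treat every site as
diploid autosomal.

## Relatedness pruning

Multiplex families contribute two affected siblings each; only one case
per family enters the test.  The proband flag (the member ascertained via
treatment-program participation) is preferred; ties and flag-free families
fall back to lexicographically smallest sample id, making the pruning
deterministic and idempotent.  Controls are treated as unrelated.

## Coverage harmonization and neutral-variation QC

A site is tested only when |fraction of cases at >=10× − fraction of
controls at >=10×| < 0.10; the comparison is made on decimal-rounded
differences so that a nominal 10-point gap (e.g. 1.00 vs 0.90) is excluded
regardless of binary float representation.  Retained-footprint accounting
uses 1 bp per SNV and max(len(ref), 1) bp per indel.  A cohort-level check
fails when either group's mean per-site fraction falls below 0.95.

The neutral-variation certificate tallies rare (LOO <= 5e-4) synonymous
variants per sample and compares cases to controls with a two-sided
Wilcoxon rank-sum test; synonymous variation is presumed neutral, so a
significant difference flags technical imbalance.  The choice of rank-sum
(robust to count skew) is a package decision — the comparison is
documented as configurable rather than canonical.

## Permutation QQ expectation and inflation lambda

Because per-gene carrier totals are fixed under case/control label
permutation, each permutation's exact p-values are computed from cached
lookup tables keyed on (n_case, n_control, total carriers), making
thousands of permuted scans cheap.  The QQ expected curve is the
permutation mean of each p-value order statistic.

Lambda needs care with discrete exact tests: sparse carrier tables put a
large atom at p = 1 (χ²(1) quantile exactly 0), and the *mean* order
statistic smooths that atom away while any single observed vector keeps
it, so a median ratio against the mean curve is structurally biased.
Lambda is therefore computed as the ratio of median χ²(1) quantiles of the
observed p-values against the permutation **median** order statistics,
restricted to informative ranks (those whose median order statistic is
below 1); identical vectors give exactly 1, and an entirely uninformative
scan reports 1 (the diagnostic is vacuous, not inflated).  On null
synthetic cohorts of 500 genes this estimator centres on 1.0 with discrete
jitter of roughly ±0.2 per cohort; the ensemble median across cohorts is
the stable diagnostic, which is what the test suite asserts.  Spiking
strong risk genes drives lambda well above 1 and removing the top hits
restores it — the intended use of the diagnostic.

## Ancestry stratification

Features are common-variant dosages (combined AF >= 0.05; rare variants
carry almost no per-site ancestry information), mean-imputed, standardized
and reduced to 10 principal components; a UMAP embedding (2 components,
15 neighbours, min_dist 0.1, fixed random state, hence single-threaded and
deterministic) is clustered with DBSCAN (eps 0.5, min_samples 5), noise
points are attached to the nearest cluster centroid, and labels are
relabelled contiguously by decreasing size.  All parameters are surfaced
because a published cluster count is data-dependent and not reproducible
without the original genotypes.  The within-cluster rerun repeats the
*entire* pipeline on the cluster members — including recomputing AC/AN and
hence leave-one-out frequencies on the restricted cohort — so a variant
common elsewhere cannot disqualify a cluster-private carrier.
Self-reported ancestry labels are reporting-only.

## Multiplicity

Bonferroni thresholds are alpha/n_genes per model and
alpha/(n_genes × n_models) across the grid; the across-model correction
uses all nine models.  The pipeline defaults n_genes to the number of
genes actually tested in the run.

## The synthetic-cohort generator

The generator emulates the statistical structure the analysis assumes; it
is the package's study-condition bench, not a population-genetics
simulator.

- **Families.** Each case family has two affected siblings, one flagged as
  proband.  Two parental genotypes are drawn per family and each sibling
  receives one allele per parent per variant independently, so siblings
  share each parental haplotype with probability 1/2 marginally; no
  recombination model, since only relatedness pruning consumes the
  structure downstream.
- **Site frequency spectrum.** A fraction of variants (default 0.5) are
  exact internal singletons (one allele copy placed uniformly); the rest
  draw an ancestral frequency from Beta(0.5, 200) truncated to (0, 0.5],
  putting most tail mass in the 1e-4..1e-2 band around the models'
  frequency ceilings so that filters have variants just inside and outside
  each threshold.
- **Sites per gene.** Poisson with mean 20 (minimum 1).  At the cohort
  sizes used for scan-level checks (~2,000 samples) real exome cohorts
  segregate tens of coding sites per gene, and with ultra-rare filters
  this density leaves a typical gene with a handful of qualifying carriers
  — the regime the published carrier tables (2–14 carriers per top gene at
  n ≈ 9,000) sit in.  Much sparser simulated genes would leave most genes
  with zero carriers and make the QQ/lambda diagnostics vacuous.
- **Effect classes.** {synonymous 0.30, missense 0.50, inframe indel 0.05,
  PTV 0.15}; 40% of missense are "probably damaging"; REVEL ~ Beta(1.5, 4)
  for missense (low-skewed, as real REVEL scores are).  These mixes are
  chosen so every model's gates see both passing and failing variants, not
  to match a mutational spectrum.
- **External frequencies.** Singletons are absent from both reference
  databases with probability 0.8 (else present at < 2e-5); tail variants
  carry the ancestral frequency under log-normal noise (sigma 0.5) with a
  20% chance of absence per database.
- **Population structure.** Samples are assigned round-robin to
  populations; per-population frequencies follow the Balding–Nichols model
  Beta(p(1−F)/F, (1−p)(1−F)/F) with F the divergence parameter; F = 0
  reduces to identical frequencies.
- **Coverage.** Per-site group fractions ~ Uniform(0.95, 1); a configurable
  fraction of sites (default 5%) gets the control fraction displaced by
  0.15, so the 10-point pruning rule has work to do.
- **Spiking.** `spike_risk_gene` clears the target gene's background
  genotypes and gives each chosen carrier a private singleton qualifying
  variant (two under the recessive model), so the gene's collapsing table
  equals the requested counts exactly under every dominant model; case
  carriers are drawn from probands so counts survive family pruning.
  Carrier choice derives from the cohort seed and the gene name, and a
  0/0 spike is a no-op that leaves background untouched.
- **Determinism.** One `numpy` Generator seeded from the config drives all
  draws in fixed order; identical config + seed give a bit-identical
  cohort and VCF byte stream.

What the generator does **not** emulate: linkage disequilibrium, realistic
per-gene mutation-rate variation, sequencing error, genotype-calling
artifacts correlated with depth, X-linked inheritance, or pedigrees beyond
sib-pairs.  Passing tests therefore demonstrate correctness of the
*computations* under the assumed statistical structure — not robustness to
real-data pathologies such as batch-correlated missingness.

## Problem sizes used in the checks

Scan-level distributional checks run 200 null cohorts of 500 genes with
50 cases / 2,000 controls and 100 permutations each, spiked-recovery runs
20 seeds at the same scale, and ancestry recovery uses 3 populations of
100 samples each at divergence 0.15 — sizes chosen so the whole suite
exercises every pipeline stage at meaningful power while remaining a
routine desk run.  The published-statistic reproductions run at the full
study sizes (53 vs 8,983 and 52 vs 2,814) since exact tests there are
cheap.

## Numerical choices and degenerate inputs

- Hypergeometric pmf comparisons in the two-sided test use a 1e-7 relative
  slack (the convention scipy shares); the test-suite oracle recomputes
  p-values in exact rational arithmetic.
- Coverage-difference comparisons round to 9 decimals before the strict
  threshold comparison (decimal semantics).
- `recover_counts_from_or` matches printed odds ratios to within half a
  unit of the last printed digit, covering both tie-rounding conventions
  (44.855 printing as 44.86).
- Partially missing diploid genotypes (e.g. ./1) read as missing; missing
  doses count as reference in carrier states and are excluded from AN.
- Feighner onset ties share the order-statistic value; a record with
  fewer than three endorsed categories returns an explicit non-diagnosis
  with undefined ages rather than NaNs.
- Empty gene lists, empty coverage tables, infeasible spike counts and
  clusters without cases raise immediately rather than returning empty
  results.

## Known limitations

- The compound-het model is the standard unphased approximation (two hets
  assumed in trans); with phase data it would overcall carriers.
- Lambda is an ensemble diagnostic here; single sparse scans give discrete
  jitter and should be read with the QQ curve, not alone.
- The per-gene exact test is conservative under discreteness; reported
  type-I error on null cohorts sits well below nominal (~0.02 at
  alpha = 0.05 in the suite's null ensemble), which is inherent to Fisher
  tests on sparse tables, not a bug.
- UMAP determinism is tied to a fixed random state and single-threaded
  execution; embeddings differ across library versions even at the same
  seed, so cluster *labels* are reproducible within an environment, not
  across environments.
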