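# genecollapse

Gene-based rare-variant collapsing analysis for case/control exome cohorts.

## The problem

Rare-variant association studies of small, deeply ascertained case cohorts
(here: probands from multiplex alcohol-use-disorder families compared against
thousands of reference-sequenced controls) cannot test individual variants —
almost every interesting variant is seen once or twice.  The collapsing
framework instead tests genes: each sample is reduced, per gene, to a binary
indicator

> state 1 — the sample carries at least one *qualifying* variant in the gene;
> state 0 — it carries none,

and the per-gene 2×2 carrier table (cases × carrier status) is tested with a
two-tailed Fisher's exact test.  The effect estimate is the unadjusted
cross-product odds ratio `OR = (a·d)/(b·c)`.

What counts as *qualifying* is a model: an inheritance mode (dominant or
unphased compound-het), a functional class (synonymous / all functional /
protein-truncating), an optional missense deleteriousness gate (PolyPhen-2
"probably damaging" or REVEL > 0.5), an internal **leave-one-out allele
frequency** ceiling `(AC − dose)/(AN − 2)` computed on the combined
case+control cohort excluding the evaluated sample, and an external
(gnomAD + ExAC) frequency ceiling.  Nine built-in models span ultra-rare
(LOO ≤ 5×10⁻⁴, absent externally) through flexible rare (≤ 10⁻³) to a
recessive model (≤ 10⁻²), plus a synonymous negative control
(`genecollapse models` prints the grid).

Around that core the package implements the full pipeline such a study
needs:

- **one-case-per-family pruning** of multiplex families (deterministic
  proband-preferring choice), so the test sees unrelated samples;
- **coverage harmonization**: sites where the fractions of cases and
  controls with ≥10× depth differ by ≥10 percentage points are pruned, and a
  per-sample rare-synonymous tally (Wilcoxon rank-sum, case vs control)
  certifies that residual technical imbalance is absent;
- **permutation QQ / lambda diagnostics**: expected p-value order statistics
  from case/control label permutations, and a median-χ²(1)-quantile
  inflation factor λ;
- **ancestry stratification**: common-variant PCA → UMAP → density
  clustering, with the whole scan rerun inside a cluster (leave-one-out
  frequencies recomputed on the restricted cohort);
- **gene-set testing** of candidate panels across all models;
- **phenotype scoring**: Feighner alcohol-dependence criteria (≥3 of 4
  problem categories; onset age = third order statistic of category onset
  ages) and DSM-V severity (2–3 mild, 4–5 moderate, ≥6 severe);
- a **synthetic-cohort simulator** (sib-pair families, singleton-heavy site
  frequency spectrum, Balding–Nichols population divergence, coverage
  imbalance, exact carrier-count spiking) so every stage is testable without
  access-controlled genotype data.

## Worked example

Spike a risk gene with 3 carriers among 53 analyzed cases and 1 among 2,000
controls, then scan under the ultra-rare model:

```python
from genecollapse import (SimConfig, SpikeSpec, generate_cohort, spike_risk_gene,
                          run_collapsing, permutation_expected)
from genecollapse.qualifying_models import get_model

cfg = SimConfig(n_case_families=53, n_control=2000, n_genes=100, seed=7)
cohort = spike_risk_gene(generate_cohort(cfg),
                         SpikeSpec("GENE0042", 3, 1, model_targeted="ultra_rare"))
scan = run_collapsing(cohort.variants, cohort.genotypes, cohort.coverage,
                      cohort.manifest, models=[get_model("ultra_rare")])
print(scan.results.sort_values("p_value").head(3)
      [["gene", "case_carriers", "control_carriers", "odds_ratio", "p_value"]]
      .to_string(index=False))
genes, states = scan.carrier_matrices["ultra_rare"]
qq = permutation_expected(states, scan.case_mask, n_permutations=1000, seed=1)
print(f"inflation lambda = {qq.lam:.3f}")
```

prints

```
    gene  case_carriers  control_carriers  odds_ratio  p_value
GENE0042              3                 1  119.940000 0.000064
GENE0036              1                 0         inf 0.025816
GENE0004              1                 1   38.442308 0.050978
inflation lambda = 1.206
```

The spiked gene tops the scan with OR = (3·1999)/(50·1) = 119.94 and an
exact p of 6.4×10⁻⁵; background genes carry only sampling noise.  The
106 sib-pair cases were pruned to 53 unrelated probands before testing, and
the λ near 1 says the rest of the scan is not systematically inflated.

The same pipeline is scriptable from the shell:

```bash
genecollapse simulate --out cohort/ --cases 53 --controls 2000 --seed 7
genecollapse qc  --vcf cohort/cohort.vcf --annotations cohort/annotations.tsv \
                 --coverage cohort/coverage.tsv --manifest cohort/manifest.tsv \
                 --out qc.tsv
genecollapse run --vcf cohort/cohort.vcf --annotations cohort/annotations.tsv \
                 --coverage cohort/coverage.tsv --manifest cohort/manifest.tsv \
                 --model ultra_rare --permutations 1000 --seed 1 --out results.tsv
```

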