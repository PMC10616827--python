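"""Synthetic case/control exome cohorts for exercising the collapsing pipeline.

The generator emulates the statistical structure the analysis assumes:
multiplex case families contributing two affected siblings each (so the
one-case-per-family pruning has something to prune), a large pool of
unrelated controls, an ultra-rare-heavy site frequency spectrum (a point
mass of singletons plus a Beta low-frequency tail), the four functional
effect classes with PolyPhen/REVEL annotations, discrete ancestry strata
with Balding-Nichols allele-frequency divergence, and a configurable subset
of sites with case/control coverage imbalance.  Risk genes are introduced
by spiking exact carrier counts, which makes published 2x2 tables
reconstructible by running the pipeline rather than by assertion.

Identical seed and configuration give a bit-identical cohort, including the
written VCF byte stream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from genecollapse.cohort_io import (
    GenotypeMatrix,
    read_annotations,
    read_coverage,
    read_manifest,
    read_vcf,
)

#: controls share a sentinel family id — they are treated as unrelated
CONTROL_FAMILY = "CTRL"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class AFSpectrum:
    """Allele-frequency spectrum: singleton point mass + Beta tail.

    ``singleton_fraction`` of variants are internal singletons (one allele
    copy in the whole cohort); the rest draw a population frequency from
    Beta(tail_beta_a, tail_beta_b) truncated to (0, 0.5].  The defaults put
    most tail mass in the 1e-4..1e-2 band, around the frequency ceilings the
    qualifying models use.
    """

    singleton_fraction: float = 0.5
    tail_beta_a: float = 0.5
    tail_beta_b: float = 200.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.singleton_fraction <= 1.0:
            raise ValueError("singleton_fraction must lie in [0, 1]")
        if self.tail_beta_a <= 0 or self.tail_beta_b <= 0:
            raise ValueError("Beta tail parameters must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for one synthetic cohort.

    Defaults mirror the analyzed study design: 53 multiplex case families
    (two affected same-sex siblings each, one flagged as the ascertainment
    proband) against 8,983 unrelated controls, with autosomal sites only.
    """

    n_case_families: int = 53
    n_control: int = 8983
    n_genes: int = 200
    sites_per_gene: float = 20.0
    af_spectrum: AFSpectrum = field(default_factory=AFSpectrum)
    effect_mix: tuple = (
        ("synonymous", 0.30),
        ("missense", 0.50),
        ("inframe_indel", 0.05),
        ("ptv", 0.15),
    )
    polyphen_damaging_rate: float = 0.4
    revel_beta: tuple = (1.5, 4.0)
    n_populations: int = 1
    population_af_divergence: float = 0.0
    coverage_imbalance_fraction: float = 0.05
    coverage_imbalance_delta: float = 0.15
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case_families < 0 or self.n_control < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.n_case_families + self.n_control == 0:
            raise ValueError("cohort must contain at least one sample")
        if self.n_genes <= 0 or self.sites_per_gene < 1:
            raise ValueError("n_genes must be positive and sites_per_gene >= 1")
        probs = dict(self.effect_mix)
        if set(probs) != {"synonymous", "missense", "inframe_indel", "ptv"}:
            raise ValueError("effect_mix must cover exactly the four effect classes")
        if any(not 0 <= p <= 1 for p in probs.values()) or abs(sum(probs.values()) - 1) > 1e-9:
            raise ValueError("effect_mix probabilities must lie in [0,1] and sum to 1")
        for name, p in (
            ("polyphen_damaging_rate", self.polyphen_damaging_rate),
            ("coverage_imbalance_fraction", self.coverage_imbalance_fraction),
            ("missing_rate", self.missing_rate),
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_populations < 1:
            raise ValueError("n_populations must be >= 1")
        if not 0.0 <= self.population_af_divergence < 1.0:
            raise ValueError("population_af_divergence must lie in [0, 1)")


@dataclass(frozen=True)
class SpikeSpec:
    """Exact carrier counts to engineer into one gene.

    ``model_targeted`` names the qualifying model the spiked variants are
    built to satisfy; ``effect_class`` may override the default effect
    chosen for that model.
    """

    gene: str
    case_carrier_count: int
    control_carrier_count: int
    effect_class: str | None = None
    model_targeted: str = "ultra_rare"

    def __post_init__(self) -> None:
        if self.case_carrier_count < 0 or self.control_carrier_count < 0:
            raise ValueError("carrier counts must be non-negative")


@dataclass
class Cohort:
    """In-memory cohort: annotation table, dose matrix, manifest, coverage."""

    variants: pd.DataFrame
    genotypes: GenotypeMatrix
    manifest: pd.DataFrame
    coverage: pd.DataFrame
    config: SimConfig

    @property
    def case_ids(self) -> np.ndarray:
        return self.manifest.loc[self.manifest["phenotype"] == "case", "sample_id"].to_numpy()

    @property
    def control_ids(self) -> np.ndarray:
        return self.manifest.loc[self.manifest["phenotype"] == "control", "sample_id"].to_numpy()


def _make_manifest(config: SimConfig) -> pd.DataFrame:
    rows = []
    for f in range(config.n_case_families):
        fam = f"FAM{f:04d}"
        pop = f"pop{f % config.n_populations}"
        rows.append((f"C{f:04d}S1", fam, "case", pop, 1))  # ascertainment proband
        rows.append((f"C{f:04d}S2", fam, "case", pop, 0))  # affected sibling
    for i in range(config.n_control):
        pop = f"pop{i % config.n_populations}"
        rows.append((f"K{i:05d}", CONTROL_FAMILY, "control", pop, 0))
    return pd.DataFrame(
        rows, columns=["sample_id", "family_id", "phenotype", "ancestry", "is_proband"]
    )


def _make_variant_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    # gene g gets 1 + Poisson(mean - 1) sites so the per-gene mean is exact
    n_sites = 1 + rng.poisson(config.sites_per_gene - 1.0, size=config.n_genes)
    genes = np.repeat([f"GENE{g:04d}" for g in range(config.n_genes)], n_sites)
    gene_idx = np.repeat(np.arange(config.n_genes), n_sites)
    site_rank = np.concatenate([np.arange(k) for k in n_sites])
    n_var = len(genes)

    chrom = (gene_idx % 22 + 1).astype(str)
    pos = (gene_idx // 22 + 1) * 1_000_000 + site_rank * 100 + 1

    effects, probs = zip(*config.effect_mix)
    effect = rng.choice(effects, size=n_var, p=probs)

    ref_idx = rng.integers(0, 4, size=n_var)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_var)) % 4
    ref = _BASES[ref_idx].astype(object)
    alt = _BASES[alt_idx].astype(object)
    # inframe indels are emitted as 3-bp deletions (ref length 4)
    indel = effect == "inframe_indel"
    extra = _BASES[rng.integers(0, 4, size=(n_var, 3))]
    ref[indel] = [r + "".join(e) for r, e in zip(ref[indel], extra[indel])]

    polyphen = np.full(n_var, "missing", dtype=object)
    is_mis = effect == "missense"
    damaging = rng.random(n_var) < config.polyphen_damaging_rate
    polyphen[is_mis & damaging] = "probably_damaging"
    polyphen[is_mis & ~damaging] = "other"
    revel = np.full(n_var, np.nan)
    a, b = config.revel_beta
    revel[is_mis] = rng.beta(a, b, size=is_mis.sum())

    vid = [f"{c}-{p}-{r}-{al}" for c, p, r, al in zip(chrom, pos, ref, alt)]
    return pd.DataFrame(
        {
            "variant_id": vid,
            "chromosome": chrom,
            "position": pos,
            "ref": ref,
            "alt": alt,
            "gene": genes,
            "effect": effect,
            "polyphen": polyphen,
            "revel": revel,
        }
    )


def _population_afs(config: SimConfig, rng: np.random.Generator, n_var: int):
    """(is_singleton, ancestral afs, per-population afs [n_pop, n_var])."""
    spec = config.af_spectrum
    singleton = rng.random(n_var) < spec.singleton_fraction
    anc = rng.beta(spec.tail_beta_a, spec.tail_beta_b, size=n_var)
    anc = np.clip(anc, 1e-6, 0.5)
    f = config.population_af_divergence
    if config.n_populations == 1 or f == 0.0:
        pop_afs = np.tile(anc, (config.n_populations, 1))
    else:
        # Balding-Nichols: AF_pop ~ Beta(p(1-F)/F, (1-p)(1-F)/F)
        scale = (1.0 - f) / f
        pop_afs = rng.beta(anc * scale, (1.0 - anc) * scale,
                           size=(config.n_populations, n_var))
        pop_afs = np.clip(pop_afs, 0.0, 0.5)
    return singleton, anc, pop_afs


def _draw_genotypes(
    config: SimConfig,
    manifest: pd.DataFrame,
    rng: np.random.Generator,
    singleton: np.ndarray,
    pop_afs: np.ndarray,
) -> np.ndarray:
    n_var = pop_afs.shape[1]
    n_samples = len(manifest)
    doses = np.zeros((n_samples, n_var), dtype=np.int8)
    pop_of = manifest["ancestry"].str.removeprefix("pop").astype(int).to_numpy()
    is_case = (manifest["phenotype"] == "case").to_numpy()
    # singleton columns are placed explicitly below; only tail columns are drawn
    tail = np.where(~singleton)[0]

    # unrelated controls: Hardy-Weinberg draws from their population AF
    ctrl_rows = np.where(~is_case)[0]
    if len(ctrl_rows) and len(tail):
        afs = pop_afs[np.ix_(pop_of[ctrl_rows], tail)]
        doses[np.ix_(ctrl_rows, tail)] = rng.binomial(2, afs).astype(np.int8)

    # case families: two parental genotypes per family, each sibling draws
    # one allele per parent per variant (independent transmissions, so sibs
    # share each parental haplotype with probability 1/2 marginally)
    family = manifest["family_id"].to_numpy()
    for f in range(config.n_case_families):
        fam_rows = np.where(family == f"FAM{f:04d}")[0]
        if not len(tail):
            continue
        af = pop_afs[pop_of[fam_rows[0]], tail]
        parents = rng.binomial(2, af, size=(2, len(tail)))
        for row in fam_rows:
            t = rng.binomial(1, parents / 2.0)  # one transmitted allele per parent
            doses[row, tail] = t.sum(axis=0).astype(np.int8)

    # singletons: exactly one allele copy placed uniformly across the cohort
    sing_cols = np.where(singleton)[0]
    if len(sing_cols):
        carriers = rng.integers(0, n_samples, size=len(sing_cols))
        doses[carriers, sing_cols] = 1

    if config.missing_rate > 0:
        miss = rng.random(doses.shape) < config.missing_rate
        doses[miss] = -1
    return doses


def _external_afs(
    rng: np.random.Generator, singleton: np.ndarray, anc: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """gnomAD/ExAC frequencies correlated with the internal spectrum.

    Singletons are usually absent from reference databases; tail variants
    get the ancestral frequency under multiplicative log-normal noise, with
    a 20% chance of being absent from each database.
    """
    n = len(anc)
    out = []
    for _ in range(2):
        af = anc * np.exp(rng.normal(0.0, 0.5, size=n))
        af = np.clip(af, 0.0, 1.0)
        absent = rng.random(n) < 0.2
        af[absent] = 0.0
        sing_present = rng.random(n) >= 0.8
        af[singleton] = np.where(sing_present[singleton],
                                 rng.uniform(0.0, 2e-5, size=n)[singleton], 0.0)
        out.append(af)
    return out[0], out[1]


def _coverage_table(
    config: SimConfig, rng: np.random.Generator, variant_ids: np.ndarray
) -> pd.DataFrame:
    n = len(variant_ids)
    frac_case = rng.uniform(0.95, 1.0, size=n)
    frac_control = rng.uniform(0.95, 1.0, size=n)
    imbalanced = rng.random(n) < config.coverage_imbalance_fraction
    frac_control[imbalanced] = np.clip(
        frac_case[imbalanced] - config.coverage_imbalance_delta, 0.0, 1.0
    )
    return pd.DataFrame(
        {
            "variant_id": variant_ids,
            "frac_case_ge10x": np.round(frac_case, 4),
            "frac_control_ge10x": np.round(frac_control, 4),
        }
    )


def generate_cohort(config: SimConfig) -> Cohort:
    """Draw a full synthetic cohort under the configured study conditions."""
    rng = np.random.default_rng(config.seed)
    manifest = _make_manifest(config)
    variants = _make_variant_table(config, rng)
    n_var = len(variants)
    singleton, anc, pop_afs = _population_afs(config, rng, n_var)
    doses = _draw_genotypes(config, manifest, rng, singleton, pop_afs)
    gnomad, exac = _external_afs(rng, singleton, anc)
    variants = variants.assign(gnomad_af=np.round(gnomad, 8), exac_af=np.round(exac, 8))
    coverage = _coverage_table(config, rng, variants["variant_id"].to_numpy())
    genotypes = GenotypeMatrix(
        doses, manifest["sample_id"].to_numpy(), variants["variant_id"].to_numpy()
    )
    return Cohort(variants, genotypes, manifest, coverage, config)


def _spike_defaults(spec: SpikeSpec) -> tuple[str, str, float]:
    """(effect, polyphen, revel) for a spiked variant satisfying the model."""
    effect = spec.effect_class
    if effect is None:
        effect = {"synonymous": "synonymous", "ptv": "ptv"}.get(spec.model_targeted, "ptv")
    if effect == "missense":
        return effect, "probably_damaging", 0.9
    return effect, "missing", float("nan")


def spike_risk_gene(cohort: Cohort, spec: SpikeSpec) -> Cohort:
    """Engineer exact case/control carrier counts into one gene.

    The targeted gene's background genotypes are cleared and each chosen
    carrier receives its own private singleton qualifying variant (two
    distinct ones under the compound-het model), so the gene's collapsing
    table under the targeted model is exactly the requested counts.  Case
    carriers are drawn from the ascertainment probands so the counts survive
    one-case-per-family pruning; carriers are chosen without replacement
    with a generator derived from the cohort seed and the gene name.
    """
    if spec.case_carrier_count == 0 and spec.control_carrier_count == 0:
        return cohort
    gene_mask = cohort.variants["gene"] == spec.gene
    if not gene_mask.any():
        raise ValueError(f"gene {spec.gene!r} not present in cohort")
    probands = cohort.manifest.loc[
        (cohort.manifest["phenotype"] == "case") & (cohort.manifest["is_proband"] == 1),
        "sample_id",
    ].to_numpy()
    controls = cohort.control_ids
    if spec.case_carrier_count > len(probands):
        raise ValueError(
            f"cannot place {spec.case_carrier_count} case carriers among {len(probands)} probands"
        )
    if spec.control_carrier_count > len(controls):
        raise ValueError(
            f"cannot place {spec.control_carrier_count} control carriers among "
            f"{len(controls)} controls"
        )

    gene_hash = int(np.frombuffer(spec.gene.encode().ljust(8, b"\0")[:8], dtype=np.uint64)[0]
                    % np.uint64(2**31))
    rng = np.random.default_rng([cohort.config.seed, gene_hash])
    case_carriers = rng.choice(probands, size=spec.case_carrier_count, replace=False)
    control_carriers = rng.choice(controls, size=spec.control_carrier_count, replace=False)
    carriers = np.concatenate([case_carriers, control_carriers])

    # clear the gene's background so carrier counts are exact by construction
    doses = cohort.genotypes.doses.copy()
    gene_cols = cohort.genotypes.variant_index(cohort.variants.loc[gene_mask, "variant_id"])
    doses[:, gene_cols] = 0

    effect, polyphen, revel = _spike_defaults(spec)
    per_carrier = 2 if spec.model_targeted == "recessive" else 1
    chrom = cohort.variants.loc[gene_mask, "chromosome"].iloc[0]
    base_pos = int(cohort.variants.loc[gene_mask, "position"].max())

    new_rows = []
    new_cols = []
    carrier_index = cohort.genotypes.sample_index(carriers)
    for j, row in enumerate(carrier_index):
        for k in range(per_carrier):
            pos = base_pos + 1 + j * per_carrier + k
            vid = f"{chrom}-{pos}-A-T"
            new_rows.append(
                {
                    "variant_id": vid,
                    "chromosome": chrom,
                    "position": pos,
                    "ref": "A",
                    "alt": "T",
                    "gene": spec.gene,
                    "effect": effect,
                    "polyphen": polyphen,
                    "revel": revel,
                    "gnomad_af": 0.0,
                    "exac_af": 0.0,
                }
            )
            col = np.zeros(cohort.genotypes.n_samples, dtype=np.int8)
            col[row] = 1
            new_cols.append(col)

    variants = pd.concat([cohort.variants, pd.DataFrame(new_rows)], ignore_index=True)
    doses = np.concatenate([doses, np.stack(new_cols, axis=1)], axis=1)
    genotypes = GenotypeMatrix(
        doses, cohort.genotypes.sample_ids, variants["variant_id"].to_numpy()
    )
    new_cov = pd.DataFrame(
        {
            "variant_id": [r["variant_id"] for r in new_rows],
            "frac_case_ge10x": 1.0,
            "frac_control_ge10x": 1.0,
        }
    )
    coverage = pd.concat([cohort.coverage, new_cov], ignore_index=True)
    return Cohort(variants, genotypes, cohort.manifest.copy(), coverage, cohort.config)


# ---------------------------------------------------------------------------
# on-disk representation

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##source=genecollapse-synthetic\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)

_GT_CODES = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_cohort(cohort: Cohort, directory) -> dict[str, str]:
    """Write the cohort as VCF + annotation/coverage/manifest TSVs.

    Round-trips losslessly through the :mod:`genecollapse.cohort_io`
    readers.  Returns the mapping of logical name to written path.
    """
    os.makedirs(directory, exist_ok=True)
    paths = {
        "vcf": os.path.join(directory, "cohort.vcf"),
        "annotations": os.path.join(directory, "annotations.tsv"),
        "coverage": os.path.join(directory, "coverage.tsv"),
        "manifest": os.path.join(directory, "manifest.tsv"),
    }

    order = np.lexsort(
        (cohort.variants["position"].to_numpy(), cohort.variants["chromosome"].astype(int))
    )
    variants = cohort.variants.iloc[order]
    col_of = cohort.genotypes.variant_index(variants["variant_id"])

    contigs = sorted(variants["chromosome"].unique(), key=int)
    with open(paths["vcf"], "w", encoding="utf-8") as fh:
        fh.write(_VCF_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        sample_cols = "\t".join(cohort.genotypes.sample_ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_cols}\n")
        doses = cohort.genotypes.doses
        for (_, v), col in zip(variants.iterrows(), col_of):
            gts = "\t".join(_GT_CODES[int(d)] for d in doses[:, col])
            fh.write(
                f"{v['chromosome']}\t{v['position']}\t{v['variant_id']}\t"
                f"{v['ref']}\t{v['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )

    ann = cohort.variants[
        ["variant_id", "gene", "effect", "polyphen", "revel", "gnomad_af", "exac_af"]
    ]
    ann.to_csv(paths["annotations"], sep="\t", index=False)
    cohort.coverage.to_csv(paths["coverage"], sep="\t", index=False)
    cohort.manifest.to_csv(paths["manifest"], sep="\t", index=False)
    return paths


def read_cohort(directory, config: SimConfig | None = None) -> Cohort:
    """Load a written cohort back into memory (inverse of write_cohort)."""
    vcf_variants, genotypes = read_vcf(os.path.join(directory, "cohort.vcf"))
    annotations = read_annotations(os.path.join(directory, "annotations.tsv"))
    variants = vcf_variants.merge(annotations, on="variant_id", how="left")
    coverage = read_coverage(os.path.join(directory, "coverage.tsv"))
    manifest = read_manifest(os.path.join(directory, "manifest.tsv"))
    return Cohort(variants, genotypes, manifest, coverage, config or SimConfig())
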