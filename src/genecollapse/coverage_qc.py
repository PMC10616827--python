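"""Case/control coverage harmonization and neutral-variation QC.

Differential sequencing depth between cases and controls biases a carrier
test toward the better-covered group, because the poorly covered group
simply fails to call variants at under-covered sites.  Harmonization prunes
any site where the fraction of cases and the fraction of controls reaching
the depth threshold (10x) differ by 10 percentage points or more, then a
cohort-level check confirms both groups cover >= 95% of the tested coding
sequence.  As a final certificate of comparability, a per-sample tally of
rare synonymous variants — presumed neutral, so any case/control difference
signals residual technical imbalance — is compared between groups with a
two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from genecollapse.cohort_io import GenotypeMatrix
from genecollapse.qualifying_models import internal_allele_counts


@dataclass(frozen=True)
class CoverageConfig:
    depth_threshold: int = 10
    site_diff_max: float = 0.10
    cohort_min_fraction: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.site_diff_max < 1:
            raise ValueError("site_diff_max must lie in (0, 1)")
        if not 0 < self.cohort_min_fraction <= 1:
            raise ValueError("cohort_min_fraction must lie in (0, 1]")


@dataclass
class PrunedSiteSet:
    kept_variant_ids: set
    removed_variant_ids: set
    retained_bases: int


@dataclass
class CohortCoverageReport:
    passed: bool
    case_mean_fraction: float
    control_mean_fraction: float


@dataclass
class SynonymousBurdenResult:
    per_sample_counts: pd.Series
    statistic: float
    p_value: float
    case_mean: float
    control_mean: float


def prune_sites(
    coverage: pd.DataFrame,
    config: CoverageConfig = CoverageConfig(),
    variants: pd.DataFrame | None = None,
) -> PrunedSiteSet:
    """Keep a site iff |case fraction - control fraction| < site_diff_max.

    ``retained_bases`` counts 1 bp per kept SNV; an indel contributes
    max(len(ref), 1) bp when a variant table with ``ref`` alleles is given.
    """
    fc = coverage["frac_case_ge10x"].to_numpy(dtype=float)
    fk = coverage["frac_control_ge10x"].to_numpy(dtype=float)
    if ((fc < 0) | (fc > 1) | (fk < 0) | (fk > 1)).any():
        raise ValueError("coverage fractions must lie in [0, 1]")
    # coverage fractions are decimal percentages; round the difference so
    # the strict < threshold behaves decimally (|0.90 - 1.00| counts as 0.10)
    keep = np.round(np.abs(fc - fk), 9) < config.site_diff_max
    ids = coverage["variant_id"].to_numpy()
    kept = set(ids[keep])
    if variants is not None and "ref" in variants.columns:
        lengths = variants.set_index("variant_id")["ref"].str.len().clip(lower=1)
        retained = int(lengths.reindex(list(kept)).fillna(1).sum())
    else:
        retained = int(keep.sum())
    return PrunedSiteSet(kept, set(ids[~keep]), retained)


def cohort_coverage_check(
    coverage: pd.DataFrame, config: CoverageConfig = CoverageConfig()
) -> CohortCoverageReport:
    """Check each group covers >= cohort_min_fraction of sites at depth.

    Fails when either group's mean per-site fraction of samples at >= 10x
    falls below the threshold (default 0.95).
    """
    if len(coverage) == 0:
        raise ValueError("coverage table is empty")
    case_mean = float(coverage["frac_case_ge10x"].mean())
    control_mean = float(coverage["frac_control_ge10x"].mean())
    passed = case_mean >= config.cohort_min_fraction and control_mean >= config.cohort_min_fraction
    return CohortCoverageReport(passed, case_mean, control_mean)


def synonymous_burden_qc(
    genotypes: GenotypeMatrix,
    annotations: pd.DataFrame,
    manifest: pd.DataFrame,
    loo_af_max: float = 0.0005,
) -> SynonymousBurdenResult:
    """Per-sample tally of rare synonymous variants, compared case vs control.

    Synonymous variants are presumed neutral, so cases and controls should
    carry indistinguishable numbers of rare ones; a significant difference
    flags technical imbalance rather than biology.  A variant counts toward
    a sample when the sample's dose is >= 1 and the leave-one-out internal
    frequency is <= ``loo_af_max``.  Inputs should already be restricted to
    coverage-pruned autosomal sites and analyzed samples.  Group counts are
    compared with a two-sided Wilcoxon rank-sum (Mann-Whitney) test.
    """
    ann = annotations.set_index("variant_id").loc[list(genotypes.variant_ids)].reset_index()
    syn = (ann["effect"] == "synonymous").to_numpy()
    if not syn.any():
        raise ValueError("no synonymous variants available for the burden QC")
    doses = genotypes.doses[:, syn]
    ac, an = internal_allele_counts(doses)
    clean = np.where(doses < 0, 0, doses)
    denom = (an - 2).astype(float)
    safe = np.where(denom > 0, denom, 1.0)
    loo = (ac[None, :] - clean) / safe[None, :]
    loo[:, denom <= 0] = 0.0
    counts = ((clean >= 1) & (loo <= loo_af_max)).sum(axis=1)
    per_sample = pd.Series(counts, index=list(genotypes.sample_ids), name="rare_synonymous_count")

    pheno = manifest.set_index("sample_id")["phenotype"].reindex(per_sample.index)
    case_counts = per_sample[pheno == "case"].to_numpy()
    control_counts = per_sample[pheno == "control"].to_numpy()
    stat, p = stats.mannwhitneyu(case_counts, control_counts, alternative="two-sided")
    return SynonymousBurdenResult(
        per_sample_counts=per_sample,
        statistic=float(stat),
        p_value=float(p),
        case_mean=float(case_counts.mean()),
        control_mean=float(control_counts.mean()),
    )
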