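"""End-to-end collapsing scan: pruning, harmonization, carrier states, tests.

`run_collapsing` stitches the pipeline together: one-case-per-family
pruning defines the analyzed samples, coverage harmonization defines the
tested sites, each qualifying-variant model yields a per-sample per-gene
carrier matrix (with leave-one-out allele frequencies computed on the
analyzed samples), and every gene is tested with the two-tailed Fisher's
exact test.  Results come back as one long-format table across models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from genecollapse.cohort_io import GenotypeMatrix, prune_one_case_per_family
from genecollapse.collapsing_stats import (
    MultiplicityConfig,
    bonferroni_threshold,
    fisher_batch,
)
from genecollapse.coverage_qc import CoverageConfig, prune_sites
from genecollapse.qualifying_models import QVModel, builtin_models, carrier_states

RESULT_COLUMNS = [
    "gene",
    "model",
    "case_carriers",
    "case_n",
    "control_carriers",
    "control_n",
    "odds_ratio",
    "p_value",
    "passes_single_model_bonferroni",
    "passes_nine_model_bonferroni",
]


@dataclass
class CollapsingRun:
    """A completed scan: the long-format result table plus its context."""

    results: pd.DataFrame
    analyzed_manifest: pd.DataFrame
    kept_variant_ids: list
    carrier_matrices: dict  # model name -> (genes, states over analyzed samples)
    case_mask: np.ndarray


def _odds_ratio_vector(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> np.ndarray:
    num = a.astype(float) * d
    den = b.astype(float) * c
    with np.errstate(divide="ignore", invalid="ignore"):
        orv = num / den
    orv[(den == 0) & (num > 0)] = np.inf
    orv[(den == 0) & (num == 0)] = np.nan
    return orv


def run_collapsing(
    variants: pd.DataFrame,
    genotypes: GenotypeMatrix,
    coverage: pd.DataFrame,
    manifest: pd.DataFrame,
    models: list[QVModel] | None = None,
    coverage_config: CoverageConfig = CoverageConfig(),
    multiplicity: MultiplicityConfig | None = None,
    sample_subset=None,
) -> CollapsingRun:
    """Run the collapsing scan over the analyzed cohort.

    ``sample_subset`` optionally restricts the cohort before pruning (used
    for ancestry-stratified reruns); internal allele frequencies are always
    recomputed on the analyzed subset.  ``multiplicity`` defaults to
    Bonferroni over the number of genes actually tested and nine models.
    """
    if models is None:
        models = list(builtin_models())

    if sample_subset is not None:
        subset = set(sample_subset)
        manifest = manifest[manifest["sample_id"].isin(subset)].reset_index(drop=True)

    analyzed = prune_one_case_per_family(manifest)
    site_set = prune_sites(coverage, coverage_config, variants)
    kept = [v for v in genotypes.variant_ids if v in site_set.kept_variant_ids]

    sub_gt = genotypes.subset(sample_ids=analyzed["sample_id"], variant_ids=kept)
    kept_ann = variants[variants["variant_id"].isin(site_set.kept_variant_ids)]
    case_mask = (analyzed["phenotype"] == "case").to_numpy()
    n_case = int(case_mask.sum())
    n_control = len(analyzed) - n_case

    if multiplicity is None:
        n_genes_tested = max(1, kept_ann["gene"].nunique())
        multiplicity = MultiplicityConfig(n_genes=n_genes_tested, n_models=len(models))
    thr_single = bonferroni_threshold(multiplicity, per_model=True)
    thr_all = bonferroni_threshold(multiplicity, per_model=False)

    frames = []
    matrices: dict = {}
    for model in models:
        genes, states = carrier_states(sub_gt, kept_ann, model)
        matrices[model.name] = (genes, states)
        a = case_mask.astype(np.int64) @ states
        totals = states.sum(axis=0).astype(np.int64)
        c = totals - a
        b = n_case - a
        d = n_control - c
        p = fisher_batch(a, totals, n_case, n_control)
        frames.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "model": model.name,
                    "case_carriers": a,
                    "case_n": n_case,
                    "control_carriers": c,
                    "control_n": n_control,
                    "odds_ratio": _odds_ratio_vector(a, b, c, d),
                    "p_value": p,
                    "passes_single_model_bonferroni": p < thr_single,
                    "passes_nine_model_bonferroni": p < thr_all,
                }
            )
        )
    results = pd.concat(frames, ignore_index=True)[RESULT_COLUMNS]
    return CollapsingRun(results, analyzed, kept, matrices, case_mask)
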