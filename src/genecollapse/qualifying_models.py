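"""Qualifying-variant models and per-sample, per-gene carrier states.

A qualifying-variant (QV) model is a rule set deciding which annotated
variants count toward a sample's gene-level carrier status: an inheritance
mode (dominant or unphased compound-het), a functional class restriction,
an optional missense deleteriousness gate (PolyPhen "probably damaging" or
REVEL > threshold), an internal leave-one-out allele-frequency ceiling, and
an external (gnomAD + ExAC) allele-frequency ceiling.  Nine built-in models
span a grid from an ultra-rare model (internal LOO AF <= 0.0005, absent from
external references) through flexible rare models (<= 0.001) to a recessive
model at <= 0.01, plus a synonymous negative-control model.

The internal frequency filter is leave-one-out: the evaluated sample's own
two alleles are removed from the cohort allele count before comparing to the
ceiling, so a genuine singleton carrier sees a frequency of zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from genecollapse.cohort_io import GenotypeMatrix

INHERITANCE_MODES = ("dominant", "compound_het")
FUNCTION_CLASSES = ("synonymous", "all_functional", "ptv")


@dataclass(frozen=True)
class QVModel:
    """One qualifying-variant rule set."""

    name: str
    inheritance: str
    function_class: str
    loo_af_max: float
    external_af_max: float
    revel_min: float | None = None
    polyphen_required: bool = False

    def __post_init__(self) -> None:
        if self.inheritance not in INHERITANCE_MODES:
            raise ValueError(f"unknown inheritance mode {self.inheritance!r}")
        if self.function_class not in FUNCTION_CLASSES:
            raise ValueError(f"unknown function class {self.function_class!r}")
        for af in (self.loo_af_max, self.external_af_max):
            if not 0.0 <= af <= 1.0:
                raise ValueError("allele-frequency ceilings must lie in [0, 1]")

    def with_overrides(self, **kwargs) -> "QVModel":
        return replace(self, **kwargs)


def builtin_models() -> tuple[QVModel, ...]:
    """The nine built-in qualifying-variant models.

    Ordered from the synonymous negative control through increasingly
    permissive frequency ceilings to the protein-truncating and recessive
    models.
    """
    return (
        QVModel("synonymous", "dominant", "synonymous", 0.0005, 0.0),
        QVModel("ultra_rare", "dominant", "all_functional", 0.0005, 0.0, polyphen_required=True),
        QVModel("rare_damaging_revel", "dominant", "all_functional", 0.0005, 0.00005, revel_min=0.5),
        QVModel("rare_damaging_polyphen", "dominant", "all_functional", 0.0005, 0.00005, polyphen_required=True),
        QVModel("flexible_revel", "dominant", "all_functional", 0.001, 0.001, revel_min=0.5),
        QVModel("flexible_polyphen", "dominant", "all_functional", 0.001, 0.001, polyphen_required=True),
        QVModel("flexible_no_score", "dominant", "all_functional", 0.001, 0.001),
        QVModel("ptv", "dominant", "ptv", 0.001, 0.001),
        QVModel("recessive", "compound_het", "all_functional", 0.01, 0.01),
    )


def get_model(name: str) -> QVModel:
    for model in builtin_models():
        if model.name == name:
            return model
    raise KeyError(f"no built-in model named {name!r}")


def leave_one_out_af(allele_count: int, allele_number: int, dose: int) -> float:
    """Internal cohort allele frequency excluding the evaluated sample.

    ``(AC - dose) / (AN - 2)``: the variant's frequency in the combined
    case+control cohort after removing the evaluated sample's two alleles.
    Missing genotypes are expected to have been excluded from AN upstream.
    """
    if not 0 <= dose <= 2:
        raise ValueError("dose must be 0, 1 or 2")
    if allele_count < dose:
        raise ValueError("allele count cannot be smaller than the sample's dose")
    if allele_number <= 2:
        raise ValueError("leave-one-out frequency undefined for AN <= 2")
    return (allele_count - dose) / (allele_number - 2)


def _function_passes(effect: str, polyphen: str, revel: float | None, model: QVModel) -> bool:
    if model.function_class == "synonymous":
        return effect == "synonymous"
    if model.function_class == "ptv":
        return effect == "ptv"
    # all_functional: missense, inframe indel and PTV; deleteriousness gates
    # apply to missense only (truncating and inframe variants pass outright)
    if effect not in ("missense", "inframe_indel", "ptv"):
        return False
    if effect != "missense":
        return True
    if model.polyphen_required and polyphen != "probably_damaging":
        return False
    if model.revel_min is not None:
        if revel is None or (isinstance(revel, float) and math.isnan(revel)):
            return False  # missing score: variant silently fails the gate
        if not revel > model.revel_min:
            return False
    return True


def variant_qualifies(variant, loo_af: float, model: QVModel) -> bool:
    """Does one annotated variant qualify for one sample under a model?

    ``variant`` is any mapping (annotation-table row) exposing ``effect``,
    ``polyphen``, ``revel``, ``gnomad_af`` and ``exac_af``; ``loo_af`` is the
    sample-specific leave-one-out frequency.  A missense missing a required
    deleteriousness score does not qualify (not an error).
    """
    if loo_af > model.loo_af_max:
        return False
    gnomad = variant["gnomad_af"]
    exac = variant["exac_af"]
    gnomad = 0.0 if gnomad is None or (isinstance(gnomad, float) and math.isnan(gnomad)) else gnomad
    exac = 0.0 if exac is None or (isinstance(exac, float) and math.isnan(exac)) else exac
    if max(gnomad, exac) > model.external_af_max:
        return False
    return _function_passes(variant["effect"], variant.get("polyphen", "missing"),
                            variant.get("revel", None), model)


def sample_gene_state(doses, model: QVModel) -> int:
    """Collapse a sample's doses over a gene's qualifying variants to 0/1.

    ``doses`` are the sample's allele doses at the variants that already
    qualified for that sample.  Dominant: carrier iff any dose >= 1.
    Compound-het (unphased approximation): carrier iff two distinct het
    qualifying variants or one homozygous qualifying variant.  Missing
    genotypes count as dose 0.
    """
    d = np.asarray(doses, dtype=int)
    d = np.where(d < 0, 0, d)
    if model.inheritance == "dominant":
        return int((d >= 1).any())
    n_hit = int((d >= 1).sum())
    return int(n_hit >= 2 or (d == 2).any())


# ---------------------------------------------------------------------------
# vectorized carrier-state computation over a whole cohort


def internal_allele_counts(doses: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant (AC, AN) over the analyzed samples; missing excluded from AN."""
    missing = doses < 0
    clean = np.where(missing, 0, doses)
    ac = clean.sum(axis=0).astype(np.int64)
    an = 2 * (doses.shape[0] - missing.sum(axis=0)).astype(np.int64)
    return ac, an


def static_variant_mask(annotations: pd.DataFrame, model: QVModel) -> np.ndarray:
    """Sample-independent part of the qualification rule, vectorized.

    Covers the functional class, the deleteriousness gates and the external
    allele-frequency ceiling; the leave-one-out internal frequency is the
    only sample-dependent part and is applied in :func:`carrier_states`.
    """
    effect = annotations["effect"].to_numpy()
    if model.function_class == "synonymous":
        mask = effect == "synonymous"
    elif model.function_class == "ptv":
        mask = effect == "ptv"
    else:
        mask = np.isin(effect, ("missense", "inframe_indel", "ptv"))
        is_mis = effect == "missense"
        if model.polyphen_required:
            mask &= ~is_mis | (annotations["polyphen"].to_numpy() == "probably_damaging")
        if model.revel_min is not None:
            revel = annotations["revel"].to_numpy(dtype=float)
            mask &= ~is_mis | (~np.isnan(revel) & (revel > model.revel_min))
    gnomad = np.nan_to_num(annotations["gnomad_af"].to_numpy(dtype=float))
    exac = np.nan_to_num(annotations["exac_af"].to_numpy(dtype=float))
    mask = mask & (np.maximum(gnomad, exac) <= model.external_af_max)
    return mask


def carrier_states(
    genotypes: GenotypeMatrix,
    annotations: pd.DataFrame,
    model: QVModel,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample, per-gene carrier indicators under one model.

    ``genotypes`` must already be restricted to the analyzed samples and to
    coverage-harmonized sites; ``annotations`` must align with (be indexable
    by) the genotype matrix's variants.  Internal AC/AN and hence the
    leave-one-out frequencies are computed on exactly these samples.

    Returns ``(genes, states)`` where ``genes`` is the sorted unique gene
    array and ``states`` is an (n_samples, n_genes) 0/1 int8 matrix.
    """
    ann = annotations.set_index("variant_id").loc[list(genotypes.variant_ids)].reset_index()
    doses = genotypes.doses
    ac, an = internal_allele_counts(doses)
    static = static_variant_mask(ann, model)

    # the leave-one-out matrix is only needed on the static-passing columns
    sub = np.where(static)[0]
    clean = np.where(doses[:, sub] < 0, 0, doses[:, sub])
    denom = (an[sub] - 2).astype(float)
    # with a single genotyped sample the leave-one-out cohort is empty and
    # the frequency filter is vacuous
    safe = np.where(denom > 0, denom, 1.0)
    loo = (ac[sub][None, :] - clean) / safe[None, :]
    loo[:, denom <= 0] = 0.0
    qual = np.zeros(doses.shape, dtype=bool)
    qual[:, sub] = (clean >= 1) & (loo <= model.loo_af_max)
    clean_full = np.where(doses < 0, 0, doses)

    genes, gene_idx = np.unique(ann["gene"].to_numpy(), return_inverse=True)
    if len(genes) == 0:
        return genes, np.zeros((doses.shape[0], 0), dtype=np.int8)
    order = np.argsort(gene_idx, kind="stable")
    starts = np.searchsorted(gene_idx[order], np.arange(len(genes)))

    n_qual = np.add.reduceat(qual[:, order], starts, axis=1)
    if model.inheritance == "dominant":
        states = n_qual >= 1
    else:
        hom = np.add.reduceat((qual & (clean_full == 2))[:, order], starts, axis=1)
        states = (n_qual >= 2) | (hom >= 1)
    return genes, states.astype(np.int8)
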