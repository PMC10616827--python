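"""The nine-model grid, leave-one-out frequencies, and carrier states."""

import numpy as np
import pandas as pd
import pytest

from genecollapse import (
    GenotypeMatrix,
    builtin_models,
    leave_one_out_af,
    sample_gene_state,
    variant_qualifies,
)
from genecollapse.qualifying_models import carrier_states, get_model
from conftest import random_annotations


class TestBuiltinModels:
    def test_nine_models(self):
        assert len(builtin_models()) == 9

    @pytest.mark.parametrize(
        "name,inheritance,function,loo,ext,revel,polyphen",
        [
            ("synonymous", "dominant", "synonymous", 0.0005, 0.0, None, False),
            ("ultra_rare", "dominant", "all_functional", 0.0005, 0.0, None, True),
            ("rare_damaging_revel", "dominant", "all_functional", 0.0005, 0.00005, 0.5, False),
            ("rare_damaging_polyphen", "dominant", "all_functional", 0.0005, 0.00005, None, True),
            ("flexible_revel", "dominant", "all_functional", 0.001, 0.001, 0.5, False),
            ("flexible_polyphen", "dominant", "all_functional", 0.001, 0.001, None, True),
            ("flexible_no_score", "dominant", "all_functional", 0.001, 0.001, None, False),
            ("ptv", "dominant", "ptv", 0.001, 0.001, None, False),
            ("recessive", "compound_het", "all_functional", 0.01, 0.01, None, False),
        ],
    )
    def test_model_grid(self, name, inheritance, function, loo, ext, revel, polyphen):
        m = get_model(name)
        assert m.inheritance == inheritance
        assert m.function_class == function
        assert m.loo_af_max == loo
        assert m.external_af_max == ext
        assert m.revel_min == revel
        assert m.polyphen_required == polyphen


class TestLeaveOneOut:
    def test_singleton_carrier_sees_zero(self):
        assert leave_one_out_af(1, 18072, 1) == 0.0

    def test_carrier_just_under_ceiling(self):
        af = leave_one_out_af(10, 18072, 1)
        assert af == pytest.approx(9 / 18070)
        assert af <= 0.0005

    def test_noncarrier_at_same_site_over_ceiling(self):
        af = leave_one_out_af(10, 18072, 0)
        assert af == pytest.approx(10 / 18070)
        assert af > 0.0005

    def test_noncarrier_af_at_least_carrier_af(self):
        for ac in (1, 5, 100):
            assert leave_one_out_af(ac, 2000, 0) >= leave_one_out_af(ac, 2000, 1)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            leave_one_out_af(5, 2, 1)
        with pytest.raises(ValueError):
            leave_one_out_af(0, 100, 1)


def variant(effect="missense", polyphen="probably_damaging", revel=np.nan,
            gnomad=0.0, exac=0.0):
    return {"effect": effect, "polyphen": polyphen, "revel": revel,
            "gnomad_af": gnomad, "exac_af": exac}


class TestVariantQualifies:
    def test_ptv_qualifies_under_ultra_rare(self):
        assert variant_qualifies(variant(effect="ptv", polyphen="missing"),
                                 0.0, get_model("ultra_rare"))

    def test_benign_missense_fails_polyphen_gate(self):
        assert not variant_qualifies(variant(polyphen="other"), 0.0, get_model("ultra_rare"))

    def test_external_ceiling_separates_flexible_from_strict(self):
        v = variant(polyphen="other", revel=0.6, gnomad=0.0008)
        assert variant_qualifies(v, 0.0, get_model("flexible_revel"))
        assert not variant_qualifies(v, 0.0, get_model("rare_damaging_revel"))

    def test_missing_revel_fails_score_gated_model(self):
        assert not variant_qualifies(variant(revel=np.nan), 0.0, get_model("flexible_revel"))

    def test_revel_gate_is_strict(self):
        assert not variant_qualifies(variant(revel=0.5), 0.0, get_model("flexible_revel"))
        assert variant_qualifies(variant(revel=0.5001), 0.0, get_model("flexible_revel"))

    def test_inframe_indel_passes_without_scores(self):
        v = variant(effect="inframe_indel", polyphen="missing")
        assert variant_qualifies(v, 0.0, get_model("ultra_rare"))

    def test_synonymous_model_accepts_only_synonymous(self):
        m = get_model("synonymous")
        assert variant_qualifies(variant(effect="synonymous", polyphen="missing"), 0.0, m)
        assert not variant_qualifies(variant(effect="ptv", polyphen="missing"), 0.0, m)

    def test_loo_ceiling_applied(self):
        v = variant(effect="ptv", polyphen="missing")
        assert not variant_qualifies(v, 0.0006, get_model("ultra_rare"))
        assert variant_qualifies(v, 0.0005, get_model("ultra_rare"))


class TestSampleGeneState:
    def test_dominant_single_het(self):
        assert sample_gene_state([1], get_model("ultra_rare")) == 1

    def test_compound_het_needs_two_alleles(self):
        m = get_model("recessive")
        assert sample_gene_state([1], m) == 0
        assert sample_gene_state([1, 1], m) == 1
        assert sample_gene_state([2], m) == 1

    def test_missing_counts_as_reference(self):
        assert sample_gene_state([-1], get_model("ultra_rare")) == 0
        assert sample_gene_state([-1, 1], get_model("recessive")) == 0


def brute_force_states(doses, ann, model):
    """Independent per-sample re-derivation of the carrier matrix."""
    n, v = doses.shape
    genes = sorted(ann["gene"].unique())
    missing = doses < 0
    clean = np.where(missing, 0, doses)
    ac = clean.sum(axis=0)
    an = 2 * (n - missing.sum(axis=0))
    out = np.zeros((n, len(genes)), dtype=np.int8)
    for i in range(n):
        for g_idx, g in enumerate(genes):
            qual_doses = []
            for j in np.where((ann["gene"] == g).to_numpy())[0]:
                dose = int(clean[i, j])
                if dose < 1:
                    continue
                if an[j] <= 2:
                    loo = 0.0
                else:
                    loo = leave_one_out_af(int(ac[j]), int(an[j]), dose)
                if variant_qualifies(ann.iloc[j], loo, model):
                    qual_doses.append(dose)
            out[i, g_idx] = sample_gene_state(qual_doses, model)
    return np.array(genes), out


@pytest.mark.parametrize("model_name", [m.name for m in builtin_models()])
def test_vectorized_states_match_brute_force(model_name):
    """Oracle equivalence on a 50-variant random table, every model."""
    rng = np.random.default_rng(99)
    ann = random_annotations(50, rng)
    doses = rng.choice([-1, 0, 1, 2], size=(30, 50), p=[0.02, 0.78, 0.15, 0.05]).astype(np.int8)
    gt = GenotypeMatrix(doses, [f"s{i}" for i in range(30)], ann["variant_id"].to_numpy())
    model = get_model(model_name)
    genes_vec, states_vec = carrier_states(gt, ann, model)
    genes_bf, states_bf = brute_force_states(doses, ann, model)
    assert list(genes_vec) == list(genes_bf)
    np.testing.assert_array_equal(states_vec, states_bf)


def test_carrier_states_antimonotone_under_tightening():
    """Tightening any filter never turns a non-carrier into a carrier."""
    rng = np.random.default_rng(7)
    ann = random_annotations(1000, rng)
    doses = rng.choice([0, 1, 2], size=(40, 1000), p=[0.9, 0.08, 0.02]).astype(np.int8)
    gt = GenotypeMatrix(doses, [f"s{i}" for i in range(40)], ann["variant_id"].to_numpy())
    base = get_model("flexible_no_score")
    tighter = [
        base.with_overrides(loo_af_max=0.0005),
        base.with_overrides(external_af_max=0.0),
        base.with_overrides(polyphen_required=True),
        base.with_overrides(revel_min=0.5),
        base.with_overrides(loo_af_max=0.0001, external_af_max=0.00005, revel_min=0.9),
    ]
    _, loose_states = carrier_states(gt, ann, base)
    for model in tighter:
        _, tight_states = carrier_states(gt, ann, model)
        assert (tight_states <= loose_states).all()
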