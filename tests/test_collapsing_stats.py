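"""Exact tests, odds ratios, multiplicity, permutation QQ, gene sets."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genecollapse import (
    ContingencyTable,
    MultiplicityConfig,
    bonferroni_threshold,
    collapse_gene,
    fisher_two_sided,
    generate_cohort,
    geneset_test,
    odds_ratio,
    permutation_expected,
    recover_counts_from_or,
    run_collapsing,
    SimConfig,
    SpikeSpec,
    spike_risk_gene,
)
from genecollapse.collapsing_stats import fisher_batch, qq_lambda
from genecollapse.qualifying_models import get_model


def fisher_oracle(table: ContingencyTable) -> float:
    """Exact-fraction enumeration of the two-sided minimum-likelihood p.

    Enumerates every table with the observed margins, computes each
    hypergeometric probability as an exact rational, and sums those no
    larger than the observed table's.  Independent of any scipy routine.
    """
    a, b = table.case_carriers, table.case_noncarriers
    c, d = table.control_carriers, table.control_noncarriers
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    probs = {
        x: Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestCollapseGene:
    def test_counts_tabulated(self, toy_manifest):
        states = {"A2": 1, "K1": 1, "K2": 0}
        t = collapse_gene(states, toy_manifest)
        assert (t.case_carriers, t.case_noncarriers) == (1, 2)
        assert (t.control_carriers, t.control_noncarriers) == (1, 2)

    def test_all_zero_states(self, toy_manifest):
        t = collapse_gene({}, toy_manifest)
        assert (t.case_carriers, t.control_carriers) == (0, 0)

    def test_unknown_sample_rejected(self, toy_manifest):
        with pytest.raises(ValueError, match="missing from manifest"):
            collapse_gene({"ghost": 1}, toy_manifest)


class TestFisherTwoSided:
    @pytest.mark.parametrize(
        "table,expected",
        [
            (ContingencyTable(2, 51, 3, 8980), 3.34e-4),
            (ContingencyTable(2, 51, 1, 8982), 1.01e-4),
            (ContingencyTable(3, 50, 14, 8969), 1.22e-4),
        ],
    )
    def test_published_tables(self, table, expected):
        assert fisher_two_sided(table) == pytest.approx(expected, rel=5e-3)

    def test_degenerate_margins(self):
        assert fisher_two_sided(ContingencyTable(0, 53, 0, 8983)) == 1.0

    @given(
        a=st.integers(0, 30), b=st.integers(0, 30),
        c=st.integers(0, 30), d=st.integers(0, 30),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        assert fisher_two_sided(t) == pytest.approx(fisher_oracle(t), rel=1e-7)

    @given(
        a=st.integers(0, 20), b=st.integers(0, 20),
        c=st.integers(0, 20), d=st.integers(0, 20),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_invariant_under_row_and_column_swap(self, a, b, c, d):
        p1 = fisher_two_sided(ContingencyTable(a, b, c, d))
        p2 = fisher_two_sided(ContingencyTable(d, c, b, a))
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_batch_agrees_with_scalar(self):
        rng = np.random.default_rng(1)
        n_case, n_control = 50, 2000
        totals = rng.integers(0, 30, size=40)
        a = np.array([rng.integers(0, min(t, n_case) + 1) for t in totals])
        batch = fisher_batch(a, totals, n_case, n_control)
        for ai, ti, pi in zip(a, totals, batch):
            t = ContingencyTable(int(ai), n_case - int(ai), int(ti - ai),
                                 n_control - int(ti - ai))
            assert pi == pytest.approx(fisher_two_sided(t), rel=1e-9)


class TestOddsRatio:
    @pytest.mark.parametrize(
        "table,expected",
        [
            (ContingencyTable(2, 51, 3, 8980), 117.39),
            (ContingencyTable(2, 51, 1, 8982), 352.24),
            (ContingencyTable(1, 1, 1, 1), 1.0),
        ],
    )
    def test_cross_product(self, table, expected):
        assert round(odds_ratio(table), 2) == expected

    def test_zero_control_carriers_infinite(self):
        assert np.isinf(odds_ratio(ContingencyTable(2, 51, 0, 8983)))

    def test_no_carriers_undefined(self):
        assert np.isnan(odds_ratio(ContingencyTable(0, 53, 0, 8983)))


class TestBonferroni:
    def test_single_model_threshold(self):
        thr = bonferroni_threshold(MultiplicityConfig(0.05, 18666, 9), per_model=True)
        assert thr == pytest.approx(0.05 / 18666)

    def test_nine_model_threshold(self):
        thr = bonferroni_threshold(MultiplicityConfig(0.05, 18666, 9), per_model=False)
        assert thr == pytest.approx(0.05 / (18666 * 9))

    def test_single_gene(self):
        assert bonferroni_threshold(MultiplicityConfig(0.05, 1, 9), per_model=True) == 0.05

    def test_decreasing_in_genes_and_models(self):
        base = bonferroni_threshold(MultiplicityConfig(0.05, 100, 2), per_model=False)
        assert bonferroni_threshold(MultiplicityConfig(0.05, 200, 2), per_model=False) < base
        assert bonferroni_threshold(MultiplicityConfig(0.05, 100, 4), per_model=False) < base


class TestRecoverCounts:
    def test_top_ultra_rare_table_unique(self):
        tables = recover_counts_from_or(117.39, 53, 8983, 30)
        assert len(tables) == 1
        assert tables[0] == ContingencyTable(2, 51, 3, 8980)

    def test_second_table(self):
        tables = recover_counts_from_or(70.42, 53, 8983, 30)
        assert ContingencyTable(2, 51, 5, 8978) in tables

    def test_balanced_or_one_non_unique(self):
        tables = recover_counts_from_or(1.0, 10, 10, 10)
        assert len(tables) > 1
        assert all(round(odds_ratio(t), 2) == 1.0 for t in tables)

    def test_no_match_raises(self):
        with pytest.raises(ValueError, match="no carrier table"):
            recover_counts_from_or(117.39, 5, 5, 2)


class TestPermutationQQ:
    def test_identical_vectors_lambda_one(self):
        v = np.sort(np.random.default_rng(0).uniform(0.001, 1.0, size=50))
        assert qq_lambda(v, v) == pytest.approx(1.0)

    def test_deterministic_given_seed(self, null_scan_cohort):
        coh = null_scan_cohort
        run = run_collapsing(coh.variants, coh.genotypes, coh.coverage, coh.manifest,
                             models=[get_model("ultra_rare")])
        _, states = run.carrier_matrices["ultra_rare"]
        q1 = permutation_expected(states, run.case_mask, 50, seed=5)
        q2 = permutation_expected(states, run.case_mask, 50, seed=5)
        np.testing.assert_array_equal(q1.expected_p, q2.expected_p)
        assert q1.lam == q2.lam

    def test_null_cohort_lambda_near_one(self, null_scan_cohort):
        coh = null_scan_cohort
        run = run_collapsing(coh.variants, coh.genotypes, coh.coverage, coh.manifest,
                             models=[get_model("ultra_rare")])
        _, states = run.carrier_matrices["ultra_rare"]
        qq = permutation_expected(states, run.case_mask, 1000, seed=5)
        assert 0.8 <= qq.lam <= 1.2

    def test_spiking_inflates_lambda_removal_restores(self):
        cfg = SimConfig(n_case_families=50, n_control=2000, n_genes=500, seed=3)
        coh = generate_cohort(cfg)
        for g in range(20):
            coh = spike_risk_gene(coh, SpikeSpec(f"GENE{g:04d}", 3, 1,
                                                 model_targeted="ultra_rare"))
        run = run_collapsing(coh.variants, coh.genotypes, coh.coverage, coh.manifest,
                             models=[get_model("ultra_rare")])
        genes, states = run.carrier_matrices["ultra_rare"]
        inflated = permutation_expected(states, run.case_mask, 200, seed=1).lam
        assert inflated > 1.2
        top = set(run.results.sort_values("p_value")["gene"].head(20))
        keep = ~np.isin(genes, list(top))
        restored = permutation_expected(states[:, keep], run.case_mask, 200, seed=1).lam
        assert 0.7 <= restored <= 1.3

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            permutation_expected(np.zeros((4, 2), dtype=np.int8),
                                 np.array([1, 1, 0, 0], bool), 0, 1)


class TestGeneSet:
    def _scan(self):
        cfg = SimConfig(n_case_families=30, n_control=500, n_genes=60, seed=21)
        coh = generate_cohort(cfg)
        for g in (3, 7, 11, 19):
            coh = spike_risk_gene(coh, SpikeSpec(f"GENE{g:04d}", 4, 1,
                                                 model_targeted="ultra_rare"))
        run = run_collapsing(coh.variants, coh.genotypes, coh.coverage, coh.manifest)
        return run.results

    def test_spiked_members_detected(self):
        results = self._scan()
        panel = [f"GENE{g:04d}" for g in (3, 7, 11, 19)] + [f"OTHER{i}" for i in range(44)]
        gs = geneset_test(results, panel)
        assert gs.n_significant >= 4

    def test_absent_genes_empty_result(self):
        gs = geneset_test(self._scan(), ["NOT_THERE_1", "NOT_THERE_2"])
        assert gs.per_gene_model.empty
        assert gs.n_significant == 0

    def test_single_gene_restriction_equals_scan_row(self):
        results = self._scan()
        gs = geneset_test(results, ["GENE0003"])
        expected = results[results["gene"] == "GENE0003"].reset_index(drop=True)
        pd.testing.assert_frame_equal(gs.per_gene_model, expected)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            geneset_test(self._scan(), [])
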