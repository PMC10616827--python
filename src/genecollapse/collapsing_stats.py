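"""Per-gene carrier statistics: exact tests, odds ratios, multiplicity,
permutation QQ expectation and inflation lambda, gene-set testing.

The collapsing test reduces each gene to a 2x2 table of carrier /
non-carrier counts in cases and controls and applies a two-tailed Fisher's
exact test (minimum-likelihood definition: the p-value sums the
hypergeometric probabilities of all same-margin tables no more probable
than the observed one).  The odds ratio is the unadjusted cross-product
``(a*d)/(b*c)``; no continuity correction is applied by default so that
printed values are exactly reproducible from integer tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: relative slack when comparing hypergeometric probabilities for the
#: two-sided minimum-likelihood p-value (guards against float round-off)
_PMF_RELATIVE_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """Carrier 2x2 counts: rows case/control, columns carrier/non-carrier."""

    case_carriers: int
    case_noncarriers: int
    control_carriers: int
    control_noncarriers: int

    def __post_init__(self) -> None:
        for v in (self.case_carriers, self.case_noncarriers,
                  self.control_carriers, self.control_noncarriers):
            if v < 0:
                raise ValueError("contingency counts must be non-negative")

    @property
    def n_case(self) -> int:
        return self.case_carriers + self.case_noncarriers

    @property
    def n_control(self) -> int:
        return self.control_carriers + self.control_noncarriers

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.case_carriers, self.case_noncarriers],
             [self.control_carriers, self.control_noncarriers]]
        )


@dataclass(frozen=True)
class MultiplicityConfig:
    """Bonferroni configuration: alpha over genes (and optionally models)."""

    alpha: float = 0.05
    n_genes: int = 18666
    n_models: int = 9

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_genes < 1 or self.n_models < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class QQResult:
    """Observed vs permutation-expected p-value order statistics."""

    observed_p: np.ndarray
    expected_p: np.ndarray
    lam: float
    n_permutations: int
    seed: int


@dataclass
class GeneSetResult:
    """Collapsing results restricted to a candidate gene list."""

    per_gene_model: pd.DataFrame
    significant_genes: list[str] = field(default_factory=list)

    @property
    def n_significant(self) -> int:
        return len(self.significant_genes)


def collapse_gene(states: dict, manifest: pd.DataFrame) -> ContingencyTable:
    """Tabulate one gene's 0/1 carrier states into the 2x2 carrier table.

    ``states`` maps sample_id -> carrier state for the analyzed samples;
    every keyed sample must be present in ``manifest``.
    """
    known = set(manifest["sample_id"])
    unknown = set(states) - known
    if unknown:
        raise ValueError(f"states given for samples missing from manifest: {sorted(unknown)}")
    pheno = manifest.set_index("sample_id")["phenotype"]
    a = b = c = d = 0
    for sid in manifest["sample_id"]:
        s = int(states.get(sid, 0))
        if pheno[sid] == "case":
            a, b = (a + 1, b) if s else (a, b + 1)
        else:
            c, d = (c + 1, d) if s else (c, d + 1)
    return ContingencyTable(a, b, c, d)


def fisher_two_sided(table: ContingencyTable) -> float:
    """Exact two-tailed Fisher p-value for a carrier 2x2 table."""
    _, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    return float(p)


def odds_ratio(table: ContingencyTable) -> float:
    """Unadjusted cross-product odds ratio ``(a*d)/(b*c)``.

    Returns ``inf`` when only the case row has carriers and ``nan``
    (undefined) when neither group has any, matching how zero cells behave
    in the cross-product.  Pass ``haldane=True`` to
    :func:`odds_ratio_corrected` for a display-friendly finite value.
    """
    num = table.case_carriers * table.control_noncarriers
    den = table.case_noncarriers * table.control_carriers
    if den > 0:
        return num / den
    return float("inf") if num > 0 else float("nan")


def odds_ratio_corrected(table: ContingencyTable) -> float:
    """Haldane-Anscombe odds ratio (0.5 added to every cell); display only."""
    return ((table.case_carriers + 0.5) * (table.control_noncarriers + 0.5)) / (
        (table.case_noncarriers + 0.5) * (table.control_carriers + 0.5)
    )


def bonferroni_threshold(config: MultiplicityConfig, per_model: bool = True) -> float:
    """Significance threshold: alpha/n_genes, or alpha/(n_genes*n_models)."""
    denom = config.n_genes * (1 if per_model else config.n_models)
    return config.alpha / denom


# ---------------------------------------------------------------------------
# fast batched Fisher tests (shared-margin caching)

_fisher_cache: dict[tuple[int, int, int], np.ndarray] = {}


def _fisher_lookup(n_case: int, n_control: int, total_carriers: int) -> np.ndarray:
    """p-values indexed by case-carrier count, for fixed margins.

    For a gene the carrier total K is fixed under label permutation, so the
    two-sided p depends only on the case-carrier count a.  Cached per
    (n_case, n_control, K).
    """
    key = (n_case, n_control, total_carriers)
    lut = _fisher_cache.get(key)
    if lut is not None:
        return lut
    n = n_case + n_control
    lo = max(0, total_carriers - n_control)
    hi = min(total_carriers, n_case)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, total_carriers, n_case)
    lut = np.full(total_carriers + 1, np.nan)
    for a, p_a in zip(support, pmf):
        lut[a] = pmf[pmf <= p_a * (1 + _PMF_RELATIVE_TOL)].sum()
    lut = np.clip(lut, 0.0, 1.0)
    _fisher_cache[key] = lut
    return lut


def fisher_batch(case_carriers: np.ndarray, total_carriers: np.ndarray,
                 n_case: int, n_control: int) -> np.ndarray:
    """Vectorized two-sided Fisher p-values for many genes at fixed cohort sizes."""
    case_carriers = np.asarray(case_carriers)
    total_carriers = np.broadcast_to(np.asarray(total_carriers), case_carriers.shape)
    p = np.ones(case_carriers.shape, dtype=float)
    flat_a = case_carriers.reshape(-1)
    flat_k = total_carriers.reshape(-1)
    out = p.reshape(-1)
    for k in np.unique(flat_k):
        lut = _fisher_lookup(n_case, n_control, int(k))
        sel = flat_k == k
        out[sel] = lut[flat_a[sel]]
    return p


def permutation_expected(
    states: np.ndarray,
    case_mask: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
) -> QQResult:
    """Permutation-based expected p-value distribution and inflation lambda.

    ``states`` is the (n_samples, n_genes) carrier matrix; ``case_mask``
    flags the analyzed cases.  Each permutation shuffles the case/control
    labels preserving group sizes and recomputes every gene's exact p; the
    expected vector is the permutation mean of each order statistic.

    Lambda is the ratio of median chi-square(1 df) quantiles of the observed
    p-values vs the permutation expectation.  Exact tests on sparse carrier
    tables put a large atom at p = 1 (a zero chi-square quantile), which
    makes a comparison against the *mean* order statistics structurally
    biased: the mean smooths the atom away while any single observed vector
    keeps it.  Lambda is therefore computed against the permutation *median*
    order statistics, restricted to the informative ranks (those whose
    median order statistic is below 1), so observed and expected share the
    same atom structure; the reported ``expected_p`` stays the mean order
    statistics, the usual QQ-plot expectation.  When no rank is informative
    the diagnostic is vacuous and lambda is reported as 1.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    states = np.asarray(states, dtype=np.int8)
    case_mask = np.asarray(case_mask, dtype=bool)
    n_samples, n_genes = states.shape
    n_case = int(case_mask.sum())
    n_control = n_samples - n_case

    totals = states.sum(axis=0).astype(np.int64)
    obs_a = case_mask.astype(np.int64) @ states
    observed = np.sort(fisher_batch(obs_a, totals, n_case, n_control))

    rng = np.random.default_rng(seed)
    perm_masks = np.zeros((n_permutations, n_samples), dtype=np.int64)
    for i in range(n_permutations):
        perm_masks[i, rng.choice(n_samples, n_case, replace=False)] = 1
    perm_a = perm_masks @ states  # (n_permutations, n_genes)
    perm_p = fisher_batch(perm_a, np.broadcast_to(totals, perm_a.shape), n_case, n_control)
    perm_p.sort(axis=1)
    expected = perm_p.mean(axis=0)
    expected_median = np.median(perm_p, axis=0)

    lam = qq_lambda(observed, expected_median)
    return QQResult(observed, expected, lam, n_permutations, seed)


def qq_lambda(observed_sorted: np.ndarray, expected_sorted: np.ndarray) -> float:
    """Median chi-square(1) quantile ratio over informative ranks.

    Both vectors must be sorted ascending; ranks whose expected p is 1 are
    excluded (their chi-square quantile is identically zero under a discrete
    exact test).  Identical vectors give exactly 1.
    """
    informative = expected_sorted < 1.0 - 1e-12
    if not informative.any():
        return 1.0
    chi_obs = stats.chi2.isf(np.clip(observed_sorted[informative], 1e-300, 1.0), df=1)
    chi_exp = stats.chi2.isf(np.clip(expected_sorted[informative], 1e-300, 1.0), df=1)
    med_obs = float(np.median(chi_obs))
    med_exp = float(np.median(chi_exp))
    if med_exp == 0.0:
        return 1.0 if med_obs == 0.0 else float("inf")
    return med_obs / med_exp


def recover_counts_from_or(
    printed_or: float,
    n_case: int,
    n_control: int,
    max_carriers: int,
) -> list[ContingencyTable]:
    """Enumerate integer carrier tables whose cross-product OR prints as given.

    Scans case carriers a in [0, max_carriers] and control carriers b in
    [0, max_carriers] and returns every table whose odds ratio prints (two
    decimals) as ``printed_or`` — the utility used to pin a published OR to
    the integer table behind it.  A table matches when its OR lies within
    half a unit of the last printed digit, which covers both tie-rounding
    conventions (e.g. 44.855 printed as 44.86).  Raises if no table matches.
    """
    if printed_or <= 0:
        raise ValueError("printed_or must be positive")
    matches = []
    for a in range(0, max_carriers + 1):
        for b in range(0, max_carriers + 1):
            table = ContingencyTable(a, n_case - a, b, n_control - b)
            orv = odds_ratio(table)
            if np.isfinite(orv) and abs(orv - printed_or) <= 0.005 + 1e-9:
                matches.append(table)
    if not matches:
        raise ValueError(
            f"no carrier table with margins ({n_case}, {n_control}) and counts "
            f"<= {max_carriers} yields OR {printed_or:.2f}"
        )
    return matches


def geneset_test(results: pd.DataFrame, gene_list) -> GeneSetResult:
    """Restrict a multi-model collapsing scan to a candidate gene list.

    ``results`` is the long-format scan output (one row per gene per model
    with ``gene``, ``model``, ``odds_ratio``, ``p_value`` columns).  Reports
    OR and exact p per gene per model over the list and tallies the genes
    significant at p < 0.05 in at least one model.
    """
    genes = list(gene_list)
    if not genes:
        raise ValueError("gene list must be non-empty")
    sub = results[results["gene"].isin(genes)].copy()
    sig = sorted(sub.loc[sub["p_value"] < 0.05, "gene"].unique().tolist())
    return GeneSetResult(per_gene_model=sub.reset_index(drop=True), significant_genes=sig)
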