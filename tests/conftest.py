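import numpy as np
import pandas as pd
import pytest

from genecollapse import AFSpectrum, SimConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small mixed cohort: 6 sib-pair families + 40 controls, 12 genes."""
    cfg = SimConfig(n_case_families=6, n_control=40, n_genes=12, sites_per_gene=6, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_scan_cohort():
    """Null cohort at the scale used for scan-level checks."""
    cfg = SimConfig(n_case_families=50, n_control=2000, n_genes=500, seed=101)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def three_pop_cohort():
    """Three diverged populations, common-variant-rich, for ancestry tests."""
    cfg = SimConfig(
        n_case_families=15,
        n_control=270,
        n_genes=100,
        sites_per_gene=20,
        n_populations=3,
        population_af_divergence=0.15,
        af_spectrum=AFSpectrum(singleton_fraction=0.1, tail_beta_a=0.8, tail_beta_b=8.0),
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def toy_manifest():
    return pd.DataFrame(
        {
            "sample_id": ["A1", "A2", "B1", "K1", "K2", "K3"],
            "family_id": ["F1", "F1", "F2", "CTRL", "CTRL", "CTRL"],
            "phenotype": ["case", "case", "case", "control", "control", "control"],
            "ancestry": ["pop0"] * 6,
            "is_proband": [0, 1, 0, 0, 0, 0],
        }
    )


def random_annotations(n, rng):
    """Random annotation table covering all effect classes and score ranges."""
    effect = rng.choice(["synonymous", "missense", "inframe_indel", "ptv"], size=n)
    polyphen = np.where(
        effect == "missense",
        rng.choice(["probably_damaging", "other"], size=n),
        "missing",
    )
    revel = np.where(effect == "missense", rng.random(n), np.nan)
    return pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(n)],
            "gene": [f"G{i % max(1, n // 5)}" for i in range(n)],
            "effect": effect,
            "polyphen": polyphen,
            "revel": revel,
            "gnomad_af": np.where(rng.random(n) < 0.4, 0.0, rng.random(n) * 2e-3),
            "exac_af": np.where(rng.random(n) < 0.4, 0.0, rng.random(n) * 2e-3),
        }
    )
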