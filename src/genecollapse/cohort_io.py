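"""Cohort file IO and relatedness pruning.

Readers for the four cohort inputs (multi-sample VCF, per-variant annotation
table, per-site coverage table, sample manifest) plus the one-case-per-family
pruning that defines the analyzed sample set.  All tabular formats are
UTF-8 TSV with a header row; the VCF is v4.2 with a GT FORMAT field.
Coordinates are 1-based throughout; genes are defined by the annotation
table's ``gene`` column, never by interval arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

#: the four functional effect classes a variant may carry
EFFECT_CLASSES = ("synonymous", "missense", "inframe_indel", "ptv")

#: PolyPhen call labels
POLYPHEN_LABELS = ("probably_damaging", "other", "missing")

#: dose code for a missing genotype
MISSING_DOSE = -1

MANIFEST_COLUMNS = ["sample_id", "family_id", "phenotype", "ancestry", "is_proband"]
ANNOTATION_COLUMNS = ["variant_id", "gene", "effect", "polyphen", "revel", "gnomad_af", "exac_af"]
COVERAGE_COLUMNS = ["variant_id", "frac_case_ge10x", "frac_control_ge10x"]


@dataclass
class GenotypeMatrix:
    """Sample x variant diploid allele-dose matrix.

    Entries are {0, 1, 2} allele doses with ``-1`` for a missing genotype.
    Rows follow ``sample_ids``, columns follow ``variant_ids``.
    """

    doses: np.ndarray
    sample_ids: np.ndarray
    variant_ids: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=np.int8)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        if self.doses.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError(
                f"dose matrix shape {self.doses.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        if self.doses.size and (self.doses.min() < -1 or self.doses.max() > 2):
            raise ValueError("dose codes must be in {-1, 0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def sample_index(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([lookup[s] for s in sample_ids], dtype=np.intp)

    def variant_index(self, variant_ids) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.variant_ids)}
        return np.array([lookup[v] for v in variant_ids], dtype=np.intp)

    def subset(self, sample_ids=None, variant_ids=None) -> "GenotypeMatrix":
        doses = self.doses
        samples = self.sample_ids
        variants = self.variant_ids
        if sample_ids is not None:
            idx = self.sample_index(sample_ids)
            doses = doses[idx, :]
            samples = samples[idx]
        if variant_ids is not None:
            jdx = self.variant_index(variant_ids)
            doses = doses[:, jdx]
            variants = variants[jdx]
        return GenotypeMatrix(doses.copy(), samples.copy(), variants.copy())


def read_vcf(path) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Read a multi-sample VCF into a variant table and a dose matrix.

    Multi-allelic sites are decomposed into one row per ALT allele; the dose
    for ALT *k* is the number of GT alleles equal to *k*.  Any genotype with
    a missing allele maps to the missing dose code.

    Returns a variant table with columns ``variant_id, chromosome, position,
    ref, alt`` and the corresponding :class:`GenotypeMatrix`.
    """
    vcf = VCF(str(path), gts012=False)
    samples = np.asarray(vcf.samples, dtype=object)
    rows: list[tuple] = []
    dose_cols: list[np.ndarray] = []
    for rec in vcf:
        gts = np.asarray([g[:2] for g in rec.genotypes], dtype=np.int16)
        missing = (gts < 0).any(axis=1)
        for k, alt in enumerate(rec.ALT, start=1):
            dose = (gts == k).sum(axis=1).astype(np.int8)
            dose[missing] = MISSING_DOSE
            if rec.ID and rec.ID != "." and len(rec.ALT) == 1:
                vid = rec.ID
            else:
                vid = f"{rec.CHROM}-{rec.POS}-{rec.REF}-{alt}"
            rows.append((vid, rec.CHROM, rec.POS, rec.REF, alt))
            dose_cols.append(dose)
    vcf.close()
    variants = pd.DataFrame(
        rows, columns=["variant_id", "chromosome", "position", "ref", "alt"]
    )
    if dose_cols:
        doses = np.stack(dose_cols, axis=1)
    else:
        doses = np.zeros((len(samples), 0), dtype=np.int8)
    return variants, GenotypeMatrix(doses, samples, variants["variant_id"].to_numpy())


def read_manifest(path) -> pd.DataFrame:
    """Read the sample manifest TSV; sample ids must be unique."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "family_id": str, "ancestry": str})
    _require_columns(df, MANIFEST_COLUMNS, "manifest")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id in manifest: {dups}")
    bad = ~df["phenotype"].isin(["case", "control"])
    if bad.any():
        raise ValueError(f"phenotype must be case/control, got {df.loc[bad, 'phenotype'].unique()}")
    df["ancestry"] = df["ancestry"].fillna("unknown")
    df["is_proband"] = df["is_proband"].astype(int)
    return df


def read_annotations(path) -> pd.DataFrame:
    """Read the per-variant annotation TSV.

    ``revel`` may be empty (missing score); external allele frequencies are
    parsed to floats in [0, 1].
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "gene": str})
    _require_columns(df, ANNOTATION_COLUMNS, "annotation table")
    bad = ~df["effect"].isin(EFFECT_CLASSES)
    if bad.any():
        raise ValueError(f"unknown effect class: {df.loc[bad, 'effect'].unique()}")
    df["polyphen"] = df["polyphen"].fillna("missing")
    df["revel"] = pd.to_numeric(df["revel"], errors="coerce")
    for col in ("gnomad_af", "exac_af"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        if ((df[col] < 0) | (df[col] > 1)).any():
            raise ValueError(f"{col} outside [0, 1]")
    return df


def read_coverage(path) -> pd.DataFrame:
    """Read the per-site coverage TSV (fraction of each group at >=10x depth)."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    _require_columns(df, COVERAGE_COLUMNS, "coverage table")
    for col in ("frac_case_ge10x", "frac_control_ge10x"):
        df[col] = df[col].astype(float)
        if ((df[col] < 0) | (df[col] > 1)).any():
            raise ValueError(f"{col} outside [0, 1]")
    return df


def prune_one_case_per_family(manifest: pd.DataFrame) -> pd.DataFrame:
    """Reduce each case family to a single case; keep all controls.

    Multiplex families contribute several affected members whose shared
    haplotypes would distort a test that assumes unrelated samples, so one
    case is retained per ``family_id``.  Within a family the lowest-sorted
    proband is kept if any member carries the proband flag, otherwise the
    lowest-sorted case.  Deterministic and idempotent.
    """
    cases = manifest[manifest["phenotype"] == "case"]
    if cases["family_id"].isna().any():
        raise ValueError("every case must have a family_id")
    keep: list[str] = []
    for _, fam in cases.sort_values("sample_id").groupby("family_id", sort=True):
        probands = fam[fam["is_proband"] == 1]
        chosen = probands if len(probands) else fam
        keep.append(chosen["sample_id"].iloc[0])
    kept_cases = manifest["sample_id"].isin(keep)
    controls = manifest["phenotype"] == "control"
    return manifest[kept_cases | controls].reset_index(drop=True)


def _require_columns(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {missing}")
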