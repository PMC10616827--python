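"""Genotype-driven ancestry stratification and within-cluster reruns.

Population structure is the dominant confounder of a rare-variant carrier
test: if cases and controls draw from different ancestries, allele-frequency
differences masquerade as association.  The stratification here follows the
common exome workflow — common-variant dosages, mean-imputed and
standardized, reduced to principal components, embedded to two dimensions
with UMAP, and clustered density-wise — after which the full collapsing
scan is rerun inside a chosen cluster with internal allele frequencies
recomputed on the restricted cohort.  Self-reported ancestry labels are
carried for reporting only; clustering uses genotypes alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA

from genecollapse.cohort_io import GenotypeMatrix
from genecollapse.pipeline import CollapsingRun, run_collapsing


@dataclass
class AncestryClustering:
    """Per-sample cluster labels with the 2-d embedding they came from."""

    sample_ids: np.ndarray
    labels: np.ndarray
    embedding: np.ndarray
    seed: int

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def cluster_sizes(self, manifest: pd.DataFrame | None = None) -> pd.DataFrame:
        """Cluster-size table, split case/control when a manifest is given."""
        df = pd.DataFrame({"sample_id": self.sample_ids, "cluster": self.labels})
        if manifest is not None:
            df = df.merge(manifest[["sample_id", "phenotype"]], on="sample_id")
            out = df.pivot_table(index="cluster", columns="phenotype", values="sample_id",
                                 aggfunc="count", fill_value=0)
            out["total"] = out.sum(axis=1)
            return out.reset_index()
        return df.groupby("cluster").size().rename("total").reset_index()


def genotype_features(
    genotypes: GenotypeMatrix,
    min_af: float = 0.05,
    n_components: int = 10,
) -> np.ndarray:
    """Common-variant dosage features reduced to principal components.

    Variants with combined-cohort alternate-allele frequency >= ``min_af``
    are mean-imputed, centered, scaled to unit variance, and projected onto
    the top ``n_components`` principal axes.  Rare variants carry almost no
    ancestry information per site, hence the frequency floor.
    """
    doses = genotypes.doses.astype(float)
    missing = doses < 0
    doses[missing] = np.nan
    af = np.nanmean(doses, axis=0) / 2.0
    common = af >= min_af
    if not common.any():
        raise ValueError(f"no variants with combined AF >= {min_af}")
    x = doses[:, common]
    col_mean = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(col_mean, inds[1])
    x -= col_mean
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x /= sd
    k = min(n_components, x.shape[0] - 1, x.shape[1])
    return PCA(n_components=k, svd_solver="full").fit_transform(x)


def embed_and_cluster(
    features: np.ndarray,
    seed: int = 0,
    sample_ids=None,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    eps: float = 0.5,
    min_samples: int = 5,
) -> AncestryClustering:
    """UMAP 2-d embedding followed by density-based cluster calling.

    Deterministic for a fixed seed (UMAP runs single-threaded with a fixed
    random state).  DBSCAN noise points are assigned to the nearest cluster
    centroid; labels are relabeled contiguous from 0 in decreasing cluster
    size.  If density clustering finds no core cluster, all samples form
    cluster 0.
    """
    import umap  # deferred: numba compilation is slow at import time

    features = np.asarray(features, dtype=float)
    if features.shape[0] <= n_neighbors:
        raise ValueError("need more samples than the UMAP neighbors parameter")
    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed
    )
    emb = np.asarray(reducer.fit_transform(features), dtype=float)

    raw = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(emb)
    labels = _assign_noise_and_relabel(emb, raw)
    if sample_ids is None:
        sample_ids = np.arange(len(labels))
    return AncestryClustering(np.asarray(sample_ids, dtype=object), labels, emb, seed)


def _assign_noise_and_relabel(emb: np.ndarray, raw: np.ndarray) -> np.ndarray:
    labels = raw.copy()
    clusters = [c for c in np.unique(labels) if c >= 0]
    if not clusters:
        return np.zeros(len(labels), dtype=int)
    centroids = np.stack([emb[labels == c].mean(axis=0) for c in clusters])
    noise = labels < 0
    if noise.any():
        dist = np.linalg.norm(emb[noise, None, :] - centroids[None, :, :], axis=2)
        labels[noise] = np.asarray(clusters)[dist.argmin(axis=1)]
    # contiguous labels, largest cluster first (stable tie-break on old label)
    sizes = pd.Series(labels).value_counts().sort_index()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[c] for c in labels], dtype=int)


def filtered_analysis(
    clustering: AncestryClustering,
    cluster_id: int,
    variants: pd.DataFrame,
    genotypes: GenotypeMatrix,
    coverage: pd.DataFrame,
    manifest: pd.DataFrame,
    **run_kwargs,
) -> CollapsingRun:
    """Rerun the whole collapsing scan inside one ancestry cluster.

    Leave-one-out allele frequencies are recomputed within the restricted
    cohort, so a variant common in another cluster does not disqualify a
    cluster-private carrier.
    """
    members = clustering.sample_ids[clustering.labels == cluster_id]
    if len(members) == 0:
        raise ValueError(f"cluster {cluster_id} is empty")
    sub = manifest[manifest["sample_id"].isin(set(members))]
    if not (sub["phenotype"] == "case").any():
        raise ValueError(f"cluster {cluster_id} contains no cases")
    return run_collapsing(
        variants, genotypes, coverage, manifest, sample_subset=members, **run_kwargs
    )
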