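"""Outlier-driven sample QC and subtype reassignment.

Histological subtype calls on archival tumors are fallible. A sample that
poorly matches its assigned subtype betrays itself on the genes that
define that subtype: for each sample and each DEG specific to its
assigned subtype, the sample's log-normalized expression is checked
against the Tukey fences ``[Q1 - 1.5*IQR, Q3 + 1.5*IQR]`` computed over
all samples carrying the same label (type-7 quartiles, the sample
included). Samples whose outlier-DEG count is itself above the upper
Tukey fence of counts within their subtype are flagged.

Reassignment then removes the flagged samples, recomputes one-vs-rest
DEGs, takes the most variable DEGs per subtype, z-scores them and
hierarchically clusters *all* samples (Euclidean distance, complete
linkage, cut at k = number of subtypes). Each cluster is named by the
majority assigned subtype of its unflagged members and flagged samples
adopt their cluster's name. PCA and k-means views of the same gene
selections are provided as diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .de import DEGSets, common_and_specific, deg_count, one_vs_rest_degs
from .permutation import permute_deg_count
from .readwrite import (
    CountMatrix,
    ExpressionMatrix,
    log_normalized,
    zscore,
)

__all__ = [
    "OutlierCountTable",
    "ReassignmentReport",
    "count_outlier_degs",
    "reassign",
    "pca_view",
    "kmeans_view",
]


class UnresolvedClusterError(RuntimeError):
    """A cluster contains only flagged samples and cannot be named."""


def _tukey_fences(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row Tukey fences with type-7 (linear interpolation) quartiles."""
    q1 = np.percentile(values, 25, axis=1, method="linear")
    q3 = np.percentile(values, 75, axis=1, method="linear")
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


@dataclass
class OutlierCountTable:
    """Per-sample outlier-DEG counts and flags."""

    table: pd.DataFrame  # index sample_id; assigned_subtype, n_outlier_degs,
    #                      n_degs_tested, flagged

    @property
    def flagged(self) -> list[str]:
        return list(self.table.index[self.table["flagged"]])


def count_outlier_degs(
    em: ExpressionMatrix,
    deg_sets: DEGSets,
    labels: pd.Series,
    *,
    specific: bool = True,
) -> OutlierCountTable:
    """Count, per sample, the subtype DEGs on which it is a boxplot
    outlier within its own label group.

    Subtypes with fewer than 3 samples are skipped with zero counts and
    no flagging (quartiles need support).
    """
    labels = labels.loc[em.sample_ids]
    rows = []
    for st in sorted(labels.unique()):
        members = list(labels.index[labels == st])
        genes = sorted(
            g for g in deg_sets.degs(st, specific=specific)
            if g in em.gene_ids
        )
        if len(members) < 3 or not genes:
            for s in members:
                rows.append((s, st, 0, len(genes), False))
            continue
        vals = em.values.loc[genes, members].to_numpy(dtype=float)
        lo, hi = _tukey_fences(vals)
        outl = (vals < lo[:, None]) | (vals > hi[:, None])
        counts = outl.sum(axis=0)
        _, fence_hi = _tukey_fences(counts[None, :].astype(float))
        for s, c in zip(members, counts):
            rows.append((s, st, int(c), len(genes), bool(c > fence_hi[0])))
    table = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "assigned_subtype", "n_outlier_degs",
            "n_degs_tested", "flagged",
        ],
    ).set_index("sample_id").loc[em.sample_ids]
    return OutlierCountTable(table)


@dataclass
class ReassignmentReport:
    removed_samples: list[str]
    new_labels: pd.Series  # every sample, including removed ones
    deg_counts_before: dict[str, int]
    deg_counts_after: dict[str, int]
    p_before: dict[str, float] = field(default_factory=dict)
    p_after: dict[str, float] = field(default_factory=dict)
    changed: dict[str, tuple[str, str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "removed_samples": self.removed_samples,
            "new_labels": self.new_labels.to_dict(),
            "deg_counts_before": self.deg_counts_before,
            "deg_counts_after": self.deg_counts_after,
            "p_before": self.p_before,
            "p_after": self.p_after,
            "changed": {s: list(v) for s, v in self.changed.items()},
        }


def reassign(
    cm: CountMatrix,
    flagged: list[str],
    k_per_type: int = 185,
    *,
    n_perm: int | None = None,
    seed: int = 0,
    de_kwargs: dict | None = None,
) -> ReassignmentReport:
    """Remove flagged samples, recompute DEGs, and reassign every sample
    by hierarchical clustering on the top variable DEGs per subtype.

    With ``n_perm`` set, permutation p-values of the per-subtype DEG
    counts are reported before and after reassignment.
    """
    de_kwargs = de_kwargs or {}
    flagged = list(flagged)
    unknown = set(flagged) - set(cm.sample_ids)
    if unknown:
        raise ValueError(f"flagged samples not in matrix: {sorted(unknown)}")
    labels = cm.subtypes
    subtypes = sorted(labels.unique())
    keep = [s for s in cm.sample_ids if s not in flagged]
    kept_labels = labels.loc[keep]
    low = kept_labels.value_counts().reindex(subtypes).fillna(0)
    if (low < 2).any():
        raise ValueError(
            "every subtype must retain >= 2 samples after removing "
            f"flagged ones (got {low.to_dict()})"
        )

    tables_before = one_vs_rest_degs(cm, **de_kwargs)
    counts_before = {st: deg_count(t) for st, t in tables_before.items()}

    cm_kept = cm.subset_samples(keep)
    tables_wo = one_vs_rest_degs(cm_kept, **de_kwargs)

    em = log_normalized(cm)  # variability measured across all samples
    gene_var = em.values.var(axis=1, ddof=1)
    union: list[str] = []
    for st in subtypes:
        tab = tables_wo[st]
        degs = tab.index[tab["is_deg"]]
        top = gene_var.loc[degs].sort_values(ascending=False)
        union.extend(top.index[:k_per_type])
    union = sorted(set(union))
    if len(union) < 2:
        raise ValueError(
            "fewer than 2 variable DEGs available for clustering; "
            "the contrasts yielded no usable gene panel"
        )

    z = zscore(ExpressionMatrix(em.values.loc[union], em.transform_tag))
    X = z.values.to_numpy(dtype=float).T  # samples x genes
    Z = linkage(X, method="complete", metric="euclidean")
    cluster_ids = fcluster(Z, t=len(subtypes), criterion="maxclust")

    new_labels = labels.copy()
    changed: dict[str, tuple[str, str]] = {}
    for cl in np.unique(cluster_ids):
        members = [s for s, c in zip(cm.sample_ids, cluster_ids) if c == cl]
        anchors = [s for s in members if s not in flagged]
        if not anchors:
            raise UnresolvedClusterError(
                f"cluster {cl} contains only flagged samples "
                f"({members}); cannot name it"
            )
        counts = labels.loc[anchors].value_counts()
        top = counts[counts == counts.max()].index.sort_values()[0]
        for s in members:
            if s in flagged and labels.loc[s] != top:
                changed[s] = (labels.loc[s], top)
            new_labels.loc[s] = top if s in flagged else labels.loc[s]

    cm_new = cm.relabel(
        {s: lab for s, (_, lab) in changed.items()}
    )
    tables_after = one_vs_rest_degs(cm_new, **de_kwargs)
    counts_after = {st: deg_count(t) for st, t in tables_after.items()}

    p_before: dict[str, float] = {}
    p_after: dict[str, float] = {}
    if n_perm is not None:
        if n_perm < 19:
            raise ValueError("n_perm must be >= 19")
        for i, st in enumerate(subtypes):
            p_before[st] = permute_deg_count(
                cm, st, n_perm=n_perm, seed=seed + i
            ).p_empirical
            p_after[st] = permute_deg_count(
                cm_new, st, n_perm=n_perm, seed=seed + i
            ).p_empirical

    return ReassignmentReport(
        removed_samples=flagged,
        new_labels=cm_new.subtypes.copy(),
        deg_counts_before=counts_before,
        deg_counts_after=counts_after,
        p_before=p_before,
        p_after=p_after,
        changed=changed,
    )


def pca_view(
    em: ExpressionMatrix, gene_list: list[str], n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on z-scored selected genes.

    Returns sample coordinates (columns ``PC1..``) and the explained
    variance fraction per component.
    """
    genes = [g for g in gene_list if g in em.gene_ids]
    if len(genes) < 2:
        raise ValueError("need at least 2 selected genes for PCA")
    if len(em.sample_ids) < 2:
        raise ValueError("need at least 2 samples for PCA")
    z = zscore(ExpressionMatrix(em.values.loc[genes], em.transform_tag))
    X = z.values.to_numpy(dtype=float).T
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    df = pd.DataFrame(
        coords, index=em.sample_ids,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return df, pca.explained_variance_ratio_


def kmeans_view(
    em: ExpressionMatrix, gene_list: list[str], k: int = 3,
    seed: int = 0, n_restarts: int = 25,
) -> pd.Series:
    """Seeded k-means clustering of samples on z-scored selected genes."""
    genes = [g for g in gene_list if g in em.gene_ids]
    if len(genes) < 2:
        raise ValueError("need at least 2 selected genes for k-means")
    z = zscore(ExpressionMatrix(em.values.loc[genes], em.transform_tag))
    X = z.values.to_numpy(dtype=float).T
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    return pd.Series(km.fit_predict(X), index=em.sample_ids, name="cluster")
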