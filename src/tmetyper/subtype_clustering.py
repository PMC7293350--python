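"""Unsupervised subtype discovery and cohort inclusion rules.

Samples are clustered by complete-linkage agglomeration on the most
variable genes (Euclidean distance on variance-stabilized values by
default, correlation distance behind a flag), the tree is cut at k = 2
and k = 3, and a cohort is retained only when the cut cleanly separates
two candidate cancer subtypes:

* at k = 2, both clusters must contain at least ``min_cancer_cluster``
  cancer samples and at least ``control_purity_threshold`` of the
  controls must sit in a single cluster (controls co-clustering with
  one subtype is expected, not disqualifying);
* failing that, at k = 3 one cluster must be control-dominant and the
  other two cancer-dominant with enough cancer samples each;
* otherwise the cohort is excluded: ``excluded_controls_split`` when
  the controls scatter across clusters at both cuts,
  ``excluded_singleton_cluster`` when a would-be subtype holds too few
  cancer samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import chi2
from sklearn.decomposition import PCA

from .preprocess import NormalizedMatrix

__all__ = [
    "Dendrogram",
    "SubtypeDecision",
    "PcaEmbedding",
    "hierarchical_cluster",
    "cut_tree",
    "evaluate_separability",
    "pca_embed",
]

DEFAULT_CONTROL_PURITY = 0.9
DEFAULT_MIN_CANCER = 2


@dataclass
class Dendrogram:
    """Complete-linkage merge tree over samples.

    ``linkage`` is the scipy linkage matrix (step, left, right, height,
    size); ``sample_ids`` maps leaf order to sample identifiers.
    """

    linkage: np.ndarray
    sample_ids: pd.Index
    metric: str

    def merge_table(self) -> pd.DataFrame:
        n = self.linkage.shape[0]
        return pd.DataFrame(
            {
                "step": np.arange(n),
                "left": self.linkage[:, 0].astype(int),
                "right": self.linkage[:, 1].astype(int),
                "height": self.linkage[:, 2],
                "size": self.linkage[:, 3].astype(int),
            }
        )


@dataclass
class SubtypeDecision:
    """Per-cohort clustering outcome and inclusion status."""

    cancer_type: str
    chosen_k: int | None
    cluster_labels: pd.Series
    status: str
    cancer_cluster_ids: tuple[int, ...] = ()
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.status == "included") != (self.chosen_k is not None):
            raise ValueError("chosen_k must be set iff status is 'included'")


@dataclass
class PcaEmbedding:
    """Sample scores on the leading principal components.

    ``ellipses`` holds per-group 95% confidence-ellipsoid parameters
    (mean vector, covariance, chi-square radius) for plotting.
    """

    coordinates: pd.DataFrame  # samples x PC1..PCk
    explained_variance_ratio: np.ndarray
    ellipses: dict[str, dict] = field(default_factory=dict)


def _submatrix(matrix: NormalizedMatrix, gene_subset) -> pd.DataFrame:
    gene_subset = list(gene_subset)
    if len(gene_subset) == 0:
        raise ValueError("gene_subset is empty")
    missing = [g for g in gene_subset if g not in matrix.gene_ids]
    if missing:
        raise ValueError(f"gene {missing[0]!r} not present in matrix")
    return matrix.values.loc[gene_subset]


def hierarchical_cluster(
    matrix: NormalizedMatrix, gene_subset, metric: str = "euclidean"
) -> Dendrogram:
    """Complete-linkage dendrogram over samples on a gene subset.

    ``metric`` is ``"euclidean"`` (default) or ``"correlation"``
    (1 - Pearson). Deterministic for fixed input.
    """
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"unknown metric {metric!r}")
    sub = _submatrix(matrix, gene_subset)
    if sub.columns.has_duplicates:
        raise ValueError("duplicate sample ids")
    if sub.shape[1] < 3:
        raise ValueError("clustering needs at least 3 samples")
    dists = pdist(sub.to_numpy(dtype=float).T, metric=metric)
    linkage = hierarchy.linkage(dists, method="complete")
    return Dendrogram(linkage=linkage, sample_ids=sub.columns, metric=metric)


def cut_tree(dendrogram: Dendrogram, k: int) -> pd.Series:
    """Partition samples into k clusters by cutting the merge tree.

    Labels are arbitrary but stable integers (0..k-1). Cuts are nested:
    every k+1 cluster refines some k cluster.
    """
    n = len(dendrogram.sample_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    labels = hierarchy.cut_tree(dendrogram.linkage, n_clusters=k).ravel()
    return pd.Series(labels, index=dendrogram.sample_ids, name=f"k{k}")


def _cluster_stats(labels: pd.Series, is_control: pd.Series):
    """Per-cluster cancer/control counts plus the controls' modal share."""
    df = pd.DataFrame({"label": labels, "control": is_control})
    cancer = df[~df["control"]].groupby("label").size()
    control = df[df["control"]].groupby("label").size()
    clusters = sorted(labels.unique())
    cancer = cancer.reindex(clusters, fill_value=0)
    control = control.reindex(clusters, fill_value=0)
    n_controls = int(control.sum())
    if n_controls > 0:
        host = int(control.idxmax())
        purity = float(control.max() / n_controls)
    else:
        host, purity = None, np.nan
    return cancer, control, host, purity


def evaluate_separability(
    labels_k2: pd.Series,
    labels_k3: pd.Series,
    is_control,
    control_purity_threshold: float = DEFAULT_CONTROL_PURITY,
    min_cancer_cluster: int = DEFAULT_MIN_CANCER,
    cancer_type: str = "",
) -> SubtypeDecision:
    """Apply the inclusion/exclusion rules to the k = 2 and k = 3 cuts.

    Preference order is k = 2 then k = 3. At k = 2 the controls' host
    cluster may still be a candidate subtype; at k = 3 the two
    candidate subtypes are the cancer-dominant clusters outside the
    control-dominant one. Cohorts with no controls are decided on the
    cancer clusters alone, with a warning.
    """
    if not labels_k2.index.equals(labels_k3.index):
        raise ValueError("k=2 and k=3 labels cover different samples")
    is_control = pd.Series(
        np.asarray(is_control, dtype=bool), index=labels_k2.index
    )
    notes: list[str] = []
    n_controls = int(is_control.sum())
    if n_controls == 0:
        warnings.warn(
            "no controls present; deciding on cancer clusters only", stacklevel=2
        )
        notes.append("no controls; control-purity rule skipped")

    control_ok_somewhere = n_controls == 0

    # k = 2: two candidate subtypes, controls concentrated in one cluster.
    cancer2, control2, host2, purity2 = _cluster_stats(labels_k2, is_control)
    ok_controls2 = n_controls == 0 or purity2 >= control_purity_threshold
    control_ok_somewhere |= ok_controls2
    if ok_controls2 and (cancer2 >= min_cancer_cluster).all() and len(cancer2) == 2:
        notes.append(f"k=2 accepted (control purity {purity2:.2f})" if n_controls
                     else "k=2 accepted (no controls)")
        return SubtypeDecision(
            cancer_type=cancer_type,
            chosen_k=2,
            cluster_labels=labels_k2,
            status="included",
            cancer_cluster_ids=tuple(int(c) for c in cancer2.index),
            notes=notes,
        )

    # k = 3: one control-dominant cluster, two cancer-dominant candidates.
    cancer3, control3, host3, purity3 = _cluster_stats(labels_k3, is_control)
    if n_controls > 0:
        ok_controls3 = purity3 >= control_purity_threshold
        candidates = [c for c in cancer3.index if c != host3]
        host_dominant = control3[host3] > cancer3[host3]
    else:
        ok_controls3 = True
        candidates = list(cancer3.sort_values(ascending=False).index[:2])
        host_dominant = True
    control_ok_somewhere |= ok_controls3
    cand_dominant = all(
        cancer3[c] > control3[c] for c in candidates
    ) if n_controls > 0 else True
    if (
        ok_controls3
        and host_dominant
        and cand_dominant
        and len(candidates) == 2
        and all(cancer3[c] >= min_cancer_cluster for c in candidates)
    ):
        notes.append(f"k=3 accepted (control purity {purity3:.2f})" if n_controls
                     else "k=3 accepted (no controls)")
        return SubtypeDecision(
            cancer_type=cancer_type,
            chosen_k=3,
            cluster_labels=labels_k3,
            status="included",
            cancer_cluster_ids=tuple(int(c) for c in candidates),
            notes=notes,
        )

    if not control_ok_somewhere:
        status = "excluded_controls_split"
        notes.append(
            f"controls split across clusters (purity {purity2:.2f} at k=2, "
            f"{purity3:.2f} at k=3)"
        )
    else:
        status = "excluded_singleton_cluster"
        notes.append(
            "a candidate cancer cluster holds fewer than "
            f"{min_cancer_cluster} cancer samples at every accepted cut"
        )
    return SubtypeDecision(
        cancer_type=cancer_type,
        chosen_k=None,
        cluster_labels=labels_k2,
        status=status,
        cancer_cluster_ids=(),
        notes=notes,
    )


def pca_embed(
    matrix: NormalizedMatrix,
    gene_subset,
    n_components: int = 3,
    groups: pd.Series | None = None,
) -> PcaEmbedding:
    """Project samples onto the leading principal components.

    Genes are mean-centered; components are ordered by decreasing
    explained variance and sample scores have zero mean. If the data
    rank is below ``n_components`` the available components are
    returned with a warning. ``groups`` adds per-group 95%
    confidence-ellipsoid parameters (mean, covariance, chi-square
    radius on the first two components).
    """
    sub = _submatrix(matrix, gene_subset)
    x = sub.to_numpy(dtype=float).T  # samples x genes
    max_rank = min(x.shape)
    k = min(n_components, max_rank)
    if k < n_components:
        warnings.warn(
            f"rank supports only {k} of {n_components} requested components",
            stacklevel=2,
        )
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    coords = pd.DataFrame(
        scores, index=sub.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    ellipses: dict[str, dict] = {}
    if groups is not None and k >= 2:
        groups = pd.Series(groups, index=coords.index)
        radius = float(np.sqrt(chi2.ppf(0.95, df=2)))
        for level, members in coords.groupby(groups):
            pts = members[["PC1", "PC2"]].to_numpy()
            if pts.shape[0] < 3:
                continue
            ellipses[str(level)] = {
                "mean": pts.mean(axis=0),
                "cov": np.cov(pts.T),
                "radius": radius,
            }
    return PcaEmbedding(
        coordinates=coords,
        explained_variance_ratio=pca.explained_variance_ratio_,
        ellipses=ellipses,
    )
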