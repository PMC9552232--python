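"""Abundance-profile clustering and ordination.

The exploratory core of the comparison: replicate-averaged, row-centered
log2 LFQ profiles (one column per preparation method) are clustered by
k-means over a range of k; the number of clusters is chosen at the
elbow of the within-cluster sum of squares (SSW) curve, operationalized
as the k with the largest second forward difference.  Cluster summaries
(mean centered profile per cluster and method) feed a heatmap and an
average-linkage (UPGMA) dendrogram, whose cophenetic distances are
ultrametric by construction.  Sample-level PCA provides the replicate-
resolution ordination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .design_io import SampleDesign
from .preprocess import LogIntensityMatrix

logger = logging.getLogger(__name__)


class ClusteringError(ValueError):
    pass


# ---------------------------------------------------------------------------
# profile construction
# ---------------------------------------------------------------------------


def average_replicates(
    matrix: LogIntensityMatrix | pd.DataFrame, design: SampleDesign
) -> pd.DataFrame:
    """Per-protein mean over each method's replicates (proteins x methods)."""
    values = matrix.values if isinstance(matrix, LogIntensityMatrix) else matrix
    out = pd.DataFrame(index=values.index)
    for method in design.methods:
        cols = design.samples_of(method)
        out[method] = values[cols].mean(axis=1)
    return out


def center_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each row's mean (center normalization of log2 profiles)."""
    return matrix.sub(matrix.mean(axis=1), axis=0)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PcaResult:
    """Scores (samples x components), loadings and variance fractions."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


def run_pca(sample_matrix: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """PCA with samples as observations and proteins as variables.

    Variables are mean-centered but not scaled, matching PCA on log2
    LFQ intensities after imputation.
    """
    if len(sample_matrix) < 2:
        raise ClusteringError("PCA needs at least 2 samples")
    k = n_components or min(len(sample_matrix) - 1, sample_matrix.shape[1])
    pca = PCA(n_components=k)
    scores = pca.fit_transform(sample_matrix.to_numpy(float))
    comp_names = [f"PC{i + 1}" for i in range(pca.n_components_)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=sample_matrix.index, columns=comp_names),
        loadings=pd.DataFrame(
            pca.components_.T, index=sample_matrix.columns, columns=comp_names
        ),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


# ---------------------------------------------------------------------------
# k-means sweep and k selection
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    """A fitted k-means model over centered profiles.

    ``assignments`` maps each protein to a cluster label 1..k; ``centers``
    holds the cluster centers in centered log2 units (k x methods).
    ``ssw`` is the total within-cluster sum of squares (the k-means
    objective) of the best restart.
    """

    k: int
    assignments: pd.Series
    centers: pd.DataFrame
    ssw: float
    restarts: int
    seed: int

    def recomputed_ssw(self, matrix: pd.DataFrame) -> float:
        x = matrix.to_numpy(float)
        c = self.centers.to_numpy(float)[self.assignments.to_numpy() - 1]
        return float(((x - c) ** 2).sum())

    def sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index().rename("n")


@dataclass
class KMeansSweep:
    """Best-of-restarts models for each k, plus the SSW curve."""

    models: Mapping[int, ClusterModel]
    ssw_curve: pd.Series  # index k, value SSW
    restarts: int
    seed: int

    def select_k(self, override: int | None = None) -> tuple[int, dict]:
        return select_k(self.ssw_curve, override=override)


def _fit_kmeans(
    x: np.ndarray, k: int, restarts: int, seed: int
) -> tuple[np.ndarray, np.ndarray, float]:
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(x)
    return labels, km.cluster_centers_, float(km.inertia_)


def sweep_kmeans(
    centered_matrix: pd.DataFrame,
    k_range: Sequence[int] = range(2, 16),
    restarts: int = 25,
    seed: int = 0,
) -> KMeansSweep:
    """Run k-means (k-means++ init, Euclidean objective) for each k.

    For each k the best of ``restarts`` restarts by SSW is kept.  If a
    larger k ever lands above the previous SSW (a restart artifact), an
    extra run seeded from the previous solution — splitting off the
    point worst-served by its center — restores monotonicity.
    """
    x = centered_matrix.to_numpy(float)
    n = len(x)
    models: dict[int, ClusterModel] = {}
    ssw: dict[int, float] = {}
    prev: tuple[np.ndarray, np.ndarray, float] | None = None
    for k in k_range:
        if k > n:
            logger.warning("k=%d exceeds %d points; skipped", k, n)
            continue
        labels, centers, inertia = _fit_kmeans(x, k, restarts, seed)
        if prev is not None and inertia > prev[2] + 1e-9:
            p_labels, p_centers, _ = prev
            dist = ((x - p_centers[p_labels]) ** 2).sum(axis=1)
            init = np.vstack([p_centers, x[np.argmax(dist)]])[:k]
            km = KMeans(n_clusters=k, n_init=1, init=init)
            lab2 = km.fit_predict(x)
            if km.inertia_ < inertia:
                labels, centers, inertia = lab2, km.cluster_centers_, float(km.inertia_)
        models[k] = ClusterModel(
            k=k,
            assignments=pd.Series(labels + 1, index=centered_matrix.index,
                                  name="cluster"),
            centers=pd.DataFrame(centers, columns=centered_matrix.columns,
                                 index=pd.RangeIndex(1, k + 1, name="cluster")),
            ssw=inertia,
            restarts=restarts,
            seed=seed,
        )
        ssw[k] = inertia
        prev = (labels, centers, inertia)
    curve = pd.Series(ssw, name="ssw").sort_index()
    curve.index.name = "k"
    return KMeansSweep(models=models, ssw_curve=curve, restarts=restarts, seed=seed)


def select_k(ssw_curve: pd.Series, override: int | None = None) -> tuple[int, dict]:
    """Elbow selection on the SSW curve.

    The elbow is the k maximizing the second forward difference
    ``ssw[k-1] - 2 ssw[k] + ssw[k+1]`` (the kink where the curve stops
    dropping).  A flat curve — maximum relative per-step drop below 1% —
    returns the smallest k with a ``no_elbow`` flag.  An explicit
    ``override`` always wins (the study's own data used k = 9).
    """
    if override is not None:
        return int(override), {"rule": "override", "no_elbow": False}
    ks = list(ssw_curve.index)
    if len(ks) < 4 or ks != list(range(ks[0], ks[0] + len(ks))):
        raise ClusteringError("need >=4 consecutive k values in the SSW curve")
    vals = ssw_curve.to_numpy(float)
    drops = (vals[:-1] - vals[1:]) / np.where(vals[:-1] > 0, vals[:-1], 1.0)
    if drops.max() < 0.01:
        logger.warning("flat SSW curve: no elbow; returning k_min=%d", ks[0])
        return ks[0], {"rule": "flat", "no_elbow": True}
    second = vals[:-2] - 2 * vals[1:-1] + vals[2:]
    k_sel = ks[1 + int(np.argmax(second))]
    return int(k_sel), {
        "rule": "max_second_difference",
        "no_elbow": False,
        "second_differences": dict(zip(ks[1:-1], second.tolist())),
    }


# ---------------------------------------------------------------------------
# cluster summaries and dendrogram
# ---------------------------------------------------------------------------


def cluster_summaries(
    model: ClusterModel, centered_matrix: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Mean centered profile per cluster and method, plus cluster sizes."""
    heat = centered_matrix.groupby(model.assignments).mean()
    heat.index.name = "cluster"
    return heat, model.sizes()


@dataclass(frozen=True)
class DendrogramResult:
    """UPGMA tree over cluster profiles; cophenetic distances are ultrametric."""

    linkage: np.ndarray
    newick: str
    cophenetic: pd.DataFrame
    leaf_labels: tuple[str, ...]


def cluster_dendrogram(heatmap: pd.DataFrame) -> DendrogramResult:
    """Average-linkage hierarchy on Euclidean distances between cluster rows."""
    if len(heatmap) < 2:
        raise ClusteringError("need at least 2 clusters for a dendrogram")
    labels = tuple(str(i) for i in heatmap.index)
    dist = ssd.pdist(heatmap.to_numpy(float), metric="euclidean")
    linkage = sch.linkage(dist, method="average")
    coph = ssd.squareform(sch.cophenet(linkage))
    cophenetic = pd.DataFrame(coph, index=heatmap.index, columns=heatmap.index)
    newick = _to_newick(sch.to_tree(linkage), labels)
    return DendrogramResult(
        linkage=linkage, newick=newick, cophenetic=cophenetic, leaf_labels=labels
    )


def _to_newick(node: sch.ClusterNode, labels: Sequence[str]) -> str:
    def fmt(n: sch.ClusterNode, parent_height: float) -> str:
        length = parent_height - (0.0 if n.is_leaf() else n.dist)
        if n.is_leaf():
            return f"{labels[n.id]}:{parent_height:.6g}"
        left = fmt(n.left, n.dist)
        right = fmt(n.right, n.dist)
        return f"({left},{right}):{length:.6g}"

    body = fmt(node, node.dist).rsplit(":", 1)[0]
    return body + ";"
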