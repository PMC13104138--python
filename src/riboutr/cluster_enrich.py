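"""TE coexpression clustering, stage dendrograms and hypergeometric enrichment.

Gene TE profiles are max-normalized per gene (each row divided by its
maximum over the stages) and clustered with seeded k-means (k = 18,
iter.max = 30, seed = 19960912 by default).  Stage similarity uses UPGMA
(average linkage) on Euclidean distances between stage columns.  Set
enrichment is the upper-tail hypergeometric test with Benjamini-Hochberg
adjustment across terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import kmeans_plusplus
from statsmodels.stats.multitest import multipletests

KMEANS_K = 18
KMEANS_MAX_ITER = 30
KMEANS_SEED = 19960912


def normalize_profiles(profiles: pd.DataFrame, min_value: float = 1.0,
                       filter_on: pd.DataFrame | None = None
                       ) -> tuple[pd.DataFrame, list[str]]:
    """Row-wise max-normalization of gene x stage profiles into [0, 1].

    Genes whose minimum over stages in ``filter_on`` (default: the profile
    matrix itself) does not exceed ``min_value`` are dropped, as are all-zero
    rows; the dropped gene ids are returned alongside the matrix.
    """
    basis = profiles if filter_on is None else filter_on.loc[profiles.index]
    keep = basis.min(axis=1) > min_value
    excluded = list(profiles.index[~keep])
    mat = profiles.loc[keep]
    row_max = mat.max(axis=1)
    zero = row_max <= 0
    excluded += list(mat.index[zero])
    mat = mat.loc[~zero]
    return mat.div(mat.max(axis=1), axis=0), excluded


@dataclass
class ClusterResult:
    k: int
    seed: int
    max_iter: int
    assignments: pd.Series            # gene -> cluster id
    centroids: pd.DataFrame           # cluster x stage
    inertia_path: list[float]         # within-cluster SS after each iteration
    phase_of_cluster: dict[int, str | None] = field(default_factory=dict)


def kmeans_te(matrix: pd.DataFrame, k: int = KMEANS_K,
              max_iter: int = KMEANS_MAX_ITER, seed: int = KMEANS_SEED,
              phase_map: dict[str, str] | None = None,
              phase_margin: float = 0.2) -> ClusterResult:
    """Seeded k-means (k-means++ init, Lloyd iterations, fixed cap).

    Deterministic for a fixed seed.  When ``phase_map`` is given, a cluster
    is called phase-specific if its centroid maximum falls in one phase's
    stages and the centroid mean inside that phase exceeds the mean over the
    other stages by ``phase_margin``.
    """
    X = matrix.to_numpy(dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of rows ({n})")
    centers, _ = kmeans_plusplus(X, n_clusters=k, random_state=seed)
    labels = np.zeros(n, dtype=int)
    inertia_path: list[float] = []
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        for c in range(k):
            members = X[new_labels == c]
            if len(members):
                centers[c] = members.mean(axis=0)
        inertia = float(((X - centers[new_labels]) ** 2).sum())
        converged = bool((new_labels == labels).all()) and inertia_path \
            and inertia_path[-1] == inertia
        labels = new_labels
        inertia_path.append(inertia)
        if converged:
            break
    assignments = pd.Series(labels, index=matrix.index, name="cluster")
    centroids = pd.DataFrame(centers, columns=matrix.columns)
    centroids.index.name = "cluster"
    res = ClusterResult(k=k, seed=seed, max_iter=max_iter,
                        assignments=assignments, centroids=centroids,
                        inertia_path=inertia_path)
    if phase_map:
        stages = list(matrix.columns)
        for c in range(k):
            prof = centroids.loc[c]
            top_phase = phase_map.get(stages[int(np.argmax(prof.to_numpy()))])
            inside = [s for s in stages if phase_map.get(s) == top_phase]
            outside = [s for s in stages if phase_map.get(s) != top_phase]
            if inside and outside and \
                    prof[inside].mean() - prof[outside].mean() >= phase_margin:
                res.phase_of_cluster[c] = top_phase
            else:
                res.phase_of_cluster[c] = None
    return res


@dataclass
class StageDendrogram:
    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix (merge order + heights)

    def newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            kids = ",".join(fmt(c, node.dist) for c in (node.left, node.right))
            return f"({kids}):{length:.6g}"

        return fmt(tree, tree.dist) + ";"


def hclust_stages(matrix: pd.DataFrame) -> StageDendrogram:
    """UPGMA dendrogram of the stage columns under Euclidean distance.

    Ties are resolved deterministically by column order (scipy's stable
    merge ordering on the condensed distance matrix).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two stage columns")
    d = pdist(matrix.T.to_numpy(dtype=float), metric="euclidean")
    Z = hierarchy.linkage(d, method="average")
    return StageDendrogram(labels=list(matrix.columns), linkage=Z)


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P[X >= k] for X ~ Hypergeom(N population, K marked, n drawn)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(gene_set: set, annotation: dict[str, set],
                     background: set) -> pd.DataFrame:
    """Term enrichment of ``gene_set`` against ``background``.

    Each term's annotated genes are intersected with the background; the
    upper-tail hypergeometric p-value is BH-adjusted across terms.  Stars
    mark raw p < 0.05 (*) and < 0.01 (**).
    """
    if not background:
        raise ValueError("background gene set is empty")
    if not gene_set <= background:
        raise ValueError("gene_set must be a subset of background")
    N = len(background)
    n = len(gene_set)
    rows = []
    for term in sorted(annotation):
        marked = annotation[term] & background
        K = len(marked)
        k = len(marked & gene_set)
        p = hypergeom_pvalue(N, K, n, k)
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    df = pd.DataFrame(rows).set_index("term")
    if len(df):
        df["adj_p"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df["stars"] = np.select([df["p"] < 0.01, df["p"] < 0.05],
                                ["**", "*"], default="")
    return df
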