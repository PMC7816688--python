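"""Hierarchical clustering on principal components (HCPC) of SNP frequencies.

Isolates are clustered on their full alternative-frequency profiles in four
steps: (1) PCA of the isolates x positions frequency matrix for noise
reduction, (2) Ward agglomeration on the retained component scores, (3)
cutting the tree at a chosen number of clusters (the inertia-gain sequence
suggests one), and (4) k-means consolidation initialised at the cut
clusters' centroids.  Because the initialisation is deterministic, the whole
pipeline is seed-free; consolidation can only decrease within-cluster
inertia.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.cluster.hierarchy import to_tree
from sklearn.cluster import KMeans


def frequency_matrix(fm) -> pd.DataFrame:
    """Isolates x positions alternative-frequency matrix (values in [0, 1]).

    Cells where an isolate shows no alternative reads are informative zeros,
    not missing data.
    """
    df = pd.DataFrame(
        fm.f_alt.T, index=list(fm.isolates),
        columns=[int(p) for p in fm.positions],
    )
    return df


@dataclass(frozen=True)
class PcaResult:
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    cumulative_percent: np.ndarray
    scores: pd.DataFrame  # isolates x components
    loadings: np.ndarray  # components x variables
    n_components: int

    def cumulative_at(self, n: int) -> float:
        n = min(n, self.n_components)
        return float(self.cumulative_percent[n - 1])


def run_pca(freq: pd.DataFrame, scale: bool = True) -> PcaResult:
    """Centered (and optionally unit-variance) PCA with a fixed sign convention.

    Zero-variance columns are dropped (with a warning) when scaling; the sign
    of each component is chosen so its largest-magnitude loading is positive.
    """
    if freq.shape[0] < 2 or freq.shape[1] < 2:
        raise ValueError("need at least 2 isolates and 2 positions")
    X = freq.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=0)
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance position(s) "
                "before unit-variance scaling"
            )
            X = X[:, keep]
            sd = sd[keep]
        X = X / sd
    n = X.shape[0]
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    ncomp = int((S > S[0] * 1e-12).sum()) if S.size else 0
    U, S, Vt = U[:, :ncomp], S[:ncomp], Vt[:ncomp]
    # deterministic sign: largest-magnitude loading positive per component
    for k in range(ncomp):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    eig = S**2 / n  # population convention
    percent = 100.0 * eig / eig.sum()
    scores = pd.DataFrame(
        U * S, index=freq.index,
        columns=[f"PC{k + 1}" for k in range(ncomp)],
    )
    return PcaResult(
        eigenvalues=eig,
        percent_variance=percent,
        cumulative_percent=np.cumsum(percent),
        scores=scores,
        loadings=Vt,
        n_components=ncomp,
    )


@dataclass(frozen=True)
class HclustResult:
    linkage: np.ndarray
    labels: tuple[str, ...]
    inertia_gains: np.ndarray  # gain of allowing k clusters, index k-2 => k
    suggested_k: int
    scores: pd.DataFrame
    n_components: int


def hierarchical_cluster(pca: PcaResult, n_components: int = 7) -> HclustResult:
    """Ward agglomeration on the first ``n_components`` PCA scores.

    The within-inertia increase of each merge (Ward.D2 height squared over
    two) read back-to-front is the gain of allowing k instead of k-1
    clusters; the suggested k maximises the drop-off ratio of successive
    gains.
    """
    if n_components > pca.n_components:
        raise ValueError(
            f"{n_components} components requested, only {pca.n_components} available"
        )
    scores = pca.scores.iloc[:, :n_components]
    Z = linkage(scores.to_numpy(), method="ward")
    n = scores.shape[0]
    heights = Z[:, 2]
    # gains[k-2] = inertia gained by going from k-1 to k clusters (k=2..n)
    gains = (heights[::-1] ** 2) / 2.0
    suggested = 2
    if n > 3 and (gains[1:] > 0).any():
        ratios = gains[:-1] / np.where(gains[1:] > 0, gains[1:], np.nan)
        # conventional HCPC practice searches a small-k window only; at large
        # k the gains are noise and their ratios are meaningless
        window = ratios[: min(9, len(ratios))]
        if not np.isnan(window).all():
            suggested = int(np.nanargmax(window)) + 2
    return HclustResult(
        linkage=Z,
        labels=tuple(scores.index),
        inertia_gains=gains,
        suggested_k=suggested,
        scores=scores,
        n_components=n_components,
    )


@dataclass(frozen=True)
class HcpcResult:
    assignments_tree: pd.Series
    assignments: pd.Series  # after k-means consolidation
    k: int
    cluster_centers: np.ndarray
    inertia_tree: float
    inertia_consolidated: float
    factor_map: pd.DataFrame  # first two component coordinates
    hclust: HclustResult


def _within_inertia(X: np.ndarray, assign: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(assign):
        pts = X[assign == c]
        total += ((pts - pts.mean(axis=0)) ** 2).sum()
    return float(total)


def cut_and_consolidate(hclust: HclustResult, k: int = 6) -> HcpcResult:
    """Cut the Ward tree at k clusters and consolidate with k-means.

    k-means is initialised at the cut clusters' centroids (one run, no
    random restarts), which makes the step deterministic and guarantees the
    consolidated partition has within-cluster inertia no larger than the
    tree partition.
    """
    X = hclust.scores.to_numpy()
    n = X.shape[0]
    if not 1 < k <= n:
        raise ValueError(f"k must be in (1, {n}]")
    tree_assign = fcluster(hclust.linkage, t=k, criterion="maxclust")
    centers = np.stack([X[tree_assign == c].mean(axis=0)
                        for c in np.unique(tree_assign)])
    if len(centers) == n:  # singleton clusters: consolidation is identity
        consolidated = tree_assign.copy()
        final_centers = centers
    else:
        km = KMeans(n_clusters=len(centers), init=centers, n_init=1,
                    max_iter=300)
        consolidated = km.fit_predict(X) + 1
        final_centers = km.cluster_centers_
    index = list(hclust.labels)
    factor = hclust.scores.iloc[:, : min(2, hclust.scores.shape[1])].copy()
    return HcpcResult(
        assignments_tree=pd.Series(tree_assign, index=index, name="tree"),
        assignments=pd.Series(consolidated, index=index, name="consolidated"),
        k=k,
        cluster_centers=final_centers,
        inertia_tree=_within_inertia(X, tree_assign),
        inertia_consolidated=_within_inertia(X, np.asarray(consolidated)),
        factor_map=factor,
        hclust=hclust,
    )


def co_clustered(result: HcpcResult, a: str, b: str) -> bool:
    return int(result.assignments[a]) == int(result.assignments[b])


# ---------------------------------------------------------------------------
# newick export
# ---------------------------------------------------------------------------

def export_tree(Z: np.ndarray, labels: list[str] | tuple[str, ...]) -> str:
    """Render a scipy linkage as newick with branch lengths = merge-height gaps."""
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")

    root = to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    left = render(root.left, root.dist)
    right = render(root.right, root.dist)
    return f"({left},{right});"
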