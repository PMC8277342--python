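"""Two-dimensional projection, k-means clustering and cluster-number choice.

The fine-tuned word vectors are projected onto their first two principal
components — the same 2D map the word scatter plots show — and clustered
with k-means there. The number of clusters is chosen by four standard
heuristics (silhouette, elbow, Calinski-Harabasz, Davies-Bouldin) plus a
simple consensus rule (mode of the four, ties to the smallest k). A config
flag allows clustering in the full embedding space instead for sensitivity
checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import (calinski_harabasz_score, davies_bouldin_score,
                             silhouette_score)

from .embedding import EmbeddingTable

__all__ = ["ProjectedEmbedding", "ClusterSolution", "ValidityReport",
           "pca_project", "kmeans", "silhouette", "calinski_harabasz",
           "davies_bouldin", "elbow_select", "select_k", "consensus",
           "plot_clusters"]

#: sentinel reported when the within-cluster scatter is exactly zero and the
#: variance-ratio criterion diverges
CH_INFINITE = np.inf

#: below this best silhouette a ValidityReport flags the clustering as weak
WEAK_STRUCTURE_SILHOUETTE = 0.25


@dataclass(frozen=True)
class ProjectedEmbedding:
    """Words with low-dimensional coordinates after PCA."""

    words: list[str]
    coords: dict[str, np.ndarray]
    explained_variance_ratio: np.ndarray

    def matrix(self, words=None) -> np.ndarray:
        words = self.words if words is None else words
        return np.vstack([self.coords[w] for w in words])


@dataclass(frozen=True)
class ClusterSolution:
    """A k-means fit: labels per word, centroids and inertia."""

    k: int
    labels: dict[str, int]
    centroids: np.ndarray
    inertia: float

    def __post_init__(self) -> None:
        used = set(self.labels.values())
        if used != set(range(self.k)):
            raise ValueError("every cluster id in 0..k-1 must be used")
        if self.inertia < 0:
            raise ValueError("inertia must be >= 0")

    def label_array(self, words) -> np.ndarray:
        return np.array([self.labels[w] for w in words])


@dataclass(frozen=True)
class ValidityReport:
    """Per-k validity indices plus each heuristic's chosen k.

    ``selected_k`` maps heuristic name -> k; ``consensus_k`` is the mode of
    the four selections (ties broken toward the smallest k).
    ``weak_structure`` is set when even the best silhouette is low, i.e. no
    candidate clustering separates the words convincingly.
    """

    k_values: list[int]
    silhouette: dict[int, float]
    calinski_harabasz: dict[int, float]
    davies_bouldin: dict[int, float]
    inertia: dict[int, float]
    selected_k: dict[str, int]
    consensus_k: int
    weak_structure: bool

    def to_dict(self) -> dict:
        return {
            "k_values": self.k_values,
            "silhouette": self.silhouette,
            "calinski_harabasz": self.calinski_harabasz,
            "davies_bouldin": self.davies_bouldin,
            "inertia": self.inertia,
            "selected_k": self.selected_k,
            "consensus_k": self.consensus_k,
            "weak_structure": self.weak_structure,
        }


def pca_project(table: EmbeddingTable,
                n_components: int = 2) -> ProjectedEmbedding:
    """Mean-centered projection onto the top principal components.

    Sign convention: each component is flipped, if necessary, so that its
    largest-magnitude loading is positive, making projections reproducible
    across linear-algebra backends.
    """
    if len(table.words) < n_components + 1:
        raise ValueError("need at least n_components + 1 words")
    X = table.matrix()
    pca = PCA(n_components=n_components, svd_solver="full")
    Z = pca.fit_transform(X)
    comps = pca.components_
    for c in range(n_components):
        j = int(np.argmax(np.abs(comps[c])))
        if comps[c, j] < 0:
            Z[:, c] = -Z[:, c]
    return ProjectedEmbedding(
        words=list(table.words),
        coords={w: Z[i] for i, w in enumerate(table.words)},
        explained_variance_ratio=pca.explained_variance_ratio_.copy())


def kmeans(points: ProjectedEmbedding, k: int, seed: int = 0,
           words=None) -> ClusterSolution:
    """k-means++ with 10 restarts, keeping the lowest-inertia solution."""
    words = points.words if words is None else list(words)
    X = points.matrix(words)
    if k > len(words):
        raise ValueError(f"k={k} exceeds the number of points {len(words)}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=300,
                tol=1e-6, random_state=seed)
    labels = km.fit_predict(X)
    return ClusterSolution(k=k,
                           labels={w: int(l) for w, l in zip(words, labels)},
                           centroids=km.cluster_centers_.copy(),
                           inertia=float(km.inertia_))


def _as_arrays(points, labels):
    """Accept (ProjectedEmbedding, ClusterSolution) or plain arrays."""
    if isinstance(points, ProjectedEmbedding):
        words = points.words
        X = points.matrix()
        y = (labels.label_array(words) if isinstance(labels, ClusterSolution)
             else np.asarray([labels[w] for w in words]))
    else:
        X = np.asarray(points, dtype=float)
        y = np.asarray(labels)
    return X, y


def silhouette(points, labels) -> float:
    """Mean silhouette score (b - a) / max(a, b); singletons score 0."""
    X, y = _as_arrays(points, labels)
    if len(set(y.tolist())) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    return float(silhouette_score(X, y, metric="euclidean"))


def calinski_harabasz(points, labels) -> float:
    """Variance-ratio criterion (between / within, df-scaled).

    Diverges when the within-cluster scatter is exactly zero; that case is
    reported as ``inf`` rather than an error so k-selection can still rank it
    above any finite value.
    """
    X, y = _as_arrays(points, labels)
    n = len(X)
    k = len(set(y.tolist()))
    if not 2 <= k < n:
        raise ValueError("calinski_harabasz requires 2 <= k < n")
    wgss = sum(float(((X[y == c] - X[y == c].mean(axis=0)) ** 2).sum())
               for c in set(y.tolist()))
    if wgss == 0.0:
        return CH_INFINITE
    return float(calinski_harabasz_score(X, y))


def davies_bouldin(points, labels) -> float:
    """Mean over clusters of the worst scatter-to-separation ratio.

    Pairs of coincident centroids are skipped with a warning (their ratio is
    undefined); a cluster with no valid partner contributes 0.
    """
    X, y = _as_arrays(points, labels)
    clusters = sorted(set(y.tolist()))
    if len(clusters) < 2:
        raise ValueError("davies_bouldin requires k >= 2")
    cents = np.vstack([X[y == c].mean(axis=0) for c in clusters])
    dists = np.sqrt(((cents[:, None, :] - cents[None, :, :]) ** 2).sum(-1))
    if np.any(dists[np.triu_indices(len(clusters), k=1)] == 0.0):
        warnings.warn("coincident centroids; skipping degenerate pairs")
        s = np.array([float(np.linalg.norm(X[y == c] - cents[i],
                                           axis=1).mean())
                      for i, c in enumerate(clusters)])
        worst = []
        for i in range(len(clusters)):
            ratios = [(s[i] + s[j]) / dists[i, j]
                      for j in range(len(clusters))
                      if j != i and dists[i, j] > 0.0]
            worst.append(max(ratios) if ratios else 0.0)
        return float(np.mean(worst))
    return float(davies_bouldin_score(X, y))


def elbow_select(inertia_by_k: dict[int, float]) -> int:
    """Pick k at the sharpest bend of the inertia curve.

    The bend is the interior k maximizing the discrete second difference
    ``inertia(k-1) - 2 inertia(k) + inertia(k+1)``; ties go to the smallest
    k. Needs at least four consecutive k values.
    """
    ks = sorted(inertia_by_k)
    if len(ks) < 4 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >= 4 consecutive k values")
    best_k, best_curv = None, -np.inf
    for k in ks[1:-1]:
        curv = (inertia_by_k[k - 1] - 2.0 * inertia_by_k[k]
                + inertia_by_k[k + 1])
        if curv > best_curv:  # strict: ties keep the smallest k
            best_k, best_curv = k, curv
    return best_k


def consensus(selections) -> int:
    """Mode of the heuristics' chosen k values, ties toward the smallest."""
    votes = sorted(selections)
    if not votes:
        raise ValueError("no selections to take a consensus of")
    counts = {k: votes.count(k) for k in votes}
    best = max(counts.values())
    return min(k for k, c in counts.items() if c == best)


def select_k(points: ProjectedEmbedding, k_range=range(2, 9),
             seed: int = 0) -> ValidityReport:
    """Run k-means for every candidate k and apply the four heuristics."""
    ks = sorted(k_range)
    n = len(points.words)
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError("k_range must lie within [2, n-1]")
    sil, ch, db, inert = {}, {}, {}, {}
    for k in ks:
        sol = kmeans(points, k, seed=seed)
        sil[k] = silhouette(points, sol)
        ch[k] = calinski_harabasz(points, sol)
        db[k] = davies_bouldin(points, sol)
        inert[k] = sol.inertia
    selected = {
        "silhouette": max(ks, key=lambda k: (sil[k], -k)),
        "calinski_harabasz": max(ks, key=lambda k: (ch[k], -k)),
        "davies_bouldin": min(ks, key=lambda k: (db[k], k)),
        "elbow": elbow_select(inert),
    }
    return ValidityReport(k_values=ks, silhouette=sil, calinski_harabasz=ch,
                          davies_bouldin=db, inertia=inert,
                          selected_k=selected,
                          consensus_k=consensus(selected.values()),
                          weak_structure=max(sil.values())
                          < WEAK_STRUCTURE_SILHOUETTE)


def plot_clusters(points: ProjectedEmbedding, solution: ClusterSolution,
                  frequency: dict[str, int] | None = None, ax=None,
                  min_font: float = 6.0, max_font: float = 24.0):
    """Scatter the words on PC1/PC2, font size scaled by word frequency."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 8))
    freqs = frequency or {w: 1 for w in points.words}
    fmax = max(freqs.values())
    fmin = min(freqs.values())
    cmap = plt.get_cmap("tab10")
    for w in points.words:
        x, y = points.coords[w]
        rel = 0.0 if fmax == fmin else (freqs[w] - fmin) / (fmax - fmin)
        ax.text(x, y, w, fontsize=min_font + rel * (max_font - min_font),
                color=cmap(solution.labels[w] % 10),
                ha="center", va="center")
    allxy = points.matrix()
    pad = 0.05 * (allxy.max(axis=0) - allxy.min(axis=0) + 1e-9)
    ax.set_xlim(allxy[:, 0].min() - pad[0], allxy[:, 0].max() + pad[0])
    ax.set_ylim(allxy[:, 1].min() - pad[1], allxy[:, 1].max() + pad[1])
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    return ax
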