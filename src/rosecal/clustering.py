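"""PCA scores and Ward/Euclidean hierarchical clustering of spectra.

The agglomeration starts from plain Euclidean distances between
preprocessed spectra and merges, at every step, the pair of clusters
whose fusion minimally increases the total within-cluster variance
(Ward's minimum-variance criterion).  Distances to a freshly merged
cluster follow the Lance-Williams recurrence on squared distances,

    D(A+B, C)^2 = ((n_A + n_C) D_AC^2 + (n_B + n_C) D_BC^2
                   - n_C D_AB^2) / (n_A + n_B + n_C),

and merge heights are reported on the Euclidean (not squared) scale, the
variant usually labelled "Ward.D2".  Ties are broken deterministically
by the smallest (first, second) cluster-index pair so dendrograms are
reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PcaResult",
    "Dendrogram",
    "pca_decompose",
    "hca_ward",
    "cut_dendrogram",
    "export_newick",
]


@dataclass
class PcaResult:
    """Scores, loadings, explained-variance ratios and the column mean."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


@dataclass
class Dendrogram:
    """Agglomeration record: n-1 merges over the leaf ids.

    Leaves are numbered 0..n-1 in ``leaf_ids`` order; merge i creates
    cluster id n+i.  Each merge is ``(cluster_a, cluster_b, height,
    new_size)`` with ``cluster_a < cluster_b``.
    """

    merges: list[tuple[int, int, float, int]]
    leaf_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if len(self.merges) != n - 1:
            raise ValueError(f"expected {n - 1} merges for {n} leaves")
        if len(set(self.leaf_ids)) != n:
            raise ValueError("duplicate leaf ids")


def pca_decompose(X: np.ndarray, n_components: int) -> PcaResult:
    """SVD-based PCA of the column-mean-centered matrix.

    Scores are ``U S`` truncated to ``n_components``; the sign of each
    component is fixed so its largest-magnitude loading element is
    positive.  Explained-variance ratios are relative to the total
    variance, so their sum is <= 1 after truncation.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} outside 1..{min(n - 1, p)}"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    for j in range(Vt.shape[0]):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    total = float((s**2).sum())
    ratios = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    return PcaResult(
        scores=U[:, :n_components] * s[:n_components],
        loadings=Vt[:n_components].T,
        explained_variance_ratio=ratios,
        mean=mean,
    )


def hca_ward(X: np.ndarray, sample_ids: list[str]) -> Dendrogram:
    """Agglomerative Ward clustering from pairwise Euclidean distances."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    if len(sample_ids) != n or len(set(sample_ids)) != n:
        raise ValueError("sample_ids must be unique and align with X rows")

    total = 2 * n - 1
    d2 = np.full((total, total), np.inf)
    d2[:n, :n] = squareform(pdist(X, metric="euclidean") ** 2)
    np.fill_diagonal(d2, np.inf)
    size = np.zeros(total, dtype=int)
    size[:n] = 1
    active: list[int] = list(range(n))

    merges: list[tuple[int, int, float, int]] = []
    for step in range(n - 1):
        best = (np.inf, -1, -1)
        for ai in range(len(active)):
            a = active[ai]
            for bi in range(ai + 1, len(active)):
                b = active[bi]
                d = d2[a, b]
                if d < best[0] or (d == best[0] and (a, b) < (best[1], best[2])):
                    best = (d, a, b)
        dab2, a, b = best
        new = n + step
        nc = size[a] + size[b]
        size[new] = nc
        merges.append((a, b, float(np.sqrt(dab2)), int(nc)))
        for c in active:
            if c in (a, b):
                continue
            d2[new, c] = d2[c, new] = (
                (size[a] + size[c]) * d2[a, c]
                + (size[b] + size[c]) * d2[b, c]
                - size[c] * dab2
            ) / (nc + size[c])
        active.remove(a)
        active.remove(b)
        active.append(new)
    return Dendrogram(merges=merges, leaf_ids=list(sample_ids))


def _components(d: Dendrogram, n_keep_merges: int) -> list[list[int]]:
    """Leaf memberships after applying the first ``n_keep_merges`` merges."""
    n = len(d.leaf_ids)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for step in range(n_keep_merges):
        a, b, _, _ = d.merges[step]
        members[n + step] = members.pop(a) + members.pop(b)
    return sorted(members.values(), key=min)


def cut_dendrogram(d: Dendrogram, n_clusters: int) -> dict[str, int]:
    """Labels from removing the ``n_clusters - 1`` highest (last) merges.

    Clusters are numbered by their smallest member leaf index, so labels
    are deterministic.
    """
    n = len(d.leaf_ids)
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters={n_clusters} outside 1..{n}")
    labels: dict[str, int] = {}
    for label, leaves in enumerate(_components(d, n - n_clusters)):
        for leaf in leaves:
            labels[d.leaf_ids[leaf]] = label
    return labels


def _sanitize(name: str) -> str:
    for ch in "(),:;' \t":
        name = name.replace(ch, "_")
    return name


def export_newick(d: Dendrogram) -> str:
    """Ultrametric Newick string; leaves sit at height 0.

    Branch lengths are parent merge height minus child merge height, so
    every root-to-leaf path length equals the final merge height.
    """
    n = len(d.leaf_ids)
    height = {i: 0.0 for i in range(n)}
    text = {i: _sanitize(d.leaf_ids[i]) for i in range(n)}
    for step, (a, b, h, _) in enumerate(d.merges):
        node = n + step
        height[node] = h
        text[node] = (
            f"({text[a]}:{float(h - height[a])!r},{text[b]}:{float(h - height[b])!r})"
        )
    return text[2 * n - 2] + ";"
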