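"""Self-organizing map training, SOM-seeded k-means and hierarchical clustering.

The SOM is trained sequentially: at each of the (default 4000) iterations a
random item is drawn, its best-matching unit (BMU) is found by Euclidean
distance over the neuron grid, and every codebook vector moves toward the
item weighted by a Gaussian neighborhood of the BMU whose width decays over
training. k-means is then run on the original items, seeded with k centers
chosen among the trained codebook vectors by k-means++ — the SOM acts as a
structure-aware initializer that makes the subsequent Lloyd iterations
robust for the very small item sets (tens of inducers or pathways) this
pipeline clusters.

Schedules: the neighborhood width decays linearly from half the grid
diagonal to a floor of 0.1, the learning rate from 0.05 to 0.02. The narrow
final neighborhood is a fine-tuning phase: late in training each occupied
neuron is updated almost exclusively as the BMU of its own items, so it
converges onto the centroid of its receptive field instead of interpolating
between clusters — which is what makes the codebook a reliable k-means
seed. Equidistant BMUs break toward the lowest neuron index, so training is
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans, kmeans_plusplus


@dataclass
class SOMModel:
    grid: tuple[int, int]
    codebook: np.ndarray          # (n_neurons, n_features)
    coords: np.ndarray            # (n_neurons, 2) grid positions
    iterations: int
    seed: int
    columns: list[str]

    @property
    def n_neurons(self) -> int:
        return self.codebook.shape[0]

    def bmu(self, x: np.ndarray) -> int:
        """Index of the best-matching unit; ties break to the lowest index."""
        d = np.linalg.norm(self.codebook - x, axis=1)
        return int(np.argmin(d))

    def write_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.codebook, columns=self.columns)
        frame.insert(0, "row", self.coords[:, 0].astype(int))
        frame.insert(1, "col", self.coords[:, 1].astype(int))
        frame.to_csv(path, sep="\t", index_label="neuron", float_format="%.6g")


def _as_array(matrix) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(matrix, pd.DataFrame):
        return (matrix.to_numpy(float), [str(i) for i in matrix.index],
                [str(c) for c in matrix.columns])
    arr = np.asarray(matrix, float)
    return (arr, [f"item{i}" for i in range(arr.shape[0])],
            [f"f{j}" for j in range(arr.shape[1])])


def train_som(
    matrix,
    grid: tuple[int, int] = (5, 5),
    iterations: int = 4000,
    seed: int = 0,
    alpha: tuple[float, float] = (0.05, 0.02),
    sigma: tuple[float, float] | None = None,
) -> SOMModel:
    """Train a rectangular SOM with Gaussian neighborhood, Euclidean distance.

    The codebook is initialized by sampling items (with replacement) plus a
    tiny per-feature jitter, so a single-item dataset is a fixed point and
    duplicate initial neurons are broken apart deterministically.
    """
    X, _, columns = _as_array(matrix)
    if X.shape[0] < 1:
        raise ValueError("need at least one item")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in input matrix")
    rows, cols = grid
    if rows < 1 or cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    n_neurons = rows * cols
    rng = np.random.default_rng(seed)

    coords = np.array([(r, c) for r in range(rows) for c in range(cols)], float)
    init_idx = rng.integers(0, X.shape[0], size=n_neurons)
    jitter_scale = 1e-4 * X.std(axis=0)
    codebook = X[init_idx] + rng.normal(size=(n_neurons, X.shape[1])) * jitter_scale

    sigma0 = (0.5 * float(np.hypot(rows - 1, cols - 1))) if sigma is None else sigma[0]
    sigma_floor = 0.1 if sigma is None else sigma[1]
    sigma0 = max(sigma0, sigma_floor)
    a0, a1 = alpha

    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    draws = rng.integers(0, X.shape[0], size=iterations)
    denom = max(iterations - 1, 1)
    for t, i in enumerate(draws):
        frac = t / denom
        sig = sigma0 + (sigma_floor - sigma0) * frac
        a = a0 + (a1 - a0) * frac
        x = X[i]
        bmu = int(np.argmin(((codebook - x) ** 2).sum(axis=1)))
        h = np.exp(-grid_d2[bmu] / (2.0 * sig * sig))
        codebook += (a * h)[:, None] * (x - codebook)

    return SOMModel(grid=grid, codebook=codebook, coords=coords,
                    iterations=iterations, seed=seed, columns=columns)


@dataclass
class ClusterAssignment:
    labels: pd.Series  # item -> cluster id
    k: int
    inertia: float

    def __post_init__(self) -> None:
        occupied = set(self.labels)
        if len(occupied) != self.k:
            raise ValueError(
                f"expected {self.k} nonempty clusters, got {len(occupied)}"
            )

    def write_tsv(self, path: str | Path) -> None:
        self.labels.rename("cluster").to_csv(path, sep="\t", index_label="item")


def som_kmeans(
    som: SOMModel,
    matrix,
    k: int = 3,
    seed: int = 0,
    max_iter: int = 4000,
    n_init: int = 20,
) -> ClusterAssignment:
    """k-means on the original items, seeded from the trained SOM codebook.

    Initial centers are picked by k-means++ among the *occupied* codebook
    vectors — neurons that are the BMU of at least one item — which excludes
    the interpolating neurons a SOM leaves between data clusters. The best
    of ``n_init`` seeded Lloyd runs (each capped at ``max_iter`` iterations)
    by final inertia is returned.
    """
    X, items, _ = _as_array(matrix)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the {X.shape[0]} items")
    distinct = np.unique(som.codebook, axis=0)
    if k > distinct.shape[0]:
        raise ValueError(
            f"k={k} exceeds the {distinct.shape[0]} distinct codebook vectors"
        )
    d2 = ((X[:, None, :] - som.codebook[None]) ** 2).sum(-1)
    occupied = np.unique(som.codebook[np.unique(d2.argmin(axis=1))], axis=0)
    pool = occupied if occupied.shape[0] >= k else distinct

    best: KMeans | None = None
    for j in range(max(n_init, 1)):
        centers, _ = kmeans_plusplus(
            pool, n_clusters=k,
            random_state=np.random.RandomState((seed + 10007 * j) % (2 ** 31)))
        km = KMeans(n_clusters=k, init=centers, n_init=1, max_iter=max_iter,
                    random_state=seed).fit(X)
        if best is None or km.inertia_ < best.inertia_:
            best = km
    labels = pd.Series(best.labels_.astype(int), index=items, name="cluster")
    return ClusterAssignment(labels=labels, k=k, inertia=float(best.inertia_))


# --------------------------------------------------------------------------
# hierarchical clustering


@dataclass
class HierarchicalResult:
    linkage_matrix: np.ndarray
    items: list[str]

    @property
    def leaf_order(self) -> list[str]:
        return [self.items[i] for i in sch.leaves_list(self.linkage_matrix)]

    def to_newick(self) -> str:
        """Dendrogram in Newick form with merge heights as branch lengths."""
        n = len(self.items)
        Z = self.linkage_matrix
        height = {i: 0.0 for i in range(n)}
        rep: dict[int, str] = {i: self.items[i] for i in range(n)}
        for j, (a, b, h, _) in enumerate(Z):
            a, b = int(a), int(b)
            la = h - height[a]
            lb = h - height[b]
            node = n + j
            rep[node] = f"({rep[a]}:{la:.6g},{rep[b]}:{lb:.6g})"
            height[node] = h
        return rep[n + len(Z) - 1] + ";"


def hierarchical_cluster(
    matrix,
    metric: str = "euclidean",
    linkage: str = "average",
) -> HierarchicalResult:
    """Agglomerative clustering of matrix rows; default average/Euclidean."""
    X, items, _ = _as_array(matrix)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 items to cluster")
    if not np.isfinite(X).all():
        raise ValueError("metric undefined on non-finite data")
    dists = pdist(X, metric=metric)
    Z = sch.linkage(dists, method=linkage)
    return HierarchicalResult(linkage_matrix=Z, items=items)


def plot_heatmap(
    matrix: pd.DataFrame,
    path: str | Path,
    row_linkage: HierarchicalResult | None = None,
    col_linkage: HierarchicalResult | None = None,
    cmap: str = "RdYlGn_r",
) -> None:
    """Render a clustered heatmap (PNG/SVG by file suffix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = matrix
    if row_linkage is not None:
        ordered = ordered.loc[row_linkage.leaf_order]
    if col_linkage is not None:
        ordered = ordered[col_linkage.leaf_order]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * ordered.shape[1] + 2),
                 max(3, 0.25 * ordered.shape[0] + 1)))
    im = ax.imshow(ordered.to_numpy(float), aspect="auto", cmap=cmap)
    ax.set_xticks(range(ordered.shape[1]))
    ax.set_xticklabels(ordered.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(ordered.shape[0]))
    ax.set_yticklabels(ordered.index, fontsize=5)
    fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
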