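"""Self-organizing-map clustering with agglomerative metaclustering.

FlowSOM-style two-stage clustering: a rectangular-grid SOM quantizes
the events into grid_rows x grid_cols codebook nodes, and the nodes
are then merged into k metaclusters by average-linkage hierarchical
clustering on the codebook vectors.  Training uses the deterministic
batch-SOM update (neighborhood-weighted node means with a shrinking
Gaussian neighborhood), with an internal event shuffle driven by the
seed, so results depend only on (data, parameters, seed) and not on
input order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import AgglomerativeClustering

from .fcs import EventMatrix

__all__ = ["ClusterModel", "fit_som", "metacluster", "assign"]


@dataclass
class ClusterModel:
    """Trained SOM codebook plus (optional) node -> metacluster map."""

    grid_rows: int
    grid_cols: int
    codebook: np.ndarray  # (n_nodes, n_markers)
    markers: list[str]
    seed: int
    node_to_meta: np.ndarray | None = None  # (n_nodes,) int

    @property
    def n_nodes(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def n_meta(self) -> int:
        if self.node_to_meta is None:
            raise ValueError("model has no metaclusters; call metacluster() first")
        return int(self.node_to_meta.max()) + 1


def _grid_distances(rows: int, cols: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    return cdist(coords, coords, "sqeuclidean")


def fit_som(
    events: EventMatrix,
    markers: list[str],
    grid_rows: int = 10,
    grid_cols: int = 10,
    seed: int = 0,
    n_epochs: int = 15,
) -> ClusterModel:
    """Train a batch SOM on the selected marker columns.

    Codebook initialization samples events with a seeded generator and
    every stochastic step derives from the seed, so refitting with the
    same seed reproduces the codebook exactly.
    """
    if not markers:
        raise ValueError("marker list must not be empty")
    if events.n_events < 1:
        raise ValueError("need at least one event to fit a SOM")
    X = events.subset_channels(markers)
    rng = np.random.default_rng(seed)
    # Canonical (lexicographic) row order: training and initialization
    # see the same sequence whatever order the events arrived in.
    X = X[np.lexsort(X.T)]

    n_nodes = grid_rows * grid_cols
    init_idx = rng.choice(X.shape[0], size=n_nodes, replace=X.shape[0] < n_nodes)
    codebook = X[init_idx].astype(float).copy()
    # Tiny seeded jitter so duplicate initial nodes can separate.
    codebook += rng.normal(scale=1e-6, size=codebook.shape)

    grid_d2 = _grid_distances(grid_rows, grid_cols)
    sigma0 = max(grid_rows, grid_cols) / 2.0
    sigma_end = 0.5
    for epoch in range(n_epochs):
        frac = epoch / max(n_epochs - 1, 1)
        sigma = sigma0 * (sigma_end / sigma0) ** frac
        bmu = np.argmin(cdist(X, codebook, "sqeuclidean"), axis=1)
        counts = np.bincount(bmu, minlength=n_nodes).astype(float)
        sums = np.zeros_like(codebook)
        np.add.at(sums, bmu, X)
        h = np.exp(-grid_d2 / (2.0 * sigma * sigma))
        denom = h @ counts
        numer = h @ sums
        ok = denom > 1e-12
        codebook[ok] = numer[ok] / denom[ok, None]
    return ClusterModel(grid_rows, grid_cols, codebook, list(markers), int(seed))


def metacluster(model: ClusterModel, k: int) -> ClusterModel:
    """Group SOM nodes into k metaclusters.

    Average-linkage agglomerative clustering on Euclidean codebook
    distances; metacluster ids are renumbered by first occurrence in
    node order, which makes the labeling canonical and deterministic.
    """
    if not 1 <= k <= model.n_nodes:
        raise ValueError(f"k={k} out of range for {model.n_nodes} nodes")
    if k == model.n_nodes:
        labels = np.arange(model.n_nodes)
    elif k == 1:
        labels = np.zeros(model.n_nodes, dtype=int)
    else:
        agg = AgglomerativeClustering(n_clusters=k, linkage="average", metric="euclidean")
        labels = agg.fit_predict(model.codebook)
    # Canonical renumbering by first appearance.
    remap: dict[int, int] = {}
    canon = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap)
        canon[i] = remap[lab]
    return replace(model, node_to_meta=canon)


def assign(model: ClusterModel, events: EventMatrix) -> np.ndarray:
    """Map events to metacluster ids via their nearest codebook node.

    Ties in node distance resolve to the lowest node index (argmin
    convention).
    """
    if model.node_to_meta is None:
        raise ValueError("model has no metaclusters; call metacluster() first")
    missing = [m for m in model.markers if m not in events.channel_names]
    if missing:
        raise ValueError(f"events lack model markers: {missing}")
    if events.n_events == 0:
        return np.empty(0, dtype=int)
    X = events.subset_channels(model.markers)
    bmu = np.argmin(cdist(X, model.codebook, "sqeuclidean"), axis=1)
    return model.node_to_meta[bmu]
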