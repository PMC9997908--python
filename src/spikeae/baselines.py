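"""Classical 2-D embeddings (PCA, ICA, Isomap) and their grid search.

These are the comparison baselines for the autoencoder variants. PCA keeps
the top principal components of the centered waveform matrix; ICA uses
FastICA with the logcosh contrast; Isomap builds a k-NN graph, computes
geodesic (shortest-path) distances and embeds them. ICA and Isomap
hyperparameters are picked per dataset by an exhaustive grid search over a
clustering-quality objective.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components, shortest_path
from sklearn.decomposition import PCA, FastICA
from sklearn.manifold import Isomap
from sklearn.neighbors import kneighbors_graph

from .datasets import LabeledSpikeSet
from .models import FeatureSet

logger = logging.getLogger(__name__)

__all__ = [
    "pca_embed",
    "ica_embed",
    "isomap_embed",
    "geodesic_distances",
    "GridSearchReport",
    "grid_search_embedding",
]


def _as_matrix(spikes) -> np.ndarray:
    if isinstance(spikes, LabeledSpikeSet):
        return spikes.waveforms
    if isinstance(spikes, FeatureSet):
        return spikes.features
    return np.asarray(spikes, dtype=float)


def _fix_signs(components: np.ndarray, scores: np.ndarray):
    """Sign convention: the largest-magnitude loading of each axis is positive."""
    for j in range(components.shape[0]):
        k = np.argmax(np.abs(components[j]))
        if components[j, k] < 0:
            components[j] *= -1
            scores[:, j] *= -1
    return components, scores


def pca_embed(spikes, n_components: int = 2) -> FeatureSet:
    """Top principal components of the centered waveform matrix."""
    X = _as_matrix(spikes)
    if X.shape[0] < n_components:
        raise ValueError("need at least n_components samples")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    _fix_signs(pca.components_, scores)
    return FeatureSet(scores, method_tag=f"pca{n_components}")


def ica_embed(
    spikes,
    n_components: int = 2,
    contrast: str = "logcosh",
    tolerance: float = 1e-5,
    seed: int = 0,
    max_iter: int = 1000,
) -> FeatureSet:
    """FastICA projection (logcosh contrast, run to convergence, seeded)."""
    X = _as_matrix(spikes)
    ica = FastICA(
        n_components=n_components,
        fun=contrast,
        tol=tolerance,
        max_iter=max_iter,
        random_state=seed,
        whiten="unit-variance",
    )
    import warnings

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        S = ica.fit_transform(X)
    for w in caught:
        if "did not converge" in str(w.message):
            raise RuntimeError(
                f"FastICA did not converge within {max_iter} iterations"
            )
    return FeatureSet(S, method_tag=f"ica{n_components}")


def geodesic_distances(X: np.ndarray, n_neighbors: int) -> np.ndarray:
    """All-pairs shortest-path distances over the symmetrized k-NN graph."""
    G = kneighbors_graph(X, n_neighbors=n_neighbors, mode="distance")
    G = G.maximum(G.T)  # undirected
    return shortest_path(G, method="D", directed=False)


def isomap_embed(
    spikes,
    n_neighbors: int = 30,
    n_components: int = 2,
    metric: str = "minkowski",
) -> FeatureSet:
    """Classical Isomap: k-NN graph -> geodesics -> low-dimensional embedding.

    If the neighborhood graph is disconnected, only the largest connected
    component is embedded; dropped spikes get NaN rows (flagged in the log)
    so row order still matches the input.
    """
    X = _as_matrix(spikes)
    n = X.shape[0]
    if not 1 <= n_neighbors < n:
        raise ValueError("n_neighbors must be in [1, n_spikes)")
    G = kneighbors_graph(X, n_neighbors=n_neighbors, mode="connectivity")
    n_comp, member = connected_components(G.maximum(G.T), directed=False)
    if n_comp > 1:
        sizes = np.bincount(member)
        keep = member == np.argmax(sizes)
        logger.warning(
            "isomap_embed: graph has %d components; embedding largest (%d/%d spikes)",
            n_comp,
            int(keep.sum()),
            n,
        )
        emb = Isomap(
            n_neighbors=min(n_neighbors, int(keep.sum()) - 1),
            n_components=n_components,
            metric=metric,
        ).fit_transform(X[keep])
        out = np.full((n, n_components), np.nan)
        out[keep] = emb
        return FeatureSet(out, method_tag=f"isomap(k={n_neighbors})")
    emb = Isomap(
        n_neighbors=n_neighbors, n_components=n_components, metric=metric
    ).fit_transform(X)
    return FeatureSet(emb, method_tag=f"isomap(k={n_neighbors})")


@dataclass
class GridSearchReport:
    method: str
    grid: dict
    scores: list  # list of (params dict, score)
    best: dict
    best_score: float

    def to_table(self):
        import pandas as pd

        rows = [dict(p, score=s) for p, s in self.scores]
        return pd.DataFrame(rows)


_EMBEDDERS = {"pca": pca_embed, "ica": ica_embed, "isomap": isomap_embed}


def grid_search_embedding(
    method: str,
    spikes: LabeledSpikeSet,
    grid: dict,
    objective: str = "ari",
    k: int | None = None,
    seed: int = 0,
) -> GridSearchReport:
    """Evaluate every grid combination of an embedding and pick the best.

    The objective is one of the six clustering metrics, computed after
    K-Means on the embedding (external metrics need ``spikes.labels``).
    Davies-Bouldin is minimized; everything else is maximized.
    """
    from .cluster_eval import kmeans_labels, metric_report

    if method not in _EMBEDDERS:
        raise ValueError(f"unknown method {method!r}")
    if not grid:
        raise ValueError("grid must be non-empty")
    objective = objective.lower()
    if objective not in ("ari", "ami", "vm", "dbs", "chs", "ss"):
        raise ValueError(f"unknown objective {objective!r}")
    if objective in ("ari", "ami", "vm") and spikes.labels is None:
        raise ValueError(f"objective {objective!r} needs ground-truth labels")

    if k is None:
        k = len(np.unique(spikes.labels)) if spikes.labels is not None else 2

    keys = sorted(grid)
    scores = []
    for combo in itertools.product(*(grid[key] for key in keys)):
        params = dict(zip(keys, combo))
        feats = _EMBEDDERS[method](spikes, **params)
        ok = np.all(np.isfinite(feats.features), axis=1)
        f = FeatureSet(feats.features[ok], feats.method_tag)
        res = kmeans_labels(f, k=k, seed=seed)
        rep = metric_report(
            f,
            res.labels,
            true_labels=spikes.labels[ok] if spikes.labels is not None else None,
        )
        scores.append((params, getattr(rep, objective)))

    vals = np.array([s for _, s in scores], dtype=float)
    idx = int(np.nanargmin(vals)) if objective == "dbs" else int(np.nanargmax(vals))
    return GridSearchReport(
        method=method,
        grid=grid,
        scores=scores,
        best=scores[idx][0],
        best_score=scores[idx][1],
    )
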