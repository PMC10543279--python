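"""Cluster-validity evaluation, elbow selection of K, and baseline clusterers.

Internal validity is scored by the Davies-Bouldin index (lower = tighter,
better separated) and the Calinski-Harabasz index (higher = better).  The
number of biotypes K is chosen at the elbow of the within-cluster
sum-of-squares curve, operationalized as the point of maximum perpendicular
distance to the chord joining the curve's endpoints.

Four reference clusterers are provided for benchmarking against GCN-BSD:
Ward agglomerative and plain K-means on the standardized features, a
fully connected (graph-free) deep K-means autoencoder, and a GCN autoencoder
followed by K-means on its embeddings.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering, KMeans

from .graph import PopulationGraph
from . import model as _model

__all__ = [
    "davies_bouldin",
    "calinski_harabasz",
    "sse_elbow_curve",
    "choose_k_elbow",
    "run_baseline",
    "benchmark_methods",
    "BASELINE_METHODS",
]

BASELINE_METHODS = ("agglomerative", "kmeans", "dnn_kmeans", "gcn_kmeans")


def _groups(points: np.ndarray, assignments: np.ndarray):
    x = np.asarray(points, float)
    a = np.asarray(assignments)
    labels = np.unique(a)
    if labels.size < 2:
        raise ValueError("need at least 2 nonempty clusters")
    return x, a, labels


def davies_bouldin(points: np.ndarray, assignments: np.ndarray) -> float:
    """Davies-Bouldin index: mean over clusters of the worst ratio of summed
    within-cluster scatters to centroid separation."""
    x, a, labels = _groups(points, assignments)
    mus = np.stack([x[a == lab].mean(axis=0) for lab in labels])
    scatters = np.array([
        np.linalg.norm(x[a == lab] - mus[i], axis=1).mean()
        for i, lab in enumerate(labels)
    ])
    k = labels.size
    ratios = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            gap = np.linalg.norm(mus[i] - mus[j])
            if gap == 0:
                raise ValueError(
                    f"coincident centroids for clusters {labels[i]} and "
                    f"{labels[j]}: index undefined")
            ratios[i, j] = (scatters[i] + scatters[j]) / gap
    return float(np.mean(ratios.max(axis=1)))


def calinski_harabasz(points: np.ndarray, assignments: np.ndarray) -> float:
    """Calinski-Harabasz index: between/within variance ratio
    (BSS/(K-1)) / (WSS/(N-K))."""
    x, a, labels = _groups(points, assignments)
    n, k = x.shape[0], labels.size
    grand = x.mean(axis=0)
    wss = 0.0
    bss = 0.0
    for lab in labels:
        grp = x[a == lab]
        mu = grp.mean(axis=0)
        wss += float(np.sum((grp - mu) ** 2))
        bss += grp.shape[0] * float(np.sum((mu - grand) ** 2))
    if wss == 0:
        raise ValueError("zero within-cluster scatter: index undefined")
    return float((bss / (k - 1)) / (wss / (n - k)))


def sse_elbow_curve(points: np.ndarray, k_range, seed: int = 0) -> dict[int, float]:
    """Within-cluster SSE of converged multi-restart K-means for each K."""
    x = np.asarray(points, float)
    ks = sorted(int(k) for k in k_range)
    if max(ks) > x.shape[0]:
        raise ValueError("max(k_range) exceeds the number of points")
    out: dict[int, float] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
        out[k] = float(km.inertia_)
    return out


def choose_k_elbow(sse_by_k: dict[int, float]) -> int:
    """K at the elbow: maximum perpendicular distance from the SSE curve to
    the chord joining its endpoints; ties and flat curves -> smallest K."""
    if len(sse_by_k) < 3:
        raise ValueError("need SSE for at least 3 values of K")
    ks = np.array(sorted(sse_by_k))
    sse = np.array([sse_by_k[k] for k in ks], dtype=float)
    p0 = np.array([ks[0], sse[0]])
    p1 = np.array([ks[-1], sse[-1]])
    chord = p1 - p0
    norm = np.linalg.norm(chord)
    pts = np.column_stack([ks, sse]) - p0
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / norm
    if np.max(dist) <= 1e-12 * max(1.0, np.max(np.abs(sse))):
        warnings.warn("SSE curve has no elbow (linear); returning smallest K")
        return int(ks[0])
    return int(ks[int(np.argmax(dist))])


def _dnn_kmeans(features: np.ndarray, k: int, seed: int,
                config: _model.ModelConfig | None) -> _model.TrainState:
    """Graph-free deep K-means: same widths as GCN-BSD, identity operator,
    reconstruction + clustering losses only."""
    x = np.asarray(features, float)
    n = x.shape[0]
    cfg = config or _model.ModelConfig()
    cfg = _model.ModelConfig(
        layer_sizes=(x.shape[1],) + tuple(cfg.layer_sizes[1:]),
        gamma1=cfg.gamma1, gamma2=0.0, gamma3=cfg.gamma3,
        learning_rate=cfg.learning_rate, epochs=cfg.epochs,
        warmup_epochs=cfg.warmup_epochs, k=k, seed=seed,
        centroid_update_period=cfg.centroid_update_period)
    # zero adjacency -> the normalized operator is the identity: a plain DNN
    g = PopulationGraph(subject_ids=[f"s{i}" for i in range(n)], features=x,
                        labels=np.ones(n, dtype=int),
                        adjacency=np.zeros((n, n)),
                        age_months=np.full(n, 120.0),
                        gender=np.array(["m"] * n))
    return _model.train(g, cfg)


def _gcn_kmeans(graph: PopulationGraph, k: int, seed: int,
                config: _model.ModelConfig | None) -> _model.TrainState:
    """GCN autoencoder trained with reconstruction loss only, then plain
    K-means on the patient embeddings."""
    cfg = config or _model.ModelConfig()
    cfg = _model.ModelConfig(
        layer_sizes=(graph.features.shape[1],) + tuple(cfg.layer_sizes[1:]),
        gamma1=1.0, gamma2=0.0, gamma3=0.0,
        learning_rate=cfg.learning_rate, epochs=cfg.epochs,
        warmup_epochs=cfg.warmup_epochs, k=k, seed=seed,
        centroid_update_period=cfg.centroid_update_period)
    return _model.train(graph, cfg)


def run_baseline(method: str, k: int, seed: int,
                 features: np.ndarray | None = None,
                 graph: PopulationGraph | None = None,
                 config: _model.ModelConfig | None = None):
    """Run one reference clusterer.

    Returns ``(assignments, points)`` where assignments are labels 1..K over
    the clustered subjects (patients for graph methods) and ``points`` is the
    space in which validity indices should be computed for that method
    (embeddings for the deep methods, input features otherwise).
    """
    if method not in BASELINE_METHODS:
        raise ValueError(f"unknown baseline '{method}'; choose from {BASELINE_METHODS}")
    if method in ("agglomerative", "kmeans", "dnn_kmeans"):
        if features is None:
            if graph is None:
                raise ValueError(f"{method} needs features or a graph")
            features = graph.features[graph.patient_index]
        x = np.asarray(features, float)
        if method == "agglomerative":
            labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(x)
            return labels + 1, x
        if method == "kmeans":
            labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(x)
            return labels + 1, x
        state = _dnn_kmeans(x, k, seed, config)
        return state.assignments, state.embeddings
    if graph is None:
        raise ValueError("gcn_kmeans needs a population graph")
    state = _gcn_kmeans(graph, k, seed, config)
    return state.assignments, state.embeddings[graph.patient_index]


def benchmark_methods(graph: PopulationGraph, k: int, seed: int,
                      gcnbsd_state: _model.TrainState | None = None,
                      config: _model.ModelConfig | None = None) -> pd.DataFrame:
    """DBI/CHI for GCN-BSD and the four baselines on one cohort.

    Every method's partition is scored in the shared standardized patient
    feature space.  Scoring each deep method in its own embedding space
    would make the indices incomparable: the deep K-means objective shrinks
    within-cluster scatter in the embedding by construction, so any such
    method would win regardless of whether its partition reflects real
    structure.  Internal indices on the common input space measure what the
    comparison is actually about — the quality of the partition.
    """
    rows = []
    if gcnbsd_state is None:
        cfg = config or _model.ModelConfig(
            layer_sizes=(graph.features.shape[1], 256, 64), k=k, seed=seed)
        gcnbsd_state = _model.train(graph, cfg)
    xp = graph.features[graph.patient_index]
    rows.append(("gcn_bsd", davies_bouldin(xp, gcnbsd_state.assignments),
                 calinski_harabasz(xp, gcnbsd_state.assignments)))
    for method in BASELINE_METHODS:
        assign, _ = run_baseline(method, k=k, seed=seed, graph=graph,
                                 config=config)
        rows.append((method, davies_bouldin(xp, assign),
                     calinski_harabasz(xp, assign)))
    return pd.DataFrame(rows, columns=["method", "dbi", "chi"]).assign(
        k=k, seed=seed)
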