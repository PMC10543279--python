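"""GCN-BSD: graph-convolutional biotype detection with deep K-means.

The model is an autoencoder over the population graph.  A stack of spectral
graph-convolution layers (H -> act(S H W), S the renormalized operator) maps
the N x 1378 FNC features to an N x d embedding; a mirror stack reconstructs
the features.  Three losses are minimized jointly,

    L = gamma1 * L_rec + gamma2 * L_CE + gamma3 * L_cluster,

where L_rec is the mean squared reconstruction error over all subjects,
L_CE the mean binary cross-entropy of a linear patient/control classifier on
the embeddings, and L_cluster the deep K-means loss (mean squared distance
of patient embeddings to their assigned centroids).  Defaults: gamma1=0.1,
gamma2=0.5, gamma3=1, Adam with learning rate 0.001.

Training runs a warm-up phase without the clustering term, seeds centroids
on the warm-up embeddings by greedy farthest-point selection, then
alternates gradient steps on the weights with periodic hard
centroid/assignment refreshes.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .graph import PopulationGraph, normalize_adjacency

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "TrainState",
    "EmptyClusterError",
    "encode",
    "decode",
    "reconstruction_loss",
    "classification_loss",
    "deep_kmeans_loss",
    "update_centroids_and_assignments",
    "farthest_point_init",
    "lloyd_kmeans",
    "total_loss",
    "train",
    "extract_biotype_templates",
]


class EmptyClusterError(ValueError):
    """A cluster has no assigned members where a nonempty one is required."""


@dataclass
class ModelConfig:
    """Hyperparameters of GCN-BSD.

    ``layer_sizes`` are the encoder widths from input to embedding; the
    decoder mirrors them.  ``epochs`` counts total epochs including the
    ``warmup_epochs`` during which the clustering term is inactive.
    """

    layer_sizes: tuple[int, ...] = (1378, 256, 64)
    gamma1: float = 0.1
    gamma2: float = 0.5
    gamma3: float = 1.0
    learning_rate: float = 0.001
    epochs: int = 200
    warmup_epochs: int = 40
    k: int = 2
    seed: int = 0
    centroid_update_period: int = 5
    soft_assignment: bool = False
    softmin_temperature: float = 1.0

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 2:
            raise ValueError("layer_sizes needs at least input and embedding widths")
        if min(self.gamma1, self.gamma2, self.gamma3) < 0:
            raise ValueError("loss weights gamma1..3 must be nonnegative")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs <= 0 or self.warmup_epochs < 0:
            raise ValueError("epochs must be positive, warmup_epochs nonnegative")
        if self.k < 2:
            raise ValueError("cluster count k must be >= 2")
        if self.layer_sizes[-1] < self.k:
            raise ValueError("embedding dimension must be >= cluster count")
        if self.centroid_update_period < 1:
            raise ValueError("centroid_update_period must be >= 1")


# ---------------------------------------------------------------------------
# forward passes


def _stack_forward(s: np.ndarray, h: np.ndarray, weights: list[np.ndarray]):
    """Graph-conv stack: hidden layers ReLU, final layer linear.

    Returns the output plus per-layer caches (S @ H_in, pre-activation).
    """
    sh_cache, pre_cache = [], []
    for li, w in enumerate(weights):
        if h.shape[1] != w.shape[0]:
            raise ValueError(
                f"layer {li}: input width {h.shape[1]} != weight rows {w.shape[0]}"
            )
        sh = s @ h
        pre = sh @ w
        sh_cache.append(sh)
        pre_cache.append(pre)
        h = pre if li == len(weights) - 1 else np.maximum(pre, 0.0)
    return h, sh_cache, pre_cache


def _stack_backward(s, d_out, weights, sh_cache, pre_cache,
                    need_input_grad: bool = True):
    """Gradients of a graph-conv stack; returns (dWs, d_input)."""
    grads = [None] * len(weights)
    dh = d_out
    for li in range(len(weights) - 1, -1, -1):
        dpre = dh if li == len(weights) - 1 else dh * (pre_cache[li] > 0)
        grads[li] = sh_cache[li].T @ dpre
        if li > 0 or need_input_grad:
            dh = s @ (dpre @ weights[li].T)
        else:
            dh = None
    return grads, dh


def encode(operator: np.ndarray, features: np.ndarray,
           weights: list[np.ndarray]) -> np.ndarray:
    """Embeddings Z from the encoder stack (hidden ReLU, linear output)."""
    z, _, _ = _stack_forward(np.asarray(operator, float),
                             np.asarray(features, float), list(weights))
    return z


def decode(operator: np.ndarray, z: np.ndarray,
           weights: list[np.ndarray]) -> np.ndarray:
    """Reconstruction X_hat from the mirror decoder stack."""
    xhat, _, _ = _stack_forward(np.asarray(operator, float),
                                np.asarray(z, float), list(weights))
    return xhat


# ---------------------------------------------------------------------------
# losses

_P_CLIP = 1e-7


def reconstruction_loss(x: np.ndarray, xhat: np.ndarray) -> float:
    x = np.asarray(x, float)
    xhat = np.asarray(xhat, float)
    if x.shape != xhat.shape:
        raise ValueError("reconstruction shapes differ")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(xhat))):
        raise ValueError("non-finite input to reconstruction loss")
    return float(np.mean((x - xhat) ** 2))


def _sigmoid(t: np.ndarray) -> np.ndarray:
    out = np.empty_like(t)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def classification_loss(z: np.ndarray, labels: np.ndarray, clf_w: np.ndarray,
                        clf_b: float) -> float:
    """Mean binary cross-entropy of the linear classifier head on Z."""
    y = np.asarray(labels, float)
    if len(np.unique(y)) < 2:
        logger.warning("classification labels are single-class; BCE still defined")
    p = np.clip(_sigmoid(np.asarray(z, float) @ clf_w + clf_b),
                _P_CLIP, 1.0 - _P_CLIP)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def deep_kmeans_loss(z_patients: np.ndarray, centroids: np.ndarray,
                     assignments: np.ndarray) -> float:
    """Mean squared Euclidean distance of each patient to its centroid."""
    z = np.asarray(z_patients, float)
    mu = np.asarray(centroids, float)
    a = np.asarray(assignments, int)
    k = mu.shape[0]
    if a.min() < 0 or a.max() >= k:
        raise ValueError("assignments out of range")
    counts = np.bincount(a, minlength=k)
    if np.any(counts == 0):
        raise EmptyClusterError(
            f"empty cluster(s) {np.flatnonzero(counts == 0).tolist()} at evaluation"
        )
    diff = z - mu[a]
    return float(np.mean(np.sum(diff ** 2, axis=1)))


def total_loss(l_rec: float, l_ce: float, l_cluster: float,
               config: ModelConfig) -> float:
    parts = (l_rec, l_ce, l_cluster)
    if not np.all(np.isfinite(parts)):
        raise ValueError("non-finite loss component")
    return config.gamma1 * l_rec + config.gamma2 * l_ce + config.gamma3 * l_cluster


# ---------------------------------------------------------------------------
# centroids

def _pairwise_sq(z: np.ndarray, mu: np.ndarray) -> np.ndarray:
    return ((z[:, None, :] - mu[None, :, :]) ** 2).sum(axis=2)


def update_centroids_and_assignments(z_patients: np.ndarray,
                                     centroids: np.ndarray):
    """One hard K-means alternation with embeddings frozen.

    Assign each point to its nearest centroid (ties to the lowest index),
    then move each centroid to the mean of its members.  An emptied cluster
    is re-seeded at the point farthest from its nearest centroid (logged).
    With Z fixed this never increases the deep K-means loss.
    """
    z = np.asarray(z_patients, float)
    mu = np.asarray(centroids, float).copy()
    k = mu.shape[0]
    d2 = _pairwise_sq(z, mu)
    assign = np.argmin(d2, axis=1)
    nearest = d2[np.arange(z.shape[0]), assign]
    for c in range(k):
        members = assign == c
        if members.any():
            mu[c] = z[members].mean(axis=0)
        else:
            far = int(np.argmax(nearest))
            logger.info("re-seeding empty cluster %d at point %d", c, far)
            mu[c] = z[far]
            assign[far] = c
            nearest[far] = 0.0
    return mu, assign


def farthest_point_init(z: np.ndarray, k: int, rng: np.random.Generator
                        ) -> np.ndarray:
    """Greedy farthest-point centroid seeding (ties -> lowest index)."""
    z = np.asarray(z, float)
    n = z.shape[0]
    if k > n:
        raise ValueError(f"cannot seed {k} centroids from {n} points")
    first = int(rng.integers(n))
    chosen = [first]
    min_d2 = np.sum((z - z[first]) ** 2, axis=1)
    while len(chosen) < k:
        nxt = int(np.argmax(min_d2))
        chosen.append(nxt)
        min_d2 = np.minimum(min_d2, np.sum((z - z[nxt]) ** 2, axis=1))
    return z[chosen].copy()


def lloyd_kmeans(z: np.ndarray, k: int, rng: np.random.Generator,
                 tol: float = 1e-6, max_iter: int = 500):
    """Plain K-means with farthest-point seeding; returns (centroids, assign)."""
    mu = farthest_point_init(z, k, rng)
    prev = None
    for _ in range(max_iter):
        mu_new, assign = update_centroids_and_assignments(z, mu)
        if prev is not None and np.array_equal(assign, prev) and \
                np.max(np.abs(mu_new - mu)) < tol:
            mu = mu_new
            break
        mu, prev = mu_new, assign
    return mu, assign


def _order_by_size(centroids: np.ndarray, assignments: np.ndarray):
    """Relabel clusters so biotype 1 is the largest subgroup (stable ties)."""
    k = centroids.shape[0]
    counts = np.bincount(assignments, minlength=k)
    order = np.argsort(-counts, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return centroids[order], remap[assignments]


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainState:
    """Trained GCN-BSD: weights, centroids, history and final assignments."""

    config: ModelConfig
    enc_weights: list[np.ndarray]
    dec_weights: list[np.ndarray]
    clf_w: np.ndarray
    clf_b: float
    centroids: np.ndarray            # K x d
    assignments: np.ndarray          # per patient, values 1..K
    patient_ids: list[str]
    subject_ids: list[str]
    embeddings: np.ndarray           # final N x d
    loss_history: pd.DataFrame = field(repr=False)

    def assignments_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"subject_id": self.patient_ids,
                             "biotype": self.assignments})

    def save(self, path) -> None:
        meta = {"schema": "gcnbsd-checkpoint-1", "config": asdict(self.config)}
        arrays = {"clf_w": self.clf_w, "clf_b": np.array([self.clf_b]),
                  "centroids": self.centroids,
                  "assignments": self.assignments,
                  "embeddings": self.embeddings}
        for i, w in enumerate(self.enc_weights):
            arrays[f"enc_{i}"] = w
        for i, w in enumerate(self.dec_weights):
            arrays[f"dec_{i}"] = w
        arrays["meta_json"] = np.frombuffer(
            json.dumps({**meta,
                        "patient_ids": self.patient_ids,
                        "subject_ids": self.subject_ids}).encode(), dtype=np.uint8)
        np.savez(path, **arrays)
        hist_path = str(path) + ".history.tsv"
        self.loss_history.to_csv(hist_path, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "TrainState":
        npz = np.load(path)
        meta = json.loads(bytes(npz["meta_json"]).decode())
        if meta.get("schema") != "gcnbsd-checkpoint-1":
            raise ValueError("unrecognized checkpoint schema")
        cfg_d = meta["config"]
        cfg_d["layer_sizes"] = tuple(cfg_d["layer_sizes"])
        cfg = ModelConfig(**cfg_d)
        enc = [npz[f"enc_{i}"] for i in range(len(cfg.layer_sizes) - 1)]
        dec = [npz[f"dec_{i}"] for i in range(len(cfg.layer_sizes) - 1)]
        try:
            hist = pd.read_csv(str(path) + ".history.tsv", sep="\t")
        except FileNotFoundError:
            hist = pd.DataFrame()
        return cls(config=cfg, enc_weights=enc, dec_weights=dec,
                   clf_w=npz["clf_w"], clf_b=float(npz["clf_b"][0]),
                   centroids=npz["centroids"], assignments=npz["assignments"],
                   patient_ids=meta["patient_ids"],
                   subject_ids=meta["subject_ids"],
                   embeddings=npz["embeddings"], loss_history=hist)


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


class _Adam:
    def __init__(self, shapes, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


def _cluster_grad_and_loss(zp, mu, assign, soft, temperature):
    """Deep K-means loss and its gradient w.r.t. patient embeddings."""
    n = zp.shape[0]
    if not soft:
        diff = zp - mu[assign]
        loss = float(np.mean(np.sum(diff ** 2, axis=1)))
        grad = 2.0 * diff / n
        return loss, grad
    d2 = _pairwise_sq(zp, mu)
    t = temperature
    logits = -d2 / t
    m = logits.max(axis=1, keepdims=True)
    lse = m + np.log(np.exp(logits - m).sum(axis=1, keepdims=True))
    loss = float(np.mean(-t * lse))
    resp = np.exp(logits - lse)
    grad = (resp[:, :, None] * 2.0 * (zp[:, None, :] - mu[None, :, :])).sum(axis=1) / n
    return loss, grad


def train(g: PopulationGraph, config: ModelConfig) -> TrainState:
    """Fit GCN-BSD on a population graph.

    Deterministic given the seed and config (up to floating-point reduction
    order).  Warm-up epochs train the autoencoder and classifier only; the
    clustering term activates afterwards with farthest-point-seeded
    centroids refreshed every ``centroid_update_period`` epochs.  Final
    biotype labels (1..k) are ordered by descending cluster size, so
    biotype 1 is always the largest subgroup.
    """
    x = np.asarray(g.features, float)
    n, f = x.shape
    if config.layer_sizes[0] != f:
        raise ValueError(
            f"layer_sizes[0]={config.layer_sizes[0]} != feature dim {f}")
    pidx = g.patient_index
    if pidx.size < config.k:
        raise ValueError("fewer patients than clusters")
    y = g.labels.astype(float)
    s = normalize_adjacency(g.adjacency)

    rng = np.random.default_rng(config.seed)
    sizes = list(config.layer_sizes)
    enc = [_glorot(rng, a, b) for a, b in zip(sizes[:-1], sizes[1:])]
    dec_sizes = sizes[::-1]
    dec = [_glorot(rng, a, b) for a, b in zip(dec_sizes[:-1], dec_sizes[1:])]
    clf_w = _glorot(rng, sizes[-1], 1).ravel()
    clf_b = np.zeros(1)

    params = enc + dec + [clf_w, clf_b]
    opt = _Adam([p.shape for p in params], config.learning_rate)

    use_cluster = config.gamma3 > 0 and config.epochs > config.warmup_epochs
    mu = None
    assign = None
    history = []

    for epoch in range(config.epochs):
        z, enc_sh, enc_pre = _stack_forward(s, x, enc)
        xhat, dec_sh, dec_pre = _stack_forward(s, z, dec)
        logits = z @ clf_w + clf_b[0]
        p = np.clip(_sigmoid(logits), _P_CLIP, 1.0 - _P_CLIP)

        l_rec = float(np.mean((x - xhat) ** 2))
        l_ce = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

        clustering_active = use_cluster and epoch >= config.warmup_epochs
        zp = z[pidx]
        if clustering_active:
            if mu is None:
                mu = farthest_point_init(zp, config.k, rng)
                _, assign = update_centroids_and_assignments(zp, mu)
            elif (epoch - config.warmup_epochs) % config.centroid_update_period == 0:
                before = deep_kmeans_loss(zp, mu, np.argmin(_pairwise_sq(zp, mu), axis=1))
                mu, assign = update_centroids_and_assignments(zp, mu)
                after = deep_kmeans_loss(zp, mu, assign)
                if after > before + 1e-9:
                    raise RuntimeError(
                        "centroid/assignment refresh increased the clustering "
                        f"loss at epoch {epoch} ({before} -> {after})")
            l_cluster, g_cluster = _cluster_grad_and_loss(
                zp, mu, assign, config.soft_assignment, config.softmin_temperature)
        else:
            l_cluster, g_cluster = 0.0, None

        l_total = total_loss(l_rec, l_ce, l_cluster, config)
        if not np.isfinite(l_total):
            raise RuntimeError(f"non-finite loss at epoch {epoch}")
        history.append((epoch, l_rec, l_ce, l_cluster, l_total))

        # --- backward ---
        d_xhat = config.gamma1 * 2.0 * (xhat - x) / x.size
        dec_grads, dz = _stack_backward(s, d_xhat, dec, dec_sh, dec_pre)
        dlogits = config.gamma2 * (p - y) / n
        dz = dz + np.outer(dlogits, clf_w)
        d_clf_w = z.T @ dlogits
        d_clf_b = np.array([dlogits.sum()])
        if g_cluster is not None:
            dz[pidx] += config.gamma3 * g_cluster
        enc_grads, _ = _stack_backward(s, dz, enc, enc_sh, enc_pre,
                                       need_input_grad=False)

        opt.step(params, enc_grads + dec_grads + [d_clf_w, d_clf_b])

    # final embeddings and assignments
    z = encode(s, x, enc)
    zp = z[pidx]
    if mu is None:
        # clustering term never active: plain K-means on the learned embeddings
        mu, assign = lloyd_kmeans(zp, config.k, rng)
    else:
        mu, assign = update_centroids_and_assignments(zp, mu)
    mu, assign = _order_by_size(mu, assign)

    hist = pd.DataFrame(history, columns=["epoch", "loss_rec", "loss_ce",
                                          "loss_cluster", "loss_total"])
    return TrainState(
        config=config, enc_weights=enc, dec_weights=dec, clf_w=clf_w,
        clf_b=float(clf_b[0]), centroids=mu, assignments=assign + 1,
        patient_ids=[g.subject_ids[i] for i in pidx],
        subject_ids=list(g.subject_ids), embeddings=z, loss_history=hist)


def extract_biotype_templates(features_raw: np.ndarray,
                              assignments: np.ndarray,
                              k: int | None = None) -> np.ndarray:
    """Per-biotype mean FNC vectors on the raw correlation scale.

    ``assignments`` uses labels 1..K aligned with the feature rows; returns
    a K x n_edges template matrix.
    """
    x = np.asarray(features_raw, float)
    a = np.asarray(assignments, int)
    if x.shape[0] != a.shape[0]:
        raise ValueError("assignments must align with feature rows")
    if k is None:
        k = int(a.max())
    templates = np.empty((k, x.shape[1]))
    for c in range(1, k + 1):
        members = a == c
        if not members.any():
            raise EmptyClusterError(f"biotype {c} has no members")
        templates[c - 1] = x[members].mean(axis=0)
    return templates
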