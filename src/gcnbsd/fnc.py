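"""Functional network connectivity (FNC) features.

Subject-level FNC is the Pearson correlation matrix between the time courses
of C independent component networks (ICNs).  The strict upper triangle,
flattened row-major, is the subject's feature vector; with the default
53-component NeuroMark parcellation this gives 53*52/2 = 1378 edges grouped
into 7 functional domains (SC, AU, SM, VI, CC, DM, CB).

All modules in this package share the canonical edge order defined by
:func:`edge_component_pairs`: components in atlas order, edge (i, j) with
i < j enumerated row by row.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NETWORK_ORDER: tuple[str, ...] = ("SC", "AU", "SM", "VI", "CC", "DM", "CB")

__all__ = [
    "NETWORK_ORDER",
    "NetworkAtlas",
    "default_atlas",
    "compute_fnc_matrix",
    "vectorize_upper_triangle",
    "devectorize",
    "edge_component_pairs",
    "n_edges",
    "components_from_edges",
    "regress_covariates",
    "network_block_summary",
    "block_edge_indices",
    "FeatureScaler",
]


@dataclass(frozen=True)
class NetworkAtlas:
    """Mapping from ICN components to named functional networks.

    Parameters
    ----------
    component_ids
        Component identifiers in canonical order.
    network_of
        Map from component id to network name; every component must be
        mapped to exactly one network.
    network_order
        Ordered network names; defaults to the 7 NeuroMark domains.
    """

    component_ids: tuple[int, ...]
    network_of: dict[int, str] = field(repr=False)
    network_order: tuple[str, ...] = NETWORK_ORDER

    def __post_init__(self) -> None:
        missing = [c for c in self.component_ids if c not in self.network_of]
        if missing:
            raise ValueError(f"components without a network assignment: {missing}")
        bad = {n for n in self.network_of.values()} - set(self.network_order)
        if bad:
            raise ValueError(f"unknown network names: {sorted(bad)}")

    @property
    def n_components(self) -> int:
        return len(self.component_ids)

    @property
    def component_counts(self) -> dict[str, int]:
        counts = {name: 0 for name in self.network_order}
        for c in self.component_ids:
            counts[self.network_of[c]] += 1
        return counts

    def network_index_of_components(self) -> np.ndarray:
        """Index into ``network_order`` for each component, canonical order."""
        pos = {name: k for k, name in enumerate(self.network_order)}
        return np.array([pos[self.network_of[c]] for c in self.component_ids])

    @classmethod
    def from_table(cls, table: pd.DataFrame,
                   network_order: tuple[str, ...] | None = None) -> "NetworkAtlas":
        ids = tuple(int(c) for c in table["component_id"])
        mapping = {int(c): str(n) for c, n in
                   zip(table["component_id"], table["network"])}
        if network_order is None:
            seen: list[str] = []
            for n in table["network"]:
                if n not in seen:
                    seen.append(str(n))
            network_order = tuple(seen)
        return cls(component_ids=ids, network_of=mapping,
                   network_order=network_order)

    @classmethod
    def from_tsv(cls, path) -> "NetworkAtlas":
        table = pd.read_csv(path, sep="\t", comment="#")
        return cls.from_table(table)


def default_atlas() -> NetworkAtlas:
    """The 53-component / 7-network NeuroMark atlas shipped with the package."""
    ref = importlib.resources.files("gcnbsd.data") / "neuromark53_atlas.tsv"
    with importlib.resources.as_file(ref) as path:
        return NetworkAtlas.from_tsv(path)


def compute_fnc_matrix(data: np.ndarray, subject_id: str | None = None) -> np.ndarray:
    """Pearson correlation matrix of component time courses.

    Parameters
    ----------
    data
        Array of shape (C components, T timepoints), C >= 2, T >= 3.

    Returns
    -------
    Symmetric C x C matrix with unit diagonal.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("time-course data must be a 2-D (components x timepoints) array")
    c, t = data.shape
    if c < 2 or t < 3:
        raise ValueError(f"need >= 2 components and >= 3 timepoints, got {c} x {t}")
    if not np.all(np.isfinite(data)):
        raise ValueError("time-course data contains non-finite values")
    var = data.var(axis=1)
    dead = np.flatnonzero(var <= 0)
    if dead.size:
        who = f" (subject {subject_id})" if subject_id else ""
        raise ValueError(f"zero-variance component(s) {dead.tolist()}{who}")
    m = np.corrcoef(data)
    np.fill_diagonal(m, 1.0)
    return np.clip(m, -1.0, 1.0)


def vectorize_upper_triangle(m: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Flatten the strict upper triangle of a symmetric matrix, row-major."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.allclose(m, m.T, atol=tol, rtol=0.0):
        raise ValueError(f"matrix is not symmetric within tolerance {tol}")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu].copy()


def n_edges(c: int) -> int:
    return c * (c - 1) // 2


def components_from_edges(length: int) -> int:
    """Invert L = C(C-1)/2; reject non-triangular lengths."""
    c = int(round((1.0 + np.sqrt(1.0 + 8.0 * length)) / 2.0))
    if c < 2 or n_edges(c) != length:
        raise ValueError(f"{length} is not a triangular number C*(C-1)/2")
    return c


def devectorize(v: np.ndarray) -> np.ndarray:
    """Rebuild the symmetric matrix (unit diagonal) from an edge vector."""
    v = np.asarray(v, dtype=float).ravel()
    c = components_from_edges(v.size)
    m = np.eye(c)
    iu = np.triu_indices(c, k=1)
    m[iu] = v
    m[(iu[1], iu[0])] = v
    return m


def edge_component_pairs(c: int) -> np.ndarray:
    """(L, 2) array of component index pairs (i, j), i < j, canonical order."""
    iu = np.triu_indices(c, k=1)
    return np.column_stack(iu)


def regress_covariates(features: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residualize each feature column on nuisance covariates (plus intercept).

    Used to remove site/scanner effects before statistical analysis.  The
    returned residuals are orthogonal to every covariate column and are
    mean-centered (the intercept is always included in the design).
    """
    x = np.asarray(features, dtype=float)
    z = np.asarray(covariates, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    if x.shape[0] != z.shape[0]:
        raise ValueError("covariate rows must align with subjects")
    design = np.column_stack([np.ones(z.shape[0]), z])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify an offending column for the diagnostic
        for j in range(1, design.shape[1]):
            sub = design[:, list(range(j)) + [j]]
            if np.linalg.matrix_rank(sub) < np.linalg.matrix_rank(design[:, :j]) + 1:
                raise ValueError(
                    f"rank-deficient covariate design: column {j - 1} is "
                    "collinear with the preceding columns/intercept"
                )
        raise ValueError("rank-deficient covariate design")
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta


def block_edge_indices(atlas: NetworkAtlas) -> dict[tuple[int, int], np.ndarray]:
    """Canonical edge indices belonging to each network block (a <= b)."""
    net = atlas.network_index_of_components()
    pairs = edge_component_pairs(atlas.n_components)
    a = np.minimum(net[pairs[:, 0]], net[pairs[:, 1]])
    b = np.maximum(net[pairs[:, 0]], net[pairs[:, 1]])
    out: dict[tuple[int, int], np.ndarray] = {}
    k = len(atlas.network_order)
    for i in range(k):
        for j in range(i, k):
            out[(i, j)] = np.flatnonzero((a == i) & (b == j))
    return out


def network_block_summary(edge_values: np.ndarray,
                          atlas: NetworkAtlas) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate an edge vector into per-network-block means and counts.

    Returns
    -------
    means, counts
        Symmetric (n_networks x n_networks) arrays.  Block (a, b) covers all
        edges with one endpoint in network a and the other in b; empty blocks
        get mean NaN.  Counts over all blocks (upper triangle incl. diagonal)
        sum to C*(C-1)/2.
    """
    v = np.asarray(edge_values, dtype=float).ravel()
    if v.size != n_edges(atlas.n_components):
        raise ValueError(
            f"edge vector length {v.size} does not match atlas with "
            f"{atlas.n_components} components ({n_edges(atlas.n_components)} edges)"
        )
    k = len(atlas.network_order)
    means = np.full((k, k), np.nan)
    counts = np.zeros((k, k), dtype=int)
    for (i, j), idx in block_edge_indices(atlas).items():
        counts[i, j] = counts[j, i] = idx.size
        if idx.size:
            means[i, j] = means[j, i] = v[idx].mean()
    return means, counts


class FeatureScaler:
    """Per-feature z-scoring fitted on the discovery cohort and reused for
    validation cohorts.  Constant features are left uncentered-scaled by 1."""

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, x: np.ndarray) -> "FeatureScaler":
        x = np.asarray(x, dtype=float)
        self.mean_ = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        self.scale_ = sd
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("scaler is not fitted")
        return (np.asarray(x, dtype=float) - self.mean_) / self.scale_

    def fit_transform(self, x: np.ndarray) -> np.ndarray:
        return self.fit(x).transform(x)
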