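"""Population graph over subjects.

Nodes are subjects carrying standardized FNC feature vectors and a binary
diagnosis label; edge weights encode phenotypic similarity (gender equality
plus age proximity).  Graph convolutions use the symmetric renormalized
operator D^-1/2 (A + I) D^-1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PopulationGraph",
    "phenotypic_similarity",
    "build_graph",
    "normalize_adjacency",
    "patient_subgraph",
]


@dataclass
class PopulationGraph:
    subject_ids: list[str]
    features: np.ndarray          # N x F, standardized FNC
    labels: np.ndarray            # N, patient=1 / control=0
    adjacency: np.ndarray         # N x N symmetric, nonnegative, zero diagonal
    age_months: np.ndarray
    gender: np.ndarray            # array of strings

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        if self.features.shape[0] != n or self.labels.shape[0] != n:
            raise ValueError("features/labels must align with subject_ids")
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be N x N")
        if not np.allclose(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(self.adjacency < 0):
            raise ValueError("adjacency weights must be nonnegative")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary (patient=1, control=0)")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def patient_index(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 1)

    def edge_list(self) -> pd.DataFrame:
        """Upper-triangle nonzero edges as a (id_i, id_j, weight) table."""
        iu = np.triu_indices(self.n_subjects, k=1)
        w = self.adjacency[iu]
        keep = w > 0
        return pd.DataFrame({
            "id_i": np.asarray(self.subject_ids)[iu[0][keep]],
            "id_j": np.asarray(self.subject_ids)[iu[1][keep]],
            "weight": w[keep],
        })


def phenotypic_similarity(age_i: float, age_j: float, gender_i: str,
                          gender_j: str, age_tol: float = 24.0) -> int:
    """Additive indicator similarity: gender equality + age within tolerance.

    Returns a weight in {0, 1, 2}.  Ages in months; gender compared as
    case-folded strings.  ``age_tol`` defaults to 24 months.
    """
    if age_i <= 0 or age_j <= 0:
        raise ValueError("ages must be positive")
    w = int(str(gender_i).casefold() == str(gender_j).casefold())
    w += int(abs(float(age_i) - float(age_j)) <= age_tol)
    return w


def build_graph(subject_ids, features, labels, age_months, gender,
                age_tol: float = 24.0,
                feature_kernel: bool = True) -> PopulationGraph:
    """Assemble the population graph from aligned cohort arrays.

    By default the phenotypic weight of each pair is multiplied by the
    clipped-nonnegative correlation of their FNC vectors.  This keeps the
    operator informative on demographically homogeneous cohorts: with the
    purely phenotypic {0, 1, 2} weights (``feature_kernel=False``) the
    graph is nearly complete and the renormalized operator is close to
    rank one, so stacked convolutions smooth every subject onto the cohort
    mean and the embeddings degenerate.
    """
    subject_ids = [str(s) for s in subject_ids]
    if len(set(subject_ids)) != len(subject_ids):
        dupes = sorted({s for s in subject_ids if subject_ids.count(s) > 1})
        raise ValueError(f"duplicate subject ids: {dupes}")
    n = len(subject_ids)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    age = np.asarray(age_months, dtype=float)
    gen = np.asarray([str(g).casefold() for g in gender])
    if np.any(age <= 0):
        raise ValueError("ages must be positive")

    same_gender = (gen[:, None] == gen[None, :]).astype(float)
    close_age = (np.abs(age[:, None] - age[None, :]) <= age_tol).astype(float)
    adj = same_gender + close_age
    if feature_kernel:
        x = np.asarray(features, dtype=float)
        xc = x - x.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(xc, axis=1)
        norms[norms == 0] = 1.0
        corr = (xc @ xc.T) / np.outer(norms, norms)
        adj = adj * np.clip(corr, 0.0, None)
    np.fill_diagonal(adj, 0.0)
    return PopulationGraph(subject_ids=subject_ids, features=features,
                           labels=labels, adjacency=adj,
                           age_months=age, gender=gen)


def normalize_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Symmetric renormalized operator D^-1/2 (A + I) D^-1/2.

    Self-loops are added here only; isolated nodes reduce to identity rows.
    Eigenvalues of the result lie in (-1, 1].
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if np.any(a < 0):
        raise ValueError("adjacency weights must be nonnegative")
    a_hat = a + np.eye(a.shape[0])
    d = a_hat.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(d)
    return a_hat * np.outer(d_inv_sqrt, d_inv_sqrt)


def patient_subgraph(g: PopulationGraph, min_patients: int = 2) -> PopulationGraph:
    """Induced subgraph on patient nodes, edge weights unchanged."""
    idx = g.patient_index
    if idx.size < min_patients:
        raise ValueError(
            f"patient subgraph needs >= {min_patients} patients, got {idx.size}"
        )
    return PopulationGraph(
        subject_ids=[g.subject_ids[i] for i in idx],
        features=g.features[idx],
        labels=g.labels[idx],
        adjacency=g.adjacency[np.ix_(idx, idx)],
        age_months=g.age_months[idx],
        gender=g.gender[idx],
    )
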