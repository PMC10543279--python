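"""Cross-cohort biotype transfer.

Discovery biotypes are summarized as mean-FNC templates (one length-1378
vector per biotype on the raw correlation scale).  Subjects of an
independent cohort are projected onto the templates by Euclidean distance
(nearest template wins, ties to the lowest biotype index), and replication
is quantified as the Pearson correlation between the cohorts'
biotype-vs-control mean-difference connectivity patterns, over all edges or
a selected subset (e.g. the top-100 discriminative edges).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "project_subject",
    "project_cohort",
    "mean_difference_pattern",
    "replication_correlation",
    "save_templates",
    "load_templates",
]


def project_subject(fnc: np.ndarray, templates: np.ndarray):
    """Assign one subject to the nearest biotype template.

    Returns ``(biotype, distances)`` with biotype in 1..K and the Euclidean
    distance to every template.  Exact ties go to the lowest index.
    """
    v = np.asarray(fnc, float).ravel()
    t = np.asarray(templates, float)
    if t.ndim != 2 or t.shape[1] != v.size:
        raise ValueError(
            f"template dimension {t.shape} incompatible with FNC length {v.size}")
    d = np.linalg.norm(t - v, axis=1)
    return int(np.argmin(d)) + 1, d


def project_cohort(fnc_matrix: np.ndarray, templates: np.ndarray,
                   subject_ids=None) -> pd.DataFrame:
    """Project every row of an N x 1378 FNC matrix onto the templates."""
    x = np.asarray(fnc_matrix, float)
    t = np.asarray(templates, float)
    if x.shape[1] != t.shape[1]:
        raise ValueError("FNC and template dimensions differ")
    d = np.linalg.norm(x[:, None, :] - t[None, :, :], axis=2)
    biotype = np.argmin(d, axis=1) + 1
    if subject_ids is None:
        subject_ids = [f"s{i}" for i in range(x.shape[0])]
    out = pd.DataFrame({"subject_id": list(subject_ids), "biotype": biotype})
    for k in range(t.shape[0]):
        out[f"distance_{k + 1}"] = d[:, k]
    return out


def mean_difference_pattern(fnc_matrix: np.ndarray, idx_a, idx_b) -> np.ndarray:
    """Elementwise mean(group a) - mean(group b) connectivity pattern."""
    x = np.asarray(fnc_matrix, float)
    ia = np.asarray(idx_a)
    ib = np.asarray(idx_b)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("both groups must be nonempty")
    return x[ia].mean(axis=0) - x[ib].mean(axis=0)


def replication_correlation(pattern_a: np.ndarray, pattern_b: np.ndarray,
                            subset=None) -> tuple[float, float]:
    """Pearson r (and two-sided p) between two connectivity patterns."""
    a = np.asarray(pattern_a, float).ravel()
    b = np.asarray(pattern_b, float).ravel()
    if a.size != b.size:
        raise ValueError("patterns must have equal length")
    if subset is not None:
        subset = np.asarray(subset, int)
        if subset.size and (subset.min() < 0 or subset.max() >= a.size):
            raise ValueError("subset indices out of range")
        a, b = a[subset], b[subset]
    if a.size < 3:
        raise ValueError("need at least 3 edges to correlate")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance pattern: correlation undefined")
    r, p = sps.pearsonr(a, b)
    return float(r), float(p)


def save_templates(path, templates: np.ndarray, cohort: str = "",
                   source: str = "trained") -> None:
    t = np.asarray(templates, float)
    with open(path, "w") as fh:
        fh.write(f"# biotype FNC templates\n# cohort: {cohort}\n"
                 f"# source: {source}\n# k: {t.shape[0]}\n")
        pd.DataFrame(t, index=[f"biotype_{i + 1}" for i in range(t.shape[0])]
                     ).to_csv(fh, sep="\t", header=False)


def load_templates(path) -> np.ndarray:
    table = pd.read_csv(path, sep="\t", comment="#", header=None, index_col=0)
    return table.to_numpy(dtype=float)
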