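"""Group statistics for biotype characterization.

Edge-level two-sample t-tests (biotype vs. control or biotype vs. biotype),
top-k discriminative edge selection, cross-cohort edge overlap, Cohen's d
effect sizes from summary statistics, edge-score correlations, and
Bonferroni correction for the cognitive/clinical scale families.

The default Cohen's d uses the root-mean-square of the two group SDs as the
standardizer, d = |m_a - m_b| / sqrt((sd_a^2 + sd_b^2) / 2); an n-weighted
pooled-SD variant is available via ``method="pooled"``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fnc import NetworkAtlas, edge_component_pairs, n_edges

__all__ = [
    "SummaryStats",
    "two_sample_t",
    "two_sample_t_from_summary",
    "cohens_d_from_summary",
    "load_reference_summaries",
    "edge_ttests",
    "top_k_edges",
    "edge_overlap",
    "scale_correlations",
    "bonferroni",
]


@dataclass(frozen=True)
class SummaryStats:
    """Per-group summary of a scale: n, mean and SD."""

    group: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


def two_sample_t(group_a, group_b) -> tuple[float, float, int]:
    """Student's pooled-variance two-sample t-test (two-sided).

    Returns (t, p, df) with df = n_a + n_b - 2.  Welch's variant is
    deliberately not the default so that t and Cohen's d share a scale.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero pooled variance: t undefined")
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue), int(a.size + b.size - 2)


def two_sample_t_from_summary(a: SummaryStats, b: SummaryStats
                              ) -> tuple[float, float, int]:
    """Pooled two-sample t from printed group summaries (n, mean, SD)."""
    if a.sd == 0 and b.sd == 0:
        raise ValueError("zero pooled variance: t undefined")
    res = sps.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                                   equal_var=True)
    return float(res.statistic), float(res.pvalue), int(a.n + b.n - 2)


def cohens_d_from_summary(a: SummaryStats, b: SummaryStats,
                          method: str = "rms") -> float:
    """Cohen's d between two groups from summary statistics.

    ``method="rms"`` (default) standardizes by sqrt((sd_a^2 + sd_b^2)/2);
    ``method="pooled"`` uses the n-weighted pooled SD.
    """
    if a.sd == 0 and b.sd == 0:
        raise ValueError("both SDs are zero: effect size undefined")
    if method == "rms":
        denom = np.sqrt((a.sd ** 2 + b.sd ** 2) / 2.0)
    elif method == "pooled":
        denom = np.sqrt(((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2)
                        / (a.n + b.n - 2))
    else:
        raise ValueError(f"unknown effect-size method '{method}'")
    return float(abs(a.mean - b.mean) / denom)


def load_reference_summaries(cohort: str = "abcd") -> pd.DataFrame:
    """Published biotype group summaries shipped with the package.

    ``cohort`` is "abcd" (discovery cognitive battery) or "pku" (validation
    IQ/symptom scales).  Columns: measure, n/mean/sd per biotype.
    """
    names = {"abcd": "abcd_biotype_cognition_summary.tsv",
             "pku": "pku_biotype_clinical_summary.tsv"}
    if cohort not in names:
        raise ValueError("cohort must be 'abcd' or 'pku'")
    ref = importlib.resources.files("gcnbsd.data") / names[cohort]
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def edge_ttests(fnc_matrix: np.ndarray, idx_a, idx_b,
                atlas: NetworkAtlas | None = None) -> pd.DataFrame:
    """Per-edge two-sample t-tests between two subject groups.

    Degenerate edges (zero pooled variance) are flagged with ``valid=False``
    rather than aborting the scan.  Returns one row per canonical edge with
    component/network annotation when an atlas is given.
    """
    x = np.asarray(fnc_matrix, float)
    ia = np.asarray(idx_a)
    ib = np.asarray(idx_b)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("both groups must be nonempty")
    if np.intersect1d(ia, ib).size:
        raise ValueError("groups must be disjoint")
    xa, xb = x[ia], x[ib]
    na, nb = xa.shape[0], xb.shape[0]
    df = na + nb - 2
    va = xa.var(axis=0, ddof=1)
    vb = xb.var(axis=0, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / df
    valid = pooled > 0
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (xa.mean(axis=0) - xb.mean(axis=0)) / se
    p = np.full_like(t, np.nan)
    p[valid] = 2.0 * sps.t.sf(np.abs(t[valid]), df)
    out = pd.DataFrame({"edge": np.arange(x.shape[1]), "t": t, "p": p,
                        "df": df, "valid": valid})
    if atlas is not None:
        if x.shape[1] != n_edges(atlas.n_components):
            raise ValueError("edge count does not match atlas")
        pairs = edge_component_pairs(atlas.n_components)
        comp = np.asarray(atlas.component_ids)
        neti = atlas.network_index_of_components()
        order = atlas.network_order
        out["icn_i"] = comp[pairs[:, 0]]
        out["icn_j"] = comp[pairs[:, 1]]
        out["network_i"] = [order[neti[i]] for i in pairs[:, 0]]
        out["network_j"] = [order[neti[j]] for j in pairs[:, 1]]
    return out


def top_k_edges(stats: pd.DataFrame, k: int = 100) -> pd.DataFrame:
    """The k edges with the largest |t| (ties -> smaller canonical index)."""
    valid = stats[stats["valid"]] if "valid" in stats else stats
    if k < 1 or k > len(valid):
        raise ValueError(f"k must be in 1..{len(valid)}")
    order = np.lexsort((valid["edge"].to_numpy(),
                        -np.abs(valid["t"].to_numpy())))
    sel = valid.iloc[order[:k]].sort_values("edge")
    out = stats.copy()
    out["selected"] = out["edge"].isin(sel["edge"]).to_numpy()
    return out


def edge_overlap(selected_a, selected_b) -> np.ndarray:
    """Shared canonical edge indices of two top-k selections (sorted)."""
    a = np.asarray(selected_a, int)
    b = np.asarray(selected_b, int)
    return np.intersect1d(a, b)


def scale_correlations(edge_values: np.ndarray, scales: pd.DataFrame
                       ) -> pd.DataFrame:
    """Pearson correlation of each edge with each scale across subjects.

    ``edge_values`` is N x E (subjects x selected edges); ``scales`` an
    N-row frame, one column per scale.  Missing scale entries are dropped
    pairwise; degenerate pairs (n < 3 or zero variance) are flagged.
    """
    x = np.asarray(edge_values, float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != len(scales):
        raise ValueError("edge values and scales must align on subjects")
    rows = []
    for e in range(x.shape[1]):
        for col in scales.columns:
            s = pd.to_numeric(scales[col], errors="coerce").to_numpy(float)
            keep = np.isfinite(s) & np.isfinite(x[:, e])
            n = int(keep.sum())
            if n < 3 or x[keep, e].std() == 0 or s[keep].std() == 0:
                rows.append((e, col, n, np.nan, np.nan, False))
                continue
            r, p = sps.pearsonr(x[keep, e], s[keep])
            rows.append((e, col, n, float(r), float(p), True))
    return pd.DataFrame(rows, columns=["edge", "scale", "n", "r", "p", "valid"])


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, m * p)."""
    p = np.asarray(p_values, float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of tests")
    return np.minimum(1.0, m * p)
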