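"""Longitudinal treatment-response analysis.

Symptom scales (ADHD RS-IV, CPRS factors) recorded at baseline and weeks
1/2/3/4/8 under methylphenidate (MPH) or atomoxetine (ATX) are summarized
as proportional reduction rates from baseline,

    reduction(w) = (score_0 - score_w) / score_0,

and compared between biotypes (or between biotype-medication cells, the
headline contrast being biotype 1 on MPH vs. biotype 2 on ATX) with
independent per-week two-sample t-tests, Benjamini-Hochberg corrected
within each week's family of scales.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .stats import two_sample_t

logger = logging.getLogger(__name__)

WEEKS = (1, 2, 3, 4, 8)

__all__ = ["WEEKS", "reduction_rate", "reduction_rates",
           "compare_groups_over_weeks", "fdr_adjust"]


def reduction_rate(baseline: float, score: float) -> float:
    """Proportional symptom reduction from baseline; positive = improvement."""
    if baseline <= 0:
        raise ValueError("baseline score must be positive")
    return (baseline - score) / baseline


def reduction_rates(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject/scale/week reduction rates from a long-format score table.

    ``table`` columns: subject_id, scale, week, score.  Week 0 is the
    baseline; subjects with a nonpositive or missing baseline for a scale
    are excluded from that scale with a log entry.
    """
    req = {"subject_id", "scale", "week", "score"}
    if not req <= set(table.columns):
        raise ValueError(f"longitudinal table needs columns {sorted(req)}")
    base = table[table["week"] == 0].set_index(["subject_id", "scale"])["score"]
    rows = []
    dropped = 0
    for (sid, scale), grp in table[table["week"] > 0].groupby(
            ["subject_id", "scale"], sort=False):
        b = base.get((sid, scale), np.nan)
        if not np.isfinite(b) or b <= 0:
            dropped += 1
            continue
        for _, rec in grp.iterrows():
            if np.isfinite(rec["score"]):
                rows.append((sid, scale, int(rec["week"]),
                             reduction_rate(b, rec["score"])))
    if dropped:
        logger.info("excluded %d subject-scale series without a positive baseline",
                    dropped)
    return pd.DataFrame(rows, columns=["subject_id", "scale", "week",
                                       "reduction_rate"])


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_groups_over_weeks(records: pd.DataFrame, phenotypes: pd.DataFrame,
                              grouping: str = "biotype",
                              weeks=WEEKS,
                              correction: str | None = "fdr") -> pd.DataFrame:
    """Per-scale per-week group contrasts of reduction rates.

    Parameters
    ----------
    records
        Long-format score table (subject_id, scale, week, score).
    phenotypes
        Per-subject table with a ``biotype`` column and, for the
        biotype-medication contrast, a ``medication`` column in
        {"MPH", "ATX", "none"}.
    grouping
        "biotype" contrasts biotype 1 vs. biotype 2; "biotype_medication"
        contrasts biotype 1 on MPH vs. biotype 2 on ATX.
    correction
        "fdr" (Benjamini-Hochberg within each week's scale family),
        "bonferroni", or None.

    Returns an empty frame when either group has fewer than 2 subjects for
    every contrast (collapsed grouping); skipped cells are logged.
    """
    rates = reduction_rates(records)
    pheno = phenotypes.set_index("subject_id")
    if grouping == "biotype":
        in_a = pheno.index[pheno["biotype"] == 1]
        in_b = pheno.index[pheno["biotype"] == 2]
    elif grouping == "biotype_medication":
        med = pheno["medication"].astype(str).str.upper()
        in_a = pheno.index[(pheno["biotype"] == 1) & (med == "MPH")]
        in_b = pheno.index[(pheno["biotype"] == 2) & (med == "ATX")]
    else:
        raise ValueError("grouping must be 'biotype' or 'biotype_medication'")

    rows = []
    for week in weeks:
        wk = rates[rates["week"] == week]
        for scale, grp in wk.groupby("scale", sort=False):
            a = grp[grp["subject_id"].isin(in_a)]["reduction_rate"].to_numpy()
            b = grp[grp["subject_id"].isin(in_b)]["reduction_rate"].to_numpy()
            if a.size < 2 or b.size < 2:
                logger.info("skipping %s week %d: cell too small (%d vs %d)",
                            scale, week, a.size, b.size)
                continue
            try:
                t, p, _ = two_sample_t(a, b)
            except ValueError:
                logger.info("skipping %s week %d: degenerate variance", scale, week)
                continue
            rows.append((scale, week, grouping, t, p, a.size, b.size))
    out = pd.DataFrame(rows, columns=["scale", "week", "grouping", "t",
                                      "p_raw", "n_a", "n_b"])
    if out.empty:
        out["p_adj"] = pd.Series(dtype=float)
        return out
    out["p_adj"] = np.nan
    for week in out["week"].unique():
        mask = out["week"] == week
        p = out.loc[mask, "p_raw"].to_numpy()
        if correction == "fdr":
            out.loc[mask, "p_adj"] = fdr_adjust(p)
        elif correction == "bonferroni":
            out.loc[mask, "p_adj"] = np.minimum(1.0, p * p.size)
        elif correction is None:
            out.loc[mask, "p_adj"] = p
        else:
            raise ValueError("correction must be 'fdr', 'bonferroni' or None")
    return out
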