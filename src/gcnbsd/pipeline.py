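"""End-to-end workflows composing the library modules.

These are the operations the command-line interface exposes: biotype
discovery (graph construction, GCN-BSD training, elbow/benchmark
evaluation, template extraction), template projection onto a validation
cohort with replication statistics, the discriminative-edge/effect-size
battery, and the longitudinal medication-response comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cluster, transfer, stats as dstats
from .fnc import FeatureScaler, NetworkAtlas, default_atlas, regress_covariates
from .graph import PopulationGraph, build_graph
from .model import ModelConfig, TrainState, extract_biotype_templates, train

__all__ = ["DiscoveryResult", "discover_biotypes", "validate_biotypes",
           "discriminative_battery", "site_design_matrix"]


def site_design_matrix(phenotypes: pd.DataFrame) -> np.ndarray | None:
    """Dummy-coded site/scanner indicators (drop-first), or None if a single
    level is present."""
    cols = [c for c in ("site", "scanner") if c in phenotypes.columns]
    if not cols:
        return None
    dummies = pd.get_dummies(phenotypes[cols].astype(str), drop_first=True)
    dummies = dummies.loc[:, dummies.std() > 0]
    if dummies.shape[1] == 0:
        return None
    # drop columns that are exact duplicates (site == scanner coding)
    dummies = dummies.T.drop_duplicates().T
    return dummies.to_numpy(dtype=float)


@dataclass
class DiscoveryResult:
    """Everything the discovery stage produces."""

    state: TrainState
    graph: PopulationGraph
    scaler: FeatureScaler
    templates: np.ndarray                 # K x n_edges, correlation scale
    sse_by_k: dict[int, float]
    chosen_k: int
    benchmark: pd.DataFrame = field(repr=False)

    @property
    def assignments(self) -> pd.DataFrame:
        return self.state.assignments_frame()


def discover_biotypes(fnc: np.ndarray, phenotypes: pd.DataFrame,
                      config: ModelConfig | None = None,
                      age_tol: float = 24.0,
                      k_range=range(1, 7),
                      run_benchmark: bool = True) -> DiscoveryResult:
    """Run the full discovery stage on one cohort.

    FNC features are z-scored over the cohort (the scaler is kept for
    validation reuse), the population graph is built from age/gender
    similarity, GCN-BSD is trained, biotype templates are extracted on the
    raw correlation scale, and the elbow curve plus the DBI/CHI benchmark
    are computed on the patient features/embeddings.
    """
    fnc = np.asarray(fnc, float)
    scaler = FeatureScaler()
    x = scaler.fit_transform(fnc)
    cfg = config or ModelConfig(layer_sizes=(fnc.shape[1], 256, 64))
    if cfg.layer_sizes[0] != fnc.shape[1]:
        cfg = ModelConfig(**{**cfg.__dict__,
                             "layer_sizes": (fnc.shape[1],) + tuple(cfg.layer_sizes[1:])})
    g = build_graph(subject_ids=phenotypes["subject_id"], features=x,
                    labels=phenotypes["diagnosis"].to_numpy(int),
                    age_months=phenotypes["age_months"].to_numpy(float),
                    gender=phenotypes["gender"].to_numpy(),
                    age_tol=age_tol)
    state = train(g, cfg)
    pidx = g.patient_index
    templates = extract_biotype_templates(fnc[pidx], state.assignments, cfg.k)
    sse = cluster.sse_elbow_curve(x[pidx], k_range, seed=cfg.seed)
    chosen = cluster.choose_k_elbow(sse)
    bench = (cluster.benchmark_methods(g, k=cfg.k, seed=cfg.seed,
                                       gcnbsd_state=state, config=cfg)
             if run_benchmark else pd.DataFrame())
    return DiscoveryResult(state=state, graph=g, scaler=scaler,
                           templates=templates, sse_by_k=sse,
                           chosen_k=chosen, benchmark=bench)


def validate_biotypes(fnc_val: np.ndarray, phenotypes_val: pd.DataFrame,
                      templates: np.ndarray,
                      discovery_fnc: np.ndarray | None = None,
                      discovery_assignments: pd.DataFrame | None = None,
                      discovery_phenotypes: pd.DataFrame | None = None,
                      residualize_sites: bool = False) -> dict:
    """Project discovery templates onto a validation cohort.

    Patients are assigned to the nearest template by Euclidean distance on
    the correlation scale (optionally after residualizing site/scanner
    within the validation cohort).  When the discovery cohort is supplied,
    biotype-vs-control mean-difference patterns are computed in both
    cohorts and their replication correlations reported.
    """
    fnc_val = np.asarray(fnc_val, float)
    x = fnc_val
    if residualize_sites:
        design = site_design_matrix(phenotypes_val)
        if design is not None:
            x = regress_covariates(fnc_val, design)
    diag = phenotypes_val["diagnosis"].to_numpy(int)
    pidx = np.flatnonzero(diag == 1)
    proj = transfer.project_cohort(
        x[pidx], templates,
        subject_ids=phenotypes_val["subject_id"].to_numpy()[pidx])
    out: dict = {"projection": proj}

    if discovery_fnc is not None and discovery_assignments is not None \
            and discovery_phenotypes is not None:
        repl = []
        d_pheno = discovery_phenotypes
        d_hc = np.flatnonzero(d_pheno["diagnosis"].to_numpy(int) == 0)
        v_hc = np.flatnonzero(diag == 0)
        assign_map = dict(zip(discovery_assignments["subject_id"],
                              discovery_assignments["biotype"]))
        d_ids = d_pheno["subject_id"].to_numpy()
        v_assign = dict(zip(proj["subject_id"], proj["biotype"]))
        v_ids = phenotypes_val["subject_id"].to_numpy()
        for k in range(1, templates.shape[0] + 1):
            d_k = np.flatnonzero([assign_map.get(s) == k for s in d_ids])
            v_k = np.flatnonzero([v_assign.get(s) == k for s in v_ids])
            if d_k.size == 0 or v_k.size == 0 or d_hc.size == 0 or v_hc.size == 0:
                continue
            pat_d = transfer.mean_difference_pattern(
                np.asarray(discovery_fnc, float), d_k, d_hc)
            pat_v = transfer.mean_difference_pattern(fnc_val, v_k, v_hc)
            r, p = transfer.replication_correlation(pat_d, pat_v)
            repl.append((k, r, p, d_k.size, v_k.size))
        out["replication"] = pd.DataFrame(
            repl, columns=["biotype", "r", "p", "n_discovery", "n_validation"])
    return out


def discriminative_battery(fnc: np.ndarray, phenotypes: pd.DataFrame,
                           assignments: pd.DataFrame,
                           atlas: NetworkAtlas | None = None,
                           k_top: int = 100,
                           scales: pd.DataFrame | None = None) -> dict:
    """Edge-level t-test screen per biotype (vs. controls), top-k selection,
    network-block counts of the selected edges, and optional edge-scale
    correlations for the selected edges."""
    from .fnc import network_block_summary

    atlas = atlas or default_atlas()
    fnc = np.asarray(fnc, float)
    diag = phenotypes["diagnosis"].to_numpy(int)
    ids = phenotypes["subject_id"].to_numpy()
    hc = np.flatnonzero(diag == 0)
    assign_map = dict(zip(assignments["subject_id"], assignments["biotype"]))
    out: dict = {}
    for k in sorted(set(assignments["biotype"])):
        members = np.flatnonzero([assign_map.get(s) == k for s in ids])
        table = dstats.edge_ttests(fnc, members, hc, atlas=atlas)
        table = dstats.top_k_edges(table, k=k_top)
        sel = table[table["selected"]]["edge"].to_numpy()
        indicator = np.zeros(fnc.shape[1])
        indicator[sel] = 1.0
        # block mean of the 0/1 indicator times block size = selected count
        frac, counts = network_block_summary(indicator, atlas)
        out[f"biotype_{k}"] = {
            "edge_stats": table,
            "selected_edges": sel,
            "network_counts": np.rint(np.nan_to_num(frac) * counts).astype(int),
        }
        if scales is not None:
            scale_cols = scales.drop(columns=["subject_id"], errors="ignore")
            out[f"biotype_{k}"]["scale_correlations"] = \
                dstats.scale_correlations(fnc[:, sel], scale_cols)
    return out
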