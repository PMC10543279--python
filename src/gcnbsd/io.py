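"""Plain-text I/O for the formats the pipeline consumes and emits.

Time courses arrive as one numeric matrix file per subject (components x
timepoints, whitespace- or comma-delimited) listed in a manifest TSV;
cohort FNC features travel as a delimited matrix with a subject_id column
and one column per canonical edge, named "icn{i}_icn{j}".
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fnc import NetworkAtlas, edge_component_pairs

__all__ = [
    "read_manifest",
    "load_timecourse",
    "fnc_feature_names",
    "write_fnc_table",
    "read_fnc_table",
    "read_phenotypes",
]


def read_manifest(path) -> pd.DataFrame:
    """Manifest TSV with columns subject_id and path (relative to manifest)."""
    table = pd.read_csv(path, sep="\t")
    if not {"subject_id", "path"} <= set(table.columns):
        raise ValueError("manifest needs columns subject_id and path")
    root = Path(path).parent
    table["path"] = [str((root / p)) if not Path(p).is_absolute() else p
                     for p in table["path"]]
    return table


def load_timecourse(path) -> np.ndarray:
    """One subject's components x timepoints matrix from a text file."""
    delim = "," if str(path).endswith(".csv") else None
    return np.atleast_2d(np.loadtxt(path, delimiter=delim))


def fnc_feature_names(atlas: NetworkAtlas) -> list[str]:
    comp = np.asarray(atlas.component_ids)
    pairs = edge_component_pairs(atlas.n_components)
    return [f"icn{comp[i]}_icn{comp[j]}" for i, j in pairs]


def write_fnc_table(path, fnc: np.ndarray, subject_ids,
                    atlas: NetworkAtlas) -> None:
    table = pd.DataFrame(np.asarray(fnc, float),
                         columns=fnc_feature_names(atlas))
    table.insert(0, "subject_id", list(subject_ids))
    table.to_csv(path, sep="\t", index=False)


def read_fnc_table(path) -> tuple[list[str], np.ndarray]:
    table = pd.read_csv(path, sep="\t")
    if table.columns[0] != "subject_id":
        raise ValueError("FNC table must start with a subject_id column")
    ids = [str(s) for s in table["subject_id"]]
    return ids, table.iloc[:, 1:].to_numpy(dtype=float)


def read_phenotypes(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"subject_id", "diagnosis", "age_months", "gender"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns {sorted(missing)}")
    table["subject_id"] = table["subject_id"].astype(str)
    return table
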