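"""Cross-cohort biotype validation by template projection.

Generates a discovery/validation cohort pair sharing the same planted
connectivity pattern, extracts mean-FNC biotype templates from the
discovery truth, projects every validation patient onto the nearest
template, and quantifies replication of the biotype-vs-control
connectivity patterns.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from gcnbsd import simulate, transfer
from gcnbsd.model import extract_biotype_templates

disc, val = simulate.generate_cohort_pair(simulate.GeneratorConfig(seed=5))

d_pat = disc.patient_index
templates = extract_biotype_templates(disc.fnc[d_pat],
                                      disc.true_labels[d_pat])
print(f"templates: {templates.shape[0]} biotypes x {templates.shape[1]} edges")

v_pat = val.patient_index
proj = transfer.project_cohort(val.fnc[v_pat], templates)
ari = adjusted_rand_score(val.true_labels[v_pat], proj["biotype"])
print(f"projection ARI on the independent cohort: {ari:.3f}")
# each patient is assigned to the biotype whose template is nearest in
# Euclidean distance; 1.0 = planted labels fully recovered

for k in (1, 2):
    dk = np.flatnonzero(disc.true_labels == k)
    vk = np.flatnonzero(val.true_labels == k)
    dh = np.flatnonzero(disc.true_labels == 0)
    vh = np.flatnonzero(val.true_labels == 0)
    pat_d = transfer.mean_difference_pattern(disc.fnc, dk, dh)
    pat_v = transfer.mean_difference_pattern(val.fnc, vk, vh)
    r, p = transfer.replication_correlation(pat_d, pat_v)
    print(f"biotype {k} pattern replication: r = {r:.3f} (p = {p:.2e})")
# high r = the biotype's whole-FNC deviation from controls is the same
# pattern in both cohorts
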