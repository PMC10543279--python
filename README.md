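# gcnbsd — population-graph deep clustering for FNC biotypes

`gcnbsd` discovers, validates and characterizes **imaging-derived patient
biotypes** from functional network connectivity (FNC).  It is aimed at
neuroimaging groups who have per-subject component time courses (e.g. from
a spatially constrained ICA such as NeuroMark) or precomputed FNC vectors
plus a phenotype table, and who want data-driven patient subgroups that
replicate across cohorts and relate to cognition, symptoms and treatment
response — the ADHD biotyping setting is the motivating use case.

## The model

Each subject contributes an FNC vector: the Pearson correlations between
C = 53 independent component networks, vectorized as the strict upper
triangle (53·52/2 = 1378 edges, grouped into 7 functional domains: SC, AU,
SM, VI, CC, DM, CB).  Subjects become nodes of a **population graph**
whose edge weights combine phenotypic similarity — a gender-equality
indicator plus an age-proximity indicator (|Δage| ≤ 24 months) — with the
correlation of the subjects' FNC vectors.  Graph convolutions use the
symmetric renormalized operator

    S = D̃^{-1/2} (A + I) D̃^{-1/2}.

**GCN-BSD** is a graph-convolutional autoencoder over this graph
(encoder 1378 → 256 → 64, mirrored decoder, ReLU hidden layers, linear
embedding) trained with the joint objective

    L = γ₁ L_rec + γ₂ L_CE + γ₃ L_cluster ,    γ₁ = 0.1, γ₂ = 0.5, γ₃ = 1

where L_rec is the mean squared reconstruction error over all subjects,
L_CE the binary cross-entropy of a linear patient/control classifier on
the embeddings, and L_cluster the deep K-means loss — the mean squared
distance of **patient** embeddings to their assigned cluster centroids
(the patient subgraph keeps its edge weights unchanged).  Optimization is
Adam (learning rate 0.001) with a warm-up phase before the clustering term
activates; centroids are seeded by greedy farthest-point selection and
refreshed by hard K-means alternations.  The cluster count K is chosen at
the elbow of the within-cluster SSE curve, and the partition is
benchmarked against Ward agglomerative clustering, plain K-means, a
graph-free deep-K-means autoencoder, and a GCN autoencoder followed by
K-means, using the Davies–Bouldin (DBI, lower better) and
Calinski–Harabasz (CHI, higher better) indices.

Downstream, biotypes are summarized as mean-FNC **templates** and
projected onto independent cohorts by nearest-Euclidean-distance;
replication is the Pearson correlation of biotype-vs-control connectivity
patterns across cohorts; edge-level two-sample t-tests select the top-100
discriminative edges with network-block aggregation and cross-cohort
overlap; Cohen's d (root-mean-square-SD standardizer) quantifies scale
differences; and longitudinal symptom scores under methylphenidate (MPH)
or atomoxetine (ATX) are compared between biotypes as proportional
reduction rates from baseline with per-week t-tests, FDR corrected.

Because the motivating clinical cohorts are access-restricted, the package
ships a seeded synthetic-cohort generator (`gcnbsd.simulate`) that plants
two patient biotypes with network-block connectivity shifts, site effects,
covariates, correlated cognitive scores and longitudinal medication-arm
trajectories, so the entire pipeline is testable end to end.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from gcnbsd import pipeline, simulate

cohort = simulate.generate_cohort(simulate.GeneratorConfig(seed=1))
result = pipeline.discover_biotypes(cohort.fnc, cohort.phenotypes)

truth = cohort.true_labels[cohort.patient_index]
print(adjusted_rand_score(truth, result.state.assignments))  # 1.000
print(result.chosen_k)                                       # 2
print(result.benchmark[["method", "dbi", "chi"]].round(3))
```

Output:

```
       method   dbi    chi
      gcn_bsd 1.152 56.168
agglomerative 1.152 56.168
       kmeans 1.152 56.168
   dnn_kmeans 1.152 56.168
   gcn_kmeans 1.152 56.168
```

The adjusted Rand index of 1.0 says the model recovered the planted
two-biotype partition exactly; the elbow on the SSE curve selects K = 2;
and on this clearly separated cohort every method finds the same
partition, so the validity indices (computed for every method in the
shared standardized feature space) coincide — GCN-BSD matches or beats
each baseline.  The `examples/` directory has one narrative script per
capability (feature extraction, discovery, cross-cohort validation,
discriminative edges and effect sizes, longitudinal response); each prints
the numbers it computes and what they mean.  A `gcnbsd` command-line
interface wraps the same pipeline (`gcnbsd simulate`, `features`,
`discover`, `validate`, `stats`, `longitudinal`, `benchmark`).

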