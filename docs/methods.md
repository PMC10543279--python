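# Methods

This note records the model, the numerical and design choices behind it,
what the synthetic cohorts do and do not emulate, and the package's known
limitations.

## FNC features

A subject's feature is the strict upper triangle of the C×C Pearson
correlation matrix between ICA component time courses, in a fixed
canonical order: components in atlas order, edge (i, j), i < j, row-major.
With the default 53-component / 7-network atlas this yields 1378 edges.
Correlations enter the model as raw Pearson r — no Fisher z-transform is
applied (one can be added upstream; the pipeline is agnostic).  Before
graph construction and training the 1378 features are z-scored per feature
over the discovery cohort; the fitted scaler is retained so validation
cohorts can be placed in the same space.  Unscaled correlation-scale
vectors are kept alongside, because biotype templates and template
projection operate on the correlation scale.

Site and scanner are treated as nuisance covariates for *statistics*, not
for model training: `regress_covariates` residualizes each feature column
on dummy-coded site/scanner indicators (with intercept, so residuals are
mean-centered and exactly orthogonal to the design).  Each cohort is
residualized internally; coefficients are not transported across cohorts
because site levels generally differ.

## Population graph

Nodes are subjects, node features the standardized FNC vectors, labels the
binary diagnosis.  The base edge weight is additive-indicator phenotypic
similarity: 1[same gender] + 1[|Δage| ≤ 24 months].  By default this is
multiplied by the clipped-nonnegative Pearson correlation of the two
subjects' FNC vectors.  The multiplicative kernel is load-bearing, not
cosmetic: on a demographically homogeneous cohort (all ages within the
tolerance, two genders) the indicator-only graph is nearly complete, its
renormalized operator is close to rank one, and two stacked convolutions
average every subject onto the cohort mean — embeddings collapse and no
partition is recoverable.  The FNC kernel makes neighborhoods
subject-specific and concentrates edge weight within connectivity-similar
(in practice, same-biotype) subjects.  Both the 24-month tolerance and the
kernel are configuration options (`age_tol`, `feature_kernel`).

Self-loops exist only inside the normalized operator
S = D̃^{-1/2}(A+I)D̃^{-1/2}, never in the stored graph.  Graph
construction is deterministic and permutation-equivariant; the patient
subgraph keeps retained edge weights exactly.

## GCN-BSD

Architecture: encoder 1378 → 256 → 64 and a mirrored decoder, each layer
computing activation(S·H·W) with ReLU on hidden layers and a linear final
layer; a single linear unit on the embeddings serves as the
patient/control classifier.  Layers carry no bias terms, keeping each
layer exactly the stated operator–feature–weight product.  The joint loss
is γ₁·L_rec + γ₂·L_CE + γ₃·L_cluster with defaults γ₁ = 0.1, γ₂ = 0.5,
γ₃ = 1 and Adam at learning rate 0.001 (full-batch; the implementation is
plain numpy with analytically derived gradients, verified against finite
differences to 1e-10 in the tests).

Deep K-means uses hard assignments: between centroid refreshes the
centroids are constants and the clustering gradient flows only through the
patient rows of the embedding matrix.  Training runs 200 epochs by
default, the first 40 as warm-up with the clustering term inactive
(centroid seeding on untrained embeddings would be meaningless); centroids
are then seeded by greedy farthest-point selection (first point drawn from
the seeded generator, ties to the lowest index) and assignments/centroids
are refreshed by one hard K-means alternation every 5 epochs.  Each
refresh asserts the alternation did not increase the clustering loss with
embeddings frozen.  An emptied cluster is re-seeded at the point farthest
from its nearest centroid and logged.  Logistic probabilities are clipped
at 1e-7 for cross-entropy stability.  A soft-min (temperature) variant of
the cluster loss exists behind `soft_assignment`; it is not the default.
With γ₃ = 0 the final partition is computed post hoc by plain K-means
(farthest-point seeding, Lloyd alternations, tolerance 1e-6, max 500
iterations) on the learned embeddings, which makes the
"reconstruction-only GCN + K-means" baseline a special case of the same
code path.

Biotype labels are reported 1..K ordered by descending cluster size, so
biotype 1 is always the larger subgroup; everything downstream
(templates, contrasts) is index-aligned to that convention.  Training is
deterministic given the seed and configuration, up to floating-point
reduction order.

## Cluster count and benchmarking

K is selected at the elbow of the within-cluster SSE curve (multi-restart
K-means per K, 10 restarts, seeded), operationalized as the K with maximum
perpendicular distance to the chord joining the curve's endpoints; a
curve with no curvature returns the smallest K with a warning.

The benchmark compares GCN-BSD with Ward agglomerative clustering, plain
K-means (both scikit-learn, seeded), a graph-free deep-K-means autoencoder
(same widths, identity operator, reconstruction + clustering losses), and
a reconstruction-only GCN autoencoder followed by K-means.  DBI and CHI
are computed for **every** method's partition in the shared standardized
patient-feature space.  The alternative — scoring each deep method in its
own embedding space — was rejected after measurement: the deep-K-means
objective shrinks within-cluster scatter in its own embedding by
construction, so such a method wins the indices regardless of whether its
partition reflects any real structure.  Internal indices on the common
input space compare what matters, the partitions.

## Cross-cohort transfer and statistics

Templates are per-biotype means of the raw correlation-scale FNC vectors.
Projection assigns each validation patient to the nearest template in
Euclidean distance (ties to the lowest index); assignments are invariant
to any common affine rescaling of subjects and templates.  Replication is
the Pearson correlation (with t-distribution p) between the two cohorts'
biotype-vs-control mean-difference patterns, over all edges or a subset
such as the top-100 screen.

Edge screens use Student's pooled-variance two-sample t-tests (Welch is
available via configuration); degenerate edges are flagged, not fatal.
Top-k selection takes the k largest |t| with ties to the smaller canonical
edge index; the selection is rank-based, so no multiplicity threshold is
applied to the screen itself.  Cognitive/clinical scale families use
Bonferroni correction; longitudinal per-week families use
Benjamini–Hochberg.  Cohen's d from summary statistics standardizes by the
root-mean-square of the two group SDs, d = |m₁−m₂| / √((s₁²+s₂²)/2); this
is the package default because it reproduces the published biotype effect
sizes from their printed summaries exactly at two decimals, while
n-weighted pooling (available as `method="pooled"`) differs on one
measure.  The shipped reference summary tables carry the published group
means/SDs/n for the discovery (cognitive battery) and validation
(IQ/symptom) cohorts; one published value (the validation
hyperactive/impulsive d of 0.68) is not reproducible from its own printed
summaries under either standardizer and is excluded from checks.

Longitudinal response is the proportional reduction from baseline,
(score₀ − score_w)/score₀ (unit-invariant; absolute change is a config
alternative), compared with independent per-week two-sample t-tests —
grouping either biotype 1 vs biotype 2 or the headline cell contrast,
biotype 1 on MPH vs biotype 2 on ATX.  Series without a positive baseline
are excluded and logged; missing mid-week scores are analyzed per
available week without interpolation.

## Synthetic cohorts

`generate_cohort` draws: a shared per-edge baseline connectivity
(N(0.10, 0.12)); biotype-specific network-block shifts (default ±0.3 on
seven/eight blocks, with opposite signs on the blocks the two biotypes
share, mirroring the qualitative profiles the biotypes are meant to show);
per-site additive edge offsets (SD 0.05, 2 sites); independent Gaussian
edge noise (SD 0.1); clipping to [−0.99, 0.99].  Group sizes default to
116 controls / 82 biotype-1 / 25 biotype-2 — the discovery cohort's
proportions at one-tenth scale, which keeps full training runs at desk
scale (a few seconds each).  Ages are uniform over 108–132 months, gender
65% male, cognitive scores Gaussian (SD 15) with controls highest and
biotype 2 lowest (gaps 4 and 6 points), and longitudinal scores follow
exponential approach to a per-(biotype, arm) plateau with biotype 2's
improvement frozen after week 4.  Everything is reproducible from the
config seed; truth labels are returned separately from all analysis
outputs.

What the generator does **not** emulate: realistic edge-edge covariance
(noise is diagonal), heavy-tailed motion artifacts, scanner-specific
multiplicative effects, missing-visit patterns, or the demographic
structure of any real cohort.  Passing tests therefore demonstrate that
the pipeline's machinery is correct and well calibrated under its stated
generative assumptions — not that the specific published biotypes would be
recovered from restricted clinical data.

## Limitations

- The decoder reconstructs node features; adjacency reconstruction is not
  implemented.
- The classifier head is an auxiliary loss, not a calibrated diagnostic
  classifier.
- Dynamic (windowed) connectivity, learned edge weights and multi-graph
  fusion are out of scope.
- Published replication correlations from the restricted clinical cohorts
  are not reproducible at desk scale; the operations that compute them are
  exercised on synthetic cohort pairs instead.
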