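# Methods

## Problem setting

`parcelgnn` learns subject-level cortical parcellations: given a
triangulated cortical surface mesh in vertex correspondence across
subjects, per-vertex functional-connectivity features derived from
resting-state BOLD time series, and training subjects with known vertex
labels, it predicts a parcel label for every vertex of a new subject. The
mesh induces an unweighted, undirected graph (vertices = mesh vertices,
edges = triangle edges), and classification is vertex-wise over C classes
with an explicit "unlabeled" code (0) for the medial wall.

## Features

**Regionalized connectivity.** For a BOLD matrix T ∈ ℝ^{N×t} and a coarse
anatomical atlas with K regions, the mean time series of region k is
T̂_k = (1/|k|) Σ_{i∈k} T_i. The feature matrix R ∈ ℝ^{N×K} holds the
Pearson correlation of each vertex series with each regional mean series.
Row indices of R mean the same thing for every subject ("connectivity to
region k"), which removes the need for exact vertex correspondence of the
functional data. Time series are demeaned per vertex; a variance floor of
1e-12 guards flat series (their correlations are set to 0 with a warning).

**Dual regression.** Alternatively, group-level spatial component maps
G ∈ ℝ^{N×C} are projected onto a subject: stage 1 regresses each time
point's spatial pattern on G (giving C×t time courses), stage 2 regresses
each vertex's series on those time courses (giving N×C subject component
loadings). Both stages are ordinary least squares; rank-deficient group
maps are rejected with the offending columns named.

**Spectral coordinates.** The eigenvectors of the symmetric normalized
graph Laplacian L = I − D^{−1/2}AD^{−1/2} for the d = 3 smallest strictly
positive eigenvalues serve as intrinsic positional features. The zero-
eigenvalue eigenvector is excluded (it carries no positional information).
Because eigenvectors are defined up to sign and near-degenerate
eigenvalues can reorder, subject coordinates are aligned to a template:
the Hungarian algorithm finds the one-to-one column matching minimizing
total Pearson-correlation distance 1 − |r|, and each matched column takes
the sign making its correlation positive. Solver sign ambiguity is removed
beforehand by forcing each eigenvector's largest-magnitude entry positive.
On highly symmetric meshes (an unperturbed icosphere graph) the low
eigenvalues are degenerate and alignment within an eigenspace is not
resolvable by column matching; this is documented, not worked around —
note that radial vertex noise perturbs geometry but not the combinatorial
graph, so the graph spectrum of an icosphere remains symmetric.

**Assembly.** Feature blocks are concatenated column-wise in the order
connectivity | spectral | scalars, with unique column names. Z-scoring is
applied to the unbounded spectral and scalar blocks by default (correlation
features are already in [−1,1]); the statistics come from the training
subjects only and are applied unchanged at test time.

## Classifiers

All models map N×F features to N×C logits; hidden activations are
LeakyReLU with negative slope 0.2.

* **baseline** — a vertex-wise MLP (depth L, hidden width k); no graph
  information.
* **GCN** — first-order spectral graph convolution: each layer computes
  σ(Â H W) with Â = D̃^{−1/2}(A+I)D̃^{−1/2} (self-loops added,
  symmetrically normalized), so depth L gives an L-hop receptive field.
* **GAT** — multi-head attention over closed neighborhoods. Per head,
  the attention vertex i pays neighbor j is
  α_ij = softmax_j( LeakyReLU( aᵀ [W h_i ‖ W h_j] ) ), j ∈ N_i ∪ {i},
  and the update is Σ_j α̃_ij W h_j. Hidden layers concatenate the M
  heads; the output layer averages them. Attention is computed on the
  directed edge list with per-segment softmax, never on dense N×N
  matrices.
* **JKGAT** — L GAT blocks whose per-layer embeddings (each N×(M·k)) are
  combined per vertex by a jumping-knowledge aggregator before a linear
  output head: `concat` (global), `maxpool` (element-wise maximum over
  layers), or `lstm` — a bidirectional LSTM reads the layer sequence, a
  learned linear functional scores each layer per vertex, and a softmax
  across layers yields a convex combination of the layer embeddings. The
  per-vertex layer weights are exposed for post-hoc inspection.

Defaults: 3 layers, 32 hidden channels, 4 attention heads, feature dropout
0.1 (applied to every layer's input features during training only, never to
attention coefficients), LSTM aggregation.

The networks, their backward passes, and Adam run on a small reverse-mode
autodiff engine over float64 numpy (`parcelgnn.autograd`). This keeps the
toolkit dependency-light and makes training bit-reproducible for a fixed
seed on a fixed platform. Weight initialization is fan-based uniform
(U(±√(6/(fan_in+fan_out)))) from a seeded generator.

## Training

Vertex-wise cross-entropy over labeled vertices, averaged per graph;
gradients accumulate across the (default 10) graphs of a mini-batch before
each Adam update (learning rate 0.01 by default — exposed and logged, as
no canonical value exists; β = (0.9, 0.999)). Two regularizers exist:
optimizer weight decay (default 5e-4, added to the gradient) and an
explicit L2 penalty λ·Σw² over non-bias parameters (default λ = 5e-3,
added to the loss; its gradient is applied in closed form). Early
stopping: after each epoch the mean validation loss is computed in
evaluation mode; a strict improvement checkpoints the weights and resets
the patience counter (default 150 epochs, maximum 1000); the returned
model always carries the best-validation weights. Mini-batches are drawn
without replacement and reshuffled each epoch from the run seed.

## Spatial prior

Vertex-wise label support: support[v, c] is true iff label c was assigned
to vertex v in at least one training parcellation. At test time,
unsupported logits are set to −∞ so their softmax probability is exactly 0
and the argmax always lands on a supported label. (Multiplying logits by a
0/1 mask would give logit 0, not probability 0, so the masking is additive
in logit space.) Vertices never labeled in training get an uninformative
all-true row, with a warning. The prior never participates in training.

## Evaluation statistics

* **Accuracy** — percent of correctly labeled vertices among truth-labeled
  vertices.
* **Dice reproducibility** — Dice(J,K) = 2|J∩K|/(|J|+|K|) per areal vertex
  set; an area absent from both maps is "missing" and skipped by the areal
  mean (not scored 0 or 1).
* **Boundary-error profile** — boundary vertices are truth-labeled
  vertices adjacent to a different truth label; misclassified vertices are
  binned by breadth-first hop distance to the boundary set and reported as
  fractions of all errors.
* **Functional homogeneity** — for parcel l, R_l holds Pearson
  correlations of each parcel-vertex series with every cortical vertex
  series; ρ_l = 100·σ₁²/Σσᵢ² from the singular values of R_l, averaged
  over parcels. A singleton parcel is trivially rank-1 and scores 100
  (flagged).
* **Scalar homogeneity** — mean within-parcel variance divided by the
  variance of parcel means, both with unbiased (n−1) estimators; smaller
  is more homogeneous; invariant to affine rescaling of the feature.
  (The ratio-of-variances *prose* definition is implemented; a literal
  sum of variance deviations about their mean is identically zero and
  therefore cannot be what is meant.)
* **Consensus** — per-vertex modal label across predictions; ties break
  to the smallest label id.
* **Mean probability maps** — element-wise mean of subject probability
  matrices; entries below 1/C (the uniform-assignment probability) are
  zeroed in the display copy only.
* **Bootstrap SE** — subjects are resampled with replacement
  (default 100 draws, 1000 repetitions) and the standard deviation of the
  resampled mean accuracies is reported.

## Synthetic cohorts

The generator produces a closed icosphere mesh (10·4^s + 2 vertices;
slight radial vertex noise is available but note it does not perturb the
combinatorial spectrum), a ground-truth parcellation grown by simultaneous
breadth-first search from farthest-point-sampled seeds (parcels are
connected and non-empty by construction), a coarser atlas of the same
construction (default max(2, P−2) regions), per-subject scalar maps
(per-parcel mean levels drawn N(0,1), vertex noise sd 0.5), and
per-session time series.

Time series follow a parcel-latent model: each parcel has a unit-variance
Gaussian white latent series and each vertex observes its parcel latent
plus i.i.d. Gaussian noise of sd 1/snr. Parcels belonging to the same
coarse atlas region (modal region over the parcel's vertices) share a
region-level signal carrying a fraction `parcel_similarity` (default 0.9)
of the latent variance, so sibling parcels have correlated connectivity
fingerprints. This property is essential: with fully independent latents,
per-vertex profiles are so separable that a vertex-wise classifier is
perfect and the benchmark cannot discriminate architectures; real cortical
areas overlap heavily in their connectivity fingerprints, which is exactly
what makes boundary labels ambiguous and spatial context informative.
Inter-subject variability is modeled by boundary jitter: per subject,
boundary vertices flip to a neighboring parcel's label with probability
0.5, repeated `boundary_jitter` times, so changes stay within that many
hops of template boundaries.

What the generator does **not** emulate: hemodynamics and temporal
autocorrelation (features are correlations only, so white latents
suffice), realistic cortical geometry and curvature-correlated signal,
scanner/session effects, spatial smoothing of the BOLD maps, and
registration error. Passing benchmarks therefore demonstrate correct
mechanics and the qualitative behavior of the methods under
parcel-structured signals — not performance on real fMRI.

## The desk-scale benchmark

`parcelgnn.benchmark.run_benchmark` (also driven by
`scripts/acceptance.py`) uses a cohort of 642 vertices (icosphere s=3),
8 parcels, 20 subjects split 12/3/5, t=200 time points, snr=3, no boundary
jitter. Three experiments:

1. **Architecture comparison** on regionalized-connectivity features only
   (the protocol under which the reference architecture grid was run);
   baseline, GCN, and GAT are trained identically and scored with and
   without the prior, with a bootstrap SE.
2. **Full-feature GAT** (connectivity + spectral + scalars) for the
   headline accuracy and homogeneity statistics. The spectral and scalar
   blocks are strong, session-stable predictors here, so this model sits
   near ceiling; the architecture comparison is only meaningful on the
   harder connectivity-only task.
3. **Session reproducibility**: the connectivity-feature GAT predicts two
   independent sessions per test subject; mean areal Dice between the two
   predictions measures reproducibility. Sessions are generated at the
   longest duration (400) and truncated to 200 and 100, so the duration
   comparison is paired — shorter scans are prefixes of the same session,
   as in real concatenation designs — and three session pairs per subject
   are averaged. The prior is not applied here: with zero jitter it would
   pin every vertex to the template and trivialize Dice.

Benchmark-specific protocol (all defaults unchanged in the library):
training capped at 250 epochs with patience 50, and the explicit L2
penalty disabled (λ·Σw² is an absolute-scale term; at this problem size it
dominates the cross-entropy and starves the attention models, whose
parameter count is ~4× the GCN's). Optimizer weight decay stays at 5e-4.

## Numerical choices and degeneracies

* Eigen-solver: dense `eigh` below 512 vertices, shift-invert `eigsh`
  above; eigenvalues below 1e-8 are treated as zero.
* Correlations clip to [−1, 1] after computation; variance floor 1e-12.
* Masked softmax subtracts the detached per-segment maximum and applies
  an additive −1e30 mask before exponentiation, so out-of-neighborhood
  scores can never overflow.
* Dice with both sets empty is NaN ("missing"), never 0 or 1.
* JK max-pool ties route gradients to the earlier layer.
* Consensus ties break to the smallest label id (documented, deterministic).
* All computation is float64; determinism claims hold for a fixed
  platform/BLAS, seed, and thread count.

## Known limitations

* The GAT/JKGAT attention is exact but O(E·M·k) per layer in Python-level
  autodiff ops; meshes beyond ~10k vertices need patience.
* Spectral alignment is undefined on graphs with symmetric (degenerate)
  spectra; use irregular meshes or rely on shared-mesh pipelines where
  alignment is the identity.
* The synthetic benchmark's full-feature task saturates near 100%
  accuracy; treat the connectivity-only numbers as the discriminating
  ones.
* `sessions: independent` treats sessions as separate samples; no
  session-level random effects are modeled.
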