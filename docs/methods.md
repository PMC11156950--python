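# Methods

## The approximation

A vertex's functional connectivity profile is its vector of Pearson
correlations with a set of reference locations.  The classical vertex-level
gradient pipeline uses all n vertices as references (an n×n matrix); `fcga`
uses k ≪ n landmarks, so each vertex is described by its correlation to the
landmarks only.  Both the vertex-by-landmark matrix CM_{n×k} and the
landmark-by-landmark matrix CM_{k×k} are thresholded row-wise — each row
keeps its m = ⌈fraction·k⌉ largest strictly positive entries (default
fraction 0.10) and zeroes everything else, negatives included — and the
affinity W_{n×k} is the cosine similarity between each vertex's thresholded
profile and each landmark's thresholded profile.  PCA of the column-centered
W yields the gradients: component scores ordered by decreasing explained
variance.

Definitional choices a reimplementation must fix, and how this package
fixes them:

* **Threshold count** m = ⌈fraction·k⌉ over strictly positive entries; ⌈·⌉
  guarantees at least one survivor for any k, and rows with fewer than m
  positive entries keep all their positives.  A row with no positive entries
  becomes all-zero; its cosine affinities are set to 0 with a warning
  (configurable to raise).  Thresholding is idempotent.
* **PCA** is plain column-mean centering with no variance scaling.  The
  sign of each component is fixed deterministically: the loading entry of
  largest absolute value is made positive (ties broken toward the lowest
  landmark index).  Landmark columns are always ordered by ascending vertex
  index / parcel id, so the PCA input — and therefore the signs — are
  reproducible.
* **The full-matrix reference** is defined as the same
  threshold→cosine→PCA pipeline with every vertex its own landmark.  This
  makes the approximation target exact: `fcga` with identity landmarks is
  bit-identical to `full_gradients`, which is asserted in the tests.
* **Zero-variance signals** make Pearson correlation undefined; the default
  policy raises, with an explicit `zero_variance="zero"` opt-in that maps
  the affected correlations to 0 and warns.
* **"Uniform" landmark placement** is farthest-point sampling on vertex
  coordinates, started deterministically from the vertex farthest from the
  coordinate centroid.  A deterministic start makes the landmark set a pure
  function of the geometry, so the same set serves every subject; ties go to
  the lowest vertex index.
* **Group-level dense-FC variant**: when a precomputed dense connectivity
  matrix is the input, landmark connectivity is obtained by averaging its
  columns (and, for CM_{k×k}, rows) within parcels — not recomputed from
  signal — and thresholding happens after this reduction.

## Comparison and alignment

PCA signs (and, between independent datasets, component order) are
arbitrary.  Group-level comparisons therefore default to absolute Spearman
rank correlation per matching component; signed comparison is meaningful
after orthogonal Procrustes alignment, which finds the g×g rotation or
reflection R minimizing ‖source·R − reference‖_F (closed form via the SVD of
sourceᵀ·reference; no scaling or translation, columns compared as-is).
Vertex-wise profile similarity correlates each vertex's g-long coefficient
row between two gradient sets; constant profiles are recorded as missing.

The similarity-vs-cost protocol (`landmark_similarity_curve`) estimates, per
landmark fraction, the expected mean |Spearman| over the first 10
components between landmark and full-matrix gradients by averaging over
random landmark draws.  Small-k levels get more draws (64 for k ≤ 30, 10
for k ≤ 150, 5 above) because a single tiny draw estimates its level with a
standard deviation of roughly 0.05 while adjacent levels can differ by only
~0.02.

## Reliability

ICC uses the two-way random-effects, absolute-agreement, single-measure
form: with s subjects and r repeats, ICC = (MS_R − MS_E) / (MS_R +
(r−1)MS_E + (r/s)(MS_C − MS_E)) from the two-way ANOVA mean squares.  It is
computed per vertex on one gradient's coefficients and summarized by the
mean over vertices; panels must be balanced (no imputation).
Discriminability is the probability that two measurements of the same
subject are closer (Euclidean distance on flattened, previously aligned
coefficient matrices) than a measurement of that subject is to one of a
different subject; ties count one half, which is unbiased under
exchangeability.  It is invariant to any monotone transform of the
distances and to measurement order.

## Prediction benchmark

Two parcel-level feature constructions from the same cohort and
parcellation P, g = 5 gradients each (a deliberately small feature space of
P·g columns): *gradients-to-parcellation* computes vertex-level landmark
gradients per subject, aligns them to a common reference by Procrustes
(components must agree across subjects before features are comparable), and
averages coefficients within parcels; *parcellation-to-gradients* averages
the time series within parcels first and runs the same gradient pipeline on
the P×P data, using all parcels as landmarks.

Two alignment choices matter for cross-subject feature consistency and are
fixed as follows.  The common reference is the gradient set of the
group-average connectome — per-subject correlation matrices averaged across
the cohort, then run through the standard pipeline — rather than any single
subject, because an individual reference inherits that subject's component
instabilities.  And alignment operates in a gradient space twice as large
as the feature count (n_align = 2g, capped by rank), with the first g
aligned components used as features: near-degenerate trailing eigenvalues
let components drift across the cut at g from subject to subject, and a
rotation fitted in the larger space absorbs that drift where a g-dimensional
rotation cannot.

Ridge regression is evaluated with nested tenfold cross-validation: per
repeat a fresh outer split; per outer fold an inner tenfold CV on the
training portion selects the penalty minimizing inner mean absolute error;
the refit model predicts the held-out fold; fold predictions are aggregated
and MAE/Pearson r computed once per repeat.  Features are z-scored inside
each training fold (never with held-out data) and the penalty grid is 30
log-spaced values spanning 1e−3·λ_max to λ_max, λ_max being the largest
absolute inner product between a z-scored feature and the centered target.
The shuffled-label baseline reruns the identical harness on permuted
targets; p-values use the add-one formula (1 + #{null ≥ observed}) /
(1 + n_perm), so 100 permutations bound p below by 1/101.  The paired
construction comparison shares fold seeds between arms, reports per-repeat
MAE differences and a sign count, and Bonferroni-adjusts the sign-test
p-value across the user's set of comparisons.  No deconfounding between
targets is performed.

## Synthetic cohorts

The generator plants everything the evaluation needs to know the truth of:

* **Toy cortex**: a rows×cols planar grid embedded in 3-space, with block
  parcellations.  A plane rather than a sphere removes mesh dependencies
  while preserving smoothness, parcellation structure and coordinates for
  uniform sampling.
* **Latent maps**: m Gaussian-filtered white-noise fields (length scale
  `smoothness`, default 1.0 grid units), row-amplitude-homogenized and
  column-orthonormalized.  Amplitude homogenization mirrors
  variance-normalized functional data and makes each vertex's connectivity
  profile a function of its loading direction alone.
* **Signal model**: X = G·diag(s)·S + ε with component scales s =
  √n·0.9^c (a gently decreasing spectrum with distinct eigenvalues, √n
  putting per-vertex amplitudes at O(1)) and sensor noise ε at
  `noise_sd` = 0.1, i.e. roughly 10:1 SNR per vertex.  The component time
  courses S are decorrelated in-sample (QR of a seeded Gaussian draw,
  scaled to unit variance) so the planted diagonal source covariance holds
  exactly at finite T instead of only in expectation.
* **Subjects and sessions**: each subject's maps are the group maps plus a
  smooth unit-norm perturbation scaled by `subject_perturbation_sd`
  (default 0.3, i.e. 30% of the map norm — sizable, stable individual
  differences), re-orthonormalized and shared across the subject's
  sessions.
* **Subject perturbations are pure novelty**: the perturbation field is
  projected orthogonal to the group maps before scaling, so individual
  differences add new spatial content rather than re-weighting the group
  components, and the re-orthonormalization step applies only small volume
  corrections.  The behavioral target contracts the weight field with the
  *raw* perturbed maps, keeping it a clean linear functional of the
  perturbation.
* **Behavior**: a vertex-level weight field (smooth, varying within
  parcels; optionally constrained to pure within-parcel contrasts) is
  contracted with each subject's maps, standardized across subjects, and
  perturbed with noise at `behavior_noise_sd` (default 0.05).  The
  prediction benchmark cohort uses smooth weights at parcel scale
  (`smoothness` 3.0, `scale_ratio` 0.7, `subject_perturbation_sd` 0.4),
  which gives both constructions access to the target in principle; the
  fine-grained construction's advantage then rests on estimation fidelity —
  vertex-level gradients are computed against 40 landmarks and averaged
  over many vertices per parcel, while the coarse construction pushes the
  parcel signal through a 20-landmark pipeline whose row-wise threshold
  keeps only 2 of 20 connections.  Across simulated cohorts the
  fine-grained construction wins the large majority of shared-split
  repeats, but at individual 50-subject cohort draws the direction can
  reverse when the target happens to align with what the coarse pipeline
  represents well — which is why the reproduction script averages the
  benchmark over three cohorts.

What the generator does **not** emulate: hemodynamics, temporal
autocorrelation, motion or physiological artifacts, surface registration
error, and spherical mesh geometry.  Passing tests therefore demonstrate
the correctness and internal consistency of the pipeline and its
evaluation statistics on data with known truth — not performance on real
fMRI.

## Known limitations

The gradients of the threshold→cosine pipeline are kernel eigenfunctions of
the vertex-direction distribution: smooth monotone transforms and, beyond
the leading components, harmonic mixtures of the planted coordinates rather
than the coordinates themselves.  Per-map rank-correlation recovery of
planted structure is therefore excellent for the leading components but
degrades toward the tail of the spectrum (the identity-landmark equivalence
and the FCGA-vs-full similarity, which are the method's actual claims, are
unaffected).  Problem sizes in the tests and the acceptance script (grids
of 100–2,400 vertices, 50-subject cohorts, 20 cross-validation repeats) are
chosen as desk-scale analogues of the method's intended regime;
`full_gradients` guards against dense pipelines beyond 10,000 vertices and
points to the approximation instead.
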