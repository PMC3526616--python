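# Methods

This note documents the models, defaults, and numerical choices behind
`adcascade`, and what the synthetic cohort does and does not emulate.

## Surface meshes

A structure surface is a closed, orientable, genus-0 triangulation; all
subjects of a structure share one triangle array (atlas correspondence),
so a subject's shape is fully described by its vertex positions. Loaded
meshes are validated strictly: every undirected edge on exactly two
triangles, consistent winding, no repeated-vertex or near-degenerate
(area < 1e-12 mm²) triangles. For such meshes Euler's relation gives
F = 2V − 4, which the package exposes as a consistency check on any
printed (V, F) specification of an atlas surface. Volume is the signed
divergence-theorem sum over triangles, reported as an absolute value so
either global orientation is accepted; it is rigid-motion invariant to
1e-9 relative and scales exactly as s³.

File I/O uses ascii OFF and PLY with coordinates written at 17
significant digits, so write/read round-trips are bit-exact for float64;
parsers report the offending line on malformed input. Deformation maps
are additionally exported as PLY with per-vertex `displacement` and
`p_value` scalar properties for standard mesh viewers.

## First-order diffeomorphic metric

The distance between corresponded vertex sets x, y is the linearization
of the LDDMM landmark geodesic distance at the identity:
d² = Σ over coordinates of Δᵀ(K + λI)⁻¹Δ, with Δ = y − x and
K the Gaussian Gram matrix on x. Because K lives on the first shape the
one-sided form is not exactly symmetric; the reported distance is
sqrt((d²_{x→y} + d²_{y→x})/2), which makes the distance-matrix symmetry
invariant exact. Each mesh's Cholesky factor is cached, so a full
pairwise matrix costs two triangular solves per pair.

Defaults: kernel width σ = 2 mm, ridge λ = 1e-6. The width is chosen
relative to the imaging resolution (~1 mm), not the mesh resolution: a
kernel wide relative to the structure makes smooth, large-scale
deformations metrically cheap and amplifies high-frequency residuals by
1/λ, which would bury the size axis that dominates real anatomical
variation. At σ = 2 mm the metric weights vertex displacements nearly
independently, the leading embedding component tracks structure volume
(|r| ≈ 0.85–0.99 on default cohorts), and localized effects surface as
separate components — the structure reported for real data. Both
parameters are recorded in run metadata and freely settable.

Subjects are rigidly aligned (rotation + translation, Kabsch; never
scaling — size is biological signal) to the cohort's first subject
before distances are computed. For synthetic cohorts, generated in a
common frame, this is a near-no-op; it matters for imported data.

## ISOMAP embedding

Geodesic distances are shortest paths on the symmetric k-NN graph
(k = 10 by default; a disconnected graph doubles k with a logged
warning). Classical scaling eigendecomposes B = −½·J·D²·J; coordinates
are the top-m eigenvectors scaled by the square roots of their
nonnegative-clamped eigenvalues, m = 20 by default. Negative eigenvalues
(non-Euclidean input) are kept in the `eigenvalues` field for
diagnostics. Determinism requires a sign rule: each eigenvector's
largest-magnitude entry is made positive. Columns are explicitly
re-centered because eigenvectors of near-zero eigenvalues can mix
numerically with the constant direction.

`ShapeEmbedding.fidelity_r` follows the standard ISOMAP convention
(correlation of embedded distances with the geodesic matrix);
`embedding_fidelity(E, D)` against the raw metric matrix gives the
quantity comparable to published metric-space fidelities. On default
cohorts the latter is ≈ 0.96 (hippocampus) and ≈ 0.98 (ventricles).

The embedding is transductive: all subjects, including later test
subjects, are embedded jointly, and shape-component selection is run
once per contrast on the full cohort outside cross-validation. This
mirrors the published analysis pipeline and shares its optimism; a
nested alternative (selection inside each trial) is deliberately not the
default, but conversion prediction does restrict selection and scaling
statistics to the NC/AD training subjects, since MCI subjects there are
a genuine test set.

## Selection and classification

Component selection uses the pooled-variance two-sample Student t-test
(df = nx + ny − 2), α = 0.05 two-tailed, no multiple-testing correction
— matching per-component reporting conventions; a Benjamini-Hochberg
switch exists (`fdr=True`). Under the null the per-component
false-selection rate is calibrated at α (checked against the binomial
95% band over 1000 replicates).

Classification is a soft-margin linear SVM (C = 1 on z-scored features;
convergence tolerance 1e-6, verified against a brute-force dual QP on
toy instances). The evaluation protocol: per trial, subsample the two
contrast groups without replacement to the smallest diagnostic-group
size (35 in the default cohort, min over NC/MCI/AD even for two-group
contrasts), run leave-one-out CV, and aggregate 100 trials. The CI is
mean ± 1.96·SD/√n_trials, which reproduces the ~±1-point intervals
typical of this protocol's published tables. The positive class is
always the more-impaired group (AD > MCI > NC), so sensitivity is
disease detection. In every balanced trial accuracy =
(sensitivity + specificity)/2 identically.

A caveat documented deliberately: this CI quantifies subsample-trial
noise only. Because every trial reuses the full smallest group, chance
structure in that group never averages out, and the cohort-level spread
of the mean accuracy is several times wider than the CI. Under a null
cohort the CI therefore covers 0.5 far less often than its nominal
level; the acceptance suite contains a strict check of this property
that fails by design of the protocol, and the regular suite asserts the
weaker true property (null accuracies centered near 0.5, with the
well-known slight pessimistic LOO bias).

Conversion prediction trains NC-vs-AD per trial (NC subsampled to the
AD group's size; a flag disables balancing) and classifies all MCI
subjects; accuracy = (sens·n_c + spec·n_s)/(n_c + n_s) identically.

## Deformation maps

Per atlas vertex, each subject's position is projected on the base
mesh's outward unit normal (area-weighted incident-triangle normals);
the map is the difference of group means (positive = outward in the
first-named group) with a per-vertex two-tailed t-test. Zero
within-group variance at a vertex yields p = 0 (exact difference) or
p = 1 (identical). No vertex-wise multiplicity correction is applied by
default — the maps are descriptive, as in published figures.

## Synthetic cohort generator

The generator is the package's study population, not a convenience
fixture. Defaults (all freely overridable in `CohortSpec`):

* **Composition**: NC 72, MCI-s 86, MCI-c 25, AD 35 (218 subjects);
  ages drawn per group at the study sample's means/SDs.
* **Geometry**: each structure is an ellipsoid (hippocampus 15×8×6 mm,
  ventricle 25×12×9 mm) meshed as a subdivision-2 icosphere (162
  vertices, 320 triangles) — a deliberately reduced stand-in for the
  1184–3947-vertex atlas surfaces, keeping the full pipeline testable in
  minutes on one core.
* **CSF** (pg/mL): NC Aβ42 205±50, t-tau 70±30, p-tau 25±10; MCI-s
  185±45, 120±50, 42±16; AD (and MCI-c) 135±45, 120±55, 42±18. Tau
  means are equal for MCI and AD — tau has plateaued before conversion —
  so only Aβ42 separates MCI from AD, while all three markers separate
  NC from MCI and from AD. At the default sample sizes each of those
  nine significance/non-significance statements holds in ≥ 90% of
  replicates (checked per statement; at α = 0.05 the joint event over
  all nine cells cannot reach 90% even with exactly equal tau means,
  since each true non-difference is still flagged 5% of the time).
* **Volume effect**: linear scale 0.95 on the hippocampus and 1.05 on
  the ventricles for *all* impaired groups — volumes separate NC from
  MCI/AD but carry no MCI-vs-AD signal.
* **Local shape effect**: AD and MCI-c carry a paired bump — outward at
  the vertex nearest a fixed direction, inward at its antipode, Gaussian
  angular profile (amplitude 1.0 mm hippocampus / 1.2 mm ventricle,
  width 0.5 rad) — volume-neutral to first order, so MCI-vs-AD
  separation lives in local shape only.
* **Individual anatomy**: per-subject size jitter (6% linear, ≈18%
  volume SD), eight smooth normal-displacement modes (leading
  eigenvectors of an 8 mm Gaussian kernel on the base vertices,
  spherical-harmonic-like, 0.25 mm RMS), and 0.01 mm iid vertex jitter.
  Atlas-injected surfaces are smooth by construction, so anatomical
  variability is modelled as low-dimensional and smooth; this is also
  what makes a 20-component quasi-isometric embedding possible at all —
  an unstructured high-dimensional cloud cannot be embedded faithfully
  in 20 dimensions.

Randomness flows from the cohort seed through per-subject
`SeedSequence` spawn keys `(group, index)`, so adding a subject or a
group never perturbs existing subjects.

**What the generator does not emulate**: MRI acquisition and
segmentation error, non-ellipsoidal anatomy, left/right correlation
(sides are independent draws), longitudinal change, age/sex effects on
markers, and non-Gaussian CSF distributions. Passing tests therefore
demonstrate that the *pipeline* recovers planted structure under
realistic noise — not that real data contain such structure.

## Problem sizes used in tests

The suite scales simulations to single-core minutes: full 218-subject
cohorts for composition, fidelity, and planted-effect checks;
half-size cohorts (5 seeds, 10 trials) for the CSF+shapes-vs-CSF
ordering property; 24–70-subject instances for LOO and null
calibrations; 50 seeds of 20-vs-20 groups for deformation-map
localization. Trial counts in tests are 10–25 (the protocol default
remains 100).
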