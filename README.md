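# adcascade

Baseline CSF and structural-shape biomarker analysis of the Alzheimer's
pathological cascade, built as a tested, reusable pipeline.

## The scientific problem

Cerebrospinal-fluid markers (Aβ42, t-tau, p-tau) and structural MRI
markers of the hippocampus and lateral ventricles become abnormal at
different stages of the progression from normal aging (NC) through mild
cognitive impairment (MCI) to Alzheimer's disease (AD). Two questions
drive the analysis:

1. Which markers — CSF concentrations, structure *volumes*, or structure
   *shapes* — separate which pairs of diagnostic groups at baseline?
2. Can a classifier trained on the extremes of the cascade (NC vs AD)
   predict, from baseline data alone, which MCI patients will convert to
   AD within two years?

The package is aimed at researchers who want the full analysis chain —
shape representation, embedding, feature selection, the classification
protocol, and conversion prediction — as composable, seeded, unit-tested
functions, exercised end-to-end on a synthetic cohort generator that
emulates the statistical structure of such a study sample (no access to
restricted clinical data is required to run or test anything).

## The method

**Shape representation.** Each structure surface is a triangulated mesh
with atlas-induced vertex correspondence across subjects. The distance
between two corresponded surfaces is the first-order (initial-momentum)
approximation of the LDDMM landmark metric: with vertex displacement
Δ = y − x and Gaussian kernel Gram matrix K<sub>ij</sub> =
exp(−‖x<sub>i</sub>−x<sub>j</sub>‖²/2σ²),

    d(x, y)² = Σ_coord Δᵀ (K + λI)⁻¹ Δ,

symmetrized as the RMS of the two one-sided values.

**Embedding.** ISOMAP: all-pairs shortest-path distances on the
symmetric k-nearest-neighbour graph of the pairwise distance matrix,
then classical scaling (eigendecomposition of B = −½ J D² J). Each
retained eigenvector is one *shape component*; bilateral structures
enter one embedding through the root-sum-square combination of the
left/right distance matrices.

**Selection and classification.** Components with a significant
two-group difference (pooled-variance Student t-test, α = 0.05) form the
shape feature set. A linear soft-margin SVM is evaluated under the
balanced-subsampling protocol: both groups subsampled to the smallest
diagnostic group's size, leave-one-out cross-validation within each of
100 trials, mean accuracy ± 1.96·SD/√100 as the confidence interval,
with sensitivity oriented toward the more-impaired group.

**Conversion prediction.** The NC-vs-AD classifier is trained on
baseline features (selection and z-scoring statistics from the training
subjects only) and applied to all MCI subjects; sensitivity is the
fraction of true converters labelled AD-like.

## Worked example

```python
import numpy as np
from adcascade import (CohortSpec, generate_cohort, pairwise_distances,
                       combine_structures, isomap, select_components,
                       assemble_features, balanced_subsample_eval,
                       predict_conversion, embedding_fidelity)

cohort = generate_cohort(CohortSpec(seed=1))        # 218 synthetic subjects
labels = np.array([r.group for r in cohort])
ids = [r.id for r in cohort]

embeddings = {}
for key, (tl, tr) in {"hippocampus": ("hippocampus_L", "hippocampus_R"),
                      "ventricle": ("ventricle_L", "ventricle_R")}.items():
    D = combine_structures(
        pairwise_distances([r.meshes[tl] for r in cohort], subject_ids=ids),
        pairwise_distances([r.meshes[tr] for r in cohort], subject_ids=ids))
    embeddings[key] = isomap(D, k=10, m=20)
    print(f"{key}: fidelity r = {embedding_fidelity(embeddings[key], D):.2f}")

sel = {k: select_components(E, labels, ("NC", "AD")) for k, E in embeddings.items()}
print("hippocampal components (NC vs AD):", sel["hippocampus"].selected)

for name in ("CSF", "Hp_volumes", "CSF+shapes"):
    F = assemble_features(cohort, name, embeddings, sel)
    print(balanced_subsample_eval(F, labels, ("NC", "AD"), n_trials=25, seed=1))

print(predict_conversion(cohort, "CSF", n_trials=25, seed=1))
```

prints

```
hippocampus: fidelity r = 0.96
ventricle: fidelity r = 0.98
hippocampal components (NC vs AD): [1, 3, 15, 19]
CSF NC vs AD: 89.1% (CI: 88.4%~89.9%) Sensitivity = 87.1%, Specificity = 91.2%
Hp_volumes NC vs AD: 68.3% (CI: 67.1%~69.5%) Sensitivity = 69.6%, Specificity = 67.0%
CSF+shapes NC vs AD: 99.4% (CI: 99.1%~99.7%) Sensitivity = 99.0%, Specificity = 99.9%
CSF: 58.7% (57.5%~60.0%) sens 70.1% spec 55.4%
```

Reading the numbers: the 20-component embeddings represent the pairwise
shape distances almost isometrically (r = 0.96 / 0.98). Component 1 —
the size axis — plus a handful of local components separate NC from AD.
CSF markers alone classify NC vs AD at 89%, volumes at 68%, and the
combination of CSF with selected shape components is nearly perfect on
this synthetic cohort, reproducing the qualitative finding that CSF and
shape markers are complementary. The last line is conversion prediction
from CSF alone: high sensitivity (70% of converters flagged) with low
specificity — converters resemble AD at baseline, while many stable MCI
subjects sit close to the decision boundary.

The same pipeline is scriptable from the shell:

```bash
adcascade run-all --seed 1 --trials 25 --out runs/demo
adcascade classify --run runs/demo
```

which writes the cohort manifest, distance matrices, embeddings, a
selection table, classification and conversion report tables, and
per-vertex deformation maps (CSV + PLY).

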