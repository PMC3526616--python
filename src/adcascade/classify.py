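"""Linear SVM classification under the balanced-subsampling LOO protocol.

The evaluation protocol: the two contrast groups are repeatedly (100
trials by default) subsampled without replacement to the size of the
smallest diagnostic group in the cohort, leave-one-out cross-validation
of a soft-margin linear SVM is run within each trial, and the mean
accuracy with its 95% confidence interval plus sensitivity and
specificity are reported. The positive class is always the more-impaired
group (AD > MCI > NC), so sensitivity is the detection rate of disease.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from .embedding import ShapeEmbedding
from .errors import CohortError
from .selection import SelectionResult, group_mask
from .synthetic import CSF_MARKERS, SubjectRecord

FEATURE_SETS = (
    "Hp_volumes",
    "Hp_shapes",
    "LV_volumes",
    "LV_shapes",
    "CSF",
    "CSF+volumes",
    "CSF+shapes",
)

#: clinical severity used to orient sensitivity/specificity
SEVERITY = {"NC": 0.0, "MCI_s": 1.0, "MCI": 1.0, "MCI_c": 1.5, "AD": 2.0}


@dataclass
class FeatureSet:
    """A named subjects-by-features matrix with z-scored columns."""

    name: str
    matrix: np.ndarray
    feature_names: list
    subject_ids: list

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if np.isnan(self.matrix).any():
            raise ValueError("feature matrix contains missing values")


@dataclass
class LinearClassifier:
    """A fitted linear decision rule sign(w . x + b); +1 = positive class."""

    weights: np.ndarray
    bias: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision(X) >= 0, 1, -1)


@dataclass
class ClassifierReport:
    """One report cell: accuracy with CI, sensitivity, specificity."""

    contrast: tuple
    feature_set: str
    mean_accuracy: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    n_trials: int
    seed: int
    accuracies: np.ndarray  # per-trial, for paired comparisons

    def __str__(self) -> str:
        return (
            f"{self.feature_set} {self.contrast[0]} vs {self.contrast[1]}: "
            f"{100 * self.mean_accuracy:.1f}% "
            f"(CI: {100 * self.ci_low:.1f}%~{100 * self.ci_high:.1f}%) "
            f"Sensitivity = {100 * self.sensitivity:.1f}%, "
            f"Specificity = {100 * self.specificity:.1f}%"
        )


def zscore_columns(x: np.ndarray, stats_from: np.ndarray | None = None):
    """Z-score columns; statistics optionally taken from a training matrix."""
    ref = x if stats_from is None else stats_from
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ValueError("constant feature column: cannot z-score")
    return (x - mu) / sd


def _structure_volumes(cohort: list[SubjectRecord], side_tags) -> np.ndarray:
    cols = []
    for tag in side_tags:
        if tag not in cohort[0].volumes:
            raise CohortError(f"cohort has no volumes for structure {tag!r}")
        cols.append([r.volumes[tag] for r in cohort])
    return np.array(cols, dtype=float).T


def _shape_columns(E: ShapeEmbedding, sel: SelectionResult, prefix: str):
    if not sel.selected:
        raise ValueError(
            f"empty component selection for contrast {sel.contrast} ({prefix}); "
            "no shape features available"
        )
    cols = np.column_stack([E.component(i) for i in sel.selected])
    names = [f"{prefix}_comp{i}" for i in sel.selected]
    return cols, names


def assemble_features(
    cohort: list[SubjectRecord],
    set_name: str,
    embeddings: dict | None = None,
    selections: dict | None = None,
    standardize: bool = True,
) -> FeatureSet:
    """Build one of the named feature sets over the whole cohort.

    ``embeddings`` / ``selections`` map "hippocampus" and "ventricle" to a
    bilateral :class:`ShapeEmbedding` and the :class:`SelectionResult` of
    the active contrast; required for the shape sets only. Columns are
    z-scored over the included subjects unless ``standardize`` is False.
    """
    if set_name not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {set_name!r}; expected one of {FEATURE_SETS}")
    blocks, names = [], []

    def add_csf():
        blocks.append(np.array([[r.csf[m] for m in CSF_MARKERS] for r in cohort], dtype=float))
        names.extend(CSF_MARKERS)

    def add_volumes(prefix, tags):
        blocks.append(_structure_volumes(cohort, tags))
        names.extend(f"volume_{t}" for t in tags)

    def add_shapes(key, prefix):
        if not embeddings or key not in embeddings or not selections or key not in selections:
            raise ValueError(f"shape set {set_name!r} needs an embedding and selection for {key!r}")
        cols, nm = _shape_columns(embeddings[key], selections[key], prefix)
        blocks.append(cols)
        names.extend(nm)

    if set_name == "CSF":
        add_csf()
    elif set_name == "Hp_volumes":
        add_volumes("Hp", ("hippocampus_L", "hippocampus_R"))
    elif set_name == "LV_volumes":
        add_volumes("LV", ("ventricle_L", "ventricle_R"))
    elif set_name == "Hp_shapes":
        add_shapes("hippocampus", "Hp")
    elif set_name == "LV_shapes":
        add_shapes("ventricle", "LV")
    elif set_name == "CSF+volumes":
        add_csf()
        add_volumes("Hp", ("hippocampus_L", "hippocampus_R"))
        add_volumes("LV", ("ventricle_L", "ventricle_R"))
    elif set_name == "CSF+shapes":
        add_csf()
        add_shapes("hippocampus", "Hp")
        add_shapes("ventricle", "LV")
    x = np.column_stack(blocks)
    if standardize:
        x = zscore_columns(x)
    return FeatureSet(set_name, x, names, [r.id for r in cohort])


def train_linear_classifier(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> LinearClassifier:
    """Soft-margin linear maximum-margin fit; y in {-1, +1}."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    svc = SVC(kernel="linear", C=C, tol=1e-6)
    svc.fit(np.asarray(X, dtype=float), y)
    return LinearClassifier(svc.coef_.ravel().copy(), float(svc.intercept_[0]))


def loo_cv(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> tuple[float, float, float]:
    """Leave-one-out CV: (accuracy, sensitivity, specificity).

    ``y`` in {-1, +1} with +1 the positive (more impaired) class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 subjects for LOO-CV")
    if (y == 1).sum() < 2 or (y == -1).sum() < 2:
        raise ValueError("each class needs at least 2 subjects")
    correct = np.zeros(n, dtype=bool)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        model = train_linear_classifier(X[keep], y[keep], C=C)
        correct[i] = model.predict(X[i : i + 1])[0] == y[i]
    acc = correct.mean()
    sens = correct[y == 1].mean()
    spec = correct[y == -1].mean()
    return float(acc), float(sens), float(spec)


def _positive_group(contrast: tuple) -> str:
    ga, gb = contrast
    return ga if SEVERITY[ga] >= SEVERITY[gb] else gb


def balanced_target_size(labels) -> int:
    """Common subsample size: min group size over NC, MCI (pooled), AD."""
    sizes = [int(group_mask(labels, g).sum()) for g in ("NC", "MCI", "AD")]
    sizes = [s for s in sizes if s > 0]
    if not sizes:
        raise CohortError("no diagnostic groups present")
    return min(sizes)


def balanced_subsample_eval(
    F: FeatureSet,
    labels,
    contrast: tuple,
    n_trials: int = 100,
    C: float = 1.0,
    seed: int = 0,
    target_size: int | None = None,
) -> ClassifierReport:
    """The full protocol: balanced subsampling + per-trial LOO-CV.

    Each trial subsamples both contrast groups without replacement to the
    common size (min diagnostic-group size by default), runs LOO-CV, and
    the report aggregates the trials: mean accuracy with a normal 95% CI
    (mean +- 1.96 SD / sqrt(n_trials)), mean sensitivity and specificity.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    labels = np.asarray(labels)
    if target_size is None:
        target_size = balanced_target_size(labels)
    ga, gb = contrast
    idx_a = np.flatnonzero(group_mask(labels, ga))
    idx_b = np.flatnonzero(group_mask(labels, gb))
    if len(idx_a) < target_size or len(idx_b) < target_size:
        raise ValueError(
            f"groups {contrast} have sizes {len(idx_a)}/{len(idx_b)} "
            f"< target {target_size}"
        )
    pos = _positive_group(contrast)
    y_a = 1 if ga == pos else -1
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_trials)]
    accs = np.empty(n_trials)
    senss = np.empty(n_trials)
    specs = np.empty(n_trials)
    for t, rng in enumerate(streams):
        sub_a = rng.choice(idx_a, size=target_size, replace=False)
        sub_b = rng.choice(idx_b, size=target_size, replace=False)
        rows = np.concatenate([sub_a, sub_b])
        y = np.concatenate([np.full(target_size, y_a), np.full(target_size, -y_a)])
        accs[t], senss[t], specs[t] = loo_cv(F.matrix[rows], y, C=C)
    mean = float(accs.mean())
    half = 1.96 * accs.std(ddof=1) / np.sqrt(n_trials)
    return ClassifierReport(
        contrast=tuple(contrast),
        feature_set=F.name,
        mean_accuracy=mean,
        ci_low=mean - half,
        ci_high=mean + half,
        sensitivity=float(senss.mean()),
        specificity=float(specs.mean()),
        n_trials=n_trials,
        seed=seed,
        accuracies=accs,
    )


@dataclass
class ComparisonResult:
    """Paired comparison of two per-trial accuracy streams."""

    p: float
    t: float
    degenerate: bool  # True when the trial differences have zero variance


def compare_classifiers(accs_a, accs_b) -> ComparisonResult:
    """Paired two-tailed Student t-test on per-trial accuracy differences."""
    accs_a = np.asarray(accs_a, dtype=float)
    accs_b = np.asarray(accs_b, dtype=float)
    if accs_a.shape != accs_b.shape:
        raise ValueError("accuracy streams must be paired (equal n_trials)")
    diff = accs_a - accs_b
    if np.var(diff, ddof=1) == 0:
        return ComparisonResult(p=0.0, t=np.inf if diff.mean() else 0.0, degenerate=True)
    t, p = stats.ttest_rel(accs_a, accs_b)
    return ComparisonResult(p=float(p), t=float(t), degenerate=False)
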