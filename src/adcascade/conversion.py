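"""Prediction of MCI-to-AD conversion from baseline markers.

A classifier separating the extremes of the cascade (NC vs AD) is
trained on baseline features and applied, untouched, to the MCI
converters (MCI-c) and non-converters (MCI-s). Sensitivity is the
fraction of converters labelled AD-like; specificity the fraction of
non-converters labelled NC-like. Feature selection and z-scoring
statistics come from the NC/AD training subjects only, so the MCI test
subjects never inform the decision rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import assemble_features, train_linear_classifier, zscore_columns
from .errors import CohortError
from .selection import select_components
from .synthetic import SubjectRecord


@dataclass
class ConversionReport:
    """Accuracy/sensitivity/specificity of conversion prediction."""

    feature_set: str
    accuracy: float
    ci_low: float
    ci_high: float
    sensitivity: float  # fraction of MCI-c predicted AD-like
    specificity: float  # fraction of MCI-s predicted NC-like
    n_converters: int
    n_nonconverters: int
    n_trials: int
    seed: int

    def __str__(self) -> str:
        return (
            f"{self.feature_set}: {100 * self.accuracy:.1f}% "
            f"({100 * self.ci_low:.1f}%~{100 * self.ci_high:.1f}%) "
            f"sens {100 * self.sensitivity:.1f}% spec {100 * self.specificity:.1f}%"
        )


def predict_conversion(
    cohort: list[SubjectRecord],
    feature_set: str,
    embeddings: dict | None = None,
    n_trials: int = 100,
    C: float = 1.0,
    seed: int = 0,
    balanced: bool = True,
) -> ConversionReport:
    """Train NC-vs-AD, apply to every MCI subject; aggregate over trials.

    Per trial the NC group is subsampled without replacement to the AD
    group's size (balanced training; disable with ``balanced=False`` to
    train on all NC), an SVM is fitted on z-scored training features, and
    all MCI subjects are classified. The report averages trials and
    carries the normal 95% CI of the accuracy.
    """
    labels = np.array([r.group for r in cohort])
    idx_nc = np.flatnonzero(labels == "NC")
    idx_ad = np.flatnonzero(labels == "AD")
    idx_c = np.flatnonzero(labels == "MCI_c")
    idx_s = np.flatnonzero(labels == "MCI_s")
    for name, idx in (("NC", idx_nc), ("AD", idx_ad), ("MCI_c", idx_c), ("MCI_s", idx_s)):
        if len(idx) == 0:
            raise CohortError(f"cohort has no {name} subjects")
    selections = None
    if embeddings is not None:
        # NC-vs-AD t-tests touch only NC and AD subjects: no MCI leakage
        selections = {
            key: select_components(E, labels, ("NC", "AD")) for key, E in embeddings.items()
        }
    F = assemble_features(cohort, feature_set, embeddings, selections, standardize=False)
    x = F.matrix
    n_c, n_s = len(idx_c), len(idx_s)
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_trials)]
    accs = np.empty(n_trials)
    senss = np.empty(n_trials)
    specs = np.empty(n_trials)
    for t, rng in enumerate(streams):
        train_nc = (
            rng.choice(idx_nc, size=min(len(idx_ad), len(idx_nc)), replace=False)
            if balanced
            else idx_nc
        )
        train = np.concatenate([train_nc, idx_ad])
        y = np.concatenate([np.full(len(train_nc), -1), np.full(len(idx_ad), 1)])
        x_train = zscore_columns(x[train])
        model = train_linear_classifier(x_train, y, C=C)
        x_c = zscore_columns(x[idx_c], stats_from=x[train])
        x_s = zscore_columns(x[idx_s], stats_from=x[train])
        sens = float((model.predict(x_c) == 1).mean())
        spec = float((model.predict(x_s) == -1).mean())
        senss[t] = sens
        specs[t] = spec
        accs[t] = (sens * n_c + spec * n_s) / (n_c + n_s)
    mean = float(accs.mean())
    half = 1.96 * accs.std(ddof=1) / np.sqrt(n_trials)
    return ConversionReport(
        feature_set=feature_set,
        accuracy=mean,
        ci_low=mean - half,
        ci_high=mean + half,
        sensitivity=float(senss.mean()),
        specificity=float(specs.mean()),
        n_converters=n_c,
        n_nonconverters=n_s,
        n_trials=n_trials,
        seed=seed,
    )
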