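"""End-to-end orchestration: simulate -> distances -> embed -> select ->
classify -> convert -> deformation maps, with deterministic seeding and
table-style CSV reports."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, conversion, defmap, embedding, selection, shape_metric, synthetic
from .synthetic import CohortSpec, generate_base_mesh

log = logging.getLogger(__name__)

CONTRASTS = (("NC", "AD"), ("NC", "MCI"), ("MCI", "AD"))
#: structure pairs entering one bilateral embedding each
BILATERAL = {
    "hippocampus": ("hippocampus_L", "hippocampus_R"),
    "ventricle": ("ventricle_L", "ventricle_R"),
}


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    cohort_spec: CohortSpec = field(default_factory=CohortSpec)
    kernel_sigma: float | None = None  # None: 5 x mean edge length of the base
    ridge: float = 1e-6
    isomap_k: int = 10
    isomap_m: int = 20
    alpha: float = 0.05
    C: float = 1.0
    n_trials: int = 100
    seed: int = 0
    feature_sets: tuple = classify.FEATURE_SETS

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=list))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        spec = d.pop("cohort_spec", None)
        d["feature_sets"] = tuple(d.get("feature_sets", classify.FEATURE_SETS))
        cfg = cls(**d)
        if spec is not None:
            cfg.cohort_spec = CohortSpec.from_dict(spec)
        return cfg

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True, default=list).encode()).hexdigest()[:12]


def _embed_structures(cohort, config, out: Path | None = None):
    """Per-bilateral-pair distance matrices and ISOMAP embeddings."""
    ids = [r.id for r in cohort]
    embeddings, distances = {}, {}
    for key, (tag_l, tag_r) in BILATERAL.items():
        if tag_l not in cohort[0].meshes:
            continue
        sides = {}
        for tag in (tag_l, tag_r):
            meshes = [r.meshes[tag] for r in cohort]
            params = (
                shape_metric.MetricParams(config.kernel_sigma, config.ridge)
                if config.kernel_sigma
                else shape_metric.MetricParams(
                    shape_metric.default_metric_params(meshes[0]).kernel_sigma, config.ridge
                )
            )
            sides[tag] = shape_metric.pairwise_distances(meshes, params, subject_ids=ids)
        D = shape_metric.combine_structures(sides[tag_l], sides[tag_r])
        E = embedding.isomap(D, k=config.isomap_k, m=min(config.isomap_m, D.n - 1))
        distances[key] = D
        embeddings[key] = E
        if out is not None:
            D.to_csv(out / f"distances_{key}.csv")
            pd.DataFrame(
                E.coordinates, index=ids,
                columns=[f"comp{i + 1}" for i in range(E.n_components)],
            ).to_csv(out / f"embedding_{key}.csv")
            (out / f"embedding_{key}.json").write_text(
                json.dumps(
                    {
                        "eigenvalues": E.eigenvalues.tolist(),
                        "fidelity_r": E.fidelity_r,
                        "neighbors_k": E.neighbors_k,
                    },
                    indent=2,
                )
            )
    return distances, embeddings


def _selection_table(embeddings, labels, alpha):
    """Table-3-style layout: marker set x contrast -> selected features."""
    rows = []
    selections = {c: {} for c in CONTRASTS}
    for key, E in embeddings.items():
        row = {"marker_set": f"{key}_shapes"}
        for c in CONTRASTS:
            sel = selection.select_components(E, labels, c, alpha=alpha)
            selections[c][key] = sel
            row[f"{c[0]}_vs_{c[1]}"] = ",".join(str(i) for i in sel.selected)
        rows.append(row)
    return pd.DataFrame(rows), selections


def _csf_selection_row(cohort, labels, alpha):
    row = {"marker_set": "CSF"}
    for c in CONTRASTS:
        flags = []
        for m in synthetic.CSF_MARKERS:
            vals = np.array([r.csf[m] for r in cohort])
            _, p = selection.two_sample_t(
                vals[selection.group_mask(labels, c[0])],
                vals[selection.group_mask(labels, c[1])],
            )
            if p < alpha:
                flags.append(m)
        row[f"{c[0]}_vs_{c[1]}"] = ",".join(flags)
    return row


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Run every stage and persist table-style reports; returns the run dir.

    Stages that fail abort the run with the stage named, leaving completed
    artifacts in place. Outputs are byte-identical for identical
    config + seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        cohort = synthetic.generate_cohort(config.cohort_spec)
        labels = np.array([r.group for r in cohort])
        synthetic.cohort_table(cohort).to_csv(out / "manifest.csv", index=False)
        config.cohort_spec.to_json(out / "cohort_spec.json")
        log.info("simulate: %d subjects (%.1fs)", len(cohort), time.perf_counter() - t0)

        stage = "distances/embed"
        t0 = time.perf_counter()
        _, embeddings = _embed_structures(cohort, config, out)
        log.info("distances/embed: %d structure pairs (%.1fs)", len(embeddings), time.perf_counter() - t0)

        stage = "select"
        sel_table, selections = _selection_table(embeddings, labels, config.alpha)
        sel_table = pd.concat(
            [sel_table, pd.DataFrame([_csf_selection_row(cohort, labels, config.alpha)])],
            ignore_index=True,
        )
        sel_table.to_csv(out / "selection.csv", index=False)

        stage = "classify"
        t0 = time.perf_counter()
        rows = []
        for set_name in config.feature_sets:
            row = {"feature_set": set_name}
            for c in CONTRASTS:
                try:
                    F = classify.assemble_features(cohort, set_name, embeddings, selections[c])
                    rep = classify.balanced_subsample_eval(
                        F, labels, c, n_trials=config.n_trials, C=config.C, seed=config.seed
                    )
                    row[f"{c[0]}_vs_{c[1]}"] = (
                        f"{100 * rep.mean_accuracy:.1f}% "
                        f"(CI: {100 * rep.ci_low:.1f}%~{100 * rep.ci_high:.1f}%) "
                        f"Sensitivity = {100 * rep.sensitivity:.1f}%, "
                        f"Specificity = {100 * rep.specificity:.1f}%"
                    )
                except ValueError as exc:
                    row[f"{c[0]}_vs_{c[1]}"] = f"NA ({exc})"
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "classification.csv", index=False)
        log.info("classify: %d feature sets (%.1fs)", len(rows), time.perf_counter() - t0)

        stage = "convert"
        rows = []
        for set_name in config.feature_sets:
            try:
                rep = conversion.predict_conversion(
                    cohort, set_name, embeddings, n_trials=config.n_trials,
                    C=config.C, seed=config.seed,
                )
                rows.append(
                    {
                        "feature_set": set_name,
                        "accuracy": f"{100 * rep.accuracy:.1f}% "
                        f"({100 * rep.ci_low:.1f}%~{100 * rep.ci_high:.1f}%)",
                        "sensitivity": f"{100 * rep.sensitivity:.1f}%",
                        "specificity": f"{100 * rep.specificity:.1f}%",
                    }
                )
            except ValueError as exc:
                rows.append({"feature_set": set_name, "accuracy": f"NA ({exc})",
                             "sensitivity": "NA", "specificity": "NA"})
        pd.DataFrame(rows).to_csv(out / "conversion.csv", index=False)

        stage = "map"
        spec = config.cohort_spec
        for tag in spec.structures:
            base = generate_base_mesh(spec.subdivision, spec.semi_axes[tag], tag)
            for former, latter in (("MCI", "NC"), ("AD", "MCI")):
                ma = [r.meshes[tag] for r in cohort if selection.group_mask([r.group], former)[0]]
                mb = [r.meshes[tag] for r in cohort if selection.group_mask([r.group], latter)[0]]
                dm = defmap.vertex_group_difference(ma, mb, base, contrast=(former, latter))
                stem = f"defmap_{tag}_{former}_vs_{latter}"
                dm.to_csv(out / f"{stem}.csv")
                dm.to_ply(base, out / f"{stem}.ply")

        stage = "metadata"
        (out / "run_metadata.json").write_text(
            json.dumps({"config_hash": config.digest(), "seed": config.seed,
                        "n_subjects": len(cohort)}, indent=2)
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
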