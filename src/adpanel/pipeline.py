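"""Experiment orchestration: the clustering runs (entire / preclinical /
impaired / amyloid-positive cohorts) and the three feature-selection tasks
(amyloid status on everyone; cognitive status on everyone and on
amyloid-positive subjects only), with report writers.

Every run is fully determined by its config (seed included) and the input
panel; reports echo the config so any number can be reproduced.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import (build_similarity, cut_clusters, edge_list,
                      select_k_elbow, wpgma_linkage)
from .panel import (AnalysisConfig, BiomarkerPanel, CohortLabels,
                    exclude_sparse_subjects, preprocess, subset_cohort)
from .selection import feature_selection_cv

__all__ = ["run_clustering_experiment", "run_feature_selection_experiment",
           "CLUSTERING_COHORTS", "FEATURE_TASKS", "stage"]

CLUSTERING_COHORTS = ("entire", "preclinical", "impaired", "amyloid_positive")
FEATURE_TASKS = ("amyloid_entire", "cognition_entire", "cognition_Apos")

# outcome-defining markers removed from each task's predictors (circularity)
_TASK_DROPS = {
    "amyloid_entire": ("amyloid_pet_centiloid",),
    "cognition_entire": ("cdr_sb", "mmse"),
    "cognition_Apos": ("cdr_sb", "mmse"),
}


class StageError(RuntimeError):
    """An experiment stage failed; the message names the stage."""


class stage:
    """Context manager tagging errors with the pipeline stage they came from."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, StageError):
            raise StageError(f"[{self.name}] {exc}") from exc
        return False


def _prepare(panel: BiomarkerPanel, labels: CohortLabels, cohort: str,
             config: AnalysisConfig):
    with stage("subset"):
        panel, labels = subset_cohort(panel, labels, cohort)
    with stage("exclude_sparse"):
        panel, labels = exclude_sparse_subjects(
            panel, config.sparse_subject_fraction, labels)
    with stage("preprocess"):
        panel = preprocess(panel)
    return panel, labels


def run_clustering_experiment(panel: BiomarkerPanel, labels: CohortLabels,
                              cohort: str, config: AnalysisConfig,
                              out_dir=None) -> dict:
    """Cluster one analysis cohort end to end.

    subset -> sparse exclusion -> preprocessing -> similarity -> permutation
    elbow -> WPGMA -> cut -> edge list; artifacts are written under
    ``out_dir`` when given.
    """
    if cohort not in CLUSTERING_COHORTS:
        raise ValueError(f"unknown cohort {cohort!r}")
    panel, labels = _prepare(panel, labels, cohort, config)
    with stage("similarity"):
        if panel.n_subjects < 3:
            raise ValueError(f"cohort has only {panel.n_subjects} subjects")
        sim = build_similarity(panel, min_pairs=config.min_pairs)
    with stage("elbow"):
        k, mean_scree = select_k_elbow(panel, config)
    with stage("linkage"):
        dendro = wpgma_linkage(sim)
    with stage("cut"):
        assignments = cut_clusters(dendro, k)
    with stage("edges"):
        edges = edge_list(sim, config.edge_threshold)

    report = {
        "cohort": cohort,
        "n_subjects": panel.n_subjects,
        "k_selected": int(k),
        "mean_scree": [float(v) for v in mean_scree],
        "clusters": {m: int(c) for m, c in zip(panel.marker_names, assignments)},
        "n_edges": len(edges),
        "config": config.to_dict(),
        "seed": config.seed,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sim.to_frame().to_csv(out / f"{cohort}_similarity.tsv", sep="\t")
        pd.DataFrame(dendro.linkage,
                     columns=["child_a", "child_b", "height", "size"]).to_csv(
            out / f"{cohort}_merges.tsv", sep="\t", index=False)
        (out / f"{cohort}_dendrogram.nwk").write_text(dendro.to_newick() + "\n")
        pd.DataFrame(edges, columns=["marker_i", "marker_j", "similarity"]).to_csv(
            out / f"{cohort}_edges.tsv", sep="\t", index=False)
        pd.DataFrame({"marker": panel.marker_names, "cluster": assignments}).to_csv(
            out / f"{cohort}_clusters.tsv", sep="\t", index=False)
        (out / f"{cohort}_clustering.json").write_text(json.dumps(report, indent=1))
        report["artifact_dir"] = str(out)
    return report


def run_feature_selection_experiment(panel: BiomarkerPanel,
                                     labels: CohortLabels, task: str,
                                     config: AnalysisConfig,
                                     out_dir=None) -> dict:
    """One gated feature-selection task.

    The outcome-defining markers are removed from the predictors (amyloid PET
    for the amyloid model; CDR-SB and MMSE for the cognition models) and the
    cohort is restricted to amyloid-positive subjects for ``cognition_Apos``.
    """
    if task not in FEATURE_TASKS:
        raise ValueError(f"unknown task {task!r}")
    cohort = "amyloid_positive" if task == "cognition_Apos" else "entire"
    panel, labels = _prepare(panel, labels, cohort, config)

    drops = list(_TASK_DROPS[task])
    if task == "amyloid_entire" and config.drop_cognitive_from_amyloid:
        drops += ["cdr_sb", "mmse"]
    with stage("predictors"):
        predictors = panel.drop_markers(drops)
        for m in drops:
            assert m not in predictors.marker_names
    with stage("outcome"):
        y = (labels.amyloid_positive if task == "amyloid_entire"
             else labels.impaired).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError(f"outcome single-class for task {task!r}")
    with stage("feature_selection"):
        weights = feature_selection_cv(
            predictors.values, y, config, predictors.marker_names,
            seed_path=(5, FEATURE_TASKS.index(task)))

    report = {
        "task": task,
        "cohort": cohort,
        "n_subjects": predictors.n_subjects,
        "dropped_predictors": drops,
        "folds_passed": weights.folds_passed,
        "weights": {m: float(v) for m, v in weights.ranking()},
        "weak": [m for m, w in zip(weights.marker_names, weights.weak) if w],
        "config": config.to_dict(),
        "seed": config.seed,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        weights.to_frame().to_csv(out / f"{task}_weights.tsv", sep="\t", index=False)
        (out / f"{task}_selection.json").write_text(json.dumps(report, indent=1))
        report["artifact_dir"] = str(out)
    return report
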