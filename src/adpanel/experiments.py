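"""Planted-structure recovery experiments on the default synthetic cohort.

These are the package's headline self-checks: regenerate the cohort many
times and measure how often the analysis recovers what was planted —
the four-block cluster count via the permutation elbow, and the five strong
amyloid predictors via gated feature selection.
"""

from __future__ import annotations

import numpy as np

from ._util import child_seed
from .cluster import select_k_elbow
from .panel import AnalysisConfig, exclude_sparse_subjects, preprocess
from .pipeline import run_feature_selection_experiment
from .selection import NoQualifyingModelError
from .synth import generate_cohort, preset

__all__ = ["cluster_count_recovery", "amyloid_ranking_recovery"]


def cluster_count_recovery(n_replicates: int = 50, n_permutations: int = 100,
                           seed: int = 0) -> dict:
    """Elbow-selected cluster count across seeded cohort replicates.

    Each replicate regenerates the default four-block cohort, applies the
    sparse-subject exclusion and preprocessing, and runs the
    permutation-averaged elbow.  Returns the modal k and the per-k counts.
    """
    ks = []
    for r in range(n_replicates):
        rep_seed = child_seed(seed, 1, r)
        cohort = generate_cohort(preset("entire_cohort", seed=rep_seed))
        panel, _ = exclude_sparse_subjects(cohort.panel, 0.5, cohort.labels)
        panel = preprocess(panel)
        k, _ = select_k_elbow(panel, AnalysisConfig(
            seed=rep_seed, n_permutations=n_permutations))
        ks.append(int(k))
    values, counts = np.unique(ks, return_counts=True)
    modal = int(values[np.argmax(counts)])
    return {
        "modal_k": modal,
        "k_counts": {int(v): int(c) for v, c in zip(values, counts)},
        "rate_k4": float(np.mean(np.asarray(ks) == 4)),
        "n_replicates": n_replicates,
    }


def amyloid_ranking_recovery(n_seeds: int = 20, seed: int = 0,
                             config_factory=None) -> dict:
    """How often the five planted strong amyloid predictors occupy the top
    five feature-weight ranks, across seeded cohort replicates.

    Each replicate regenerates the cohort and runs the full gated protocol
    (amyloid task: outcome = amyloid positivity, amyloid PET dropped from
    the predictors) at a reduced search budget.
    """
    if config_factory is None:
        config_factory = lambda s: AnalysisConfig.scaled(seed=s)
    hits = []
    folds_passed = []
    for r in range(n_seeds):
        rep_seed = child_seed(seed, 2, r)
        cohort = generate_cohort(preset("entire_cohort", seed=rep_seed))
        truth = set(cohort.truth["informative"]["amyloid"])
        try:
            report = run_feature_selection_experiment(
                cohort.panel, cohort.labels, "amyloid_entire",
                config_factory(rep_seed))
        except NoQualifyingModelError:
            hits.append(False)
            folds_passed.append(0)
            continue
        top5 = set(list(report["weights"])[:5])
        hits.append(top5 == truth)
        folds_passed.append(report["folds_passed"])
    return {
        "recovery_rate": float(np.mean(hits)),
        "mean_folds_passed": float(np.mean(folds_passed)),
        "n_seeds": n_seeds,
    }
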