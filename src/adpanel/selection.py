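"""The gated feature-weight protocol: cross-validated embedded selection.

For each outer fold, hyperparameters are tuned by Bayesian optimization on
the training portion, the tuned ensemble is fitted (with per-tree pruning on
an internal holdout) and evaluated on the held-out fold; only folds whose
model reaches the sensitivity/specificity gate contribute their importance
vector.  Contributions are averaged, min-max rescaled to [0, 1], and any
marker below the weak threshold is flagged a weak predictor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import spawn_rng, stratified_folds
from .forest import fit_forest, importance, predict, prune_forest, sens_spec
from .optimize import tune_forest
from .panel import AnalysisConfig
from .stats import minmax_rescale

__all__ = ["FeatureWeights", "feature_selection_cv", "NoQualifyingModelError"]


class NoQualifyingModelError(RuntimeError):
    """Raised when no CV fold's best model reaches the sens/spec gate."""


@dataclass
class FeatureWeights:
    """Per-marker predictor strengths with fold metadata.

    ``raw`` is the mean importance over gate-passing folds; ``rescaled`` maps
    it onto [0, 1] (max -> 1, min -> 0); ``weak`` flags rescaled < threshold.
    """

    marker_names: list[str]
    raw: np.ndarray
    rescaled: np.ndarray
    weak: np.ndarray
    folds_passed: int
    gate: tuple[float, float]
    fold_records: list[dict]

    def ranking(self) -> list[tuple[str, float]]:
        order = np.argsort(-self.rescaled, kind="stable")
        return [(self.marker_names[i], float(self.rescaled[i])) for i in order]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({
            "marker": self.marker_names,
            "raw": self.raw,
            "rescaled": self.rescaled,
            "weak": self.weak,
        })
        return df.sort_values("rescaled", ascending=False).reset_index(drop=True)


def _fit_and_prune(X, y, hyper, config, rng):
    """Fit on 80% of the data and reduced-error prune each tree on the
    remaining 20% (kept out of growing so pruning sees fresh data)."""
    holdout = stratified_folds(y, 5, rng) == 0
    grow = ~holdout
    model = fit_forest(X[grow], y[grow], hyper, rng, config.n_surrogates)
    if holdout.sum() and len(np.unique(y[holdout])) > 1:
        model = prune_forest(model, X[holdout], y[holdout])
    return model


def feature_selection_cv(X, y, config: AnalysisConfig,
                         marker_names: list[str] | None = None,
                         seed_path: tuple[int, ...] = (5,)) -> FeatureWeights:
    """Embedded feature selection with an outer CV and a performance gate.

    ``y`` must be binary 0/1 with 1 the positive class; outcome-defining
    markers must already have been removed by the caller.  Raises
    :class:`NoQualifyingModelError` if no fold's tuned model reaches
    sensitivity and specificity >= the configured gate on its held-out fold.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("outcome must be binary 0/1 with both classes present")
    p = X.shape[1]
    if marker_names is None:
        marker_names = [f"m{j}" for j in range(p)]
    rng_outer = spawn_rng(config.seed, *seed_path, 0)
    outer = stratified_folds(y, config.cv_folds, rng_outer)

    contributions = []
    records = []
    for f in range(config.cv_folds):
        tr = outer != f
        te = ~tr
        if len(np.unique(y[te])) < 2:
            records.append({"fold": f, "skipped": True})
            continue
        rng_f = spawn_rng(config.seed, *seed_path, 1, f)
        best, inner_err = tune_forest(X[tr], y[tr], config, rng_f)
        model = _fit_and_prune(X[tr], y[tr], best, config,
                               spawn_rng(config.seed, *seed_path, 2, f))
        pred = predict(model, X[te]).argmax(axis=1)
        sens, spec = sens_spec(pred, y[te], positive_label=1)
        passed = sens >= config.gate_sens and spec >= config.gate_spec
        records.append({"fold": f, "hyper": best, "inner_cv_error": inner_err,
                        "sensitivity": sens, "specificity": spec,
                        "passed": passed})
        if passed:
            contributions.append(importance(model, p))

    if not contributions:
        raise NoQualifyingModelError(
            f"no qualifying model: no fold reached sensitivity >= "
            f"{config.gate_sens} and specificity >= {config.gate_spec}")
    raw = np.mean(contributions, axis=0)
    rescaled = minmax_rescale(raw)
    return FeatureWeights(
        marker_names=list(marker_names),
        raw=raw,
        rescaled=rescaled,
        weak=rescaled < config.weak_threshold,
        folds_passed=len(contributions),
        gate=(config.gate_sens, config.gate_spec),
        fold_records=records,
    )
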