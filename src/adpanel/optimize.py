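"""Gaussian-process Bayesian optimization of the forest hyperparameters.

A small, fully seeded GP surrogate with expected-improvement acquisition over
the encoded search space: aggregation method (bag/boost), number of learning
cycles (log scale), learn rate (log scale, boosting only), minimum leaf size
(log scale) and maximum number of splits (log scale).  The objective is the
inner-k-fold cross-validated misclassification rate; every objective
evaluation runs a separate internal CV, and the returned incumbent is the
best evaluated point after the iteration budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import norm

from ._util import spawn_rng, stratified_folds
from .forest import ForestHyper, fit_forest, predict
from .panel import AnalysisConfig

__all__ = ["SearchSpace", "bayes_opt", "tune_forest", "cv_misclassification"]

_JITTER = 1e-8


@dataclass
class SearchSpace:
    """Bounds of the hyperparameter search (integers on a log scale)."""

    n_train: int
    max_cycles: int = 500
    max_splits_cap: int | None = None

    def __post_init__(self) -> None:
        self.max_splits = self.max_splits_cap or max(1, self.n_train - 1)
        self.max_min_leaf = max(2, self.n_train // 4)

    @property
    def dim(self) -> int:
        return 5  # method, log n_cycles, log learn_rate, log min_leaf, log max_splits

    def decode(self, z: np.ndarray) -> ForestHyper:
        """Map a unit-cube point to a ForestHyper."""

        def logint(u, lo, hi):
            return int(round(np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))))

        method = "bag" if z[0] < 0.5 else "boost"
        return ForestHyper(
            method=method,
            n_cycles=logint(z[1], 10, self.max_cycles),
            learn_rate=float(np.exp(np.log(1e-3) + z[2] * (np.log(1.0) - np.log(1e-3)))),
            min_leaf=logint(z[3], 1, self.max_min_leaf),
            max_splits=logint(z[4], 1, self.max_splits),
        )


def _gp_posterior(Z, y, Zq, lengthscale=0.3, noise=0.01):
    """GP posterior mean/sd at query points (RBF kernel, fixed scales)."""
    d2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(-1)
    K = np.exp(-d2 / (2 * lengthscale**2)) + (noise + _JITTER) * np.eye(len(Z))
    dq = ((Zq[:, None, :] - Z[None, :, :]) ** 2).sum(-1)
    Ks = np.exp(-dq / (2 * lengthscale**2))
    cf = cho_factor(K)
    alpha = cho_solve(cf, y)
    mu = Ks @ alpha
    v = cho_solve(cf, Ks.T)
    var = np.clip(1.0 + noise - (Ks * v.T).sum(1), 1e-12, None)
    return mu, np.sqrt(var)


def bayes_opt(objective, space: SearchSpace, n_iter: int,
              rng: np.random.Generator, n_candidates: int = 256):
    """Minimise ``objective(ForestHyper) -> float`` with GP + EI.

    The first quarter of the budget (at least 4 points) is a random design;
    the rest are expected-improvement picks over seeded random candidates.
    Returns ``(best_hyper, best_value, history)``.
    """
    if n_iter < 2:
        raise ValueError("iteration budget must be at least 2")
    n_init = min(max(4, n_iter // 4), n_iter - 1)
    Z: list[np.ndarray] = []
    vals: list[float] = []
    for _ in range(n_init):
        z = rng.random(space.dim)
        Z.append(z)
        vals.append(float(objective(space.decode(z))))
    for _ in range(n_iter - n_init):
        Zm = np.vstack(Z)
        y = np.asarray(vals)
        mu_y, sd_y = y.mean(), y.std()
        yn = (y - mu_y) / sd_y if sd_y > 0 else y - mu_y
        cand = rng.random((n_candidates, space.dim))
        mu, sd = _gp_posterior(Zm, yn, cand)
        best = yn.min()
        imp = best - mu - 0.01
        zscore = imp / sd
        ei = imp * norm.cdf(zscore) + sd * norm.pdf(zscore)
        z = cand[int(np.argmax(ei))]
        Z.append(z)
        vals.append(float(objective(space.decode(z))))
    i_best = int(np.argmin(vals))
    history = [(space.decode(z), v) for z, v in zip(Z, vals)]
    return space.decode(Z[i_best]), vals[i_best], history


def cv_misclassification(X, y, hyper: ForestHyper, folds: np.ndarray,
                         rng_seed: int, n_surrogates: int = 5) -> float:
    """Inner-CV misclassification rate of a hyperparameter setting."""
    errs = 0
    n = len(y)
    for f in np.unique(folds):
        tr = folds != f
        te = ~tr
        model = fit_forest(X[tr], y[tr], hyper,
                           spawn_rng(rng_seed, int(f)), n_surrogates)
        pred = predict(model, X[te]).argmax(axis=1)
        errs += int((pred != y[te]).sum())
    return errs / n


def tune_forest(X, y, config: AnalysisConfig, rng: np.random.Generator):
    """Bayesian optimization of the forest on (X, y) under ``config``.

    The inner-CV split is fixed across evaluations (common random numbers),
    so the surrogate sees a less noisy objective.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    folds = stratified_folds(y, config.inner_cv_folds, rng)
    fit_seed = int(rng.integers(2**31 - 1))
    space = SearchSpace(n_train=len(y), max_cycles=config.max_cycles,
                        max_splits_cap=config.max_splits_cap)

    def objective(hyper: ForestHyper) -> float:
        return cv_misclassification(X, y, hyper, folds, fit_seed,
                                    config.n_surrogates)

    best, value, _ = bayes_opt(objective, space, config.bo_iterations, rng)
    return best, value
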