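"""Shared numerical helpers: seeded RNG splitting, masked correlation, folds."""

from __future__ import annotations

import numpy as np

__all__ = [
    "spawn_rng",
    "child_seed",
    "masked_pearson",
    "stratified_folds",
]


def spawn_rng(seed: int, *path: int) -> np.random.Generator:
    """Derive an independent generator from a master seed and a stage path.

    Every stage of the pipeline draws from its own stream so that scaling one
    stage's workload (e.g. fewer permutations) never perturbs another stage.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(path)))


def child_seed(seed: int, *path: int) -> int:
    """A derived scalar seed (< 2**31) for APIs that want an integer."""
    ss = np.random.SeedSequence(seed, spawn_key=tuple(path))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def masked_pearson(values: np.ndarray, mask: np.ndarray, min_pairs: int = 3):
    """Pairwise-complete Pearson correlation of columns.

    Parameters
    ----------
    values : (n, p) array with arbitrary content where ``mask`` is True.
    mask : (n, p) boolean array, True = missing.
    min_pairs : entries computed from fewer complete pairs are set to NaN.

    Returns
    -------
    corr : (p, p) correlation matrix (NaN where undefined).
    n_pairs : (p, p) integer matrix of complete-pair counts.

    Each pairwise entry uses only rows where both columns are observed, so
    every entry can rest on a different subject subset (the estimator the
    analysis relies on; unbiased under data missing completely at random).
    """
    present = (~mask).astype(np.float64)
    x = np.where(mask, 0.0, values)
    n = present.T @ present
    sx = x.T @ present  # sum of column i over rows where j present
    sxx = (x * x).T @ present
    sxy = x.T @ x
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        var_i = sxx - sx**2 / n
        var_j = var_i.T
        corr = cov / np.sqrt(var_i * var_j)
    corr = np.where((n >= min_pairs) & (np.abs(corr) <= 1.5), np.clip(corr, -1, 1), np.nan)
    np.fill_diagonal(corr, 1.0)
    return corr, n.astype(np.int64)


def stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Assign each row a fold index in [0, n_folds), stratified by class."""
    y = np.asarray(y)
    folds = np.empty(len(y), dtype=np.int64)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        folds[idx] = np.arange(len(idx)) % n_folds
    return folds
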