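"""Marker clustering: pairwise-complete similarity, WPGMA linkage,
permutation-averaged elbow selection of the cluster count, and exports.

Similarity between two markers is the absolute Spearman correlation computed
over the subjects observed on *both* markers (pairwise-complete).  |rho| is a
similarity, so linkage runs on the standard conversion d = 1 - |rho|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._util import spawn_rng
from .panel import AnalysisConfig, BiomarkerPanel
from .stats import pca_scree, spearman_abs

__all__ = [
    "SimilarityMatrix",
    "Dendrogram",
    "build_similarity",
    "wpgma_linkage",
    "cut_clusters",
    "select_k_elbow",
    "elbow_index",
    "edge_list",
]


@dataclass
class SimilarityMatrix:
    """Marker x marker |Spearman rho| with per-pair complete-sample counts."""

    sim: np.ndarray
    n_pairs: np.ndarray
    marker_names: list[str]

    def __post_init__(self) -> None:
        self.sim = np.asarray(self.sim, dtype=np.float64)
        self.n_pairs = np.asarray(self.n_pairs, dtype=np.int64)
        p = len(self.marker_names)
        if self.sim.shape != (p, p) or self.n_pairs.shape != (p, p):
            raise ValueError("shape inconsistent with marker names")
        if not np.allclose(self.sim, self.sim.T, equal_nan=True):
            raise ValueError("similarity matrix not symmetric")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.sim, index=self.marker_names, columns=self.marker_names)


@dataclass
class Dendrogram:
    """WPGMA merge tree in scipy linkage form plus the leaf names."""

    linkage: np.ndarray  # (p-1, 4) scipy linkage matrix
    marker_names: list[str]

    def __post_init__(self) -> None:
        self.linkage = np.asarray(self.linkage, dtype=np.float64)
        if self.linkage.shape != (len(self.marker_names) - 1, 4):
            raise ValueError("linkage shape inconsistent with leaf count")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Newick string with branch lengths taken from merge heights."""
        p = len(self.marker_names)
        height = {i: 0.0 for i in range(p)}

        def node(i: int) -> str:
            if i < p:
                return self.marker_names[i]
            a, b, h, _ = self.linkage[i - p]
            height[i] = h
            la = h - height[int(a)]
            lb = h - height[int(b)]
            return f"({node(int(a))}:{la:.6g},{node(int(b))}:{lb:.6g})"

        # evaluate children first so 'height' is populated
        for row in range(p - 1):
            a, b, h, _ = self.linkage[row]
            height[p + row] = h
        root = p + (p - 1) - 1
        return node(root) + ";"


def build_similarity(panel: BiomarkerPanel, min_pairs: int = 3) -> SimilarityMatrix:
    """Pairwise-complete |Spearman| similarity between all marker pairs.

    A subject is removed from a pair's calculation only if it is missing one
    of the two markers in question, so each entry rests on the maximum number
    of subjects available.  Entries with fewer than ``min_pairs`` complete
    pairs (or a constant side) are NaN and abort clustering downstream.
    """
    p = panel.n_markers
    sim = np.eye(p)
    n_pairs = np.zeros((p, p), dtype=np.int64)
    present = ~panel.missing_mask
    np.fill_diagonal(n_pairs, present.sum(axis=0))
    for i in range(p):
        for j in range(i + 1, p):
            rho, n = spearman_abs(panel.values[:, i], panel.values[:, j])
            sim[i, j] = sim[j, i] = rho
            n_pairs[i, j] = n_pairs[j, i] = n
    low = (n_pairs < min_pairs) & ~np.eye(p, dtype=bool)
    sim[low] = np.nan
    return SimilarityMatrix(sim, n_pairs, list(panel.marker_names))


def wpgma_linkage(sim: SimilarityMatrix) -> Dendrogram:
    """WPGMA agglomeration of d = 1 - similarity.

    WPGMA updates d(ab, c) = (d(a,c) + d(b,c)) / 2 — the plain average of the
    two merged members' distances, regardless of cluster size.  Undefined
    similarity entries abort with an error rather than being imputed.
    Pairwise-complete input need not be metric; height inversions are flagged
    with a warning.
    """
    d = 1.0 - sim.sim
    if np.isnan(d).any():
        raise ValueError("undefined similarity entries; cannot cluster "
                         "(too few complete pairs for some marker pair)")
    np.fill_diagonal(d, 0.0)
    z = hierarchy.linkage(squareform(d, checks=False), method="weighted")
    if np.any(np.diff(z[:, 2]) < -1e-12):
        warnings.warn("non-monotone merge heights (non-metric input)", stacklevel=2)
    return Dendrogram(z, list(sim.marker_names))


def cut_clusters(dendro: Dendrogram, k: int) -> np.ndarray:
    """Partition the leaves into ``k`` clusters (labels arbitrary, stable)."""
    p = len(dendro.marker_names)
    if not 1 <= k <= p:
        raise ValueError(f"k must lie in [1, {p}]")
    if k == p:
        return np.arange(1, p + 1)
    return hierarchy.fcluster(dendro.linkage, t=k, criterion="maxclust")


def elbow_index(scree: np.ndarray) -> int:
    """Elbow of a descending scree by maximum second forward difference.

    Returns k = argmax_i (scree[i] - 2 scree[i+1] + scree[i+2]) with i
    1-based; ties break toward smaller k.  A single dominant factor gives
    k = 1; a curve with a cliff after the m-th eigenvalue gives k = m.
    """
    scree = np.asarray(scree, dtype=np.float64)
    if len(scree) < 3:
        raise ValueError("scree too short for an elbow")
    d2 = scree[:-2] - 2.0 * scree[1:-1] + scree[2:]
    return int(np.argmax(d2)) + 1


def select_k_elbow(panel: BiomarkerPanel, config: AnalysisConfig,
                   rng: np.random.Generator | None = None):
    """Permutation-averaged elbow selection of the number of marker clusters.

    For each of ``config.n_permutations`` replicates a uniformly random
    ``holdout_fraction`` of subjects is dropped, the PCA scree of the
    pairwise-complete correlation matrix of the retained subjects is
    computed, and the scree curves are averaged; the returned k is the elbow
    of the mean curve.
    """
    if rng is None:
        rng = spawn_rng(config.seed, 3)
    n = panel.n_subjects
    n_drop = int(round(n * config.holdout_fraction))
    if n - n_drop < 3:
        raise ValueError("holdout leaves fewer than 3 subjects")
    total = np.zeros(panel.n_markers)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-PSD clip warnings inside the loop
        for _ in range(config.n_permutations):
            drop = rng.choice(n, size=n_drop, replace=False)
            keep = np.setdiff1d(np.arange(n), drop)
            total += pca_scree(panel.values[keep], panel.missing_mask[keep],
                               min_pairs=config.min_pairs)
    mean_scree = total / config.n_permutations
    return elbow_index(mean_scree), mean_scree


def edge_list(sim: SimilarityMatrix, threshold: float):
    """Marker pairs with similarity strictly above ``threshold``.

    Upper triangle only, sorted by similarity descending; the machine twin of
    a circle plot of strong associations.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    p = len(sim.marker_names)
    edges = []
    for i in range(p):
        for j in range(i + 1, p):
            s = sim.sim[i, j]
            if not np.isnan(s) and s > threshold:
                edges.append((sim.marker_names[i], sim.marker_names[j], float(s)))
    edges.sort(key=lambda e: -e[2])
    return edges
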