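"""Low-level statistical kernels used throughout the analysis.

Spearman correlation under missingness, chi-square and one-way ANOVA
reconstructions from group summaries (the demographic-table comparisons),
PCA scree of a pairwise-complete correlation matrix, and min-max rescaling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import stats as sps

from ._util import masked_pearson

__all__ = [
    "ContingencyTable",
    "GroupSummary",
    "spearman_abs",
    "chisq_from_table",
    "anova_from_summary",
    "pca_scree",
    "minmax_rescale",
    "load_reference_demographics",
    "demographic_tests",
]


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D table")
        if (self.counts < 0).any():
            raise ValueError("negative count")
        if self.counts.sum() == 0:
            raise ValueError("empty table")


@dataclass
class GroupSummary:
    """Per-group mean / sample-sd / n triples for a continuous variable."""

    means: np.ndarray
    sds: np.ndarray
    ns: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=np.float64)
        self.sds = np.asarray(self.sds, dtype=np.float64)
        self.ns = np.asarray(self.ns, dtype=np.int64)
        if not (len(self.means) == len(self.sds) == len(self.ns)) or len(self.means) < 2:
            raise ValueError("need >= 2 groups with aligned means/sds/ns")
        if (self.ns < 2).any():
            raise ValueError("each group needs n >= 2")


def spearman_abs(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """|Spearman rho| over indices where both vectors are observed.

    Missing entries are NaN.  Ties receive average ranks (rho computed as
    Pearson on midranks).  Returns ``(abs_rho, n_pairs)``; ``abs_rho`` is NaN
    when fewer than 3 complete pairs exist or either side is constant.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        return float("nan"), n
    xs, ys = x[ok], y[ok]
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return float("nan"), n
    rho = sps.spearmanr(xs, ys).statistic
    return float(abs(rho)), n


def chisq_from_table(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square test of independence (no continuity correction)."""
    counts = table.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero margin; expected counts undefined")
    res = sps.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def anova_from_summary(summary: GroupSummary) -> tuple[float, int, int, float]:
    """One-way ANOVA reconstructed from group means, sample sds and sizes.

    SSB = sum n_i (m_i - grand_mean)^2, SSW = sum (n_i - 1) s_i^2,
    F = (SSB / (k-1)) / (SSW / (N-k)).
    """
    m, s, n = summary.means, summary.sds, summary.ns
    k, total = len(m), int(n.sum())
    grand = float((n * m).sum() / total)
    ssb = float((n * (m - grand) ** 2).sum())
    ssw = float(((n - 1) * s**2).sum())
    df1, df2 = k - 1, total - k
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, df1, df2, 1.0
        return float("inf"), df1, df2, 0.0
    f = (ssb / df1) / (ssw / df2)
    return f, df1, df2, float(sps.f.sf(f, df1, df2))


def pca_scree(values: np.ndarray, mask: np.ndarray | None = None,
              min_pairs: int = 3) -> np.ndarray:
    """Eigenvalues (descending, clipped at 0) of the pairwise-complete
    correlation matrix of a subjects x markers array.

    Pairwise-complete correlation matrices need not be positive semi-definite;
    negative eigenvalues are clipped with a warning, which is harmless for
    elbow purposes (only the decay shape matters).
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("need a 2-D array with >= 2 markers")
    if mask is None:
        mask = np.isnan(values)
    mask = np.asarray(mask, dtype=bool)
    if mask.all(axis=0).any():
        j = int(np.flatnonzero(mask.all(axis=0))[0])
        raise ValueError(f"marker column {j} is entirely missing")
    corr, _ = masked_pearson(values, mask, min_pairs=min_pairs)
    if np.isnan(corr).any():
        raise ValueError("undefined correlation entry (too few complete pairs)")
    eig = np.linalg.eigvalsh(corr)
    if eig.min() < -1e-8:
        warnings.warn("pairwise-complete correlation matrix is not PSD; "
                      "negative eigenvalues clipped at 0", stacklevel=2)
    return np.sort(np.clip(eig, 0.0, None))[::-1]


def minmax_rescale(v: np.ndarray) -> np.ndarray:
    """Affine map of a vector onto [0, 1] (min -> 0, max -> 1)."""
    v = np.asarray(v, dtype=np.float64)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        raise ValueError("constant vector; rescale undefined")
    return (v - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# Demographic-table reconstruction
# ---------------------------------------------------------------------------

def load_reference_demographics() -> dict:
    """The shipped demographic summary of the reference cohort."""
    return json.loads(resources.files("adpanel.data").joinpath("table1.json").read_text())


def demographic_tests(summary: dict | None = None) -> dict[str, float]:
    """Recompute the group-comparison p-values from a demographic summary.

    Categorical rows are compared with chi-square tests on the counts,
    continuous rows with one-way ANOVAs reconstructed from the printed
    means/sds/ns.
    """
    if summary is None:
        summary = load_reference_demographics()
    n = np.asarray(summary["n"])
    groups = list(summary["groups"])
    out: dict[str, float] = {}
    for key in ("sex_female", "race_nhw", "apoe4_carrier"):
        if key in summary:
            yes = np.asarray(summary[key])
            table = ContingencyTable(np.vstack([yes, n - yes]),
                                     [key, f"not_{key}"], groups)
            out[key] = chisq_from_table(table)[2]
    for key in ("age", "education"):
        if f"{key}_mean" in summary:
            gs = GroupSummary(summary[f"{key}_mean"], summary[f"{key}_sd"], n)
            out[key] = anova_from_summary(gs)[3]
    return out
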