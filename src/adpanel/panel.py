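"""Core data model: the biomarker panel, cohort labels, preprocessing and I/O.

The panel is a subjects x markers matrix with an explicit missingness mask.
Most subjects in the kind of cohort this package models are missing at least
one marker, so every downstream computation must consult the mask; missing
cells are stored as NaN but the mask is authoritative.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .markers import LABEL_COLUMNS, LOG_MARKERS, MARKERS

__all__ = [
    "BiomarkerPanel",
    "CohortLabels",
    "AnalysisConfig",
    "CENTILOID_THRESHOLD",
    "read_panel",
    "write_panel",
    "preprocess",
    "exclude_sparse_subjects",
    "subset_cohort",
]

# Amyloid-PET positivity cut-point on the Centiloid scale (inclusive).
CENTILOID_THRESHOLD = 16.4


@dataclass
class BiomarkerPanel:
    """Subjects x markers matrix with missingness mask.

    ``values`` holds NaN exactly where ``missing_mask`` is True; marker names
    are unique and ordered.  ``transforms`` records preprocessing applied, for
    the sidecar written next to exported panels.
    """

    subject_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray
    marker_names: list[str]
    transforms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("values and missing_mask shapes differ")
        if self.values.shape != (len(self.subject_ids), len(self.marker_names)):
            raise ValueError("matrix shape inconsistent with ids / marker names")
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ValueError("marker names not unique")
        # keep the NaN sentinel and the mask in lock step
        self.values = np.where(self.missing_mask, np.nan, self.values)
        if np.isnan(self.values[~self.missing_mask]).any():
            raise ValueError("NaN value present where mask says observed")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def marker_index(self, name: str) -> int:
        try:
            return self.marker_names.index(name)
        except ValueError:
            raise KeyError(f"unknown marker {name!r}") from None

    def take_subjects(self, idx: np.ndarray) -> "BiomarkerPanel":
        return BiomarkerPanel(
            [self.subject_ids[i] for i in np.atleast_1d(idx)],
            self.values[idx],
            self.missing_mask[idx],
            list(self.marker_names),
            list(self.transforms),
        )

    def drop_markers(self, names) -> "BiomarkerPanel":
        keep = [i for i, m in enumerate(self.marker_names) if m not in set(names)]
        return BiomarkerPanel(
            list(self.subject_ids),
            self.values[:, keep],
            self.missing_mask[:, keep],
            [self.marker_names[i] for i in keep],
            list(self.transforms),
        )


@dataclass
class CohortLabels:
    """Per-subject outcome and demographic labels aligned with a panel."""

    cdr_group: np.ndarray  # "CDR0" | "CDRgt0"
    centiloid: np.ndarray
    age: np.ndarray
    sex: np.ndarray  # "F" | "M"
    apoe4_carrier: np.ndarray
    education: np.ndarray
    race_nhw: np.ndarray

    def __post_init__(self) -> None:
        self.cdr_group = np.asarray(self.cdr_group, dtype=object)
        bad = ~np.isin(self.cdr_group, ["CDR0", "CDRgt0"])
        if bad.any():
            raise ValueError(f"cdr_group contains invalid levels: {set(self.cdr_group[bad])}")
        self.centiloid = np.asarray(self.centiloid, dtype=np.float64)
        self.age = np.asarray(self.age, dtype=np.float64)
        self.sex = np.asarray(self.sex, dtype=object)
        self.apoe4_carrier = np.asarray(self.apoe4_carrier, dtype=bool)
        self.education = np.asarray(self.education, dtype=np.float64)
        self.race_nhw = np.asarray(self.race_nhw, dtype=bool)

    @property
    def amyloid_positive(self) -> np.ndarray:
        """Positivity on the Centiloid scale; the threshold is inclusive."""
        return self.centiloid >= CENTILOID_THRESHOLD

    @property
    def impaired(self) -> np.ndarray:
        return self.cdr_group == "CDRgt0"

    def __len__(self) -> int:
        return len(self.centiloid)

    def take(self, idx: np.ndarray) -> "CohortLabels":
        return CohortLabels(
            self.cdr_group[idx],
            self.centiloid[idx],
            self.age[idx],
            self.sex[idx],
            self.apoe4_carrier[idx],
            self.education[idx],
            self.race_nhw[idx],
        )


@dataclass
class AnalysisConfig:
    """Tunable parameters for the full analysis.

    Defaults mirror the study protocol (1000 elbow permutations with 20%
    holdout, 10-fold outer CV, 300 Bayesian-optimization iterations with an
    internal 10-fold CV, 80% sensitivity/specificity gate, weak-predictor
    threshold 0.5, edge-list threshold 0.5, >50% missing-subject exclusion).
    ``scaled()`` gives a cheaper profile for exploratory runs; scaling only
    changes precision, never the code path.
    """

    seed: int = 0
    n_permutations: int = 1000
    holdout_fraction: float = 0.2
    cv_folds: int = 10
    bo_iterations: int = 300
    inner_cv_folds: int = 10
    gate_sens: float = 0.8
    gate_spec: float = 0.8
    weak_threshold: float = 0.5
    edge_threshold: float = 0.5
    sparse_subject_fraction: float = 0.5
    min_pairs: int = 3
    n_surrogates: int = 5
    # search-space caps for Bayesian optimization (log-scale for n_cycles)
    max_cycles: int = 500
    max_splits_cap: int | None = None  # None = n - 1
    drop_cognitive_from_amyloid: bool = False

    def __post_init__(self) -> None:
        for name in ("holdout_fraction", "gate_sens", "gate_spec", "weak_threshold",
                     "sparse_subject_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not 0.0 <= self.edge_threshold <= 1.0:
            raise ValueError("edge_threshold must lie in [0, 1]")
        for name in ("n_permutations", "cv_folds", "bo_iterations", "inner_cv_folds",
                     "min_pairs", "max_cycles"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    @classmethod
    def scaled(cls, seed: int = 0, **overrides) -> "AnalysisConfig":
        """Reduced-budget profile (fewer permutations/BO iterations)."""
        base = dict(
            seed=seed,
            n_permutations=100,
            bo_iterations=30,
            inner_cv_folds=2,
            cv_folds=10,
            max_cycles=40,
            max_splits_cap=24,
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_panel(path, schema=MARKERS, reject_impaired_negative: bool = True):
    """Read a cohort table (CSV/TSV, empty cell = missing).

    Returns ``(BiomarkerPanel, CohortLabels)``.  Subjects who are cognitively
    impaired yet amyloid negative are rejected with a warning (the analysis
    population requires the impaired group to be on the amyloid pathway).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)
    dupes = {c for c in header if header.count(c) > 1}
    if dupes:
        raise ValueError(f"duplicated column(s): {sorted(dupes)}")
    df = _read_table(path)
    missing_cols = [c for c in schema if c not in df.columns]
    if missing_cols:
        raise ValueError(f"marker column(s) absent from file: {missing_cols}")
    unknown = [c for c in df.columns if c not in set(schema) | set(LABEL_COLUMNS)]
    if unknown:
        raise ValueError(f"unknown column(s): {unknown}")

    n = len(df)
    values = np.full((n, len(schema)), np.nan)
    mask = np.zeros((n, len(schema)), dtype=bool)
    for j, m in enumerate(schema):
        col = df[m].str.strip()
        empty = col == ""
        mask[:, j] = empty
        parsed = pd.to_numeric(col.where(~empty), errors="coerce")
        bad = parsed.isna() & ~empty
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric value {col.iloc[i]!r} at row {i + 2}, column {m!r}"
            )
        values[:, j] = parsed.to_numpy()

    def _label(name, caster):
        if name not in df.columns:
            raise ValueError(f"label column {name!r} absent from file")
        try:
            return caster(df[name])
        except Exception as exc:  # pragma: no cover - message forwarding
            raise ValueError(f"cannot parse label column {name!r}: {exc}") from exc

    labels = CohortLabels(
        cdr_group=_label("cdr_group", lambda s: s.to_numpy(dtype=object)),
        centiloid=_label("centiloid", lambda s: pd.to_numeric(s).to_numpy()),
        age=_label("age", lambda s: pd.to_numeric(s).to_numpy()),
        sex=_label("sex", lambda s: s.to_numpy(dtype=object)),
        apoe4_carrier=_label("apoe4_carrier", lambda s: pd.to_numeric(s).astype(bool).to_numpy()),
        education=_label("education", lambda s: pd.to_numeric(s).to_numpy()),
        race_nhw=_label("race_nhw", lambda s: pd.to_numeric(s).astype(bool).to_numpy()),
    )
    ids = (df["subject_id"].to_numpy(dtype=object).tolist()
           if "subject_id" in df.columns else [f"S{i:04d}" for i in range(n)])
    panel = BiomarkerPanel(ids, values, mask, list(schema))

    if reject_impaired_negative:
        bad = labels.impaired & ~labels.amyloid_positive
        if bad.any():
            warnings.warn(
                f"rejected {int(bad.sum())} impaired, amyloid-negative subject(s)",
                stacklevel=2,
            )
            keep = np.flatnonzero(~bad)
            panel, labels = panel.take_subjects(keep), labels.take(keep)
    return panel, labels


def write_panel(panel: BiomarkerPanel, labels: CohortLabels, path, seed=None) -> None:
    """Write panel + labels as CSV and a sidecar JSON of applied transforms."""
    path = Path(path)
    df = pd.DataFrame(panel.values, columns=panel.marker_names)
    df = df.where(~pd.DataFrame(panel.missing_mask, columns=panel.marker_names), other=np.nan)
    df.insert(0, "subject_id", panel.subject_ids)
    df["cdr_group"] = labels.cdr_group
    df["centiloid"] = labels.centiloid
    df["age"] = labels.age
    df["sex"] = labels.sex
    df["apoe4_carrier"] = labels.apoe4_carrier.astype(int)
    df["education"] = labels.education
    df["race_nhw"] = labels.race_nhw.astype(int)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df.to_csv(path, sep=sep, index=False, na_rep="")
    sidecar = {"transforms": panel.transforms, "seed": seed, "n_subjects": panel.n_subjects}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def preprocess(panel: BiomarkerPanel, log_markers=LOG_MARKERS) -> BiomarkerPanel:
    """Natural-log transform the listed markers, then z-score every marker.

    z-scores use each marker's non-missing entries only (sample sd, ddof=1);
    missing entries are untouched.  Raises on non-positive values in a log
    marker and on zero-variance columns.
    """
    unknown = [m for m in log_markers if m not in panel.marker_names]
    if unknown:
        raise ValueError(f"log markers not in panel: {unknown}")
    values = panel.values.copy()
    for m in log_markers:
        j = panel.marker_index(m)
        obs = ~panel.missing_mask[:, j]
        if np.any(values[obs, j] <= 0):
            raise ValueError(f"non-positive value in log marker {m!r}")
        values[obs, j] = np.log(values[obs, j])
    for j, m in enumerate(panel.marker_names):
        obs = ~panel.missing_mask[:, j]
        col = values[obs, j]
        if len(col) < 2:
            raise ValueError(f"marker {m!r} has fewer than 2 observed values")
        sd = col.std(ddof=1)
        if sd == 0:
            raise ValueError(f"marker {m!r} is constant; z-score undefined")
        values[obs, j] = (col - col.mean()) / sd
    out = BiomarkerPanel(
        list(panel.subject_ids), values, panel.missing_mask.copy(),
        list(panel.marker_names),
        panel.transforms + [f"log:{','.join(log_markers)}", "zscore"],
    )
    return out


def exclude_sparse_subjects(panel: BiomarkerPanel, fraction: float = 0.5,
                            labels: CohortLabels | None = None):
    """Drop subjects missing strictly more than ``fraction`` of the markers."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    frac_missing = panel.missing_mask.mean(axis=1)
    keep = np.flatnonzero(frac_missing <= fraction)
    out = panel.take_subjects(keep)
    if labels is None:
        return out
    return out, labels.take(keep)


def subset_cohort(panel: BiomarkerPanel, labels: CohortLabels, which: str):
    """Select an analysis cohort.

    ``entire`` keeps everyone; ``preclinical`` = cognitively normal and
    amyloid positive; ``impaired`` = impaired and amyloid positive;
    ``amyloid_positive`` = Centiloid >= 16.4 regardless of cognition.
    """
    if which == "entire":
        sel = np.ones(len(labels), dtype=bool)
    elif which == "preclinical":
        sel = (~labels.impaired) & labels.amyloid_positive
    elif which == "impaired":
        sel = labels.impaired & labels.amyloid_positive
    elif which == "amyloid_positive":
        sel = labels.amyloid_positive
    else:
        raise ValueError(f"unknown cohort {which!r}")
    if not sel.any():
        raise ValueError(f"cohort {which!r} is empty")
    idx = np.flatnonzero(sel)
    return panel.take_subjects(idx), labels.take(idx)
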