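"""Synthetic cohort generator with planted structure.

The generator emulates the statistical features the analysis depends on:
four correlated biomarker blocks (core pathology, neurodegeneration,
AT8-epitope phosphorylation sites, neuronal dysfunction/inflammation),
group-dependent mean shifts along disease axes, per-marker missingness with
a small fraction of very sparse subjects, and demographics drawn from the
reference cohort's published group summaries.

Model: for subject in group g, block b with latent factor
``f_b ~ N(shift_b[g], 1)``, a marker with signed loading ``l`` has value
``l * f_b + direct[g] + sqrt(1 - l^2) * noise_sd * eps``.  Blocks are mutually
independent given the group; group shifts are what couple markers across
blocks, so shift patterns are chosen close to orthogonal (under group-size
weighting) to keep between-block correlation near zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import spawn_rng
from .markers import (
    AT8_SITES,
    CORE_PATHOLOGY,
    DYSFUNCTION_INFLAMMATION,
    MARKERS,
    NEURODEGENERATION,
)
from .panel import CENTILOID_THRESHOLD, BiomarkerPanel, CohortLabels
from .stats import load_reference_demographics

__all__ = ["CohortSpec", "SyntheticCohort", "generate_cohort",
           "generate_demographics", "preset", "PRESETS"]

GROUP_NAMES = ("CN_Aneg", "CN_Apos", "CI")

# Markers whose raw scale is positive and right-skewed; generated on the log
# scale and exponentiated (preprocess() logs them back).
_EXP_MARKERS = ("csf_nfl", "plasma_nfl")


@dataclass
class CohortSpec:
    """Recipe for a synthetic cohort.

    ``blocks`` maps block name -> {marker: signed loading}; ``assigned``
    names the markers that truly belong to each block (extra entries in
    ``blocks`` are weak tethers, not members).  ``factor_shift`` gives each
    block factor's mean per group (z units), ``direct_effect`` adds
    marker-specific group shifts on top of the factor.
    """

    group_sizes: tuple[int, int, int] = (211, 228, 88)
    blocks: dict = field(default_factory=dict)
    assigned: dict = field(default_factory=dict)
    factor_shift: dict = field(default_factory=dict)
    direct_effect: dict = field(default_factory=dict)
    noise_sd: float = 1.0
    missing_rate: float = 0.10
    sparse_subject_rate: float = 0.04
    separator_marker: str | None = None
    informative: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, members in self.assigned.items():
            if name not in self.blocks:
                raise ValueError(f"assigned block {name!r} has no loadings")
            for m in members:
                if m in seen:
                    raise ValueError(f"marker {m!r} assigned to two blocks")
                seen.add(m)
        for name, loadings in self.blocks.items():
            for m, l in loadings.items():
                if m not in MARKERS:
                    raise ValueError(f"unknown marker {m!r}")
                if not 0.0 < abs(l) <= 1.0:
                    raise ValueError(f"loading for {m!r} must have magnitude in (0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.sparse_subject_rate < 1.0:
            raise ValueError("sparse_subject_rate must lie in [0, 1)")
        if any(n < 0 for n in self.group_sizes):
            raise ValueError("group sizes must be non-negative")

    @property
    def block_of(self) -> dict:
        """Planted block membership per marker (None = unassigned)."""
        out = {m: None for m in MARKERS}
        for name, members in self.assigned.items():
            for m in members:
                out[m] = name
        return out


@dataclass
class SyntheticCohort:
    panel: BiomarkerPanel
    labels: CohortLabels
    truth: dict


def _weighted_orthogonalize(v, u, weights):
    """Remove the component of pattern v along pattern u (weighted, centred)."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    uc = u - (w * u).sum()
    vc = v - (w * v).sum()
    denom = (w * uc * uc).sum()
    if denom == 0:
        return vc
    return vc - (w * uc * vc).sum() / denom * uc


# Amyloid axis across (CN(A-), CN(A+), CI): negatives below threshold, the
# two amyloid-positive groups elevated.
_AMYLOID_PATTERN = np.array([-0.9, 0.7, 0.9])
# Core-factor shifts use an attenuated version of the axis: every core
# marker tracks amyloid through the shared factor, but only the planted
# strong predictors carry large direct effects.
_CORE_FACTOR_SCALE = 0.65
# Impairment axis: only the CI group elevated; orthogonalized against the
# amyloid axis at generation time so neurodegeneration markers do not pick
# up spurious correlation with core-pathology markers.
_IMPAIRED_RAW = np.array([0.0, 0.0, 1.0])

# Strong planted predictors of amyloid status and their direct shift scale
# (multiplies the amyloid pattern; sign mirrors the marker's direction).
_STRONG_AMYLOID = {
    "csf_pT217_T217": 1.20,
    "csf_pT111_T111": 1.10,
    "csf_ptau_abeta40": 1.00,
    "csf_abeta42_40": -0.95,
    "csf_pT231_T231": 0.90,
}


def _entire_cohort_spec(seed: int) -> CohortSpec:
    core_loading = {
        m: 0.45 for m in CORE_PATHOLOGY
    }
    # decreasing markers load negatively (lower value = more pathology)
    for m in ("csf_abeta42_40", "abeta42_40_plasma"):
        core_loading[m] = -0.45
    # weak tethers of the unassigned markers (kept below the 0.5 edge
    # threshold so they sit outside every block at the similarity level)
    core_loading["mmse"] = -0.35
    core_loading["prs"] = 0.30

    neuro_loading = {"csf_nfl": 0.92, "plasma_nfl": 0.92,
                     "mri_cortical_signature": -0.92}
    at8_loading = {m: 0.89 for m in AT8_SITES}
    at8_loading["csf_pT175_T175"] = 0.45
    dys_loading = {m: 0.88 for m in DYSFUNCTION_INFLAMMATION}

    amyl = _AMYLOID_PATTERN
    ci = _IMPAIRED_RAW
    direct = {m: s * amyl for m, s in _STRONG_AMYLOID.items()}
    direct["cdr_sb"] = 1.3 * ci
    direct["tau_pet_suvr"] = 0.5 * ci
    direct["csf_pT205_T205"] = 0.45 * ci
    direct["mmse"] = -0.6 * ci

    return CohortSpec(
        group_sizes=(211, 228, 88),
        blocks={"core_pathology": core_loading,
                "neurodegeneration": neuro_loading,
                "at8_sites": at8_loading,
                "dysfunction_inflammation": dys_loading},
        assigned={"core_pathology": CORE_PATHOLOGY,
                  "neurodegeneration": NEURODEGENERATION,
                  "at8_sites": AT8_SITES,
                  "dysfunction_inflammation": DYSFUNCTION_INFLAMMATION},
        factor_shift={"core_pathology": _CORE_FACTOR_SCALE * amyl,
                      "neurodegeneration": 0.85 * ci,
                      "at8_sites": np.zeros(3),
                      "dysfunction_inflammation": np.zeros(3)},
        direct_effect=direct,
        informative={"amyloid": tuple(_STRONG_AMYLOID),
                     "cognition": ("cdr_sb", "tau_pet_suvr", "csf_pT205_T205",
                                   "csf_nfl", "plasma_nfl",
                                   "mri_cortical_signature")},
        seed=seed,
    )


def preset(name: str, seed: int = 0) -> CohortSpec:
    """Named cohort recipes.

    ``entire_cohort``: four planted blocks, group sizes (211, 228, 88),
    strong amyloid predictors and impairment effects.  ``preclinical_only`` /
    ``impaired_only``: single-group versions (neurodegeneration attenuated in
    the preclinical preset).  ``null_panel``: no structure at all.
    ``single_separator``: one marker deterministically equal to amyloid
    status.
    """
    if name == "entire_cohort":
        return _entire_cohort_spec(seed)
    if name == "preclinical_only":
        spec = _entire_cohort_spec(seed)
        spec.group_sizes = (0, 228, 0)
        # cortical thinning barely underway before symptoms: the MRI
        # signature decouples from the NfL factor and tracks accumulating
        # pathology weakly instead
        spec.blocks["neurodegeneration"]["mri_cortical_signature"] = -0.12
        spec.blocks["core_pathology"]["mri_cortical_signature"] = -0.62
        return spec
    if name == "impaired_only":
        spec = _entire_cohort_spec(seed)
        spec.group_sizes = (0, 0, 88)
        return spec
    if name == "null_panel":
        return CohortSpec(group_sizes=(80, 80, 40), seed=seed)
    if name == "single_separator":
        return CohortSpec(
            group_sizes=(80, 80, 40),
            separator_marker="csf_pT217_T217",
            informative={"amyloid": ("csf_pT217_T217",)},
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}")


PRESETS = ("entire_cohort", "preclinical_only", "impaired_only",
           "null_panel", "single_separator")


def generate_demographics(group_sizes, rng: np.random.Generator,
                          params: dict | None = None) -> dict:
    """Draw per-subject demographics from the reference group summaries."""
    if params is None:
        params = load_reference_demographics()
    ref_n = np.asarray(params["n"], dtype=float)
    out = {k: [] for k in ("age", "education", "sex", "apoe4_carrier", "race_nhw")}
    for g, n in enumerate(group_sizes):
        out["age"].append(rng.normal(params["age_mean"][g], params["age_sd"][g], n))
        out["education"].append(
            rng.normal(params["education_mean"][g], params["education_sd"][g], n))
        p_f = params["sex_female"][g] / ref_n[g]
        out["sex"].append(np.where(rng.random(n) < p_f, "F", "M"))
        out["apoe4_carrier"].append(rng.random(n) < params["apoe4_carrier"][g] / ref_n[g])
        out["race_nhw"].append(rng.random(n) < params["race_nhw"][g] / ref_n[g])
    return {k: np.concatenate(v) if len(v) else np.array([]) for k, v in out.items()}


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate one seeded cohort from a recipe.

    Group sizes are exact.  Missingness is applied per marker (MCAR), then a
    ``sparse_subject_rate`` fraction of subjects is forced past the 50%
    missingness mark so the exclusion rule is exercised.  The Centiloid label
    is generated consistently with the group definition around the 16.4
    threshold.
    """
    rng = spawn_rng(spec.seed, 11)
    sizes = spec.group_sizes
    n = int(sum(sizes))
    if n == 0:
        raise ValueError("empty cohort")
    group = np.concatenate([np.full(k, g) for g, k in enumerate(sizes)]).astype(int)
    p = len(MARKERS)
    midx = {m: j for j, m in enumerate(MARKERS)}

    values = np.zeros((n, p))
    loading_sq = np.zeros(p)
    for bname, loadings in spec.blocks.items():
        shift = np.asarray(spec.factor_shift.get(bname, np.zeros(3)), dtype=float)
        if bname == "neurodegeneration":
            # keep the impairment axis uncorrelated with the amyloid axis
            core_shift = np.asarray(
                spec.factor_shift.get("core_pathology", np.zeros(3)), dtype=float)
            if np.any(core_shift) and np.any(shift):
                scale = np.linalg.norm(shift)
                shift = _weighted_orthogonalize(shift, core_shift, sizes)
                if np.linalg.norm(shift) > 0:
                    shift = shift * scale / np.linalg.norm(shift)
        f = rng.standard_normal(n) + shift[group]
        for m, l in loadings.items():
            j = midx[m]
            values[:, j] += l * f
            loading_sq[j] += l * l
    if (loading_sq > 1.0 + 1e-12).any():
        raise ValueError("total squared loading exceeds 1 for some marker")

    eps = rng.standard_normal((n, p))
    values += np.sqrt(np.clip(1.0 - loading_sq, 0.0, None)) * spec.noise_sd * eps
    for m, effect in spec.direct_effect.items():
        values[:, midx[m]] += np.asarray(effect, dtype=float)[group]

    # amyloid-positivity label, consistent with the group definition
    centiloid = np.empty(n)
    a_neg = group == 0
    centiloid[a_neg] = rng.uniform(-10.0, CENTILOID_THRESHOLD - 0.1, a_neg.sum())
    centiloid[~a_neg] = CENTILOID_THRESHOLD + rng.exponential(30.0, (~a_neg).sum())

    if spec.separator_marker is not None:
        values[:, midx[spec.separator_marker]] = (~a_neg).astype(float)

    for m in _EXP_MARKERS:
        values[:, midx[m]] = np.exp(values[:, midx[m]])

    mask = rng.random((n, p)) < spec.missing_rate
    n_sparse = int(round(spec.sparse_subject_rate * n))
    if n_sparse:
        sparse_idx = rng.choice(n, size=n_sparse, replace=False)
        for i in sparse_idx:
            mask[i, rng.choice(p, size=15, replace=False)] = True

    demo = generate_demographics(sizes, rng)
    labels = CohortLabels(
        cdr_group=np.where(group == 2, "CDRgt0", "CDR0"),
        centiloid=centiloid,
        age=demo["age"],
        sex=demo["sex"],
        apoe4_carrier=demo["apoe4_carrier"],
        education=demo["education"],
        race_nhw=demo["race_nhw"],
    )
    panel = BiomarkerPanel(
        [f"S{i:04d}" for i in range(n)],
        np.where(mask, np.nan, values),
        mask,
        list(MARKERS),
    )
    truth = {
        "blocks": spec.block_of,
        "informative": dict(spec.informative),
        "group": group,
    }
    return SyntheticCohort(panel, labels, truth)
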