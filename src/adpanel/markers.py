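"""Canonical registry of the 27-marker Alzheimer's disease biomarker panel.

The panel spans amyloid and tau PET, CSF immunoassay ratios normalised to
Abeta40, ten mass-spectrometry tau phosphorylation-occupancy ratios, CSF and
plasma neurofilament light, an MRI cortical-thickness signature, CSF markers
of synaptic/neuronal dysfunction and inflammation, two cognitive scores and a
polygenic risk score.  The registry is shipped as a versioned text resource
(``data/markers.txt``); order is canonical and stable.
"""

from __future__ import annotations

from importlib import resources

__all__ = [
    "MARKERS",
    "LOG_MARKERS",
    "CORE_PATHOLOGY",
    "NEURODEGENERATION",
    "AT8_SITES",
    "DYSFUNCTION_INFLAMMATION",
    "UNASSIGNED",
    "LABEL_COLUMNS",
]


def _load_registry() -> tuple[str, ...]:
    text = resources.files("adpanel.data").joinpath("markers.txt").read_text()
    names = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if len(names) != len(set(names)):
        raise ValueError("marker registry contains duplicates")
    return tuple(names)


MARKERS: tuple[str, ...] = _load_registry()

# Markers whose raw distributions are right-skewed and are log transformed
# before z-scoring (neurofilament light in both fluids).
LOG_MARKERS: tuple[str, ...] = ("csf_nfl", "plasma_nfl")

# Field-standard grouping of the panel into four biological themes; the
# synthetic generator plants correlation blocks with these memberships.
CORE_PATHOLOGY: tuple[str, ...] = (
    "amyloid_pet_centiloid",
    "tau_pet_suvr",
    "abeta42_40_plasma",
    "csf_abeta42_40",
    "csf_ptau_abeta40",
    "csf_ttau_abeta40",
    "csf_pT111_T111",
    "csf_pT153_T153",
    "csf_pT181_T181",
    "csf_pS208_S208",
    "csf_pT217_T217",
    "csf_pT231_T231",
    "cdr_sb",
)
NEURODEGENERATION: tuple[str, ...] = ("csf_nfl", "plasma_nfl", "mri_cortical_signature")
AT8_SITES: tuple[str, ...] = ("csf_pS199_S199", "csf_pS202_S202", "csf_pT205_T205")
DYSFUNCTION_INFLAMMATION: tuple[str, ...] = (
    "csf_ng",
    "csf_snap25",
    "csf_vilip1",
    "csf_ykl40",
    "csf_strem2",
)
UNASSIGNED: tuple[str, ...] = ("csf_pT175_T175", "mmse", "prs")

LABEL_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "cdr_group",
    "centiloid",
    "age",
    "sex",
    "apoe4_carrier",
    "education",
    "race_nhw",
)
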