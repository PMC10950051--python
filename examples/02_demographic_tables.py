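"""Recompute the demographic group-comparison tests of the reference cohort.

Categorical rows (sex, race, APOE e4) are compared across the three clinical
groups with Pearson chi-square tests on the published counts; continuous rows
(age, education) with one-way ANOVAs reconstructed from the published
means/SDs/ns — no subject-level data needed.
"""

from adpanel import demographic_tests
from adpanel.stats import load_reference_demographics

summary = load_reference_demographics()
print("groups:", ", ".join(summary["groups"]), "| n =", summary["n"])
for name, p in demographic_tests(summary).items():
    flag = "  (differs across groups)" if p < 0.05 else ""
    print(f"{name:16s} p = {p:.3f}{flag}")

# Age and APOE e4 carriage differ between groups (the amyloid-positive and
# impaired groups are older and carry e4 more often); sex, race and
# education do not.
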