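"""Simulate a 56-implant cohort with the study's factor layout.

Generates the unbalanced three-factor design (registration method 21/35,
jaw 23/33, guide support 28/20/8), with the dental-surface group registered
on artifact-inflated landmarks, and prints group means of the lateral apex
deviation.
"""

from guidedev import ScenarioConfig, generate_cohort, table_design

cohort = generate_cohort(table_design(), ScenarioConfig(seed=11))
print(f"cohort: {len(cohort)} implants")
for factor in ("registration_method", "jaw", "guide_support"):
    means = cohort.groupby(factor)["lateral_apex_mm"].agg(["count", "mean", "std"])
    print(f"\nlateral apex deviation by {factor}:")
    print(means.round(3).to_string())
# The dental-surface group mean exceeds the fiducial-marker group mean:
# anisotropic streak-artifact noise degrades the surface registration, and
# the effect size is calibrated to the ~0.3 mm contrast reported in vivo.
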