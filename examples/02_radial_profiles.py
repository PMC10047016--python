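"""Radial-distribution profiles of benign vs malignant lesions.

Computes the core imaging feature: the area-normalized histogram of
intensity over concentric bands around each finding's center of mass
(computed from the contour-masked density image), then averages the
profiles per class.  Malignant lesions put more of their mass in the
innermost bands.
"""

import numpy as np

from cemradial import CohortConfig, case_histograms, exclusion_filter, generate_cohort
from cemradial.radial import class_average_profile

cohort = generate_cohort(CohortConfig(n_findings=80, image_size=128, seed=5))
cases, labels, _ = exclusion_filter(cohort.cases, "malignant_vs_benign")

n_bands = 16
hists = [case_histograms(c, n_bands)["density"] for c in cases]
benign_mean, malignant_mean = class_average_profile(hists, labels)

print(f"{'band':>4} {'benign':>9} {'malignant':>10}")
for b in range(6):
    print(f"{b:>4} {benign_mean[b]:>9.4f} {malignant_mean[b]:>10.4f}")
print("...")
central_ratio = malignant_mean[0] / benign_mean[0]
print(
    f"\nband-0 (innermost annulus) mass: malignant/benign = {central_ratio:.2f}x\n"
    "Values are per-band masses normalized to unit sum per case, so a\n"
    "ratio above 1 in the first bands means malignant findings concentrate\n"
    "their density closer to the center of mass."
)
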