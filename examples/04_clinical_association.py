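"""Immunoreactivity scoring and exact-test association.

Builds a 47-patient cohort whose 2x2 margins match a published MCT1
immunohistochemistry table, derives each patient's immunoreactivity
score (intensity 0-3 times percent-positive grade 1-3, high iff >= 4),
and tests each clinicopathological feature with a two-sided Fisher's
exact test.
"""

import scmetland as sm
from scmetland.clinical import associate, association_frame

# (yes_high, yes_low, no_high, no_low) against the MCT1 expression class
counts = {
    "sex_male": (19, 3, 17, 8),
    "age_le_2y": (16, 6, 20, 5),
    "uveal_invasion": (12, 2, 24, 9),
    "optic_nerve_invasion": (25, 2, 11, 9),
    "anterior_chamber_invasion": (1, 2, 35, 9),
}
cohort = sm.generate_ihc_cohort(counts, seed=0)
print(f"cohort: {len(cohort)} patients, {cohort.n_high} high / {cohort.n_low} low "
      f"({100 * cohort.n_high / len(cohort):.1f}% / {100 * cohort.n_low / len(cohort):.1f}%)")

results = associate(cohort, alpha=0.05)
print()
print(association_frame(results).to_string(index=False))
print()
print("Only post-laminar optic nerve invasion associates with high MCT1")
print("expression (p = 0.0044); the other features do not reach alpha = 0.05.")
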