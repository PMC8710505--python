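"""Convert observed 2-year transition frequencies to annual probabilities.

The trial observed each patient's blood-pressure level at baseline and
after two years of bi-monthly follow-up.  The whole-cohort frequency of
each level-to-level move (the "study probability") is converted to a
1-year transition probability through a constant-hazard assumption:
rate = -(1/t) ln(1 - p), annual p = 1 - exp(-rate).
"""

from htncea import (
    StudyWindow,
    annual_transition_probabilities,
    load_packaged_study_counts,
    study_probability,
)
from htncea.states import L1, PREHYPERTENSION

counts = load_packaged_study_counts()
print(f"analyzable cohort: {counts.total_n} patients")

p = study_probability(counts, L1, PREHYPERTENSION)
print(f"study probability L1 -> prehypertension: {counts.count(L1, PREHYPERTENSION)}"
      f"/{counts.total_n} = {p:.4f}")

annual = annual_transition_probabilities(counts, StudyWindow(2.0))
print("\nannual transition probabilities (trial-derived rows):")
for (o, d), v in sorted(annual.items()):
    if v > 0:
        print(f"  {o:>15s} -> {d:<15s} {v:.4f}")
print("\nEach value is the probability of making the move within one model"
      "\ncycle (one year) under the constant-hazard assumption.")
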