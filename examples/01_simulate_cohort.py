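"""Simulate a synthetic TSPO blocking cohort and inspect its ground truth.

Each subject gets a baseline and a post-blocking scan: arterial blood
series, a true input function, and one TAC per brain region generated from
known 2TCM parameters that share a single V_ND = K1/k2 across regions.
"""

from petblock import CohortConfig, simulate_subject

config = CohortConfig(n_subjects=7, seed=42)
subject = simulate_subject(config, 0)

print(f"{subject.subject_id}: weight {subject.weight_kg:.0f} kg, "
      f"true occupancy {100 * subject.occupancy:.0f}%, true V_ND {subject.true_vnd} mL/cm3")
print(f"baseline injected dose {subject.baseline.injected_dose_mbq:.0f} MBq, "
      f"blocking {subject.blocking.injected_dose_mbq:.0f} MBq")
print(f"{'region':<15} {'V_T base':>9} {'V_T block':>9}  (mL/cm3, truth)")
for region in config.regions:
    print(f"{region:<15} {subject.baseline.true_vt[region]:>9.2f} "
          f"{subject.blocking.true_vt[region]:>9.2f}")

# the blocking V_T drop is proportional to the specific binding:
# V_T,block = V_ND + (1 - occupancy) * (V_T,base - V_ND) for every region.
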