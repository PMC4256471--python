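"""Simulate a small eQTL study with planted truth and write it to disk.

One cis-eQTL (snp1 -> probe1, R2 = 0.3) and one trans-eQTL on another
chromosome mediated by that cis transcript (probe1 -> probe2, beta = 0.6).
"""

from cismed import CisEffect, StudyConfig, TransEffect, simulate_study
from cismed.io import write_study

config = StudyConfig(
    n_samples=400,
    n_variants=40,
    n_probes=20,
    seed=11,
    planted_cis=(CisEffect("snp1", "probe1", 0.3),),
    planted_trans=(TransEffect("snp1", "probe2", "mediated", 0.6, "probe1"),),
)
study = simulate_study(config)
write_study(study, "example_study")

print("planted truth:")
print(study.truth.to_string(index=False))
print(f"\ngenotypes: {study.genotypes.dosages.shape[0]} samples x "
      f"{study.genotypes.dosages.shape[1]} variants")
print(f"expression: {study.expression.values.shape[1]} probes")
print("\nEach truth row is one planted effect; the 'mediated' row means the")
print("trans association exists only through the probe1 transcript.")
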