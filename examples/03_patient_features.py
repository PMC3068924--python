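"""Turn expression profiles into per-patient signature features.

Simulates a cohort in which good-outcome patients keep hub-neighbor
co-expression intact while poor-outcome patients lose it, then prints
the group-level discrimination score of each planted hub and the first
patients' feature values (mean absolute rank-scaled expression
difference between hub and neighbors, always in [0, 1]).
"""

from domainsig import (
    SimConfig,
    discrimination_score,
    patient_features,
    simulate_bundle,
    simulate_cohort,
)

cfg = SimConfig(seed=3, n_patients_good=30, n_patients_poor=20)
bundle, truth = simulate_bundle(cfg)
cohort = simulate_cohort(bundle, truth, cfg)
hubs = sorted(truth.planted_signatures)

print("group-level discrimination (mean |r_good - r_poor| / 2 over neighbors):")
for hub in hubs:
    ds = discrimination_score(hub, bundle, cohort)
    print(f"  {hub}: {ds.score:.3f} over {ds.n_neighbors} neighbors")

fm = patient_features(hubs, bundle, cohort)
print()
print("per-patient features (3 good and 3 poor patients):")
print("patient   label " + " ".join(f"{h:>7}" for h in fm.signatures))
for i, p in enumerate(fm.patients[:3] + fm.patients[-3:]):
    row = fm.values[fm.patients.index(p)]
    print(f"{p:<9} {cohort.labels[p]:<5} "
          + " ".join(f"{v:7.3f}" for v in row))

print()
print("Good patients co-express hubs with their neighbors, so their rank")
print("differences stay small; poor patients' neighbors decouple and the")
print("features grow - this contrast is what the classifier learns.")
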