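"""Train the 20-bin naïve Bayes classifier and inspect its predictions.

Fits the classifier on a simulated cohort's features, prints the class
priors, and shows MAP predictions with posterior probabilities for a
few held-out-style patients.
"""

from domainsig import (
    SimConfig,
    fit,
    patient_features,
    predict,
    simulate_bundle,
    simulate_cohort,
)

cfg = SimConfig(seed=11, n_patients_good=30, n_patients_poor=20)
bundle, truth = simulate_bundle(cfg)
cohort = simulate_cohort(bundle, truth, cfg)
fm = patient_features(sorted(truth.planted_signatures), bundle, cohort)

model = fit(fm, cohort.labels, alpha=1.0)
print(f"priors: P(good) = {model.prior('good'):.2f}, "
      f"P(poor) = {model.prior('poor'):.2f} (class frequencies)")
print()
print("patient    truth  predicted  P(good | x)")
for patient in fm.patients[:4] + fm.patients[-4:]:
    pred = predict(model, fm.row(patient), patient=patient)
    print(f"{patient:<10} {cohort.labels[patient]:<6} {pred.predicted:<10}"
          f" {pred.posterior_good:.3f}")

print()
print("Each feature is discretized into 20 equal bins on [0, 1]; the")
print("posterior combines per-signature bin likelihoods with the priors")
print("in log space (alpha = 1 Laplace smoothing avoids zero bins).")
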