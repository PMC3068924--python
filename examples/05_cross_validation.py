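"""Estimate outcome-prediction performance by nested cross-validation.

Runs the 5-fold protocol (inner LOOCV tunes the signature threshold c,
outer folds estimate performance) on a planted-signal cohort and on a
matched null cohort where good and poor patients are exchangeable.
"""

from domainsig import SimConfig, nested_cv, simulate_bundle, simulate_cohort


def run(effect_delta, label):
    cfg = SimConfig(seed=0, effect_delta=effect_delta)
    bundle, truth = simulate_bundle(cfg)
    cohort = simulate_cohort(bundle, truth, cfg)
    res = nested_cv(bundle, cohort, seed=0)
    m = res.pooled
    print(f"{label}:")
    print(f"  chosen c per fold : {[f.chosen_c for f in res.folds]}")
    print(f"  pooled accuracy   : {m.accuracy:.3f}  "
          f"(tp={m.tp} fp={m.fp} tn={m.tn} fn={m.fn})")
    print(f"  sensitivity/specificity : {m.sensitivity:.3f} / {m.specificity:.3f}")
    print(f"  AUC               : {res.auc:.3f}")


run(1.0, "planted signal (delta = 1, neighbors decouple in poor patients)")
print()
run(0.0, "null cohort (delta = 0, classes exchangeable)")
print()
print("With a planted signal the pooled accuracy and AUC approach 1; on the")
print("null cohort accuracy falls back to the majority-class rate (0.6) and")
print("AUC to about 0.5, showing the protocol does not leak test labels.")
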