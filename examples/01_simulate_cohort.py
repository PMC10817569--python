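"""Generate a synthetic patient cohort and summarize it.

The generator mimics a small emergency-department cohort: sparse binary
clinical features, an imbalanced 30-day adverse-event outcome, missing
values, constant columns, and planted conjunctive effects linking feature
combinations to outcome probability.
"""

from ruleboost import Literal, PlantedRule, SynthConfig, describe_cohort, generate

cfg = SynthConfig(
    planted_rules=(
        PlantedRule((Literal("f23", 1),), 1.2),  # one risk factor
        PlantedRule((Literal("f30", 1), Literal("f33", 1)), 1.6),  # one risky combination
    ),
    seed=7,
)
cohort, truth = generate(cfg)

print(f"cohort: {cohort.n_patients} patients x {len(cohort.feature_names)} features")
print(f"events: {int(cohort.outcome.sum())} ({100 * cohort.outcome.mean():.1f}%)")
print(f"missing cells: {cohort.n_missing}")
print(f"calibrated intercept: {truth.intercept:.3f} (log-odds of the baseline risk)")
print()
print(describe_cohort(cohort).tail(6).to_string(index=False))
print()
print("The last row is the outcome; the generator targets ~17% prevalence,")
print("and each planted rule raises the event odds of the patients it matches.")
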