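"""Generate a synthetic ED-visit cohort and inspect what was planted.

The generator matches the published marginal summaries (truncated-normal
vitals, 0.66% LAMA prevalence) and plants a configurable log-odds signal;
here higher ESI (lower acuity) raises the odds of leaving against medical
advice while longer waits lower them.
"""

from edlama import GeneratorConfig, degrade, generate_visits

cfg = GeneratorConfig(n=20_000, prevalence=0.0066, seed=7)
table, truth = generate_visits(cfg)

lama = table["disposition"].eq("LAMA").sum()
print(f"{len(table)} visits, {lama} LAMA ({100 * lama / len(table):.2f}%; target 0.66%)")
print(table[["age", "esi", "o2_saturation", "waiting_time"]].describe().loc[["mean", "std", "min", "max"]].round(2))
print(f"planted effects (log-odds per sd): {truth['effect_weights']}")
print(f"Bayes-optimal AUC of the planted mechanism: {truth['bayes_auc']:.3f}")
print("any classifier fit to this cohort is bounded by that Bayes AUC")

# class-dependent missingness, emulating heavier BMI missingness among LAMA
degraded = degrade(table, {"bmi": 0.1}, seed=7, class_rates={"bmi": {"LAMA": 0.3, "SAT": 0.1}})
rates = degraded.groupby("disposition")["bmi"].apply(lambda s: s.isna().mean())
print("realized BMI missingness by class:", rates.round(3).to_dict())
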