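"""Generate a seeded synthetic cohort and summarize it.

Draws 91 virtual subjects (51:40 male:female odds) whose hook angles
follow a Normal(122.55, 8.20) truncated to [97.20, 139.31] degrees,
each measured three times with 0.5-degree noise and averaged."""

import carpalcone as cc

config = cc.CohortConfig(seed=1)
cohort = cc.generate_cohort(config)
cc.cohort_to_csv(cohort, "cohort.csv")

angles = [s.angle_mean for s in cohort]
summary = cc.descriptive_summary(angles)
males = sum(s.sex == "male" for s in cohort)
print(f"Simulated n={len(cohort)} subjects ({males} male, "
      f"{len(cohort) - males} female), written to cohort.csv")
print(f"Hook angle: mean {summary.mean:.2f} deg, SD {summary.sd:.2f}, "
      f"range [{summary.min:.2f}, {summary.max:.2f}]")
print("The sample mean/SD track the configured truncated-normal "
      "parameters (122.55 +- 8.20 deg); repeats with the same seed are "
      "byte-identical.")
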