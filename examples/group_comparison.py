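"""Full cohort analysis: maps, parameters and three-group statistics.

Generates a reduced cohort with planted group effects, runs the whole
pipeline, and prints the MANOVA (Wilks' Lambda) and per-class post-hoc ANOVA
for coverage, the parameter on which the planted effects are strongest.
"""

import warnings

import eegmicrostates as em

cfg = em.GeneratorConfig(
    group_sizes={"seizure": 5, "seizure_free": 5, "control": 5},
    epochs_per_subject=10,
)
cohort = em.make_cohort(cfg, seed=21)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    res = em.analyze_cohort(cohort.recordings, seed=22, min_epochs=10)

print("mean GEV per group:",
      {g: round(v, 3) for g, v in res.group_gev().items()})

block = res.stats["coverage"]
m = block["manova"]
print(f"\ncoverage MANOVA: Wilks' Lambda = {m.wilks_lambda:.3f}, "
      f"F({m.df[0]:.0f}, {m.df[1]:.0f}) = {m.f_stat:.2f}, "
      f"p = {m.p_value:.4g}, eta^2 = {m.eta_squared:.3f}")

alpha = block["alpha_bonferroni"]
print(f"post-hoc one-way ANOVAs (Bonferroni alpha = {alpha:.6f}):")
for cls, ph in sorted(block["posthoc"].items()):
    flag = "significant" if ph.significant else "n.s."
    print(f"  class {cls}: F({ph.df[0]},{ph.df[1]}) = {ph.f_stat:6.2f}, "
          f"p = {ph.p_value:.4g}  [{flag}]")
print(
    "\nClasses A and C carry the planted effects (more class A, less class C "
    "in the seizure group); B and D were left untouched and should stay "
    "non-significant. At this reduced size (5 subjects per group, 10 epochs) "
    "a planted effect can miss the strict Bonferroni threshold - the full "
    "10/12/17-subject design detects both reliably."
)
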