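"""Backfit template maps to every sample and compute the temporal parameters.

Labels each sample of a subject's epochs with its best-matching microstate
class, smooths out runs shorter than 20 ms, and prints Duration, Frequency
and Coverage per class, verifying the exact bookkeeping identity
coverage = frequency x duration.
"""

import warnings

import eegmicrostates as em

cfg = em.GeneratorConfig(group_sizes={"seizure": 1}, epochs_per_subject=10)
templates = em.make_templates(cfg.n_channels, cfg.k)
profile = em.default_group_profiles(cfg)["seizure"]
rec, labels = em.synthesize_subject(cfg, templates, profile, "s01", "seizure",
                                    rng=3)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    es = em.preprocess_recording(rec)
ls = em.smooth_labels(em.backfit(es, templates), min_duration_ms=20.0)
table = em.compute_parameters(ls, "s01", "seizure")

print(table[["class", "duration_ms", "frequency_per_s", "coverage_fraction"]]
      .round(3).to_string(index=False))

row = table.iloc[0]
product = row.frequency_per_s * row.duration_ms / 1000.0
print(f"\nidentity check, class {row['class']}: "
      f"{row.frequency_per_s:.3f}/s x {row.duration_ms:.1f} ms = "
      f"{product:.4f} = coverage {row.coverage_fraction:.4f}")

truth = em.parameters_from_labels(labels, cfg.srate, cfg.k)
print("\nplanted durations (ms):", truth.duration_ms.round(1).tolist())
print(
    "Class C runs are planted short in the seizure profile; the recovered "
    "Duration column reproduces that within a few percent."
)
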