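"""Cluster GFP-peak topographies into the four canonical microstate maps.

Fits the polarity-invariant modified K-means to one subject's GFP-peak maps,
orders the result into the canonical A-D classes, and reports the global
explained variance and the match to the planted ground-truth templates.
"""

import warnings

import numpy as np

import eegmicrostates as em
from eegmicrostates.clustering import spatial_correlation
from eegmicrostates.gfp import peak_topographies

cfg = em.GeneratorConfig(group_sizes={"control": 1}, epochs_per_subject=10)
templates = em.make_templates(cfg.n_channels, cfg.k)
profile = em.null_group_profiles(cfg)["control"]
rec, _ = em.synthesize_subject(cfg, templates, profile, "s01", "control", rng=2)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    es = em.preprocess_recording(rec)
g = em.find_gfp_peaks(em.compute_gfp(es))
peaks = peak_topographies(es, g)
print(f"clustering {peaks.shape[0]} peak topographies "
      f"({peaks.shape[1]} channels) into K=4 maps")

maps = em.modified_kmeans(peaks, k=4, n_restarts=20, seed=5)
maps = em.order_maps_canonical(maps)
print(f"GEV on peaks: {maps.gev:.3f} "
      "(fraction of GFP-weighted topographic variance explained)")

r = np.abs(np.diag(spatial_correlation(maps.maps, templates.maps)))
for label, corr in zip(maps.labels, r):
    print(f"  class {label}: |spatial correlation| with planted template = "
          f"{corr:.3f}")
print(
    "\n|r| near 1 for every class means the clustering recovered the planted "
    "topographies; GEV near the study's 0.73-0.75 would be typical for real "
    "EEG, higher here because synthetic noise is milder than biology."
)
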