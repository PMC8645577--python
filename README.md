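# eegmicrostates

Resting-state EEG microstate analysis for case-control studies: preprocessing,
GFP-peak topographic clustering, backfitting, the Duration / Frequency /
Coverage parameters, and three-group statistics — plus a synthetic multichannel
EEG generator with full ground truth, so the whole pipeline is verifiable by
parameter recovery without any clinical data.

Multichannel EEG alternates among a small set of quasi-stable scalp
topographies ("microstates", typically labeled A–D) that each last tens of
milliseconds. Case-control studies compare how long each class lasts
(**Duration**, ms), how often it occurs (**Frequency**, segments/s) and what
fraction of time it occupies (**Coverage**) between patient and control
groups. This package implements that analysis as a tested Python library for
64-channel resting-state recordings (EDF or delimited matrices), aimed at the
three-group design (patients with recent seizures, seizure-free patients,
healthy controls) but generic over groups, channel counts and K.

## Method

- **GFP and peaks.** With average-referenced potentials `v(t)` over `C`
  channels, the global field power is the spatial standard deviation
  `GFP(t) = sqrt((1/C) Σᵢ (vᵢ(t) − v̄(t))²)`. Clustering uses only the
  topographies at strict local maxima of GFP, where topographic SNR is
  highest.
- **Modified K-means.** Peak maps are clustered into K = 4 unit-norm template
  topographies. Assignment maximizes squared spatial correlation — a map and
  its polarity flip are equivalent — and each template is updated as the first
  principal component of its member maps. The objective is the global
  explained variance `GEV = Σₜ GFP²ₜ r²ₜ / Σₜ GFP²ₜ`, with `rₜ` the spatial
  correlation to the assigned template; best of 20 random restarts is kept.
  Subject-level maps are pooled and re-clustered into cohort/group maps
  (two-level aggregation), then ordered to the canonical classes A–D by
  exhaustive permutation matching against built-in reference topographies.
- **Backfitting and parameters.** Every sample is labeled with its
  best-matching template (polarity-invariant); runs shorter than 20 ms are
  smoothed into their neighbors. Per subject and class, Coverage =
  Frequency × mean Duration holds exactly by construction.
- **Statistics.** Per parameter, the four class values per subject form a
  profile; groups are compared by one-way MANOVA on the class-profile
  differences (Wilks' Λ = det(E)/det(E+H), Rao's F, multivariate
  η² = 1 − Λ^(1/s)), followed by per-class one-way ANOVAs with
  pooled-variance pairwise t contrasts at the Bonferroni level
  α = 0.05/(3·4) = 0.004167.
- **Synthetic cohorts.** A semi-Markov generator plants the ground truth:
  dwell times are per-class gamma variables (means 60–120 ms), the next class
  is drawn from entry weights with no self-transitions, topographies follow
  an alpha-band carrier, and spatially smoothed noise is added at SNR 4.
  Planted group effects reproduce the coverage separations reported for this
  design (more class A, less class C in the seizure group).

## Worked example

`examples/` contains one short script per capability. Clustering one
synthetic subject (`python examples/cluster_microstates.py`):

```
clustering 480 peak topographies (64 channels) into K=4 maps
GEV on peaks: 0.989 (fraction of GFP-weighted topographic variance explained)
  class A: |spatial correlation| with planted template = 1.000
  class B: |spatial correlation| with planted template = 1.000
  class C: |spatial correlation| with planted template = 1.000
  class D: |spatial correlation| with planted template = 1.000
```

The four planted topographies are recovered exactly (|r| = 1.000) and the
templates explain 98.9% of the GFP-weighted variance at the peaks. A
three-group comparison on a reduced cohort
(`python examples/group_comparison.py`):

```
coverage MANOVA: Wilks' Lambda = 0.149, F(6, 20) = 5.31, p = 0.002027, eta^2 = 0.614
post-hoc one-way ANOVAs (Bonferroni alpha = 0.004167):
  class A: F(2,12) =   5.62, p = 0.01895  [n.s.]
  class B: F(2,12) =   2.02, p = 0.1751  [n.s.]
  class C: F(2,12) =  18.83, p = 0.0001993  [significant]
  class D: F(2,12) =   1.93, p = 0.1883  [n.s.]
```

The planted class-C coverage deficit is detected at the Bonferroni threshold;
the untouched classes B and D are not. The full-size design (10/12/17
subjects, 30 epochs each) detects both planted effects (A and C) reliably.

Analyzing your own data is three calls:

```python
import eegmicrostates as em

manifest = em.load_manifest("manifest.csv")  # subject_id, group, path
recordings = [em.read_recording(r["path"], r) for _, r in manifest.iterrows()]
result = em.analyze_cohort(recordings, k=4, seed=0)
print(result.parameter_table)     # subject x class Duration/Frequency/Coverage
print(result.stats["coverage"])   # MANOVA + post-hoc per class
```

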