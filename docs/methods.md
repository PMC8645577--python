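# Methods

## Model and procedure

The package treats multichannel resting-state EEG as a sequence of discrete
topographic states. At any time `t` the average-referenced scalp potential
`v(t) ∈ R^C` is modeled as `a(t) · m_k + ε(t)`: a class template `m_k` (unit
norm, zero channel mean) scaled by a fluctuating field strength `a(t)` plus
spatial noise. Analysis proceeds in the standard stages:

1. **Preprocessing.** Zero-phase Butterworth band-pass (4th order per pass,
   applied forward and backward), polyphase downsampling with anti-aliasing,
   segmentation into non-overlapping fixed-length epochs (trailing remainder
   discarded; epoch k spans samples `[kL, (k+1)L)`), amplitude-based epoch
   rejection (an epoch whose peak |amplitude| reaches the threshold is
   removed; the comparison is ≥), and average re-referencing. The band-pass
   runs on the continuous signal before downsampling; for pass-bands far
   below the lower Nyquist the two orders agree within tolerance (asserted by
   a property test), so the choice is one of convenience. Defaults: 1–40 Hz,
   500 Hz, 2-s epochs, 100 µV, minimum 30 retained epochs (a warning, not an
   error, unless zero survive). A pluggable epoch keep/drop hook accepts
   externally determined artifact decisions (e.g. manually marked discharges
   or ICA-cleaned selections); no automatic ICA is attempted because
   component selection is not reproducible from a written description.
2. **GFP peaks.** GFP is the spatial standard deviation across channels;
   peaks are strict interior local maxima, optionally thinned by a minimum
   separation (keep the larger of a violating pair). GFP is well defined as a
   reference-independent quantity only under the average reference, which is
   why re-referencing precedes it; non-average-referenced input triggers a
   warning and an implicit re-reference.
3. **Modified K-means.** Peak topographies are zero-meaned and unit-normed;
   assignment maximizes |spatial correlation| (polarity ignored — the
   convention for spontaneous EEG, configurable off), and the template update
   is the dominant eigenvector of the members' scatter matrix, since a
   polarity-invariant mean is ill-defined. The objective, GEV, is
   non-decreasing over iterations; convergence is a relative GEV change below
   1e-6 or 100 iterations, best of 20 restarts by GEV. Empty clusters are
   re-seeded from the worst-fit map. Ties in assignment go to the lower class
   index. Results are deterministic for a fixed seed.
4. **Aggregation and canonical ordering.** Each subject contributes its K
   templates (equal weight per subject regardless of epoch count); pooling
   and re-clustering them yields cohort- or group-level maps. Maps are
   ordered to classes A–D by maximizing total |r| against built-in reference
   topographies over all K! permutations. The references are idealized
   analytic patterns on the standard 64-channel layout: A a left–right
   oriented field tilted toward the front, B its mirror image (the tilt
   coefficient is solved from the layout so A ⊥ B), C an anterior–posterior
   gradient, D a fronto-central radial maximum decorrelated from C to
   |r| ≤ 0.3; pairwise |r| ≤ 0.5. Users may substitute their own reference
   set.
5. **Backfitting and smoothing.** Every sample is assigned to the template
   with maximal |r|; samples below a correlation floor (default 0 = always
   assign) are left unlabeled. Runs shorter than 20 ms are resolved shortest
   first: each sample of the offending run is re-assigned to whichever
   flanking run's template correlates better at that sample, recomputing runs
   after each step. The shortest-first order lets brief misassignment islands
   heal back into their parent run before the parent is touched — processing
   all short runs simultaneously measurably biases Duration upward. Because
   the samplewise rule admits flip-flop fixed points, any residual zone of
   consecutive short runs is finally relabeled as the optimal contiguous
   two-segment split between its flanking classes (split point maximizes
   summed |r|), preserving at most one transition per zone. Runs never cross
   epoch boundaries, and epoch-edge runs are exempt from the duration floor
   (they are truncations, not observations of a full dwell).
6. **Parameters.** Per subject and class: Duration = mean run length (ms),
   Frequency = runs per second of analyzed time, Coverage = fraction of
   analyzed samples. The denominator is always all samples, so per-class
   coverages plus the unlabeled fraction sum to one and
   Coverage = Frequency × Duration holds exactly per subject and class.
   (The identity does not survive group averaging — the product of means is
   not the mean of products — so group tables never assert it.) Runs
   truncated by epoch edges are counted; discarding them would bias Frequency
   down. A class that never occurs has missing Duration, zero Frequency and
   zero Coverage.
7. **Group statistics.** For each parameter the per-class values of a subject
   form a multivariate profile. Groups are compared with a one-way MANOVA via
   Wilks' Λ = det(E)/det(E+H) (within- and between-group SSCP), Rao's F
   approximation, and multivariate η² = 1 − Λ^(1/s) with s = min(p, k−1).
   `compare_groups` tests the K−1 successive class-profile differences — the
   multivariate group × class interaction of the mixed design — because raw
   coverage profiles are compositional (they sum to one per subject) and
   their raw SSCP is singular by construction; the raw-profile response
   remains available for non-compositional parameters. Post-hoc per-class
   one-way ANOVAs use df (k−1, N−k); pairwise contrasts are pooled-variance t
   tests (df = N−k) reported unadjusted and judged against
   α = family α / (groups × classes) = 0.05/12 ≈ 0.004167. Normality or
   homogeneity diagnostics never gate the analysis. Subjects missing a value
   (class absent) are excluded listwise per test. A permutation mode
   (label shuffling) is available as a check on the parametric p.

## Synthetic cohorts and what they do (not) show

The generator emulates the recording design the pipeline targets: 64
channels at 1,000 Hz, three groups of 10/12/17 subjects, 30 two-second
epochs each. Label dynamics are semi-Markov: dwell times are gamma(shape 4,
mean per class) — durations at 500 Hz are far from geometric, so an explicit
duration law is required for controllable ground truth — and the next class
is drawn proportionally to per-class entry weights with self-transitions
excluded. Default mean durations are (75, 78, 88, 82) ms, inside the 60–120
ms regime expected of resting microstates. The signal is
`sin(2π·10·t + φ) · m_label(t)`: the GFP of the pure signal is the rectified
alpha envelope, and the signed carrier is DC-free, so the 1 Hz high-pass
passes it undistorted (a strictly positive envelope would lose most of its
energy to the high-pass; polarity-invariant analysis cannot tell the two
apart). Noise is spatially smoothed white noise (Gaussian mixing over
electrode distances, scale 0.35 of the layout radius), average-referenced,
scaled to a template-to-noise RMS ratio of 4; recordings are scaled to an
80 µV peak with a 200 ms raised-cosine fade at both ends (zero-phase filters
ring on recordings that start mid-oscillation, and the transient would
otherwise trip the 100 µV rejection on edge epochs).

Between-subject variability multiplies each class's mean duration and entry
weight by independent lognormal factors with CV 0.15, which reproduces
within-group coverage SDs of ~3–5 percentage points and duration SDs of
~8–12 ms — the order observed in comparable cohort tables. Planted group
effects follow the study design's direction and magnitude: the seizure group
enters class A 1.8× more often and dwells in class C 0.65× as long; the
seizure-free group enters C 0.75× as often and dwells 0.88× as long. Under
the semi-Markov stationary law (coverage_k ∝ π_k µ_k) these put expected
coverages at ~33% (A) and ~18% (C) in the seizure group versus ~23%/27% in
controls, with the seizure-free group intermediate in C. Classes B and D are
untouched; note that coverage is compositional, so large A/C shifts still
move B and D slightly.

Ground-truth Duration/Frequency/Coverage are computed from the planted
labels by the same run-length code the analysis uses — recovery tests
compare like with like. Passing them shows the pipeline's stages are
correct and its statistics calibrated; it does not show robustness to what
the generator omits: non-stationary artifacts (blinks, muscle, electrode
drift), interictal discharges, imperfect template stationarity across
subjects, broadband 1/f background, or montage/reference mismatches. GEV on
synthetic cohorts (~0.99) is far above the ~0.73–0.75 typical of clinical
EEG because the noise model is milder than biology.

## Numerical choices

- Filter: 4th-order Butterworth SOS, `sosfiltfilt` (zero phase, 8th order
  overall). Downsampling: `resample_poly` (polyphase FIR anti-aliasing).
- Flat (zero-GFP) topographies normalize to zero vectors and correlate 0
  with every template; with the default min_corr = 0 they take class A by
  the lower-index tie rule. EDF writing quantizes to 16 bits over the
  symmetric data range (error ≤ one digital step); reading uses MNE.
- Eigen-update via `eigh` on the C×C member scatter; restarts initialize
  templates from K distinct random peak maps.
- Smoothing floor 20 ms ≙ 10 samples at 500 Hz; iteration cap of 10× the
  initial run count before the zone-resolution fallback.
- Wilks' Λ uses determinants directly; a singular within-group SSCP raises
  an error suggesting class removal rather than silently regularizing.
  Degenerate ANOVA inputs (zero within-group variance) short-circuit to
  p = 0 or 1 with a warning.
- Seeds: every stochastic routine takes a seed or Generator;
  `analyze_cohort` spawns independent per-subject streams from one seed.

## Problem sizes used in validation

The validation suite runs the full pipeline once at the study's scale (39
subjects × 30 epochs, ~80 s on one CPU), calibrates the null at the
label-sequence level (2,000 cohort simulations, skipping signal synthesis —
the statistics operate on the parameter table either way), and measures
planted-effect detection over 200 label-level cohorts. The acceptance script
reports the same quantities at 400 null simulations and 100 detection runs
(~2 minutes total).

## Known limitations

- No ICA or regression-based artifact correction; only amplitude rejection
  plus the external keep/drop hook.
- No channel interpolation, sleep staging, source localization, transition
  syntax analysis, or model-order selection for K.
- The canonical A–D references are idealized; on unusual montages users
  should supply their own reference maps before trusting the A–D labels.
- Backfit Duration is upward-biased by a few percent at SNR 4 (the smoothing
  floor absorbs genuinely short dwells); recovery tests bound this at the
  default settings.
- The mixed-design "interaction" MANOVA on profile differences is the only
  testable multivariate response for compositional coverage; it matches the
  reported df/η² conventions but is not a covariate-adjusted MANCOVA.
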