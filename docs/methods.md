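# Methods

This note documents the models, parameter choices and numerical
conventions behind `duofield`, and what the synthetic-data tests do and
do not establish about real recordings.

## Device geometry

The mirror pair displaces the FOV center to radius `d_mm` (mirror-to-
mirror distance, default 2.5 mm) from the objective axis; rotating the
holder by θ moves two sequential FOV positions `2 d_mm sin(θ/2)` apart.
The square FOV (side 1.0 mm) rides the rotating assembly with a corner
pointing radially, so the reachable set is the annulus
`d_mm ± (side·√2/2)` — outer diameter ≈ 6.4 mm for the defaults — and a
brute-force sweep over a 0.1° rotation grid confirms every annulus
point is covered. The ideal dual-field rate is `1/(2(t_scan +
t_rot(θ)))` with rotation times interpolated linearly between tabulated
angles (43 ms at 60°, 80 ms at 180°); extrapolation is refused rather
than guessed. Pixel throughput is the plain product
width × height × fields × rate. The ~5.2 mm "longest stitched line"
figure sometimes quoted for such devices is not computed here: no
closed-form construction reproduces it unambiguously from the annulus
geometry, so the package reports only the annulus bounds.

## Bead PSF characterization

Bead stacks are acquired with repeats (default 5 frames per plane,
voxels 0.249 × 0.249 × 0.5 µm); repeats are averaged first. Lateral
profiles are the single row/column through the intensity-weighted bead
centroid in the brightest plane; axial profiles are sampled from the XZ
and YZ sections along each section's principal (elongation) axis and
interpolated to uniform physical spacing. A Gaussian with offset is fit
by least squares; FWHM = 2√(2 ln 2) σ; the axial estimate is the mean
of the XZ- and YZ-derived values.

Numerical choices that matter at low SNR: centroids and principal axes
are computed on a lightly smoothed copy (Gaussian, σ = 1 voxel) with
weights below 20% of the peak zeroed — otherwise isolated noise voxels
dominate the second moments; the fit is initialized from a half-max
walk around the peak and restricted to a ±6σ₀ window with the width
bounded to physical values, which prevents the optimizer from latching
onto broad noise. Background is the median of the border voxels. A
volume containing a second component whose peak exceeds half the
brightest one (ignoring components under 5 voxels) is rejected: the
estimator is per-bead. Recovery on synthetic beads: median relative
error ≈ 1% at SNR 20 and ≈ 7% at SNR 5 over 50 beads.

## Trace processing

- ΔF/F baseline: per-unit 8th percentile of the whole series (linear
  interpolation between order statistics); units with F₀ ≤ 0 are
  excluded and reported.
- Event smoothing: unit-sum Gaussian kernel (σ = 100 ms for soma–soma
  analyses, 500 ms for soma–axon), truncated at ±4σ, reflected edges. A
  symmetric FIR applied in one pass is zero-phase by construction, so no
  forward–backward pass is needed; impulse responses peak exactly at the
  impulse and total mass is conserved to 1e-6 away from edges.
- Peak events: local maxima strictly above both neighbours and above
  2 s.d. of the analysed (masked) trace; units used for pairwise
  analyses must show more than 10 peak events.
- Down-sampling is frame skipping (no anti-alias filter), deliberately:
  with ~100 ms-to-0.5 s smoothed signals the pairwise CC structure is
  essentially preserved (the suite asserts r > 0.8 between the 30 Hz
  and 5 Hz CC vectors on matched kinetics).
- Dual-field alignment: each field is acquired at 5.4 Hz with the two
  clocks offset by half a period; both are linearly interpolated onto
  their union clock (10.8 Hz). Extrapolation outside the recorded span
  is an error.
- Movement masking drops frames within 1 s of any lever-movement
  interval and concatenates the remainder.

## ROI selection

Footprints from source extraction are soft; the support is pixels above
10% of the footprint's maximum weight (configurable). Area is support
count × scale²; eccentricity is that of the ellipse matching the
weighted second central moments (a binary-mask variant exists for
cross-checks against standard region properties). The keep rule is
strict: area > 50 µm² AND eccentricity > 0.5; the comparator is
configurable because the elongation rule, while effective at removing
apical dendrites in L2/3 planes, is counterintuitive and a user may
want to invert it.

## Soma–axon matching

Candidate parent somata in one area are correlated (Pearson, on 0.5
s-smoothed events) against every bouton in the other area. Per soma the
table records the sorted top-15 CCs and the mean and s.d. of its full
CC distribution; the z-score of a CC is (CC − mean)/s.d. with the
distribution mean (near 0) subtracted. Matches default to the absolute
criterion CC > 0.6; a z-score criterion is available. Undefined CCs
(zero-variance units) are excluded from distribution statistics, not
imputed. A worked single-number check: a top CC of 0.78 against a
0.12-s.d. distribution is 6.5 s.d. above its mean.

## Behavior

Success requires the lever to cross 5 mm within 1 s of the cue and stay
continuously beyond it for ≥ 400 ms (continuous hold was chosen over
net displacement; the task electronics reward a maintained pull). Pull
onset is the last sample below the noise floor (3× the s.d. of the
second before the cue) preceding the crossing — an onset definition the
task itself does not supply. A pre-pull is any excursion above 20% of
the threshold between cue and onset (configurable). Two
lever-correlation windows are supported: (−0.5, 2.0) s for learning
curves and (−0.43, 1.85) s for the behavioral-cluster analysis; the
window only changes the correlation values, never trial selection
(success ∧ ¬pre-pull ∧ RT ∈ [0.1, 0.5] s).

## Population covariation

Events resampled to 10.8 Hz are compared between the movement window
(−5..20 frames ≈ −0.46..+1.85 s around pull onset) and the resting
window (−25..−10 frames) with a one-sided rank-sum test per neuron,
pooling samples over trials; a neuron is movement-related if p < 0.05
and the movement-window mean exceeds the resting mean. The direction
check uses means rather than medians: deconvolved event trains are
sparse, so both window medians are almost always exactly zero and a
median rule would classify nothing. On continuous i.i.d. null traces
the classifier's false-positive rate calibrates to α (checked at 1000
neurons).

Population vectors are per-trial means over the movement window of
events z-scored over the *full session* (z-scoring precedes trial
realignment; a per-trial z-score would erase amplitude differences
between trials). Trial similarity is the Pearson CC between population
vectors (negative squared Euclidean distance is the supported variant).

**Affinity propagation** is implemented directly as the standard
responsibility/availability message-passing updates with damping 0.9,
up to 1000 iterations, convergence declared after 100 iterations with
an unchanged exemplar set. The preference (diagonal) defaults to the
median of the off-diagonal similarities; percentile variants ("1%",
"10%", "30%", "70%") are supported, and the cluster count is
non-increasing as the preference percentile drops. The updates are
deterministic; exact ties resolve to the lowest index; an optional
seeded jitter exists for pathological symmetric inputs but is off by
default. On small instances (≤ 12 trials, balanced planted clusters)
the result matches an exhaustive exemplar-search oracle, and a
scikit-learn cross-check agrees on well-separated instances.

The cross-area statistic: trials are clustered on area A's vectors;
within each cluster with ≥ 2 members the mean pairwise CC of area B's
vectors is taken and averaged over clusters (singletons contribute
nothing). The null permutes the trial-to-cluster assignment 1000 times
with a recorded seed and reports the mean over permutations (permuting
target-trial identities instead is available and agrees in
distribution). Inter-cluster distance matrices are CCs (or Euclidean
distances) between cluster-mean vectors per area; agreement is the
Pearson r over the vectorized upper triangles, requiring k ≥ 3.

## Synthetic session model

Per trial, area A draws a latent cluster identity uniformly from k = 10;
area B copies it with probability `coupling` and redraws otherwise.
Cluster identities index movement variants on a shared ring: neuron i
(preferred cluster p_i, round-robin) receives a tuning gain
`2.5 Hz · exp(−ring(p_i, c_t)²/(2·0.8²))` — without this shared
inter-cluster geometry the two areas' distance matrices would have
nothing to agree on and the agreement-r sweep would be powerless even
at full coupling. On top sit a baseline rate (0.15 Hz), heterogeneous
per-neuron movement gains (uniform 0.25–1.75 × 0.8 Hz; a uniform
movement response would cancel in across-cell Pearson CCs), a per-trial
multiplicative excitability shared within an area (s.d. 0.2), and
per-neuron trial noise (0.25 Hz). Events are Bernoulli-per-frame
impulses with Gamma(4, 0.25) amplitudes on a 30 Hz grid; fluorescence
is the event train convolved with a single-exponential kernel (decay
1.40 s in RFA, 1.22 s in CFA) plus Gaussian noise; each field is then
binned onto its own 5.4 Hz clock, the two clocks interleaved half a
period apart. Defaults — 65 analysed trials, 40 neurons per area, ~8
recovered clusters at median preference — mirror a typical trained-
mouse session.

What the generator does *not* emulate: motion artifacts, neuropil
contamination, slow shared brain states (synthetic overall
trial-to-trial CC is ≈ 0 rather than the ~0.1 of real motor cortex;
the within-cluster and cross-area contrasts, which are what the tests
assert, do not depend on that offset), spike-inference errors, and
non-Poisson firing statistics. Passing tests therefore demonstrate that
the pipeline recovers planted structure at realistic size and noise,
not that real data would show any particular effect size.

The soma–axon generator copies each parent spike train to its boutons
with 60 ms timing jitter, amplitude CV 0.5, 15% release failures and a
0.05 Hz independent event rate — calibrated so the sibling-bouton CC
cluster sits in [0.6, 0.9] (centered near 0.75), at which point the
default CC > 0.6 match criterion recovers parentage exactly with no
false boutons. The behavior generator varies pull shape (rise, hold,
peak) and appends variable sub-threshold post-return movements, scaled
so the session lever correlation is ≈ 0.88, the reproducibility of a
trained animal; planted success/failure/pre-pull labels remain exactly
recoverable by the detector.

## Problem sizes and determinism

The reproduction experiments use 50 seeded sessions for the null/power
calibration, 20 seeds per coupling level for the agreement sweep, 50
beads for FWHM recovery and 1000 null neurons for classifier
calibration — sizes at which every check is stable across seeds while
the whole battery completes in about a minute. All generators take an
explicit seed and are byte-deterministic given their spec; every
stochastic analysis (shuffle nulls, optional AP jitter) records its
seed in its result object, and `run_full_analysis` writes the config
hash, seed and package version alongside the report.

## Known limitations

- The affinity-propagation heuristic does not globally optimize net
  similarity; on ambiguous (unbalanced, noisy) instances it can return
  a different exemplar set than exhaustive search, typically within a
  hair of the optimal score. The oracle comparison is therefore stated
  for well-separated balanced instances.
- The annulus model treats the FOV as mounted corner-radial; other
  mounting orientations shrink the reachable annulus and are not
  modeled.
- Lateral FWHM uses a single-pixel line profile (band averaging would
  be more robust at low SNR but changes the estimator's definition).
- `inter_area_cc_compare` applies no multiple-comparison correction
  across the three group pairs; with tens of thousands of pairs per
  group the rank-sum p-values are already extreme, but users comparing
  many groups should correct downstream.
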