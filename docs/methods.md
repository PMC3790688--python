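# Methods

This note records the models, conventions, and design choices behind
`rivalerp`, in the spirit of a package's statistical documentation: what
is computed, under which assumptions, and what the synthetic-data tests
do and do not establish.

## Paradigm and trial model

A trial is S1 (1000 ms) → gap (200 ms) → S2 (1000 ms) → mask (1000 ms) →
ITI (2000 ms); successive S1 onsets are therefore exactly 5200 ms apart.
Sessions are blocks of trials, half rivalry (orthogonal gratings to the
two eyes) and half fusion (identical gratings, with a physical
orientation change after the gap on half of them).  Counterbalancing is
exact where the arithmetic allows it: rivalry eye-orientation assignment
is exactly half-and-half per block (hence `trials_per_block` divisible
by 4), fusion pre-gap orientation is exactly balanced, and fusion
physical change is balanced across the fusion set.  The condition of a
block's first trial alternates block to block.

Behavioral outcomes are i.i.d. across trials given a participant's
probabilities.  Group defaults are 37/57/6 % (changed/same/no response)
for rivalry and 94 % correct for fusion.  Because the emulated study
reports between-participant standard deviations (14/19/10 % and 7 %),
per-participant probabilities are drawn from moment-matched Beta
hyperpriors; setting the SD fields to zero disables the spread (used in
calibration studies so that repeated small groups keep every condition
cell occupied).

## Synthetic EEG

Each display onset evokes three components, each a Gaussian-windowed
half-period cosine `cos(πu/4)·exp(−u²/2)` with `u = (t−latency)/width`
(compact support |u| ≤ 2), projected to the scalp with a Gaussian
topography in geodesic distance from a component-specific center:

| component | latency | width | amplitude | topography center |
|---|---|---|---|---|
| P1 | 100 ms | 20 ms | +4 µV | posterior (POz/Oz) |
| N1 | 180 ms | 25 ms | −5 µV | posterior (POz/Oz) |
| late positivity | peak 400 ms, window 300–800 ms | asymmetric (rise 50 ms, fall 200 ms) | +3 µV | vertex (Cz) |

The two predictive effects are injected only on rivalry trials whose
outcome is "changed": the S1 N1 is deepened (default 2 µV, posterior)
and the S1 late positivity reduced (default 1.5 µV, central).  Fusion
responses never depend on the outcome — the negative control is
generated, not assumed.  Component amplitudes are free parameters of the
generator: the emulated study shows ERP morphology only graphically, so
the defaults are ordinary visual-ERP magnitudes, not reported values.
All amplitudes enter linearly, so the recording of summed effects equals
the sum of recordings (tested).

Background noise is 1/f-shaped (exponent 1, RMS 8 µV) plus white sensor
noise (2 µV); blinks are 400-ms raised-cosine transients (150 µV at the
lower vertical EOG site, Gaussian spatial decay toward posterior sites)
at Poisson times, returned with their ground-truth sample indices so
artifact-rejection tests can compare the rejected set against truth.

Two generation paths share the same evoked-response code: a continuous
path (full record, event markers, filtering, epoching) and a fast
epoch-level path that samples each trial directly on the epoch grid with
white noise.  Calibration and power studies use the fast path — the
statistical properties under test live at the participant/condition
level, and FIR filtering of stationary noise does not change the null
calibration of pointwise tests — while the continuous path is exercised
end-to-end by its own tests (blink rejection ground truth, event
round-trips, N1 trough location).

What the generator does *not* emulate: real EEG's spatial correlation
structure, non-stationarities (drowsiness, impedance drift), rivalry
dynamics (dominance durations), or genuine neural sources of the
components (topographies are parametric, not forward-modelled, unless
driven through the leadfield).  Passing tests therefore demonstrate the
*operations* are correct and calibrated, not that real recordings would
yield any particular result.

## Preprocessing conventions

- **Reference.** Linked earlobes = arithmetic mean of the two earlobe
  channels, subtracted from every channel; the former recording
  reference (FCz) thereby becomes an ordinary scalp channel, giving 59
  informative scalp electrodes in the default 65-channel montage
  (59 scalp + 4 EOG + 2 earlobes).  Double re-referencing is an error.
- **Filter.** Kaiser-windowed sinc FIR band-pass, 1857 taps,
  β = 5.65326 (a ~60 dB window with a ~0.98 Hz transition at 500 Hz),
  built as the difference of two windowed-sinc low-passes and applied in
  a single pass with the (n−1)/2-sample group delay compensated, so
  event latencies are preserved; the first/last 928 samples are flagged
  unusable.  *Cutoff convention:* the nominal band edges (0.3 and 35 Hz)
  are treated as stop-band edges — the half-amplitude cutoffs sit half a
  transition width inside the band.  With a half-amplitude cutoff at
  0.3 Hz the kernel's ~1 Hz transition band would straddle 0 Hz and
  leave DC only ~18 dB down; the stop-band-edge convention gives the
  window's full design attenuation (measured: 61 dB at DC, >100 dB at
  100 Hz) while the pass band (1.3–34 Hz) is flat to within ±0.001 dB at
  10 Hz.  Slow drift that survives either convention is absorbed by
  baseline correction.
- **Epochs.** −100…2000 ms around S1 onset, both endpoints on the sample
  grid (1051 samples at 500 Hz); the window endpoint convention is a
  declared choice.  Baseline is the inclusive mean over −100…0 ms.
  Epochs overlapping record boundaries or filter edges are dropped and
  counted.
- **Rejection.** Peak-to-peak per channel over the whole epoch: > 60 µV
  on any EOG channel or > 150 µV on any scalp channel rejects the epoch.
  Rivalry no-response trials and fusion trials with incorrect or missing
  responses are excluded from averaging.

## Statistical battery

- **Windows and regions** are half-open in time, `[start, end)` on the
  2-ms grid: the 80–250 ms ROI over the 10 parieto-occipital/occipital
  electrodes has exactly 10 × 85 = 850 cells (this is the only endpoint
  convention that yields the 85-sample count); the 170–190 and
  380–420 ms windows have 10 and 20 samples.
- **Pointwise t-maps** are paired two-sided t across participants at
  every (electrode, sample) cell, df = n − 1, uncorrected and
  thresholded at p = .01.  Zero-variance cells are flagged not
  significant with a warning.
- **Count chi-square** is the 1-df goodness-of-fit test on
  {significant, not} with expectations {Nα, N(1−α)}; it is invariant to
  exchanging the cells and zero iff observed equals expected.
- **Permutation maps** operationalize "running permutation tests" as
  pointwise sign-flip permutation of each participant's condition
  difference: full enumeration of all 2ⁿ flips for n ≤ 12 (2048 at
  n = 11; exact and seed-free), random flips otherwise.  The two-sided p
  is the fraction of flips with |t| at least the observed |t| (identity
  included, so p ≥ 1/2ⁿ; because flips come in ± pairs the smallest
  attainable p is 2/2ⁿ and the realized test size at α = .01 is
  20/2048 ≈ .0098, inside the calibration band).
- **rm-ANOVA** is a balanced cell-means sums-of-squares decomposition
  for one or two within-subject factors, each effect tested against its
  subject-by-effect interaction, with partial η² = SS_eff/(SS_eff+SS_err).
  For a 2-level single factor F equals the squared paired t exactly.
  Missing or duplicated cells raise; nothing is imputed.  The
  supplementary-style two-factor analysis is exposed generically (factor
  mapping is configuration, since cluster identities are not data).
- **Multiple-testing stance** mirrors the analysis being emulated:
  t-maps stay uncorrected at .01, guarded by the count chi-square, the
  fusion negative control, and the permutation maps; no cluster
  correction is added.

## Source analysis

The forward model is a current dipole in a homogeneous conducting sphere
(radius 100 mm, σ = 0.33 S/m), evaluated by the classical Legendre
series with the dipole-at-center closed form `3q·ê/(4πσR²)` as an
implementation anchor (agreement to 2e-16).  Sources live on a cubic
voxel lattice inside an 75-mm brain sphere; the default test grid
(14–25 mm spacing, ≲400 voxels) runs in seconds, and a 7-mm spacing
reproduces the dense configuration as documented configuration, not a
test requirement.

The inverse is `(GᵀG + λ²I + w·L⊗I₃)⁻¹Gᵀ` with L the voxel-graph
Laplacian — ridge plus spatial smoothness, i.e. a "smoothest current
density compatible with the data" estimator on a spherical head instead
of an anatomical atlas.  λ defaults to generalized cross-validation on
the group-average scalp vector; the emulated method's regularization is
unpublished, so none is inferred.  Group maps are one-sample Hotelling
T² per voxel on the 3-component current vectors (F-transform
T²(n−p)/(p(n−1)), df (3, n−3), hence (3, 8) at n = 11), and condition
contrasts are Hotelling tests of the paired differences; correction is
Bonferroni over voxels at α = .01 (replacing random-field theory, which
needs an anatomical lattice and smoothness estimates this simplified
model does not supply).  Singular voxel covariances are flagged
untestable rather than imputed.

**Resolution and the confinement test.**  On grids where 3·V exceeds the
sensor count the minimum-norm/smoothness inverse necessarily blurs a
point source over many voxels, and at high SNR a Hotelling-vs-zero map
flags that whole blur — that is a property of underdetermined distributed
inverses, not an error.  The package therefore checks *peak* localization
(error ≤ 1 voxel spacing for a noiseless dipole) on the dense test grid,
and checks *confinement* of the condition-contrast map on the coarse
grid where the gain matrix has full column rank (19 voxels × 3 = 57
components for 59 sensors): there the reconstruction is leak-free
(non-source noncentrality ≤ 1e-5 of the source's) and significant voxels
must stay within one spacing of the injected source.

## Problem sizes in the repeated studies

Type-I calibration runs 200 null datasets (plus 100 effect-bearing for
the fusion control) of 11 participants × 40 trials on a 12-channel
montage (the full 10-electrode ROI plus FCz/Cz) and a −100…300 ms epoch;
power/recovery runs 100 replicates of the same geometry with the N1
deepening set to 3× the analytic ERP-noise SD of the window-mean
difference.  These sizes give the binomial bands quoted in the tests
(99 % band ±0.06 percentage points around 1 % for 170 000 cells) and are
the package's chosen defaults for its own validation studies.

## Known limitations

- The spherical forward model and Bonferroni correction make source maps
  comparable in spirit, not in anatomy, to atlas-based distributed
  solutions; no gyrus-level claims are possible.
- The behavioral model is i.i.d. per trial; sequential dependencies
  (adaptation carry-over across trials) are not modelled.
- The permutation scheme is pointwise; cluster-mass statistics are out
  of scope by design.
- BrainVision support is fixed to one binary dialect (multiplexed IEEE
  float32 little-endian, µV); integer dialects and EDF/FIF are not read.
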