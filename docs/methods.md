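# Methods

`spikememd` analyses how the interstimulus interval (ISI) of a repeated
visual stimulus is reflected in multi-electrode spiking activity, at the
level of firing rate, response reliability, and oscillatory structure. This
note documents the models and procedures the package implements, the
defaults and why they were chosen, and what the synthetic data can and
cannot establish.

## Experimental structure assumed

A drifting grating (temporal frequency 6 Hz) is shown for 500 ms, separated
by dark intervals of 1, 3, 5 or 7 s; each ISI condition is one continuous
recording of 16 presentations on a 16-electrode array, of which the first is
excluded from analysis, leaving 15 analysed trials. Spike times (multiunit,
already sorted) are the pipeline's input.

## Preprocessing

Spikes are binned at 1 ms with half-open bins `[t, t + dt)` (a spike on an
edge opens the bin; bin 0 starts at stimulus onset). Electrodes whose
whole-session mean rate is not strictly above 0.5 spikes/s are discarded.
Trial windows run from 1 s before to 1 s after each presentation (2.5 s);
windows are extracted only when fully inside the recording, the first
presentation is always dropped, and the surviving electrodes are averaged
into one population channel per trial. Normalization divides each trial by
its own pre-stimulus (−1000..0 ms) mean, which makes rates dimensionless and
comparable across animals; z-scoring or max-scaling could be substituted but
division is the default because it preserves the multiplicative structure of
gain effects. For ISI 1 s the 1 s post-stimulus window runs up to the next
onset; the overlap is kept, matching the uniform 1 s analysis window across
conditions.

## NA-MEMD

Multivariate EMD decomposes a d-channel signal into a shared set of
intrinsic mode functions (IMFs) by projecting the signal onto unit
directions, interpolating d-variate envelopes through the signal at each
projection's extrema (not-a-knot cubic splines), and iteratively subtracting
the direction-averaged mean envelope (sifting). Implementation choices:

- **Directions.** Hammersley low-discrepancy points in the unit d-cube
  (centred van der Corput ramp plus radical inverses in the first d−1 prime
  bases), pushed through the inverse normal CDF and normalised to the unit
  sphere. Deterministic and bit-reproducible; 300 directions for the d = 19
  production geometry, fewer for low-dimensional test decompositions.
- **Boundaries.** Mirror-symmetric extension of up to two extrema of each
  kind about each end, anchored on the outermost extremum or on the endpoint
  depending on whether the signal starts/ends beyond the first/last
  opposite-kind extremum. This is the classical symmetric rule; the naive
  two-point mirror was measurably worse (edge RMS error ~10× the interior on
  tone-recovery benchmarks).
- **Stopping.** Rilling two-threshold criterion on the ratio of the mean
  envelope norm to the mean envelope amplitude: stop when the ratio is below
  θ1 = 0.05 on at least 95% of samples (α = 0.05) and below θ2 = 0.5
  everywhere. Caps: 500 sift iterations per IMF, 30 IMFs.
- **Noise assistance.** k = 4 white-Gaussian-noise channels appended
  (d = n + k), SD matched to the mean per-channel SD of the data. The WGN
  drives dyadic filter-bank behaviour that reduces mode mixing;
  noise-channel IMFs are flagged and dropped after decomposition.
- **Termination.** Decomposition ends when every projection of the residue
  has fewer than three extrema. Reconstruction (ΣIMFs + residue) is exact to
  floating point by construction.

Measured filter-bank behaviour on pure WGN (d = 4): mean IF ratios of
successive modes ≈ 1.6–1.7, inside the expected quasi-dyadic band — the
multivariate filter bank is slightly denser than the univariate factor-2.

### Decomposition units

Two decompositions serve different questions:

1. **Trial decomposition** — all per-trial population channels of every ISI
   condition of one animal, jointly (d = n_ISI·n_trials + 4). Joint sifting
   aligns mode indices across channels, which the across-trial statistics
   require.
2. **Evoked decomposition** — one channel per ISI condition, the
   trial-averaged normalized response, plus the WGN channels (d = n_ISI + 4).
   Trial-averaging removes trial-incoherent shot noise before sifting, and
   the low dimensionality keeps the 64–300 directional envelopes
   well-sampled. The mode-frequency table, the Hilbert-Huang spectra and the
   phase-space axes come from this decomposition.

## Hilbert analytics

The analytic signal is built in the frequency domain (negative frequencies
zeroed); instantaneous amplitude (IA) is its modulus and instantaneous
frequency (IF) the central-difference derivative of the unwrapped phase
over 2π. Raw discrete IF is spiky wherever IA is small, so an 11-sample
moving median is applied before any summary (disable for closed-form
oracles); the first and last 5% of samples are excluded from IF summaries
(edge artifacts); IF is marked invalid where IA < 1e−12. Mode frequencies
are reported as the IA-weighted mean IF — weighting suppresses meaningless
excursions at near-zero amplitude and is scale-invariant.

The Hilbert-Huang spectrum deposits IA² at each (time, IF) sample into a
time × frequency grid (64 log-spaced bins over 1–200 Hz by default);
binning conserves in-range energy exactly.

The **stimulus-band mode** of a session is identified by evoked power: mean
squared value of the trial-averaged mode inside the stimulation window minus
the same quantity in the pre-stimulus second. Subtracting the pre-stimulus
term removes the rate-dependent shot-noise floor, which otherwise always
crowns the fastest mode; trial-averaging retains only stimulus-locked
energy. The selected mode's frequency is summarised by the IA-weighted mean
IF over the stimulation window only — outside it the mode carries band
noise at its natural centre frequency rather than the driven oscillation.
On synthetic sessions this selects the grating-band mode (measured
6.24–6.35 Hz for a 6 Hz drive; the residual upward bias comes from
admixture of the neighbouring 10.5 Hz component, which sits less than one
octave away — at the resolution limit of EMD-family methods).

## Condition statistics

All comparisons are two-sided Wilcoxon rank-sum tests: exact null when the
combined sample is ≤ 25 without ties, normal approximation with tie
correction otherwise; two all-identical samples give p = 1. Families of
p-values are corrected with Storey q-values: π̂0(λ) = #{p > λ}/(m(1−λ)) on
λ = 0.05..0.95 (step 0.05), smoothed by a precision-weighted quadratic fit
(weights ∝ √(1−λ), since the variance of π̂0(λ) grows like 1/(1−λ)) and
evaluated at λ = 0.95, clipped into [1/m, 1]; q-values are the usual
step-up minima, so q = π̂0 × Benjamini–Hochberg. For families smaller than
12 the smoother is degenerate and π̂0 is fixed at 1 (the conservative BH
limit). Two significance tiers are carried: q < 0.05 ("significant") and
q < 0.1 ("statistically relevant").

- **Discriminability maps**: per (IMF, time) cell, rank-sum across trials of
  the instantaneous amplitude between two ISI conditions; Storey correction
  across all cells of one map.
- **Rate comparisons**: per-trial normalized stimulation-window means,
  pooled across animals, each longer ISI versus 1 s; Storey over the
  comparison family.
- **Variability**: coefficient of variation (SD/mean) across trials per
  stimulation-window time bin, computed on 25 ms boxcar-smoothed trial rates
  (raw 1 ms Poisson bins are mostly 0/1 and make CV degenerate); pooled
  across animals and compared the same way.

Under identical generative conditions the maps' q < 0.05 discovery fraction
stays at or below 0.05 (null calibration), and window-level p-values are
uniform.

## Phase space

Each ISI condition is embedded as a trajectory in three axes: normalized
mean firing rate (25 ms boxcar), IA of the mode nearest 6 Hz, and IA of the
mode nearest 18 Hz. Axis modes are selected by measured IA-weighted mean IF
(nearest in log frequency, error if nothing lies within a factor of 2) —
ordinal mode indices are dataset-dependent. The IA axes use the amplitude of
the *trial-averaged* (and, cohort-level, animal-averaged) mode: averaging
before the modulus cancels incoherent noise, whereas averaging IAs leaves a
rectified noise floor. IA axes are smoothed with a 250 ms boxcar: evoked
amplitude dynamics are slow, while sub-octave mode admixture beats at
4–8 Hz and would otherwise dominate the geometry.

Axes are normalized by their SD pooled over all ISIs and time points
(idempotent; min-max scaling available as an alternative). The resting
centroid is the mean of all trajectories over −400..−200 ms. Distances:

- per-time Euclidean distance of each trajectory to the centroid, summarised
  over the stimulation window as an RMS;
- pairwise trajectory distance = RMS over stimulation-window samples of the
  instantaneous Euclidean distance. The RMS form is deliberate: sampling
  noise enters as a single additive variance term common to all pairs, so
  the *ranking* of pairwise distances reflects the true trajectory gaps,
  which a mean of rectified instantaneous distances does not guarantee;
- average-linkage hierarchical tree over the pairwise matrix, exportable as
  Newick.

With default generator settings the geometry reproduces the qualitative
structure the analysis targets: the 1 s trajectory stays nearest the
centroid, 3 s and 5 s project farthest and merge first in the tree, and 7 s
leaves the fixed point only transiently before returning toward the 1 s
branch.

## Synthetic data generator

Spikes are drawn per electrode and presentation from an inhomogeneous
Poisson process by Lewis–Shedler thinning (exact given a verified intensity
bound; negative intensities are rejected as misconfiguration). The intensity
for a presentation, with t relative to onset:

    λ(t) = b_e · g(t) · [ 1 + γ_ISI(t) · s(t) · (r0 + Σ_j a_j cos(2π f_j t + φ_j))
                          + A_on · exp(−(t − t_on)² / 2w²) ]

- `b_e`: per-electrode baseline, drawn once per animal from a Gamma
  distribution (shape 4, mean 20 spikes/s — multiunit scale; occasional
  draws fall under the 0.5 spikes/s filter). 20 spikes/s also keeps the
  grating-band mode's evoked energy above the 1 ms shot-noise floor, a
  precondition for frequency recovery at the study's own resolution.
- `g(t)`: slow per-trial gain state, log-normal with SD 0.30 for the 1 s ISI
  and 0.15 otherwise (less reliable responses at short intervals). The state
  switches one second *before* each onset, so a trial's pre-stimulus
  baseline carries the same state as its response and baseline division
  removes it — gain variability then shows up in the across-trial CV, not in
  the normalized rates.
- `γ_ISI(t)`: response gain. Sustained values 1.0 / 1.3 / 1.32 / 1.05 for
  1 / 3 / 5 / 7 s (3 s and 5 s nearly identical — no clear 3-vs-5 difference
  during stimulation; both well above 1 s). The 7 s condition additionally
  starts at 1.8 and decays exponentially (τ = 120 ms) to its sustained
  value: its discrimination is transient, an early excursion that returns
  toward the 1 s level within ~200 ms.
- `r0 = 1`: evoked plateau the oscillations ride on; it carries the
  sustained rate increase and, being at least Σa_j = 0.95, guarantees a
  non-negative intensity at every gain the defaults reach.
- components `(f_j, a_j)` = (6, 0.5), (10.5, 0.2), (18.4, 0.15), (40, 0.1),
  all phase-locked to onset (φ = 0) by default — one component per frequency
  band the analysis is expected to resolve. Phase locking is what lets
  trial- and animal-averaging isolate the evoked oscillation.
- onset transient: Gaussian, latency 150 ms, width 50 ms, amplitude 1.0 —
  shared across ISIs.

All randomness derives from a single seed through a spawned seed tree;
identical configuration gives a bit-identical spike table.

**What the generator does not emulate**: refractoriness and spike-history
dependence, adaptation within and across presentations, correlated noise
between electrodes, anticipatory pre-stimulus dynamics, non-Poisson count
dispersion, and any biophysics. Passing tests therefore establish that the
*analysis* recovers the structure the generator encodes at realistic rates,
trial counts and noise levels — not that cortical data contain that
structure.

## Problem sizes and numerical conventions

Production geometry (15 trial channels + 4 WGN, 2500 samples at 1 ms, 300
directions) decomposes in about a minute; test and cohort-level runs use
5–10 ms analysis bins (rebinned by summing counts) and 48–64 directions,
which preserve every band the generator populates (Nyquist ≥ 50 Hz). The
20-cohort phase-space check runs 4 pooled animals per cohort at 10 ms bins.
Degenerate inputs are explicit errors: constant signals (no IF), zero
baselines (no normalization), dead datasets (no electrode above threshold),
zero-variance axes (no normalization scale). Ties in rank-sum tests switch
the test to the tie-corrected normal approximation; identical samples give
p = 1 rather than NaN.
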