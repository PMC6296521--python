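# spikememd

Multiscale analysis of multi-electrode spike trains under repeated visual
stimulation: how the interstimulus interval (ISI) of a 500 ms drifting
grating (1, 3, 5 or 7 s of darkness between presentations) is reflected in
population firing rate, response reliability, and oscillatory structure.
Built for systems neuroscientists analysing stimulus-locked population
activity, and usable wherever trial-structured point-process data carry
oscillations at several time scales.

## What it computes

- **Synthetic cohorts** — an inhomogeneous-Poisson multi-electrode generator
  (exact Lewis–Shedler thinning) whose intensity
  `λ(t) = b·g·[1 + γ_ISI(t)·s(t)·(r₀ + Σⱼ aⱼcos(2πfⱼt + φⱼ)) + onset(t)]`
  encodes ISI-dependent gain, trial-to-trial variability and multi-frequency
  stimulus-locked oscillations.
- **Preprocessing** — 1 ms binning, the 0.5 spikes/s electrode filter,
  stimulus-aligned ±1 s trial windows (first presentation excluded),
  electrode averaging, per-trial baseline normalization.
- **NA-MEMD** — from-scratch noise-assisted multivariate empirical mode
  decomposition: `d = n + k` white-noise channel augmentation, Hammersley
  direction vectors on the unit sphere, multivariate envelope sifting with
  the Rilling two-threshold stop, exact additive reconstruction, and the
  dyadic filter-bank behaviour on white noise.
- **Hilbert analytics** — analytic signal, instantaneous amplitude `IA(t)`
  and frequency `IF(t) = (1/2π)·dφ/dt`, amplitude-weighted mode frequencies,
  and the Hilbert–Huang spectrum (time × frequency energy grid).
- **Discriminability statistics** — per-(IMF, time) two-sided Wilcoxon
  rank-sum maps between ISI conditions with Storey q-value correction
  (`q = π̂₀ × BH`), across-trial coefficient-of-variation profiles, and
  pooled cohort rate comparisons.
- **Phase space** — trajectories in (normalized rate, ~6 Hz mode IA,
  ~18 Hz mode IA), the pre-stimulus resting centroid (fixed point),
  distance profiles, and an average-linkage tree over the ISI conditions,
  exportable as Newick.

See `docs/methods.md` for the model, the defaults and their rationale, and
what the synthetic benchmarks do and do not establish.

## Worked example

Decompose a 4 Hz + 40 Hz mixture with NA-MEMD and read off mode frequencies
(`examples/03_namemd_hilbert.py`):

```text
10 IMFs, reconstruction error 4.44e-16
  IMF 0:  77.07 Hz   variance 0.0001
  IMF 2:  40.01 Hz   variance 0.2162
  IMF 6:   4.00 Hz   variance 0.4934
  IMF 9:   0.91 Hz   variance 0.0000
```

The two injected tones land in exactly one mode each (40.01 Hz and 4.00 Hz,
carrying essentially all the variance: 0.216 ≈ 0.7²/2 and 0.493 ≈ 1²/2);
the remaining modes are near-zero decomposition residuals, and the sum of
all modes plus the residue reproduces the input to machine precision.

On a simulated cohort the preprocessing chain shows the encoded effect
structure (`examples/02_preprocess_rates.py`):

```text
ISI 1 s: 16 electrodes kept, normalized stim rate 2.26 x baseline, median CV 0.34
ISI 3 s: 16 electrodes kept, normalized stim rate 2.55 x baseline, median CV 0.27
ISI 5 s: 16 electrodes kept, normalized stim rate 2.51 x baseline, median CV 0.28
```

— a stronger and more reliable (lower CV) response at 3/5 s than at 1 s.
The other examples cover simulation + TSV round-trip, discriminability
maps, and the phase-space tree, each printing what its numbers mean.

A thin CLI covers the two shell-level entry points:

```sh
spikememd simulate --seed 1 --out data/        # spike TSV + protocol JSON
spikememd run-all  --seed 1 --out results.h5   # full pipeline, one HDF5
```

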