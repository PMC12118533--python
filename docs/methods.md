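# Methods

## Scope and model class

`koopmodes` treats a multichannel EEG recording of a near-steady brain
state as a trajectory of an (unknown, nonlinear, noisy) dynamical system
and approximates its action on the measured observables by a linear
propagator per analysis window, `x_{t+1} = A x_t`.  The linear description
is local in time — the operator is refit for every sliding window — and
the nonstationarity between windows is handled not by the operator itself
but by the adiabatic tracking layer, which only trusts modes that drift
slowly from window to window.  Everything downstream (effective modes,
generative models) is built from these tracked eigenpairs.  The
approximation is intentionally blind to nonlinear interactions inside a
window and to any dynamics faster than the window length.

## Pipeline stages and their parameters

**Preprocessing.** Zero-phase (forward–backward) 4th-order Butterworth
high-pass at `hp_cutoff` = 0.5 Hz, then polyphase anti-aliased resampling
to `target_fs` = 100 Hz.  Zero-phase filtering is essential: mode phases
are the quantity of interest, and a causal filter would rotate them
frequency-dependently.  The 0.5 Hz corner's edge transients span several
seconds, so analyses that compare filtered signals sample-by-sample should
discard ~7 s at each end.

**Windowed DMD.** Window length `n` = 200 samples, stride `n/2` (50 %
overlap), stacking degree `h` = 10.  With 19 channels this makes the
embedded matrix 190 × 190 — nearly square, so up to 190 modes can tile the
spectrum.  Window duration and sample count are deliberately independent
knobs: at 100 Hz the default window spans 2 s.  SVD truncation keeps the
leading singular values holding 99.9 % of squared energy (capped at the
numerical rank); the truncation mainly sheds exactly-degenerate directions,
and noise-mode rejection is delegated to tracking rather than to an
aggressive rank cut.  Eigenvectors are reduced to channel space by taking
the first delay block, unit-normalizing, and rotating the phase gauge so
the maximum-amplitude channel has phase 0 (only relative phase is
physical).  Mode amplitudes `b` are least-squares coefficients of the
window's first embedded state, rescaled to refer to the stored normalized
channel modes so that `x_t ≈ Re Σ φ_k b_k λ_k^t` holds with the stored
quantities.

**Adiabatic tracking.** Two gates per window step: `|Δf| ≤ df_max` = 1 Hz
and eigenvector overlap `|⟨φ_{t+1}|φ_t⟩| ≥ o_min` = 0.9.  The modulus of
the Hermitian product is used because it is the only gauge-invariant scalar
ordering of the complex overlap.  Qualifying pairs are resolved into a
one-to-one matching by minimum total cost
`|Δf|/df_max + (1−|o|)/(1−o_min)` (optimal assignment; ties broken toward
smaller `|Δf|`).  Only positive-frequency conjugate representatives are
tracked; a mode missing for one window ends its track (no gap bridging).
Tracks shorter than `min_track_windows` = 3 are discarded.  The incidence
distribution uses 0.5 Hz bins and is amplitude-weighted (`|b|`) by
default, with a pure-count option; both normalizations sum to 1.

**Effective modes.** Incidence peaks are local maxima with prominence
≥ 5 % of the largest bin (boundary bins qualify when they rise above their
single neighbor).  For each peak, all track entries within ± one bin
contribute, each entry re-gauged to a common reference channel (largest
pooled mean amplitude).  Per channel, a Gaussian KDE (Scott's bandwidth)
runs on the complex plane `(a cos φ, a sin φ)` — circularity of phase is
then automatic — evaluated on a 128 × 128 grid over the sample bounding box
padded by 3 bandwidths; the density maximum defines the effective
amplitude and phase.  Degenerate clouds are handled explicitly: identical
points are returned exactly, collinear clouds fall back to a 1-D KDE along
the spread axis.  The KDE is per channel rather than jointly over all
channels; a joint density in 2·n_ch dimensions would be hopelessly
undersampled by a few hundred track entries.

**Generative model.** From a window's DMD result the model keeps up to
`keep_modes` = 12 positive-frequency modes (plus conjugate partners),
selected by amplitude among those with `|λ| ≥ lambda_min` = 0.95.  Three
numerical choices here were forced by experiments with the obvious
alternatives:

1. *Subset amplitudes are refit.*  Full-mode-set DMD amplitudes rely on
   cancellation between non-orthogonal modes; inheriting them for a kept
   subset leaves uncancelled remainders that appear as spurious transients
   orders of magnitude above the signal.  The kept subset's coefficients
   are therefore refit by least squares against the whole window
   trajectory.
2. *Stable modes are projected onto the unit circle*
   (`project_unit_circle=True` in the pipeline).  Window-fitted magnitudes
   like `|λ| = 0.998` are noise-level decay, but they compound to `e^{−4}`
   over a 20 s epoch and the generated state dies out.  A steady state's
   persistent oscillations sit on the unit circle by assumption, so the
   magnitudes of kept modes are normalized (growing modes are equally
   clamped; the `clamp` flag additionally guards generation from any
   remaining `|λ| > 1`).
3. *The spectral objective is linear-power, horizon-length.*  The BFGS
   boundary-condition fit minimizes the channel-wise squared difference of
   Welch PSD between simulated and target data, normalized by the target's
   total squared power, with the simulation evaluated over the full
   generation horizon rather than only the fitted segment.  A log-PSD
   objective was tried first and is pathological for mode-poor models: the
   model has no broadband floor, the unreachable floor bins dominate the
   log loss, and the optimizer inflates modes whose spectral leakage mimics
   noise.  Evaluating over the horizon forbids solutions in which two
   near-degenerate modes cancel inside the fitted segment and beat to large
   amplitude outside it.  Free parameters are the Re/Im parts of the
   positive-frequency representatives' coefficients (conjugate partners
   tied, so generated data stay real); BFGS runs with numerical gradients,
   `bfgs_maxiter` = 60 in the pipeline, and the returned loss never exceeds
   the initial one.

Per state, one model is fitted per 20 s epoch on the epoch's leading third
and generates the full epoch (the remaining two thirds are extrapolation).
When segments from different models are concatenated, the first 0.25 s of
each new segment is linearly cross-faded with the previous model's
extrapolation; consecutive segments of the same model continue exactly
(the per-model step counter advances).

**Validation.** Welch estimates use 2 s Hann segments with 50 % overlap.
Band edges: δ 0.5–4, θ 4–8, α 8–13, β 13–30, γ 30–45 Hz (Nyquist 50 Hz).
wPLI is `|E[Im S]| / E[|Im S|]` over segment observations (0/0 defined as
0), computed per epoch for classification; dwPLI is the debiased squared
estimator pooled over all epochs' segments, with an epoch-wise
sufficient-statistic decomposition so label permutations can re-pool
without recomputing spectra.  Band values are the cross-power-weighted
mean of the per-bin estimator (weights: mean |Im S| per bin); a flat mean
would dilute a narrow coherent line with noise-only bins whose phase-lag
estimate is ≈ 0, while the weighting leaves the zero expectation under
independence intact.  SSIM is the global closed form
`(2μ_aμ_b+C1)(2cov+C2)/((μ_a²+μ_b²+C1)(σ_a²+σ_b²+C2))` with K1 = 0.01,
K2 = 0.03 and data range = joint max − min — these are physical matrices,
not natural images, so no sliding window is used.  Permutation tests
shuffle epoch condition labels (N = 1000 by default); the p-value is the
proportion of permuted statistics ≥ the observed one; the significance
mask applies `p ≤ α/6` (Bonferroni over the 6 pairs of 4 conditions).
Classification is L2 logistic regression (C = 1) on *unstandardized*
linear-power PSD features (or wPLI upper-triangle features), 10-fold
stratified cross-validation with pooled out-of-fold predictions, and
percentile bootstrap confidence intervals (N = 10000 by default).
Per-feature standardization was removed deliberately: modeled epochs are
near-deterministic within a state, and dividing by their vanishing
variances amplifies numerical noise into dominant features; likewise,
log-power features would locate the measured-vs-modeled difference in the
noise floor a mode-based model intentionally lacks.

## The synthetic generator

Each synthetic state is a sum of planted coherent oscillations — fixed
frequency, per-channel amplitude gains, per-channel phase offsets, optional
exponential decay (default 1.0: pure steady state) — plus independent pink
(1/f power, spectrally shaped white noise renormalized to exact unit
variance per channel) and white noise.  The default presets mirror the two
clinical states: *Status* has one strong 2.5 Hz coherent mode with a
frontal-dominant amplitude gradient and a π/3 phase gradient;
*Resolved* has a posterior-dominant 10.5 Hz mode plus a weak 2.5 Hz
remnant.  Noise scales (pink 0.30, white 0.10 relative to unit-order mode
amplitudes) give an in-band SNR typical of high-amplitude pathological
slow-wave EEG, where the rhythm visibly dominates the background.  The 19
channels carry 10–20 montage names so topographic exports work.

What the generator does *not* emulate — and what passing tests therefore
cannot certify for real data: physiological artifacts (blinks, muscle),
volume-conduction mixing with realistic lead fields, non-sinusoidal
waveform shape of epileptiform discharges, frequency drift and
amplitude modulation of real rhythms, and inter-epoch nonstationarity
beyond independent noise draws.  Passing tests show the algorithms recover
planted structure under realistic noise; clinical claims require patient
data.

## Problem sizes

The test suite and the acceptance script run the full pipeline on two
states of 200 s each (10 epochs of 20 s per state, 19 channels, generated
at 200 Hz and analyzed at 100 Hz), with 100 SSIM permutations and 1000
bootstrap resamples in the heavyweight fixture; unit tests use smaller
constructions (2–4 channels, tens of seconds).  These sizes were chosen to
match the per-patient scale of a typical clinical recording session while
keeping a complete from-scratch replication convenient on one CPU.

## Known limitations

- One frequency per mode per window: broadband or strongly
  frequency-modulated activity fragments into multiple short tracks.
- No gap bridging in tracking: a mode occluded for a single window starts
  a new track, which deflates incidence for intermittent rhythms.
- The generative model reproduces the coherent part of the spectrum, not
  the stochastic floor; measured-vs-modeled comparisons must use metrics
  that tolerate this (linear-power SSIM and features do; log-scale metrics
  do not).
- The BFGS fit optimizes spectra only; time-domain alignment between
  measured and modeled epochs is not a fitting target.
- Matching cost weights (`df_max`, `o_min`) are thresholds, not estimates;
  results near the gates can be sensitive to their values, which is why
  both are exposed in the configuration.
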