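# Methods

`nfdrift` implements, as a tested pipeline, the analysis of a passive
neurofeedback-like EEG experiment: does band power in the classically trained
EEG bands (theta 4–8, alpha 8–12, SMR 12–15, beta 15–30 Hz) drift
spontaneously across trials, does watching a continuously modified feedback
stimulus change it, and does the modification rate (1/5/10 Hz) matter?  The
package covers the whole chain — synthetic cohort generation with known
ground truth, preprocessing, spectral band power, contrast coding, Bayesian
multilevel inference with Bayes factors, and generation of the sham-feedback
stimulus itself — so every stage can be exercised and validated without any
recorded data.

## Task design

A session is 4 conditions × 8 trials × 60 s at 250 Hz on electrodes Fz, Cz,
Pz.  In the Control condition a gray circle (radius 100 px) stays fixed; in
the 1/5/10 Hz conditions its size is re-drawn at that rate.  Condition order
is counterbalanced by a partial Latin square with the four quadruplets
(2143, 1432, 3214, 4321), so each condition occupies each temporal position;
subjects are distributed evenly across quadruplets.

## Synthetic EEG generator

Each channel-trial is synthesized in the frequency domain as

* an aperiodic background with PSD ∝ 1/(knee^χ + f^χ) (default χ = 1,
  knee = 2 Hz, 12 µV RMS).  The knee bounds low-frequency power the way
  resting spectra flatten below a few hertz; without it the 1/f divergence
  would dominate the PSD maximum, which belongs to the alpha peak;
* band-limited oscillations: Gaussian spectral bumps centered in each band
  (σ = bandwidth/6), normalized to a per-trial RMS amplitude (defaults
  theta 5, alpha 10, SMR 3, beta 4 µV — the alpha-dominant profile of
  eyes-open resting EEG);
* optionally a steady-state sinusoid at the stimulation frequency
  (5/10 Hz conditions only; the 1 Hz condition deliberately carries none,
  mirroring the empirical absence of a 1 Hz photic response).

**Ground-truth effects in z-units.**  The downstream models analyze band
power z-scored across the pooled cohort, so the generator's effect sizes —
`alpha_trend` (default 0.02 z per global trial) and
`theta_condition_effect` (default 0.165 z, experimental vs Control,
localized at Pz) — are specified in those units and must be realized in dB.
Two mechanisms make this exact:

1. *Power-level offsets* (per-subject band intercepts, SD 2.5 dB; shared
   trial-to-trial power fluctuations, SD 0.4 dB) are applied as per-band
   gains to the whole band content (background and oscillation), so the
   realized dB offset equals the drawn offset by construction.
2. *Effects* scale only the oscillation amplitude.  Because the band measure
   is the mean of per-bin dB values, its response to an amplitude factor a is
   mean_f 10·log10((a²·s_osc(f) + s_bg(f)) / (s_osc(f) + s_bg(f))) over the
   band's bins.  A cached, seeded pre-run calibration measures the
   oscillation and background PSD profiles through the *full* analysis chain
   (filter → trim → Welch → dB) and inverts this monotone response on a grid,
   so a requested dB shift is realized faithfully rather than assumed
   proportional to 20·log10(a).

One z-unit is defined as the pooled dB SD the analysis will divide by: the
generator combines the SD of its own injected power offsets with the
calibrated spectral-estimation noise floor.  This keeps injected and
recovered effect scales consistent to a few percent (the small residual
shrinkage comes from effect-induced variance inflating the empirical
z-denominator).

Between-subject heterogeneity of the *effects* is multiplicative:
slope_i = slope·(1 + subject_sd·z_i) with subject_sd = 0.5, i.e., a 50%
coefficient of variation, justifying the maximal varying-effect structure.
The free noise scales were chosen once so that the synthetic band-power
distributions match the published data's printed scales (pooled SD ≈ 2.6 dB;
credible-interval widths of the same order as the published tables) and are
not tuned per analysis.

What the generator does **not** emulate: volume conduction / channel
covariance (channels are independent), non-stationarity within a trial,
ocular and muscle artifacts beyond the optional blink injector, the
"rebound" drop of alpha at block starts, and real spectral shape diversity
across subjects.  Passing recovery tests therefore demonstrate correctness
of the estimation chain under the stated generative model, not robustness to
every property of real EEG.

## Preprocessing

Zero-phase (forward–backward) filtering: 6th-order Butterworth high-pass at
0.5 Hz plus 2nd-order IIR notch at 50 Hz (Q = 35, bandwidth ≈ 1.4 Hz; the
bandwidth is a package default, not a published value).  Each trial then
loses its first 2 s and last 1 s (sample-accurate: round(seconds × fs)
samples; 60 s → 57 s), removing the filter transients — the high-pass rings
for seconds, which the test suite demonstrates directly.  Artifact removal
is a pluggable stage whose default is the identity: ocular-component
selection is inherently manual, so real-data users plug their own
decomposition; a regression remover for known artifact time courses is
provided and validated by a known-mixing round trip.

## Spectral band power

Welch averaged periodograms: the longest Hamming-tapered segments giving at
most 8 segments at 50% overlap (a 57-s trial yields exactly 8), constant
detrend, density scaling (µV²/Hz), then 10·log10 with a 1e-12 floor.  Band
power is the arithmetic mean of dB bins with low ≤ f < high; the half-open
convention assigns 8 Hz to alpha, 12 Hz to SMR, 15 Hz to beta, so no bin is
counted twice.  A configured reporting grid (`bin_spacing`, default
0.305 Hz) is honored by zero-padding when it is finer than the natural
segment grid; it can never coarsen it (the natural grid of an 8-segment
57-s Welch is ≈ 0.079 Hz, already finer than 0.305 Hz, so the default is a
no-op — the two printed conventions are mutually inconsistent and the
segmentation rule wins).  Band powers are z-scored per (electrode, band)
pooled over all subjects, conditions and trials.

## Condition contrasts

The three planned hypotheses (any-modification vs Control; 5 vs 1 Hz;
10 vs 5 Hz) are written as rows of a hypothesis matrix with a grand-mean
intercept row (1/4 per condition); the model's condition columns are its
Moore–Penrose generalized inverse, computed in exact rational arithmetic
(floats appear only at design-matrix export).  The grand-mean intercept
convention is what makes the inverse produce the all-ones intercept column
of the published matrix, which the implementation reproduces entry-exactly.
The trial covariate is coded trial − 1 (trial 1 is the reference, so
condition effects are read at the first trial); the whole-task variant codes
global trial 1..32 as global − 1 with no condition columns.

## Bayesian multilevel model

For one (electrode, band) response: power_z ~ 1 + trial × contrasts with the
same structure varying by subject, Gaussian residuals, independent
N(0, prior_sd²) priors on the population coefficients (prior_sd = 1:
±2 standardized SD at 95%), and half-normal(0,1) priors on all scale
parameters.  Varying effects are modeled as mutually independent (diagonal
covariance).  Effect correlations are poorly identified at 32 subjects and
dropping them reduces the non-Gaussian posterior to at most 9 scale
parameters — which enables the sampling strategy below; this is a deliberate
simplification relative to an unstructured covariance.

**Sampling.**  Conditional on the scales, everything else is Gaussian, so
subject effects *and* population coefficients are integrated out
analytically (Woodbury identities on per-subject sufficient statistics; the
implementation is verified against a dense linear-algebra oracle).  An
affine-invariant ensemble sampler explores the log-scale posterior
(4×ndim walkers, 400 burn-in + 300 retained sweeps by default), and exact
conditional Gaussian draws of the coefficients are generated per retained
sample.  Because each coefficient draw is a fresh conditional Gaussian
sample, their autocorrelation is far lower than the scale chains'.
Convergence is gated on split-R̂ < 1.01 and bulk ESS > 400 of the
coefficient draws (arviz, 4 pseudo-chains); non-convergence raises by
default, carrying the diagnostics.

**Bayes factors.**  Evidence for each coefficient's point null at 0 is the
Savage–Dickey ratio: prior density at 0 over posterior density at 0, the
latter estimated from the draws by a Gaussian KDE with Silverman bandwidth
(a moment-matched normal estimate is available as an option).  The KDE is
accurate to a few percent when 0 lies within ~2 posterior SDs of the mean
and biased conservatively (BF10 underestimated) when the null is far in the
tail; when the posterior mass at 0 underflows, BF10 is reported as +∞ and
rendered "> 100", matching how overwhelming directional evidence is usually
printed.  The one-sided BF10+ multiplies BF10 by twice the posterior mass
above zero (the half-prior renormalization for a symmetric prior).
Classification: BF10 > 3 → evidence for an effect (H1), < 1/3 → evidence
for its absence (H0), otherwise insensitive.

**Stability and sensitivity.**  Every reported analysis is refit 5 times
with distinct seeds; reports carry the per-run BFs, their mean, and the
credible-interval envelope (min lower, max upper).  The prior-sensitivity
sweep repeats the protocol over prior SDs 1.0 down to 0.2 (95% prior mass
±2 SD down to ±0.4 SD); on null data BF10 decreases as the prior widens
(Lindley–Bartlett behavior), which the tests assert.

## Stimulus generation

Candidate circle-size deltas are successive differences of a band-power
series mapped linearly to pixels (configurable px/dB scale; the original
pixel mapping is not published, so only shape statistics are meaningful).
At each update instant (every 1000/200/100 ms at 1/5/10 Hz) one delta is
drawn uniformly with replacement and added to the radius, hard-clipped to
bounds (default 20–180 px around the 100 px baseline; clipping is recorded
in provenance because it can bias moments).  Validation statistics —
variance, skewness, excess kurtosis, lag-1 autocorrelation — are computed on
the *variation* (delta) series, not the radius levels.  I.i.d. resampling
preserves the pool's distributional shape but destroys temporal structure:
generated lag-1 autocorrelation tends to 0 regardless of the source
dynamics.  The package reproduces this as a property and flags it in
`compare_stats`, mirroring the post hoc finding that motivated it.

## Problem sizes and numerical choices

Default analysis scale is the study's (32 subjects, 5 stability runs).  The
test suite uses reduced sizes chosen as a deliberate compromise between
statistical resolution and turnaround: parameter recovery runs 20 replicates
of 12 subjects × 32 trials (credible-interval coverage of the true slope
0.02 and condition effect 0.165 must reach 90%); the null-calibration check
uses 2 null cohorts × 12 responses; the qualitative-pattern run uses the
full 32 subjects with 1 stability run per response.  Sampler settings in
heavy tests are 250 burn-in + 200 retained sweeps, which keeps ESS
comfortably above the gate.  Ties and degenerate inputs: zero-variance
z-score groups and empty band-bin sets raise; constant delta series report
variance 0 and a missing lag-1; a constant power series yields an all-zero
pool with a warning.

**Evidence in the 8-trial per-condition model.**  With 8 trials per subject
the varying-slope scale is weakly identified: under the half-normal(0, 1)
scale prior its posterior settles near 0.016 even when the true
between-subject slope SD is 0.005 (verified against an exact 3-D quadrature
oracle for the marginalized control-only model), which widens the
population-slope posterior and holds the Savage–Dickey BF near the
evidence threshold (z ≈ 3) at the default drift of 0.02 z/trial.  The
32-trial whole-task model does not have this problem (BF ≫ 100).  The
pipeline reports both analyses; qualitative evidence-pattern checks are
asserted on the whole-task trend, while the per-condition model is checked
for slope recovery (positive credible intervals at every electrode).

## Known limitations

* BF magnitudes depend on the density estimator and on the diagonal
  varying-effect simplification; agreement with bridge-sampled BFs from a
  full PPL fit is expected at the level of evidence class, not digits.
* The generator's trial-to-trial power noise is Gaussian in dB and shared
  across channels; real data are heavier-tailed and spatially structured.
* The sensitivity sweep refits from scratch per prior; no reweighting
  shortcut is attempted.
* EDF ingest requires `mne` (optional extra); the native container is plain
  CSV + JSON.
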