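# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic-data tests do and do not
establish about real recordings.

## The experimental structure being modeled

A session consists of corridor traversals ("trials") with four grating
presentations at fixed positions. Block 1 (default 160 trials) shows the
trained sequence A–B–A–B except on a randomly chosen 10 % of trials,
where the stimulus at position 4 is replaced by the oddball identity
(default a novel grating C); block 2 (default 40 trials) shows the
oddball identity at position 4 on every trial. "Unexpected" presentations
are the block-1 oddballs; "expected" presentations of the same stimulus
are taken from the second half of block 2, after repeated exposure. The
oddball count in block 1 is exactly `round(p·n)`, drawn uniformly without
replacement (the alternative — independent Bernoulli trials — would make
the count itself random; the fixed count matches the stated design and
makes trial bookkeeping exactly reproducible). A shortened variant
(60-trial block 1, 15 % oddballs) mirrors the axonal-bouton imaging
sessions.

## Synthetic session generator

The generator's purpose is to emulate the statistical structure the
analysis assumes, with per-cell ground truth for recovery testing.

**Cell population.** Cells belong to one of four classes (defaults:
25 % highly selective, 15 % intermediate, 30 % non-selective responsive,
30 % unresponsive). Peak response amplitudes are fractions of baseline
fluorescence: 0.25–0.40 ΔF/F for tuned cells, 0.15–0.30 for
non-selective cells, ≤ 0.02 for unresponsive cells. Planted selectivity
is derived from the tuning amplitudes by the same ratio formula the
analysis uses.

**Prediction-error amplification.** Unexpected events multiply the
stimulus amplitude by `1 + g·λ^k`, where `g` (default 1.0) is the
amplification gain, `λ` (default 0.9) the per-exposure decay, and `k`
the number of prior presentations of that identity. The exposure counter
never resets, so late block-2 responses are effectively un-amplified
(λ³⁶ ≈ 0.02). Amplification is planted only in cells whose planted
selectivity exceeds 0.8 **and** whose target amplitude is at least
0.1 ΔF/F: a selectivity ratio computed from two near-zero amplitudes is
noise, not tuning, and such cells carry no detectable response for
amplification to act on.

**Trace rendering.** Event amplitudes (plus a per-cell running-speed
term, a per-animal additive offset, and multiplicative trial-to-trial
jitter of SD 0.25) form an impulse train on the frame grid, convolved
with a peak-normalized double-exponential kernel (rise 0.05 s, decay
0.6 s, a typical fast-indicator scale; the analysis itself never assumes
a kernel). The cell trace is `F0·(1 + signal) + noise` (baseline ~100
a.u., white noise SD 3 a.u.); the measured trace adds `r_np` times a
slow per-animal neuropil trace, with `r_np` drawn from 0.3–0.8.
Omission events carry no drive.

**What the generator does not emulate:** drifting baselines within a
session, correlated noise across cells, spiking nonlinearities and
indicator saturation, eye/brain motion coupling, reward signals. Passing
recovery tests therefore demonstrates the correctness and calibration of
the analysis chain under its own assumptions, not robustness to every
pathology of real recordings.

**Problem sizes.** The default session is 5 animals × 40 cells and
12-s trials (onsets at 1.0/3.6/6.2/8.8 s; 18,000 frames at 7.5 Hz).
Trial duration is shorter than real traversals but preserves the
window/baseline geometry and inter-stimulus spacing relative to the
kernel; more frames would only add runtime.

## Preprocessing decisions

**Registration** is integer-pixel phase correlation (no subpixel stage)
against a reference averaged from 30 evenly spaced 40-frame batches
(mean of all frames below 1,200). Large motion is flagged at > 10 px
displacement or > mean + 3 SD of the session's displacement magnitudes
(the original workflow inspected displacements manually; an automatic
rule is needed for reproducibility). Events losing more than half their
response-window frames to flagged frames are dropped.

**Neuropil model.** The contamination coefficient is estimated by
maximizing an asymmetric Student-t likelihood on the residuals of
`F_meas − r·F_np − b`: ν = 5, scale multiplied by 3 for positive
residuals. Positive residuals are where transients live; giving them a
wide tolerance means the fit tracks the baseline relationship between
cell and neuropil rather than chasing transients. Fitting is IRLS with
the standard t EM weights, alternating `(r, b)` and an EM scale update,
with `r` clipped to [0, 1); convergence tolerance 1e-8 on `r`, cap 100
iterations. On transient-free traces it agrees with ordinary least
squares; on transient-rich traces with bleed-through its bias is several
times smaller (both properties are tested). A constant neuropil trace is
unidentifiable and returns r = 0 with a warning.

**F0** is the smaller component mean of a two-Gaussian mixture fitted to
the trace's value distribution: EM capped at 50 iterations, tolerance
1e-6, deterministic initialization at the 25th/90th percentiles with the
overall variance — repeated fits are bit-identical, and the component
relabeling ambiguity is irrelevant because the minimum of the means is
taken. By default neuropil subtraction runs first and F0 is fitted on
the decontaminated trace (a contaminated baseline would inflate F0 and
shrink ΔF/F); `f0_on_raw=True` restores the literal raw-trace order.

**z-scoring** uses each cell's full-session ΔF/F mean and SD.
Zero-variance cells cannot be z-scored; they are flagged invalid and
excluded from response tables.

## Response windows and classification

Responses are means over the half-open window [onset + 0.4, onset + 2.0)
minus the baseline mean over [onset − 0.5, onset); half-open intervals
prevent a frame from being counted twice. At 7.5 Hz the response window
holds 12 frames and the baseline 3–4.

A numerical subtlety matters here: stimulus onsets can coincide exactly
with frame times, and raw floating-point comparisons then assign the
boundary frame inconsistently across trials (the rounding error of
`trial_start · rate` varies with the trial index). All window-edge
comparisons and onset-frame placements therefore carry a 1 µs tolerance
(`responses.TIME_EPS`) — physically negligible, but without it a
systematic ~0.1 z early-versus-late artifact appears in every responsive
cell.

"Late block 2" is the final `floor(n₂/2)` trials. The t-tests default to
the classical equal-variance form (Welch by flag). For responsiveness,
the default pipeline calls a cell stimulus-responsive if its mean
response crosses the threshold in either the unexpected or the expected
condition. The selectivity reference is the mean late-block-2 response
to base gratings at the mid-corridor positions (A3/B2 in the standard
corridor); cells with a zero denominator are excluded from selectivity
analyses, and raw values beyond ±1 are clipped.

## Hierarchical bootstrap

Cells recorded in the same animal are not independent. Each iteration
resamples animals with replacement, resamples cells with replacement
within each drawn animal (to that animal's original cell count), then
shuffles the pairing by independently swapping each resampled pair with
probability 0.5; the default statistic is the mean paired difference,
and the p-value compares the original-sample statistic against the null
distribution two-sidedly with the +1 correction (p is never 0, and is
monotone in the observed magnitude). The observed statistic is computed
on the original sample, not on resampled-but-unshuffled data — the
latter would mix resampling noise into the observed value.

Calibration is assessed on nested null data in which the animal random
effect is shared between the paired conditions (intraclass correlation
of the *values* 0 or 0.2, matching the generator's additive per-animal
offset), so paired differences are exchangeable under the null; measured
type-I error at α = 0.05 is within [0.03, 0.07] at 1,000 datasets ×
1,000 resamples, with power > 0.8 for a paired shift of one value-SD at
5 × 40 cells. An animal-level shift (a random effect in the differences
themselves) is *not* a null this cell-level test should be calibrated
against — that comparison belongs to across-animal tests, which is why
the single-animal case raises an error pointing to the flat
randomization test.

Confidence intervals are BCa by default (percentile by flag); a constant
sample yields a zero-width interval. Cohen's d uses the pooled SD with
n − 1 weights; a zero pooled SD with unequal means is reported as signed
infinity and flagged.

## Behavior controls

Fast/slow trial splits use the same 0.4–2.0 s window as the calcium
responses and a strict median split (stable sort; lower ⌊n/2⌋ events are
"slow"), so the two sets always partition the events and ties break by
event order. Pupil detection is binary thresholding plus the centroid of
the largest connected region. The pupil outlier filter is a Hampel
identifier: a sample deviating from its 11-sample window median by more
than 3 scaled MADs of the window values is replaced by linear
interpolation between inliers. The window-value MAD (not the residual
MAD) is essential: it keeps smooth trends and curvature from registering
as outliers while still isolating single-sample spikes. On any noisy
trace a robust identifier will occasionally touch a legitimate ~3σ
sample; the tests therefore demand bit-identity only for smooth or
constant traces.

## Determinism

All randomness flows from explicit seeds through `numpy.random.Generator`
(PCG64); identical (config, seed) pairs reproduce trial tables, traces
and statistics tables byte for byte. GMM and IRLS fits use fixed
deterministic initializations.

## Known limitations

- ROI segmentation is out of scope (masks are inputs); registration is
  rigid and integer-pixel.
- The asymmetric-t neuropil model is this package's own concrete
  formulation of "down-weight transients asymmetrically"; its defaults
  (ν = 5, asymmetry 3) were chosen a priori and validated by the
  OLS-agreement and bias properties, not fitted to data.
- The class-wise amplification contrast inherits the classification's
  misassignments near the 0.8 selectivity cutoff; cells that are truly
  amplified but measured as intermediate dilute the intermediate class
  rather than the contrast of interest.
- Generator realism limits are listed above; none of the tests speak to
  indicator nonlinearity or non-stationary baselines.
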