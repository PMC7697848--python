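# Methods

## Signal model and analysis chain

The package analyses epoched single-trial time series around a balance
perturbation at time 0: Cz EEG (−1000..2000 ms, 1 kHz), bilateral medial
gastrocnemius (MG) and tibialis anterior (TA) EMG (−400..1400 ms, 1 kHz),
and vertical ground-reaction forces used only to label step trials.  Epoch
windows are closed on both ends, so the EEG epoch holds 3001 samples and
time 0 maps to a unique sample.

**Step exclusion.**  A trial is a step trial when the vertical load under
either foot falls strictly below 5 N anywhere in (0, 2000] ms.  Only
feet-in-place (nonstep) trials are analysed; participants left with an
empty magnitude cell are excluded from balanced magnitude comparisons but
retained elsewhere.

**ERSP.**  Oscillatory power is measured by convolving the raw epoch with
unit-energy complex Morlet kernels at 10 linearly spaced frequencies from
11.7 to 50 Hz.  The cycle count rises linearly from 3 at the lowest to 6 at
the highest frequency; the Gaussian envelope SD is n_cyc/(2πf) and kernels
are truncated at ±3.5 SD, making the longest kernel ~286 ms.  The 200 time
centers are spaced so this kernel fits inside the epoch at every center
(first = epoch start + W/2, last = epoch end − W/2), giving ~13.6 ms
spacing, referred to nominally as 14 ms.  Power is 10·log₁₀(|W|² + ε) with
ε at the smallest-positive-double scale purely so that zero signal maps to
a finite number; absolute dB levels are preserved (no divisive baseline).
Because the transform is itself band-limited, raw data are not pre-filtered:
60 Hz line noise and sub-Hz drift are rejected by construction.  Beta power
is the dB mean over the grid frequencies inside 13–30 Hz — exactly four on
the default grid (~16.0, 20.2, 24.5, 28.7 Hz; the grid is taken as stated
even though round-number labels like 15/20/24/28 Hz do not lie exactly on a
10-point 11.7–50 Hz linear grid).  Baseline handling is a single
subtraction of the per-trial mean over −400..0 ms; the per-trial baseline
level (≈67 dB on the default synthetic cohort) is stored, and subtracting
twice is a state error.

**EMG envelopes.**  Stages run in a fixed order: 35 Hz high-pass
(third-order Butterworth applied forward–backward, i.e. zero-lag), mean
subtraction over the full epoch (the demeaning window is not dictated by
the procedure definition; full-epoch is the package's choice and is
configurable in principle), half-wave rectification (negatives clipped —
not absolute value), 40 Hz zero-lag low-pass.  Each side is normalized to a
within-participant maximum of 1 over trials and samples, sides are averaged
per trial, and trials averaged within magnitude.  Values can exceed [0, 1]
only by low-pass overshoot, which is bounded by the filter's step response
(a few percent).

**Time-bin statistics.**  Peaks are signed maxima of the
baseline-subtracted condition-averaged beta trace over the overall
(0–400 ms), early (50–150 ms) and late (150–250 ms) bins.  Pre-vs-post and
across-magnitude comparisons use additive (no-interaction) two-way ANOVAs
with participant as the second factor, the natural model for one
observation per participant × level cell; Tukey HSD post hocs use the
studentized range on the additive-model residual mean square.  Because
balance ability is a between-participant covariate, it cannot enter a model
alongside participant fixed effects; the ability model is
peak ~ magnitude + ability with participant-clustered standard errors,
displayed alongside a univariate regression of participant-mean peak on
ability (whose R² equals the squared Pearson correlation).  Confound
checks regress ability and large-magnitude peaks on the percentage of
successful nonstep large trials, flagging degenerate (constant) predictors
instead of fitting them.

**Wavelet-domain functional statistics.**  Condition-averaged traces are
shortened to 128 samples: beta traces take the 128 consecutive ERSP grid
samples starting at the center nearest −400 ms (spanning ~1790 ms — hence
the "~1400 ms" endpoint), EMG envelopes are uniformly decimated over
−400..1400 ms; both are re-baseline-subtracted over their pre-onset
samples.  The discrete wavelet transform uses third-order coiflets (18-tap
filters) at level 2 with symmetric half-point extension and non-periodized
convolution — the only common boundary mode that maps 128 samples to 160
coefficients (blocks [44, 44, 72]; len_k = ⌊(n_k−1)/2⌋ + 9).  Coefficients
are flattened [approx-L2, detail-L2, detail-L1]; reconstruction is exact to
machine precision and verified in the tests against an independently coded
direct-convolution transform.

Per-coefficient one-sample t-tests across participants use a Bonferroni
per-test α of 0.05/160 = 0.0003125; the inverse transform of the
significant coefficient means gives a curve on which any nonzero value is a
significant departure from baseline.  Zero-variance coefficients (possible
only in degenerate synthetic input) are declared significant iff their mean
is nonzero, with a warning.  Per-coefficient magnitude × participant ANOVAs
gate Tukey contrasts of each level against the small perturbation at
α = 0.05 / (number of significant F tests), recomputed per signal.  Before
the ANOVAs (only — t-tests use raw values), each coefficient's sample is
screened with the Lilliefors Kolmogorov–Smirnov normality test at α = 0.05;
failing coefficients are Box–Cox transformed after a positivity shift of
(1 − min) when min ≤ 0, with the shift and fitted λ recorded.  The
transform affects only the significance decisions; contrast curves
reconstruct mean differences in original units, so a Box–Cox rescaling
cannot silently change the physical scale of a curve.

**Onsets and offsets.**  On a significance or contrast curve, onset is the
first post-onset sample strictly above threshold and offset the first later
sample strictly below it (0.75 dB for beta, 0.02 normalized units for EMG).
The thresholds exist to step over the small ripples the coiflet places on
either side of each reconstructed peak; a larger threshold can never give
an earlier onset.  Note the offset is the *first* subsequent crossing: a
curve that dips transiently between early and late peaks reports that dip,
not the final return to baseline.

## Synthetic cohort: what it emulates and what it does not

Defaults: 19 participants × 8 trials × 3 magnitudes (456 trials).  Each
EEG trial is 1/f-shaped background noise (unit SD, exponent 1) plus
fixed-phase-per-trial 60 Hz line noise (amplitude 0.5) plus a beta-band
burst: a 20 Hz carrier with random phase, amplitude-modulated by the sum of
an early Gaussian envelope (center 100 ms, SD 30 ms, amplitude 0.42
noise-SD units), a late Gaussian (center 200 ms, SD 45 ms, amplitude 0.6),
and a smooth sustained plateau (amplitude 0.32) whose duration grows with
magnitude (250/400/950 ms) — producing the magnitude-graded return-to-
baseline times.  The whole envelope is gated at the 50 ms onset and rises
linearly over 40 ms: an instantaneous step would leak backward through the
~286 ms analysis kernel and bias detected onsets early by more than one
grid sample, which no detector could undo.  Magnitude gains are 1 / 1.45 /
2.1 (ties are allowed by validation so that an equal-gain level can serve
as a built-in null condition; only decreasing gains are rejected).  Only
the late component carries the ability coupling,
amplitude × (1 + s·ability) with s = −0.7: lower ability, larger
late-phase beta.  Ability is uniform on [0.1, 1] to span low-to-ceiling
performance without degenerate zeros.  A height-like multiplier
(SD 0.05 around 1) jitters the medium/large responses.  MG bursts start at
100 ms and scale with magnitude; TA adds an antagonist burst slightly later
and a second agonist-like burst after platform deceleration (500 ms).  EMG
is modeled as envelope-modulated broadband noise, so the rectify-and-
smooth pipeline recovers the envelope.  Step trials occur only in the large
magnitude (probability 0.45 by default); a stepping foot's load ramps to
zero around a random time between 300 and 1200 ms.

Scale calibration is cosmetic: a global EEG multiplier of 1700 puts
baseline beta power near the realistic 67 dB regime, and all statistics are
invariant to it.  The evoked-amplitude defaults put grand-average peaks at
roughly 4.5/7/10 dB across magnitudes.  This regime matters for onset
detection: the coiflet reconstruction's leading ripple scales with peak
height, and above ~13 dB it exceeds the 0.75 dB threshold, so the fixed
published threshold presupposes responses of this order.  The defaults are
free parameters — the real study reports no numeric effect sizes in dB —
chosen once for comfortable statistical power at n = 19 (the ability
coupling of −0.7 yields late-bin association p < 1e-3 across a range of
cohort draws).

What passing tests show: the pipeline recovers injected onsets to one grid
sample, orders magnitudes correctly, detects the ability coupling with the
right sign, keeps the family-wise error of the coefficient t-tests at or
below its nominal level, and is numerically faithful (exact coefficient
bookkeeping, perfect reconstruction, exact dB law).  What they do not show:
robustness to real-EEG nuisances absent from the generator — eye and
movement artifacts, non-stationary baselines, electrode noise, inter-trial
dependence, genuinely burst-like (non-sinusoidal) beta dynamics, or
kinematic structure in the force traces beyond the 5 N criterion.

## Numerical choices and degenerate inputs

dB floor = smallest positive normal double (zero signal maps to a large
negative but finite dB).  ERSP grid centers are evaluated at the nearest
raw sample.  The baseline window uses centers in [−400, 0) ms.  Balanced
designs are required by the ANOVA (unbalanced input raises); single-level
factors contribute zero SS and the model reduces to the one-way case.
F statistics with zero residual variance are reported as +inf (p = 0) when
the effect SS is nonzero and 0 (p = 1) otherwise.  Tukey with zero residual
variance declares any nonzero difference significant.  Constant coefficient
samples skip the normality gate with a flag.  All randomness flows from a
single integer seed through numpy Generators; equal configurations produce
bit-identical cohorts.

## Known limitations

* The DWT path is fixed to coif3/level 2/128 samples — other bases and
  lengths are not supported (deliberately, matching the analysis design).
* The ability model's participant-clustered standard errors are one
  defensible reading of "controlling for participant" alongside a
  between-participant covariate; a literal participant fixed effect would
  be collinear with ability.
* Onset detection reports the first threshold crossing; bimodal curves
  whose valley dips below threshold yield an early "offset".
* The EMG demeaning window (full epoch) is an assumption; results are
  insensitive to it for zero-mean broadband EMG.
* Type-I calibration of the magnitude ANOVA is established on simulated
  null peak tables (1000 replicates, 6 participants) rather than full
  EEG cohorts: the property belongs to the ANOVA, not the signal chain, and
  the scaled-down design keeps the check cheap.
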