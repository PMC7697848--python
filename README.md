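# betabalance

Analysis of perturbation-evoked cortical beta oscillations and muscle
activity during reactive balance recovery, with a synthetic cohort generator
that makes the whole pipeline testable without any recordings.

When a standing person's support surface suddenly translates, sensorimotor
cortex produces a burst of beta-band (13–30 Hz) oscillatory power over the
Cz electrode beginning ~50 ms after perturbation onset, followed by
balance-correcting muscle activity (~100 ms).  Both scale with perturbation
difficulty, and the late phase (150–250 ms) of the beta response is larger
in people with lower balance ability.  This package implements the full
analysis chain used to establish those findings, for researchers in
posture/EEG who want a reproducible, tested reference implementation:

* **Single-trial ERSP** — Morlet wavelet convolution on raw Cz epochs
  (−1000..2000 ms, 1 kHz): 10 linearly spaced frequencies 11.7–50 Hz, cycle
  count rising linearly 3 → 6, power in dB (`10·log₁₀|W(t,f)|²`) at 200
  time centers ~14 ms apart.  Beta power is the dB average over the four
  grid frequencies inside 13–30 Hz, baseline-subtracted by the per-trial
  mean over −400..0 ms.
* **EMG envelopes** — 35 Hz third-order zero-lag Butterworth high-pass,
  mean subtraction, half-wave rectification, 40 Hz low-pass; normalized to
  a within-participant, within-side maximum of 1, bilaterally averaged,
  then trial-averaged per perturbation magnitude.
* **Time-bin statistics** — peak beta power in the overall (0–400 ms),
  early (50–150 ms) and late (150–250 ms) bins; additive two-way ANOVAs
  (magnitude × participant) with Tukey HSD post hocs; linear models of peak
  power on balance ability; trial-count confound regressions.
* **Wavelet-domain functional statistics (wfANOVA-style)** —
  condition-averaged traces shortened to 128 samples (−400..~1400 ms) and
  expanded on a coif3 level-2 basis with symmetric extension (128 samples →
  160 coefficients in blocks [44, 44, 72]); coefficient-wise one-sample
  t-tests (Bonferroni, per-test α = 0.05/160 = 0.0003125) or magnitude ×
  participant ANOVAs with Tukey contrasts vs the small perturbation
  (Bonferroni-corrected by the number of significant F tests);
  significant coefficients are inverse-transformed into time-domain
  significance/contrast curves, on which any nonzero value is a significant
  effect.  Onsets/offsets are threshold crossings (0.75 dB for beta, 0.02
  normalized units for EMG) chosen to step over the coiflet reconstruction's
  small leading ripples.
* **Synthetic cohort** — 19 participants × 8 trials × 3 magnitudes of Cz
  EEG (beta burst with early/late Gaussian envelopes on 1/f + 60 Hz line
  noise), bilateral MG/TA EMG, and vertical ground-reaction forces with
  step trials (a foot unloading below 5 N within 2 s) in the large
  magnitude.  Every injected parameter is recoverable ground truth.

## Worked example

```python
from betabalance import (
    CohortConfig, simulate_cohort, trials_to_epochset, filter_nonstep,
    compute_ersp, beta_timecourse, subtract_baseline, average_by_condition,
    compute_time_bin_peaks, magnitude_anova,
)

cfg = CohortConfig(seed=1)
trials, participants = simulate_cohort(cfg)
epochs, counts = filter_nonstep(trials_to_epochset(trials, cfg, "Cz"))
bt = subtract_baseline(beta_timecourse(compute_ersp(epochs)))
avg = average_by_condition(bt)
peaks = compute_time_bin_peaks(avg)
res = magnitude_anova(peaks[peaks["bin"] == "overall"])
print(res.factor_F["magnitude"], [r["significant"] for r in res.posthoc])
```

On the default cohort at seed 1 this prints a magnitude F ≈ 175.6 with all
three Tukey contrasts significant — peak beta power rises with each step in
perturbation magnitude, as injected.  The same run recovers a baseline beta
level of 67.0 dB, a reconstructed beta onset of 43.1 ms against the
injected 50 ms (one ~14 ms grid sample), an MG muscle onset of 110 ms
against the injected 100 ms, and a late-bin ability slope of −2.56 dB per
unit ability (p ≈ 4.6 × 10⁻⁴, univariate R² ≈ 0.43): lower balance
ability, larger late-phase beta power.

Or from the shell:

```
betabalance --outdir run --seed 1 run      # simulate → ersp → emg → binstats → wfa → report
cat run/report.json
```

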