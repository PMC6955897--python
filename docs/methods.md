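# Methods

This note documents the models, conventions and design choices behind
`avmsi`, in the spirit of a statistical software appendix.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Task and schedule model

A session is `n_blocks` blocks; each block presents
`trials_per_condition_per_block` auditory (A), visual (V) and audiovisual
(AV) stimuli in a per-block shuffled order.  Defaults are 8 blocks × 34
trials per condition, a 60 ms visual disk, an ~180 ms auditory word, and
2048 Hz sampling.

**Fixation/ISI convention.** The 1000–3000 ms fixation interval precedes
each stimulus.  Because the source design does not say whether the interval
is onset-to-onset or offset-to-onset, we fix one reading: the
onset-to-onset gap equals (previous stimulus duration + a uniform
1000–3000 ms fixation draw).  The generated mean gap is therefore
~2000 ms + 140 ms (the mean stimulus duration), which the tests check
directly.  AV stimuli are exactly simultaneous; no stimulus-onset asynchrony
is modelled.

## EEG signal model

A recording is baseline noise plus per-condition templates inserted at event
onsets:

* **Templates.** Gaussian components peaking at 120 ms (width 16 ms):
  a parieto-occipital positive visual component (maximal at PO7/PO8, then
  P7/P8) and a centro-parietal negative auditory component (maximal at
  CPz/Cz).  The AV response is `A + V + msi_gain × interaction`, where the
  interaction is a narrower Gaussian hard-windowed to 100–140 ms, negative
  at P7/P8/PO7/PO8 and positive at CPz/Cz — i.e. *subadditive*: it pulls the
  AV response below the unisensory sum at both clusters.  `msi_gain`
  defaults to 1.0 (control) and 0.3 (SCNP), and `group_scaling` to 1.0 /
  0.8, so the control group shows both larger ERPs and more integration.
  With `msi_gain = 0`, AV equals A + V exactly — the superposition null.
* **Noise.** White Gaussian (default SD 15 µV per sample) plus 1/f-amplitude
  noise (default SD 5 µV) per channel, independent across channels.  The
  source design specifies no noise model; these values give realistic
  single-trial SNR (a 6 µV component against ~16 µV noise) while keeping
  272-trial averages clean.  Real EEG has spatially correlated noise, alpha
  rhythms and non-stationarities that this model omits — passing tests show
  the pipeline's statistical behaviour under its stated assumptions, not
  performance on recorded data.
* **Artifacts.** Blink-like 200 ms raised-cosine transients (default
  150 µV at 2% of trials) on the frontal channels, present solely to
  exercise the ±100 µV rejector.

The default montage is the analysis electrodes (P7, P8, PO7, PO8, CPz, Cz,
Pz), the frontal artifact carriers (Fp1, Fp2), and POz/Oz.

## Reaction-time model

Unisensory channels are Gaussian: control A ~ N(310, 55) ms,
V ~ N(245, 50) ms; the SCNP group adds 30 ms to both locations.  Gaussians
keep every moment of the architecture analytically checkable; empirical RT
skew is not reproduced and does not matter for the quantile-based analyses.

* **Race.** AV = min of the two channel draws with correlation ρ
  (default 0.2).  ρ = 0.2 puts the expected V−AV redundancy gain at
  ~6 ms, matching typical group-level gains in this paradigm.  Any race —
  whatever ρ — satisfies the Miller bound, because
  P(min(X,Y) ≤ t) ≤ P(X ≤ t) + P(Y ≤ t) unconditionally.
* **Coactivation.** The race minimum minus a fixed gain (default 30 ms for
  controls, 0 for SCNP), a deliberately simple stand-in for evidence
  pooling: it shifts the whole AV distribution left of the bound at the
  fast quantiles, where violations are expected.
* **Between-subject variability.** Each participant gets a shared offset
  (SD 20 ms) and a per-condition jitter (SD 12 ms).  Without these, cell
  means collapse to sampling error and *every* post-hoc contrast becomes
  significant; with them, the generator reproduces the canonical pattern
  (A vs. V and A vs. AV significant, V vs. AV not).

## ERP pipeline conventions

* **Filtering.** Butterworth high-pass at 1.6 Hz and low-pass at 45 Hz,
  orders derived from the nominal 12 and 24 dB/octave slopes at
  6 dB/octave/pole and *halved* because both stages run forward–backward
  (zero phase), so the two-pass roll-off matches the nominal slope.  The
  cutoff is the single-pass −3 dB point (−6 dB after two passes); tests pin
  both conventions.
* **Epoching.** −100 to +500 ms; `pre = round(0.1·fs)`,
  `post = round(0.5·fs)` samples, start-inclusive — 1229 samples at
  2048 Hz.  Baseline correction subtracts the mean of −100–0 ms (standard
  practice; the pre-stimulus window exists for this purpose; switchable
  off).  Events too close to a recording edge are dropped with a warning
  and counted, so kept + rejected + dropped always equals scheduled.
* **Artifact rejection.** An epoch is rejected when any |sample| strictly
  exceeds 100 µV on any channel ("±100 µV" read as the allowed range).  If
  a condition loses all epochs the pipeline raises rather than averaging
  nothing.
* **Reference and resampling.** Data are analysed as generated/recorded at
  full rate; no re-referencing or downsampling is applied by default.
* **Topographic selection.** Candidate bins (default width 40 ms) slide on
  a 10 ms grid over 0–200 ms; the winner maximizes (strongest positive +
  strongest negative channel mean) of the AV grand average; the top 4
  positive and top 2 negative channels form the clusters.  Flat input is an
  error.  The 0–200 ms constraint restricts selection to early, modality-
  specific latencies.

## Statistics

* **Mixed ANOVA.** Classic split-plot decomposition on one value per
  subject × within-level: the between factor is tested against
  subjects-within-groups, the within factor and interaction against the
  subject × within residual.  Aggregation to cell means (matching the
  (2, 44)/(1, 22) degrees of freedom of a 12 + 12 × 3 design) is the
  assumed input.  No sphericity correction by default (uncorrected dfs are
  reported); Greenhouse–Geisser is available by flag.  A constant response
  raises a degenerate-design error; a zero-SS effect over a zero error term
  (e.g. SUM ≡ MSI exactly) reports F = 0 rather than 0/0.  Partial η² is
  `F·df1/(F·df1 + df2)`, identical to `SS_eff/(SS_eff + SS_err)` for
  single-error-term effects.  The implementation is cross-checked against
  pingouin and a hand sums-of-squares oracle in the tests.
* **Tukey HSD.** Pairwise condition differences over the studentized-range
  distribution, using the repeated-measures error term of the ANOVA (the
  subject × condition residual) — the published analysis does not state its
  error term, so we use the one the omnibus within-effect was tested
  against.
* **Race-model testing.** Quantile latencies use plotting positions
  p_i = (i − 0.5)/n with linear interpolation between order statistics
  (ties stable-sorted), the convention of the standard algorithmic
  tutorials for this test; an Ulrich-style probability grid is the default
  (deciles 0.1…1.0).  The bound B(t) = min(1, F_A + F_V) is computed per
  participant on the pooled A∪V latency grid and inverted at the same
  probabilities (first attainment at plateaus).  Tests compare latencies at
  fixed probabilities (not probabilities at fixed latencies), and the
  select-then-test procedure — paired t only where the group-mean AV CDF is
  faster than the bound — is reproduced as published; an all-quantile
  Holm-corrected report is available but off by default.  The bound is
  averaged only for display; tests always use per-participant values.
* **Method 2 / time course.** The fixed-bin (20 ms, 60–180 ms) ANOVA
  sequence is the default deterministic reading of the published
  "Monte Carlo" time-course analysis, whose exact resampling scheme is not
  recoverable; a label-permutation null (`method1_permutation`) is provided
  for users who want a resampled reference.  No multiple-testing correction
  across bins by default, matching per-bin reporting; Holm by flag.

## Problem sizes in the replicate studies

The operating-characteristic studies in `avmsi.experiments` scale the design
down while preserving its structure, chosen once as follows: the
superposition-null calibration uses 1000 replicates of a 4-channel, 256 Hz,
one-block (8 trials/condition), 6 + 6-participant cohort; race
discrimination uses 100 replicates of 12 participants at the full 272
trials per condition; localization recovery uses 12 + 12 participants at
512 Hz with 2 blocks (68 trials per condition).  These sizes keep whole-
suite runs at desk scale while leaving the tested effects comfortably
powered (or, for null calibrations, unbiased).

## Known limitations

* Synthetic EEG omits spatially correlated background activity, ocular/
  muscle artifacts beyond the stylized blink model, and any head-model
  forward projection; electrode labels are nominal, not positioned.
* The Gaussian RT channels cannot express slow-tail phenomena (lapses,
  ex-Gaussian tails); conclusions about quantile-test calibration transfer
  to real data only to the extent the tails behave.
* The split-plot ANOVA assumes (near-)balanced groups and complete
  within-subject data; there is no mixed-model fallback.
* The zero-phase filter smears sharp temporal boundaries by a few
  milliseconds, so an interaction hard-windowed to 100–140 ms can produce
  weak spillover effects in the adjacent 140–160 ms bin.
* One open naming discrepancy in the source analyses (negative cluster
  described once as "CPz and Pz" but tabulated as "CPz, Cz", and a
  tabulated "150–150" bin) is resolved in favour of the tabulated
  100–140 ms / CPz, Cz selection.
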