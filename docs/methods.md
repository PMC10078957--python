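# Methods

## The decoding problem

A two-site electrotactile BCI delivers 0.25 ms current pulses alternately
(pseudo-randomly) to the dorsal (D) and volar (V) right forearm at a
700 ms inter-stimulus interval while the user silently counts the stimuli
at one *attended* site. Attention modulates the amplitude of the evoked
somatosensory potential (SEP). The decoder's task is binary: from the EEG
of a single channel, decide whether the user is attending D or V. One
decision consumes `n_avg` stimuli at *each* site (the averaging depth), so
decision time is `T = 2 · n_avg · ISI` — 4.2 s, 7 s and 14 s for 3, 5 and
10 averaged trials.

## Stimulus schedule

Blocks of 300 stimuli are divided into five sub-blocks of 60. Per block we
draw five per-sub-block D counts uniformly from 25–35 constrained to sum
to 150, which makes the D/V split exact per block and hence over the whole
session (900/900); each sub-block's order is a uniformly shuffled multiset,
redrawn until no same-site run exceeds 3 — including runs that straddle
sub-block boundaries, so a global scan of the event list finds none. The
attended site alternates across blocks; the starting site is drawn from
the seed (or fixed). Onsets live on the 1,200 Hz sample clock: 700 ms
(840 samples) within a sub-block, a 10 s pause after each sub-block, and a
2 s warm-up before the first stimulus so its baseline window exists.
Generation is rejection sampling; the feasible region is large enough that
a draw practically never needs more than a few attempts.

## Synthetic EEG

The generator is a test bed, not a forward model. Each stimulus adds a
transient response — Gaussian lobes P1 (+2 µV, 50 ms, width 15 ms), N1
(−4 µV, 120 ms, 25 ms), P3 (+3 µV, 280 ms, 60 ms) — on the five scalp
channels with contralateral weighting (C3 = CP3 = 1.0, Cz = 0.8,
Pz = 0.6, C4 = 0.4; Fp1 carries no SEP). Attention multiplies the attended
site's whole template by `attention_gain` (default 1.5). Background noise
is 1/f (spectral shaping, exponent 1) at `noise_sd_uV = 10` µV per
channel — a typical ongoing-EEG amplitude that puts the SEP3 decoder in a
sensitive mid-accuracy regime rather than at ceiling or chance. Blinks are
Poisson-timed 300 ms Hann lobes, 120 µV on Fp1 with fixed small
propagation weights to the scalp. All randomness flows from one seed.

The published waveforms are shown but not numerically parameterized, so
the template amplitudes and channel weights above are package conventions.
What the generator deliberately omits: habituation and latency jitter,
line noise (the acquisition chain notch-filters at 50 Hz), volume-
conduction realism, non-blink artifacts (EMG, electrode drift), and
between-subject variability. Passing tests therefore demonstrate that the
*pipeline* is correct and calibrated — at chance when no effect exists,
monotone in averaging depth when one does — not that human data would
yield any particular accuracy.

## Preprocessing

Order is fixed: filter → epoch → baseline → reject. The bandpass is a
2nd-order Butterworth, 0.1–25 Hz, applied zero-phase (forward–backward)
by default since the analysis is offline; a causal mode exists for
pseudo-online replay. Epochs are half-open windows of 600 samples,
[onset−120, onset+480), stimulus at index 120; the baseline mean of
samples 0–119 is subtracted per channel. Rejection scans the full 500 ms
epoch and is strict: an epoch is dropped only if |amplitude| *exceeds*
50 µV on a scalp channel or 80 µV on Fp1 (boundary-equal values kept);
the 50 µV rule does not apply to Fp1, which has only its own 80 µV rule.

## Averaging, balancing, difference waves

Kept epochs are partitioned by (attended, stimulated) site into ADSD,
ADSV, AVSD, AVSV (450 each per full session before rejection).
"Consecutive" averaging means non-overlapping groups in acquisition
order — not sliding windows — because that matches the group-count
arithmetic and is executable online. With `m = min_cluster ⌊size/n_avg⌋`,
every cluster is truncated *from the end* to `m·n_avg` trials, giving
equally many groups per cluster. Group averages keep the 480-sample
post-stimulus window and are decimated by 8 (every 8th sample, starting at
the first post-stimulus sample) to 60 samples at 150 Hz; plain decimation
is safe under the 25 Hz low-pass, and block-averaging is available as an
alternative via the `factor` argument. Difference waves subtract V-stim
from D-stim sERPs within a condition; the between-condition ADAV wave is
the difference of *class means* of those difference waves.

## Features and threshold selection

F1 concatenates the i-th consecutive sERP pair, D-stim half first
(120 features); F2 is the i-th difference wave (60 features); each i gives
one example per class, so the per-group (not condition-mean) reading of
the difference waves is used — cross-validation needs many examples. The
selection sweep rectifies the ADAV wave and raises a threshold from 0 in
0.1 µV steps, stopping at the first empty selection; index sets are nested
and shrinking. FS1 applies the selected indexes to both halves of F1, FS2
to F2; threshold 0 reproduces F1/F2 exactly.

How the final threshold is picked is genuinely open in the source
procedure (its description both places fine-tuning on the test set and
asserts train/test independence). The default here is the leakage-free
reading: inside each outer fold, an inner leave-one-out on the training
fold scores every threshold and the smallest threshold attaining maximal
inner accuracy wins (ties go to more features). A fixed-threshold mode and
a report-the-max mode (`selection="max"`, which lets the ADAV wave see all
data) exist for sensitivity analysis and are not the default. If a fold's
chosen threshold selects nothing, it falls back to threshold 0 so the
classifier always receives features.

## Classification and cross-validation

SVM: Gaussian kernel, box constraint 1, kernel scale from the median
pairwise Euclidean distance of a seeded subsample (≤1000 points; the full
set when smaller), i.e. `gamma = scale⁻²`; identical points make the
heuristic degenerate and raise. LDA: SVD solver. No feature
standardization by default (optional, fit on training folds). The LOO unit
is one averaged-group example; each fold recomputes ADAV, threshold and
kernel scale from its training fold. A decision value of exactly 0 maps to
class AD (fixed tie rule). Confusion matrices are reported in percent of
all folds: TP(D)/TP(V) correct D-/V-attention folds, FP(D)/FP(V) the
misclassified ones; accuracy = TP(D) + TP(V).

## ITR and statistics

Bits per decision follow the Wolpaw formula with the P→0/1 limits handled
exactly; the printed ceiling rates (14.29/8.57/4.29 bpm) are the P = 1
limit, 60/T. Accuracy panels are compared with two-way repeated-measures
ANOVA (pingouin backend) requiring a complete balanced design;
Greenhouse–Geisser correction applies to factors with >2 levels and both
corrected and uncorrected df are reported. A zero-variance panel is
reported as F = 0 rather than NaN. Wilcoxon post-hocs use the Pratt
zero-handling rule; all-zero differences are flagged degenerate and
non-significant. Bonferroni thresholds are α/m (0.017 for 3 comparisons,
0.0083 for 6).

## Problem sizes and numerical choices

The behavioural test battery uses: 10 seeds × 4-block sessions (exactly
200 examples at SEP3) for the chance-level calibration, asserting the
median accuracy lies in the binomial 95% interval around 50% for n = 200;
and 10 seeds × full 6-block sessions for the averaging-effect check
(median accuracy non-decreasing SEP3 → SEP5 → SEP10). Fewer blocks make
the class labels confound with per-block slow-noise differences, which is
why the monotonicity check uses the full alternating 6-block design.
Floating-point comparisons in tests use exact equality only where the
computation is exact (slicing, concatenation, counting) and tolerances of
~1e-10 elsewhere.

## Limitations

Single-channel decoding only (no multichannel fusion); no ocular
regression/ICA; no re-referencing; EDF is read-only (recordings are
written as HDF5/TSV); accuracies on synthetic data characterize the
pipeline under the generator's assumptions and do not predict human
performance.
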