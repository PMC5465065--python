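# Methods

`zfeeg` analyses multichannel skin-surface EEG from adult zebrafish in an
acute PTZ (pentylenetetrazole) seizure model, and ships a synthetic-data
generator that reproduces the statistical structure of such recordings so
that every analysis stage can be validated against exact ground truth.
This note documents the models, the defaults and why they were chosen,
and what the synthetic validation does and does not establish.

## Session model

A recording session follows a fixed timeline (`TimelineMarks`): a control
window (default 0–600 s) used only for baseline statistics, convulsant
injection at 600 s, a 90-s stabilization window whose data are excluded
from analysis, and a 3600-s total session. All latencies are measured
from the injection time. These defaults are configurable; the invariant
`control_start < injection_time < stabilization_end ≤ session_end` is
enforced.

The montage maps channel 1/2 to the right/left telencephalon and
channels 3/4 to the posterior head over the midbrain. Reports of
posterior-onset seizures in this model sometimes attribute them to the
cerebellum even though the electrodes sit over the midbrain; the region
labels are therefore configurable (`localize.Montage`) and the default
labels say "posterior" rather than committing to either name.

## Synthetic EEG generator

**Baseline.** Pink (1/f) noise, low-passed at 40 Hz (4th-order
Butterworth, zero-phase), matching quiet skin-surface recordings whose
spectral content stays below 40 Hz and whose peak-to-peak amplitude stays
under 20 μV. The noise is scaled so the median 2-s sliding-window
peak-to-peak amplitude is 15 μV; the scale factor between unit variance
and median 2-s peak-to-peak (5.04) was measured once over long
realizations and is stable to ~1% across sampling rates of 200–1000 Hz.

**Ictal classes.** Two waveform classes are planted:

* *theta* (5–7 Hz): an amplitude-modulated sinusoid; the envelope wanders
  between 60% and 100% of the peak at 0.1–0.3 Hz. High-amplitude theta
  runs are the generalized-seizure signature in this model.
* *spike_wave* (2–3 Hz): a repeating complex of a 40-ms biphasic spike
  followed by a positive half-sine slow wave filling the rest of the
  cycle, with ±10% per-cycle gain jitter; the absence-like signature of
  longer, SE-like runs. The kernel is an invented but conventional
  spike-and-slow-wave morphology; its spectral peak sits at the complex
  repetition rate.

Event amplitudes are drawn uniformly from 60–200 μV peak-to-peak, well
above the ≤20 μV baseline, with 0.5-s raised-cosine edges so planted
onset/offset times are sharp.

**Per-animal statistics** (`AnimalProfile`): event counts are
zero-truncated Poisson, with the rate λ solved so the *truncated* mean
equals the target (for small means plain truncation would bias the mean
upward, e.g. 3.38 → 3.50). Durations and latencies are log-normal with
CV 0.5, parameterized by their arithmetic means — non-negative and
right-skewed, the simplest shapes consistent with summary means and box
plots. Events are placed after the stabilization window with a minimum
5-s gap and never overlap on any channel; the first event's onset is
injection time + latency draw, later events are spread uniformly over
the remaining free time. Each event is focal (onset channel only) with
probability 0.3, otherwise generalized to all four channels with
per-channel onset delays uniform in 0.1–2.0 s. Onset channels are drawn
from a per-sex probability vector.

**Status-epilepticus events.** With per-animal probability `se_prob`,
one event is an SE-like event with duration uniform in 310–420 s. Because
the cohort's mean event durations *include* such events, the non-SE
log-normal component is re-centred so that the overall per-event mean
stays at the profile's stated mean:
`m_non_SE = (c·m − p_SE·m_SE) / (c − p_SE)` with `c` the mean count.
Without this, planting SE events on top of a log-normal already centred
at the cohort mean would inflate the overall mean by ~15%.

**The study preset** (`paper_cohort`): 8 males + 9 females with 1 + 2
non-responders (17 animals, 3 without seizures). Responder profiles:
mean counts 6.50 / 3.38 (male / female), mean durations 79 s / 88 s,
mean latencies 269 s / 462 s, SE probabilities 0.50 / 0.25. Onset
probabilities put 32% on the right and 39% on the left telencephalon for
both sexes (71% telencephalic in total); the posterior remainder is
19% right-posterior for males and 24% left-posterior for females, with
the residual mass (10% / 5%) on the opposite posterior channel — the
anterior/posterior split is reported, the left–right split of the small
posterior remainder is an assumption.

**Sampling rate.** Default 500 Hz (comfortable margin over the 55 Hz
analysis band); cohort-scale validation experiments run at 250 Hz, which
retains full fidelity for a 55 Hz band while quartering the cost of a
30-seed × 14-animal × 1-h experiment. The rate is a parameter everywhere
(minimum 200 Hz).

**What the generator does not emulate:** anaesthesia-depth drift,
opercular-movement and electrode-drift artefacts, channel cross-talk,
non-stationary baseline, and any biophysical forward model of the fish
head. Passing recovery tests therefore demonstrates that the analysis
stages are correct and well-calibrated *given* the assumed signal and
noise structure — not that the detector would reach the same sensitivity
on real recordings with artefacts.

## Acquisition band-pass

0.1–55 Hz, chosen to exclude 60 Hz line noise, realized as a Butterworth
band-pass applied forward–backward (zero phase). The default order is 14:
with a 55 Hz edge only ~5 Hz from the line frequency, lower orders do not
reach 20 dB of attenuation at 60 Hz after the forward–backward pass
(a 4th-order band-pass reaches only ~10 dB). Order and edges are
configurable through `FilterSpec`.

## Seizure detection

The screening rule — high-voltage repetitive discharges faster than
2.5 Hz with polyphasic spike/wave complexes — is automated as the
conjunction of:

1. **Amplitude:** the rectified, 0.5-s-smoothed envelope exceeds
   `k × MAD` of the same channel's pre-injection control window
   (default `k = 4`). The MAD is robust to any stray transients in the
   control window. The 0.5-s smoothing window covers at least one full
   cycle of the slowest (2 Hz) class; a shorter window lets the
   within-cycle amplitude variation of spike-wave complexes fragment one
   discharge into many candidates.
2. **Repetition rate:** suprathreshold peaks of the rectified signal,
   counted with a 0.1-s refractory spacing, arrive at more than 2.5 per
   second in a centred 2-s window. The refractory spacing counts one peak
   per discharge complex phase rather than per filter-ringing
   oscillation; a 2 Hz spike-wave run still yields ≥4 counted peaks per
   second (spike + wave), whereas a 1 Hz spike train yields ≤2 and is
   rejected.

Candidates are restricted to t ≥ stabilization end, merged per channel
when closer than 2 s (`merge_gap`), unified across channels on any
temporal overlap (a propagating discharge is one seizure), and discarded
below 5 s. Classification takes the dominant Welch-spectrum peak of the
onset channel over 1–40 Hz: theta if in [4.5, 7.5] Hz, spike-wave if in
[1.5, 3.5] Hz, otherwise "other". Events strictly longer than 300 s are
flagged SE-like. Spread is "generalized" only when all four channels are
involved — the strictest reading, since no channel-count cut-off between
focal and generalized is established for this montage.

`k` is exposed rather than asserted: the implicit amplitude threshold of
a human screener is unknowable, and `k = 4` was chosen from the baseline
noise model (4 × MAD ≈ 8 μV, far above baseline envelope excursions yet
half the weakest planted event envelope).

## Time–frequency analysis

Complex Morlet CWT with centre frequency ω0 = 6 (the standard
admissibility-respecting value), delegated to PyWavelets (`cmorB-C` with
B = 2, C = ω0/2π — the exact mapping of ψ(t) = π^{-1/4} e^{iω0 t}
e^{-t²/2}). The frequency grid is 100 log-spaced points over 0.5–50 Hz.
Edges inside half a wavelet width (ω0/2πf seconds) are zeroed as the
cone of influence. The global wavelet spectrum is the time-average of
power. Onset confirmation declares the earliest channel whose
class-band power exceeds 10× its pre-event median, with the reference
floored at 0.1% of the in-event peak so a numerically silent pre-event
window cannot let the wavelet's Gaussian tails trigger spuriously;
simultaneous crossings resolve to the lowest channel index.

## Skin–electrode impedance model

The electrode–skin interface is modelled as
`Z(ω) = R_s + (R_sub ∥ 1/(jωC_sub)) + (R_ct ∥ Z_CPE)` with
`Z_CPE = 1/(Q(jω)^n)`, `n ∈ [0, 1]`: a series/solution resistance, a
subcutaneous RC block (skull, scales, epidermis), and an electrode block
whose non-ideal double layer over the mucous skin is a constant phase
element. The series chain is the minimal realization of the two-block
description; with only five magnitude points the subcutaneous block is
not identifiable and a reduced chain `R_s + (R_ct ∥ Z_CPE)` (4 free
parameters) is fitted; the full 6-parameter model engages at ≥8 points.

Fitting minimizes residuals of log10|Z| (the spectrum spans MΩ to kΩ
across 1–50 Hz, so a linear objective would see only the lowest
frequency), via `lmfit` least squares, multistarted over the CPE
exponent (n₀ ∈ {0.6, 0.7, 0.8, 0.9}) because the exponent creates
shallow local minima. Phase residuals (scaled by 90°) join the objective
when the spectrum carries phase. The goodness-of-fit report is the
chi-square of the log-magnitude residuals plus the maximum absolute
residual in dex. The bundled `paper_impedance.csv` fixture holds the
five reference magnitudes measured on fish skin at 1, 5, 10, 30 and
50 Hz — one frequency per classical EEG band (delta–gamma).

Fitted parameters are descriptive, not electrochemically interpreted;
with five magnitude-only points, `R_ct` in particular is weakly
identified (only a lower bound is constrained) and only the fitted
|Z(ω)| curve should be consumed.

## Cohort statistics

Per-animal metrics: event count (≥5 s, post-stabilization), count of
events > 120 s, mean duration, latency from injection to first onset,
and an SE flag. Group means are computed over seizing animals only;
non-responders are counted separately. Sex comparisons use the classical
pooled-variance two-sample Student t-test (df = n1 + n2 − 2, matching a
reported df of 12 for 7-vs-7 groups), two-sided, with no
multiple-testing correction (none is applied in the source workflow).
Whether the printed overall mean count averages exactly the 14 seizing
animals is not stated in the source; the seizing-only reading is adopted
because the weighted group means reproduce it to 0.01.

## Validation experiment sizes

* Cohort recovery: 30 seeds × 14 seizing animals × 1 h at 250 Hz
  (≈2100 events); recovered means are compared to the generative means.
* Localization recovery: ≥200 single-event recordings (5-min sessions)
  with propagation delays ≥0.5 s.
* Structural check: one 17-animal preset run must yield exactly 3
  zero-event animals.
* Detector quality on these conditions: sensitivity, precision and
  class agreement ≥0.95 with interval-Jaccard ≥0.5 matching.

## Known limitations

* The detector's thresholds are calibrated to the synthetic noise model;
  real recordings with artefacts would need `k`, the merge gap, and
  possibly artefact rejection re-tuned.
* EDF output is minimal (16-bit, one-second records, no annotations);
  clipping beyond the ±500 μV physical range is an error by design.
* The spike-wave kernel is a stylized morphology; only its repetition
  rate and amplitude are calibrated.
* Onset-channel recovery degrades for propagation delays below the
  envelope smoothing scale (~0.25 s); the stated ≥0.9 accuracy holds for
  delays ≥0.5 s.
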