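# zfeeg

Multichannel skin-surface EEG analysis for adult zebrafish seizure
models: synthetic labelled ictal EEG, automated seizure detection and
classification, Morlet time–frequency maps, onset-channel localization,
skin–electrode impedance modelling with a constant phase element, and
cohort statistics.

## Why

Adult zebrafish are an increasingly used epilepsy model: a 4-channel
electrode array on the head (two channels over the telencephalon, two
over the midbrain) records non-invasive EEG while an orally delivered
convulsant (PTZ, pentylenetetrazole) induces acute seizures. Analysing
such sessions means answering, per animal: how many epileptiform
discharges occurred, how long they lasted, how quickly the first one
followed the injection, where each started and whether it generalized,
and whether any run became status-epilepticus-like (> 5 min) — then
comparing those metrics between sexes. `zfeeg` packages that workflow as
a tested, reproducible pipeline for electrophysiologists working with
small aquatic models.

No public recordings of this kind exist, so the package ships a
synthetic-data generator that plants labelled ictal events — 5–7 Hz
high-amplitude theta runs and 2–3 Hz spike-and-slow-wave ("absence-like")
complexes — on sub-20 μV pink-noise baseline, following the cohort's
published summary statistics. Every analysis stage is validated against
that exact ground truth. See `docs/methods.md` for the models,
assumptions and limitations.

## Core definitions

* **Epileptiform discharge:** high-voltage repetitive discharge faster
  than 2.5 Hz with polyphasic spike/wave complexes. Automated as
  envelope > k·MAD(control window) **and** suprathreshold peak rate
  > 2.5 s⁻¹ in a sliding 2-s window; events < 5 s are discarded, events
  > 300 s are SE-like.
* **Timeline:** 10-min control recording, injection, 90-s stabilization
  (excluded from analysis), 60-min session.
* **Skin–electrode impedance:** Z(ω) = R_s + (R_sub ∥ 1/jωC_sub) +
  (R_ct ∥ Z_CPE) with Z_CPE = 1/(Q(jω)ⁿ) — fitted in log10|Z| space; the
  reduced 4-parameter chain is used for sparse magnitude-only spectra.
* **Sex comparison:** pooled-variance two-sample Student t
  (df = n₁+n₂−2) on counts, durations and latencies of seizing animals.

## Worked example: impedance of a dry-skin electrode

The bundled five-point magnitude spectrum (1–50 Hz, one frequency per
EEG band) is fitted with the reduced CPE circuit:

```bash
$ zfeeg eis fit src/zfeeg/data/paper_impedance.csv
model=reduced R_s=1.805e+04 Ω  R_ct=3.052e+08 Ω  Q=6.778e-08 S·s^n  n=0.938
chi-square=0.0006  max|log10 residual|=0.0194 dex
  |Z| delta:     2631.7 kΩ
  |Z| theta:      583.7 kΩ
  |Z| alpha:      305.9 kΩ
  |Z|  beta:      111.6 kΩ
  |Z| gamma:       71.2 kΩ
```

The CPE exponent n ≈ 0.94 confirms a near-capacitive but non-ideal
interface (the mucous skin layer); the fitted curve reproduces the
measured 2.7 MΩ at 1 Hz and 72.8 kΩ at 50 Hz within ~2.5%, and the
maximum log-magnitude residual is 0.019 dex. The kΩ-level magnitude at
EEG frequencies is what makes quiet sub-20 μV recordings feasible with
this electrode.

## Worked example: a full pipeline run

```bash
$ cat cfg.yml
seed: 1
fs: 250.0
preset: demo_small
out_dir: run1
tf_map_example: false
$ zfeeg run cfg.yml
run complete: run1
$ head -12 run1/summary.md
# Cohort summary

## all
- animals: 4 (3 seizing, 1 non-responders)
- mean events / seizing animal: 2.33
- mean event duration: 30.1 s
- mean latency to first event: 155.6 s
- animals with SE-like events: 0
```

The run directory also contains the planted ground truth, per-animal
detected-event tables, onset-channel proportions, group comparisons, a
stage log, and a SHA-256 manifest of every file; rerunning the same
config reproduces identical event tables. The `paper_cohort` preset
generates the full 17-animal study cohort (8 male / 9 female, 3
non-responders) with sex-specific count, duration, latency and
onset-channel distributions.

Other entry points: `zfeeg generate` (synthetic cohorts as EDF/CSV with
ground truth), `zfeeg filter` (0.1–55 Hz zero-phase band-pass),
`zfeeg detect`, `zfeeg tfa` (Morlet scalogram), `zfeeg localize`,
`zfeeg cohort`. Everything is equally available as a library
(`import zfeeg`).

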