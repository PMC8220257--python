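# figground

Stochastic figure-ground (SFG) stimulus synthesis and auditory-cortex
multi-unit activity (MUA) analysis, with a ground-truth synthetic session
generator so every stage of the pipeline is testable without animal data.

## The problem

Hearing out an auditory "figure" — a set of frequency components that repeat
coherently over time — from a random multi-tone background is a central test
of auditory scene analysis. In the SFG paradigm a stimulus is a gapless
sequence of 50-ms chords, each the sum of 15 pure tones drawn from a pool of
129 log-spaced frequencies (179–7246 Hz, ~1/24 octave apart). A figure is a
subset of 8 or 12 frequencies (coherence Coh8/Coh12) repeated identically
across 20 consecutive chords; coherent elements replace random ones, so
broadband power per chord is constant and the figure is defined purely by
temporal coherence. Macaques detect these figures in a go/no-go task, and
recording sites across primary and anterior auditory cortex raise their
firing when a figure appears.

This package re-implements that entire analysis chain as a tested library:

- **`stimulus`** — deterministic-given-seed synthesis of SFG stimuli
  (60 × 15 chord-element matrices + rendered audio), pure-tone batteries
  (14 half-octave tones at 3 levels), click trains and white noise.
- **`session`** — synthetic recording sessions with planted ground truth:
  chord-locked 20-Hz envelope responses, log-frequency Gaussian tuning,
  coherence-dependent figure gains with a ~2-chord latency, a simulated
  go/no-go observer, and a small pre-release motor transient.
- **`signal`** — MUA envelope extraction (band-pass 600–9000 Hz, rectify,
  200-Hz low-pass, 1 kHz), spike-density functions, baseline normalization
  `(x − μ_b)/μ_b`, and the analysis windows (figure-onset 201–400 ms,
  response-aligned −300…−100 ms, and the motor-control windows).
- **`tonotopy`** — site inclusion (onset SNR > 3 and frequency ANOVA
  p < 0.05), best frequency via a smoothing spline over log2 frequency,
  spatial maps with masked Gaussian smoothing, the low-frequency
  gradient-reversal boundary between anterior and posterior fields,
  click-train phase locking, and 20-Hz sound responsiveness.
- **`figure_ground`** — the modulation classifier (two-sample t test,
  p < 0.01, on response-aligned window means), neurometric d′
  `d_AB = (m_A − m_B)/s` with pooled SD, non-parametric AUROC, the
  96-difference-curve bootstrap modulation-onset latency (first significant
  bin followed by ≥ 4 consecutively significant 1-ms bins), population time
  courses with Benjamini–Hochberg FDR, and the bar-release motor control.
- **`behavior`** — trial scoring (hit/miss/CR/FA within a 900-ms response
  window), session d′ = Z(hit) − Z(FA), reaction-time mean and coefficient
  of variation, and across-session coherence comparisons.
- **`pipeline` / `studies`** — end-to-end session analysis and canned
  planted-parameter recovery studies.

## Worked example

```sh
python examples/04_figure_ground_modulation.py
```

```
modulated sites: 8/30 (t-test p < 0.01 and 20-Hz sound responsive)
median figure-vs-control d' (onset window): 0.705
median AUROC fig-vs-ctr: onset 0.688, response 0.691
modulation-onset latencies (ms): [131, 171, 180, 181, 182, 200, 213, 221]
median latency: 182 ms (planted figure-gain latency: 110 ms + 100 ms ramp)
```

The session planted 9 modulated sites out of 30; the classifier recovers 8
and flags none of the null sites. A d′ of 0.7 means the figure raises the
onset-window response by ~0.7 pooled standard deviations; AUROC ≈ 0.69 is
the probability that a random figure trial exceeds a random control trial.
Latencies are upper bounds on the planted 110-ms modulation onset: the
bootstrap flags the first bin where the ramping effect clears the noise.

The other examples cover stimulus synthesis (`01`), behavioral scoring
(`02`), tonotopic mapping and the gradient-reversal boundary (`03`), and the
silent bar-release motor control (`05`). Each prints what it computes and
what the numbers mean.

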