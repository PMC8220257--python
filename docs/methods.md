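# Methods

This note documents the models and procedures the package implements, the
choices made where the underlying descriptions were open, and what the
synthetic tests do and do not establish about real recordings.

## Stimulus synthesis

An SFG stimulus is 60 gapless 50-ms chords (3000 ms) at 44.1 kHz. Each chord
is the equal-amplitude sum of 15 distinct pure tones from a fixed pool;
every tone is gated by 10-ms raised-cosine on/off ramps, so gapless
concatenation produces amplitude dips at chord boundaries rather than
discontinuities. Tones start at zero phase for bit-reproducibility (uniform
random phases are available behind a flag). The rendered stimulus is scaled
to RMS 0.05 full-scale; absolute SPL (nominally 65 dB) is a playback concern
recorded as metadata only.

**Frequency pool.** 129 log-evenly spaced frequencies including both
endpoints 179 and 7246 Hz. The implied step, log2(7246/179)/128 ≈ 0.041712
octaves, is the "1/24 octave" spacing to within 0.1%; the printed endpoints
and count are honored exactly because the three cannot all hold
simultaneously (179 × 2^(128/24) ≈ 7217 ≠ 7246 Hz).

**Figures.** A figure is a set of 8 or 12 pool indices drawn once per
stimulus and placed in all 20 figure chords; the remaining elements of each
figure chord are drawn from the pool *excluding* the figure set, preserving
15 distinct elements per chord. Coherent elements replace random ones, so
per-chord broadband power carries no figure-onset cue (verified: figure vs
ground chords differ in mean RMS by < 3%; individual chords fluctuate ±~12%
because tone pairs 1/24 octave apart beat more slowly than one chord).
Figure onsets are drawn uniformly over chords 6–40 (300–2000 ms), so the
20-chord figure always ends by chord 60. Within-chord draws are without
replacement (distinctness assumed; the original procedure does not say).

**Session set.** 20 stimuli per session: 6 Coh8 + 6 Coh12 + 8 controls
(60% with figure). One master seed spawns an independent child stream per
stimulus, so any stimulus is reproducible in isolation.

**Characterization sounds.** Pure tones: 14 frequencies at exact half-octave
steps from 180 Hz (top tone 16292 Hz), 200 ms, 10-ms ramps, at 50/60/70 dB
with 20·log10 amplitude scaling (70 dB ↦ amplitude 0.1 full-scale). Tones
are equal-amplitude, not equal-loudness. Click trains: monophasic 2-ms
pulses at 25/50/75/100 Hz for 200 ms. White noise: Gaussian, fixed RMS.

## Synthetic sessions

Each site is a 1-kHz envelope rate model:

    rate(t) = base · chord_term(t) · fig_term(t) · motor_term(t)

- `chord_term`: during the stimulus, `d_c · (1 + g_chord · k(t))` where
  `k` is a raised-cosine kernel per 50-ms chord (fundamental exactly 20 Hz)
  and `d_c` is the chord's tuning drive — Gaussian in log2 frequency around
  the site's best frequency (SD = tuning bandwidth, default 1 octave),
  driven by the chord element closest to BF (max over the 15 elements,
  bounded below by a floor of 0.3 so off-BF chords still evoke activity).
  Default chord gain 0.6.
- `fig_term`: ramps linearly from 1 to the condition's figure gain over
  100 ms, starting a fixed latency (default 110 ms ≈ 2 chords) after figure
  onset, sustained to figure offset, then ramps back. Anterior modulated
  sites default to gains 1.15 (Coh8) / 1.30 (Coh12); posterior modulated
  sites to 1.20 at both coherences (the planted regional coherence effect);
  non-modulated sites have unit gains.
- `motor_term`: a raised-cosine bump over the 150 ms before touch-bar
  release, amplitude 0.02. Note its overlap with the −301…−100 ms response
  window is only 50 ms, so the measured window difference is ≈ 0.073 × the
  bump amplitude by construction; tests check recovery against that
  shape-integral oracle.

**Envelope noise.** `env = rate · (1 + e_fast + e_slow)`, clipped at zero,
with two stationary AR(1) components: fast τ = 5 ms (the smoothness of a
200-Hz-low-passed envelope at 1 kHz) with SD 0.4, and slow τ = 200 ms
(excitability drift carrying trial-to-trial variability) with SD 0.2. No
per-trial variance is reported for real MUA; these values were fixed once so
that the planted figure gains produce single-trial discriminability in the
AUROC ≈ 0.6–0.8 range and the classifier stays calibrated, and were not
revisited. The raw 32-kHz path (Poisson spikes → biphasic waveforms + band
noise) exists for envelope-extraction tests and is opt-in; the 1-kHz
envelope path is the default because it is ~30× cheaper.

**Behavior.** Figure trials: hit with probability 0.85 (Coh8) / 0.95
(Coh12); hit reaction times are shifted lognormal (shift 150 ms, σ = 0.35,
means 600/450 ms), resampled into the 900-ms response window. Control
trials: false alarm with probability 0.08, release uniform over the
stimulus. Outcomes are produced by the same scoring function the analysis
applies, so trial tables are consistent by construction. Behavioral
meta-simulations use 20 repetitions per stimulus (400-trial sessions),
matching the several-hundred-trial sessions that survive the
"more than 200 trials" session filter.

**What the generator does not emulate:** spike waveform diversity, LFP
beyond what click-train phase locking needs, adaptation, serial trial
dependencies, eye/arm kinematics, non-Poisson spiking statistics, and
electrode drift. Passing tests therefore demonstrate that the analysis
recovers planted effects under the stated statistical structure, not that
real cortical data satisfy that structure.

## Signal conditioning

The MUA envelope is |band-pass 600–9000 Hz| → 3rd-order Butterworth low-pass
at 200 Hz → decimation to 1 kHz. The band-pass is 4th-order (the acquisition
filter order is unspecified) and all filtering is zero-phase
(forward–backward): a causal hardware filter would add a small constant
delay, which the latency tolerances absorb. Baseline normalization is
`(x − μ_b)/μ_b` with μ_b the mean over the 400 ms before sound onset —
dimensionless modulation around 0; z-scoring is not used because the
neurometric d′ divides by the across-trial SD separately and would
double-count variance. Degenerate (non-positive) baselines raise.

All analysis windows are half-open `[start, end)` at 1-ms resolution
(endpoint convention unstated in the source): figure-onset window
[201, 401) and response window [−300, −100) span 200 samples; the printed
motor-control windows [−301, −100) and [−501, −300) span 201 samples each.
Miss trials use the last 200 ms of the figure ([onset + 800, onset + 1000));
control trials use the same logic at a pseudo figure onset drawn per trial
from the real onset distribution (uniform over chords 6–40) with a fixed
seed. Spike-density functions are sums of unit-area 5-ms-SD Gaussians,
averaged over trials.

## Tonotopy and parcellation

**Inclusion.** Onset SNR slides a 50-ms window (1-ms steps) over 10–150 ms
after tone onset on the trial-averaged trace; SNR = mean over positions of
(window mean − baseline mean)/baseline SD, baseline = 200 ms pre-onset. The
baseline-SD-standardized form is chosen so the inclusion threshold 3 reads
"3 noise SDs". Inclusion additionally requires a frequency main effect
(p < 0.05) in a two-way fixed-effects ANOVA (frequency × intensity with
interaction; ≥ 2 replicates per cell required for residual df).

**Best frequency.** The 14-point tuning curve (averaged across intensities)
is smoothed with a cubic smoothing spline over log2 frequency under the
convention p = 1 → interpolation, p = 0 → linear fit (penalty weight
lam = (1 − p)/p, p = 0.98); BF is the argmax on a 1/96-octave grid. Flat
curves return the grid midpoint with a degenerate flag. Peak latency is the
argmax time of the trial-averaged response in 10–150 ms (the source does not
define its latency estimator).

**Maps and boundary.** Site coordinates are rounded to integer mm and
best frequencies averaged per cell in log2 units (geometric mean — tonotopy
is organized in octaves). Maps are smoothed with a Gaussian kernel of SD
1 mm truncated at ±1 mm per axis ("2 × 2 mm" support), renormalized over
in-map cells so edge cells are never diluted and a lone cell is unchanged.
The smoothed map is collapsed across the mediolateral axis; the boundary is
the midpoint of the two adjacent anteroposterior positions with the lowest
summed mean BF (a boundary must separate contiguous fields). Smoothing
precedes boundary finding. Monotone profiles (no reversal) place the
boundary at the rostral edge of the single minimum with a warning flag.
Sites rostral of the boundary are anterior.

**Phase locking.** Per click rate, the 200-ms stimulus and baseline periods
are FFT'd per trial; the channel is locked at that rate iff trial-mean
stimulus power at the click-frequency bin exceeds baseline mean + 2 SD
across trials (the SD could also be across frequency bins; across-trials is
used). Strength = number of locked rates (0–4). Baseline = the 200 ms
immediately preceding click onset.

**20-Hz sound responsiveness.** Responsive iff relative 20-Hz power during
the stimulus is ≥ 2× the baseline level. Two estimation details are pinned
here because the bare criterion is statistically fragile: both periods are
mean-normalized first (with multiplicative envelope noise, a tonic rate
change would otherwise scale 20-Hz power quadratically — the criterion is
meant to be chord-locking specific), and the stimulus power is
Welch-averaged over 250-ms segments while the baseline level is the mean
baseline density over 5–35 Hz (a single periodogram bin is exponentially
distributed and would let flat noise pass ~1/3 of the time).

## Figure-ground statistics

**Classifier.** Pooled-variance two-sample t test (Welch behind a flag)
comparing response-aligned window means of hit trials against
pseudo-windowed correct rejections; modulated iff p < 0.01 and the site is
20-Hz sound responsive. Calibration is verified on ≥ 500 simulated null
sites (fraction flagged within the binomial 95% interval around 0.01).

**Effect sizes.** Neurometric d′ = (m_A − m_B)/pooled SD (identical to the
SMD used for all reported contrasts); AUROC is the Mann–Whitney
U/(n_A · n_B) with ties counted ½. For Gaussian data AUROC = Φ(d′/√2),
checked as an invariant. Hit-vs-miss and miss-vs-CR contrasts use identical
window logic and require ≥ 20 miss trials; false alarms are excluded
(consistently too few trials).

**Modulation-onset latency.** Per-stimulus mean difference curves are formed
for every (figure, control) pair — 12 × 8 = 96 for a standard session, with
controls aligned at per-stimulus pseudo onsets drawn once per session — and
pooled; the per-bin pooled mean is bootstrapped (5000 resamples) and the
latency is the first post-onset bin with two-sided percentile p < 0.01
followed by ≥ 4 more consecutively significant 1-ms bins. The bootstrap
resampling unit is *trials within each stimulus* (the pooled mean is then
recomputed). Resampling the 96 pooled difference curves themselves, as if
exchangeable, is also implemented (`resample="curves"`) but is
anti-conservative by construction: the 96 curves share only 20 underlying
stimulus responses (each figure curve enters 8 differences), so that scheme
understates the sampling SD of the pooled mean by ~3× regardless of noise
scale and produces spurious near-zero latencies. The trial-level bootstrap
is calibrated conditional on the session's stimulus set; stimulus-specific
frequency-content offsets remain a genuine source of early/imprecise
latencies for narrowly tuned sites, which is why the latency-recovery study
uses broadly tuned, strongly modulated sites (gain 2.0, reduced noise) as
its favorable regime. Recovered latencies are upper bounds on the planted
onset: detection occurs where the ramping effect clears the bootstrap
threshold, typically 10–25 ms up a 100-ms ramp at high SNR.

**Population time courses.** Across-site mean ± SEM per 1-ms bin; per-bin
two-sided Wilcoxon rank-sum between figure and control across sites
(across-site, not across-trial), Benjamini–Hochberg FDR at q = 0.05. All
FDR corrections are BH step-up over the family passed in; families are the
caller's choice and are therefore explicit at every call site.

**Motor control.** Bar-release traces are normalized per trial by their mean
over −800…−501 ms (a neutral reference; there is no sound onset to
normalize to in silence), then the per-site difference between the
[−301, −100) and [−501, −300) window means is tested across sites with a
signed-rank test against zero.

## Behavior

Hits require a release within [figure onset, onset + 900 ms]; reaction time
runs from figure onset (not sound onset). Releases before sound onset
invalidate the trial. Session d′ = Z(hit) − Z(FA) with rates clamped to
[1/(2n), 1 − 1/(2n)] (the source is silent on 0/1 rates; the clamp keeps Z
finite). CV = sample SD/mean of hit RTs. Across-session coherence
comparisons report the SMD and a two-sided rank-sum p per metric, after
excluding sessions with ≤ 200 trials. The source names both a signed-rank
and a rank-sum test for these comparisons; both are provided, rank-sum is
the default for unpaired session sets, and the discrepancy is documented
rather than resolved. The trial-level mixed-effects RT model is out of
scope; a per-session comparison stands in.

## Problem sizes and determinism

All studies run on one core in minutes: latency recovery uses 20 sites
(2 × 10-site sessions, 10 reps/stimulus, 5000 bootstrap resamples);
classifier calibration 500 null sites in 50-site sessions; behavioral
ordering 100 sessions of 400 trials; tonotopy 80 sites × 30 tone trials ×
14 frequencies; the regional coherence study one 60-site session. Every
source of randomness descends from a single `SeedSequence`, so identical
seeds give bit-identical trial tables and float-identical traces.

## Interface notes

The package is a library: the importable API plus the `examples/` scripts
are the interface, and `scripts/acceptance.py` is the only entry point run
from a shell, so no console commands are installed. Audio I/O is 16-bit PCM
WAV via scipy; session bundles are CSV (trials) + HDF5 (traces and ground
truth, one group per site) + JSON sidecars.

## Known limitations

- The envelope noise model (two AR(1) components, multiplicative) is a
  stand-in for real MUA variability; classifier calibration and latency
  precision on real data depend on noise structure not modeled here.
- Saturation-artifact exclusion applies a configurable full-scale-touch
  rule; real artifact distributions may differ.
- The latency estimator is conditional on the session's stimulus set;
  between-stimulus frequency-content differences bias it early for narrowly
  tuned sites with strong effects.
- Anterior/posterior parcellation is a 1-D gradient reversal; finer areal
  attribution (A1/R/RT vs belt) requires anatomy and is out of scope.
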