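"""Synthesis of stochastic figure-ground (SFG) stimuli and site-characterization sounds.

An SFG stimulus is a gapless sequence of 50-ms chords, each the sum of 15 pure
tones drawn from a fixed log-spaced frequency pool.  A "figure" is a subset of
``coherence`` frequencies (8 or 12 here) repeated identically across 20
consecutive chords; the remaining elements of each chord stay random, so the
figure is defined purely by temporal coherence, not by extra energy.  Coherent
elements replace random ones rather than being added on top, which keeps the
broadband power per chord constant and removes level cues at figure onset.

The module also synthesizes the pure-tone battery (14 half-octave tones at
three levels), monophasic click trains (25-100 Hz) and white-noise bursts used
to characterize recording sites.

All randomness flows through :class:`numpy.random.Generator`; a session's
stimuli are derived from one master seed via ``SeedSequence.spawn`` so each
stimulus is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

# Pool geometry (printed endpoints and count; the ~1/24-octave spacing follows)
POOL_SIZE = 129
POOL_F_MIN_HZ = 179.0
POOL_F_MAX_HZ = 7246.0

N_CHORDS = 60
ELEMENTS_PER_CHORD = 15
CHORD_DUR_MS = 50.0
FIGURE_LEN_CHORDS = 20
RAMP_MS = 10.0
SAMPLE_RATE_HZ = 44100
STIM_DUR_MS = N_CHORDS * CHORD_DUR_MS  # 3000 ms

# Figure onset must fall between 300 and 2000 ms after sound onset; with
# 50-ms chords that is chord index 6..40 (the 20-chord figure then ends at
# or before chord 60).
ONSET_MIN_CHORD = 6
ONSET_MAX_CHORD = 40

VALID_COHERENCES = (0, 8, 12)


@dataclass(frozen=True)
class FrequencyPool:
    """Ordered pool of tone frequencies all chords draw from."""

    frequencies_hz: np.ndarray

    @property
    def n(self) -> int:
        return len(self.frequencies_hz)

    @property
    def f_min_hz(self) -> float:
        return float(self.frequencies_hz[0])

    @property
    def f_max_hz(self) -> float:
        return float(self.frequencies_hz[-1])

    @property
    def step_octaves(self) -> float:
        """Log2 spacing between neighbours (constant for a log-even pool)."""
        return float(np.log2(self.f_max_hz / self.f_min_hz) / (self.n - 1))


def build_frequency_pool(
    n: int = POOL_SIZE,
    f_min_hz: float = POOL_F_MIN_HZ,
    f_max_hz: float = POOL_F_MAX_HZ,
) -> FrequencyPool:
    """Build the log-evenly spaced frequency pool.

    Both printed endpoints are included; the resulting step is
    ``log2(f_max/f_min)/(n-1)`` octaves (~1/24 octave for the defaults).
    """
    freqs = np.geomspace(f_min_hz, f_max_hz, n)
    freqs.setflags(write=False)
    return FrequencyPool(frequencies_hz=freqs)


@dataclass
class SFGStimulus:
    """One SFG stimulus: chord-element matrix plus figure annotation.

    ``chord_elements[c]`` holds the pool indices of the tones making up chord
    ``c``.  For figure stimuli, ``figure_set`` is contained in every chord of
    the figure span ``[figure_onset_chord, figure_onset_chord + 20)``.
    """

    chord_elements: np.ndarray
    coherence: int
    figure_onset_chord: Optional[int]
    figure_set: Optional[np.ndarray]
    pool: FrequencyPool
    figure_len_chords: int = FIGURE_LEN_CHORDS
    chord_dur_ms: float = CHORD_DUR_MS
    ramp_ms: float = RAMP_MS
    sample_rate_hz: int = SAMPLE_RATE_HZ
    level_db_spl: float = 65.0
    stimulus_id: str = ""
    seed: Optional[int] = None

    @property
    def n_chords(self) -> int:
        return self.chord_elements.shape[0]

    @property
    def duration_ms(self) -> float:
        return self.n_chords * self.chord_dur_ms

    @property
    def is_figure(self) -> bool:
        return self.coherence > 0

    @property
    def figure_onset_ms(self) -> Optional[float]:
        if self.figure_onset_chord is None:
            return None
        return self.figure_onset_chord * self.chord_dur_ms

    @property
    def condition(self) -> str:
        return {0: "control", 8: "coh8", 12: "coh12"}[self.coherence]


def sample_sfg(
    coherence: int,
    figure_onset_chord: int | str | None = "auto",
    rng: np.random.Generator | int | np.random.SeedSequence | None = None,
    pool: Optional[FrequencyPool] = None,
    stimulus_id: str = "",
) -> SFGStimulus:
    """Draw the chord-element matrix of one SFG stimulus (metadata only).

    Parameters
    ----------
    coherence : {0, 8, 12}
        Number of coherent figure elements per chord; 0 means control.
    figure_onset_chord : int, "auto" or None
        First chord of the figure.  ``"auto"`` draws uniformly from chords
        6..40 (onset time 300-2000 ms).  Ignored/None for controls.
    """
    if coherence not in VALID_COHERENCES:
        raise ValueError(f"coherence must be one of {VALID_COHERENCES}, got {coherence}")
    pool = pool or build_frequency_pool()
    rng = np.random.default_rng(rng)

    if coherence == 0:
        onset = None
        figure_set = None
    else:
        if figure_onset_chord == "auto" or figure_onset_chord is None:
            onset = int(rng.integers(ONSET_MIN_CHORD, ONSET_MAX_CHORD + 1))
        else:
            onset = int(figure_onset_chord)
            if not (ONSET_MIN_CHORD <= onset <= ONSET_MAX_CHORD):
                raise ValueError(
                    f"figure_onset_chord {onset} outside [{ONSET_MIN_CHORD}, "
                    f"{ONSET_MAX_CHORD}] (figure must start 300-2000 ms in and "
                    f"end by chord {N_CHORDS})"
                )
        figure_set = np.sort(rng.choice(pool.n, size=coherence, replace=False))

    elements = np.empty((N_CHORDS, ELEMENTS_PER_CHORD), dtype=np.intp)
    if coherence == 0:
        for c in range(N_CHORDS):
            elements[c] = np.sort(rng.choice(pool.n, ELEMENTS_PER_CHORD, replace=False))
    else:
        ground_pool = np.setdiff1d(np.arange(pool.n), figure_set)
        fig_span = range(onset, onset + FIGURE_LEN_CHORDS)
        for c in range(N_CHORDS):
            if c in fig_span:
                rand = rng.choice(ground_pool, ELEMENTS_PER_CHORD - coherence, replace=False)
                elements[c] = np.sort(np.concatenate([figure_set, rand]))
            else:
                elements[c] = np.sort(rng.choice(pool.n, ELEMENTS_PER_CHORD, replace=False))

    return SFGStimulus(
        chord_elements=elements,
        coherence=coherence,
        figure_onset_chord=onset,
        figure_set=figure_set,
        pool=pool,
        stimulus_id=stimulus_id,
    )


def _raised_cosine_envelope(n_samples: int, n_ramp: int) -> np.ndarray:
    env = np.ones(n_samples)
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    env[:n_ramp] = ramp
    env[-n_ramp:] = np.minimum(env[-n_ramp:], ramp[::-1])
    return env


def render_waveform(
    stim: SFGStimulus,
    target_rms: float = 0.05,
    randomize_phase: bool = False,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Render an SFG stimulus to mono audio.

    Each chord is the equal-amplitude sum of its pure tones, every tone gated
    by 10-ms raised-cosine on/off ramps; chords are concatenated gaplessly.
    The whole stimulus is scaled to a fixed RMS (absolute SPL is a playback
    concern, recorded as metadata only).  Tones start at zero phase by
    default for bit-reproducibility; ``randomize_phase`` draws uniform phases.
    """
    fs = stim.sample_rate_hz
    n_chord = int(round(stim.chord_dur_ms * fs / 1000.0))
    n_ramp = int(round(stim.ramp_ms * fs / 1000.0))
    t = np.arange(n_chord) / fs
    env = _raised_cosine_envelope(n_chord, n_ramp)
    freqs = stim.pool.frequencies_hz
    rng = np.random.default_rng(rng)

    chords = []
    for row in stim.chord_elements:
        f = freqs[np.asarray(row)]
        if randomize_phase:
            phase = rng.uniform(0, 2 * np.pi, size=len(f))
        else:
            phase = np.zeros(len(f))
        tones = np.sin(2 * np.pi * f[:, None] * t[None, :] + phase[:, None])
        chords.append(env * tones.sum(axis=0))
    wave = np.concatenate(chords)

    rms = float(np.sqrt(np.mean(wave**2)))
    if rms > 0:
        wave = wave * (target_rms / rms)
    if np.max(np.abs(wave)) > 1.0:
        raise ValueError("rendered waveform clips after RMS normalization")
    return wave


def make_session_stimulus_set(
    seed: int | np.random.SeedSequence,
    n_coh8: int = 6,
    n_coh12: int = 6,
    n_control: int = 8,
    pool: Optional[FrequencyPool] = None,
) -> list[SFGStimulus]:
    """Draw the per-session stimulus set: 12 figure stimuli (6 Coh8 + 6 Coh12)
    and 8 controls, i.e. 20 stimuli of which 60% contain a figure.

    Each stimulus gets its own child stream of the master seed, so any one
    stimulus can be regenerated independently.
    """
    pool = pool or build_frequency_pool()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_coh8 + n_coh12 + n_control)
    plan = [(8, "coh8")] * n_coh8 + [(12, "coh12")] * n_coh12 + [(0, "control")] * n_control
    stimuli = []
    for i, ((coh, label), child) in enumerate(zip(plan, children)):
        stim = sample_sfg(coh, "auto", rng=np.random.default_rng(child), pool=pool,
                          stimulus_id=f"{label}_{i:02d}")
        stimuli.append(stim)
    return stimuli


def common_run_subset_size(chord_elements: np.ndarray, run_len: int = FIGURE_LEN_CHORDS) -> int:
    """Largest element set shared by *all* chords of any ``run_len`` consecutive
    chords (brute-force scan).  Controls must stay below the lowest coherence
    level (8); figure stimuli reach at least their coherence."""
    n = chord_elements.shape[0]
    best = 0
    for start in range(0, n - run_len + 1):
        common = set(chord_elements[start].tolist())
        for c in range(start + 1, start + run_len):
            common &= set(chord_elements[c].tolist())
            if len(common) <= best:
                break
        best = max(best, len(common))
    return best


# ---------------------------------------------------------------------------
# Site-characterization sounds
# ---------------------------------------------------------------------------

TONE_BATTERY_F0_HZ = 180.0
TONE_BATTERY_N = 14
TONE_LEVELS_DB = (50.0, 60.0, 70.0)
CLICK_RATES_HZ = (25.0, 50.0, 75.0, 100.0)

# 70 dB SPL nominally maps to amplitude 0.1 full-scale; relative levels follow
# 20*log10 amplitude scaling.
_REF_LEVEL_DB = 70.0
_REF_AMPLITUDE = 0.1


def tone_battery_frequencies() -> np.ndarray:
    """14 pure-tone frequencies at exact half-octave steps from 180 Hz
    (the highest is 16292 Hz to the nearest Hz)."""
    return TONE_BATTERY_F0_HZ * 2.0 ** (np.arange(TONE_BATTERY_N) / 2.0)


def _level_to_amplitude(level_db: float) -> float:
    return _REF_AMPLITUDE * 10.0 ** ((level_db - _REF_LEVEL_DB) / 20.0)


def make_tone(
    f_hz: float,
    level_db: float = 60.0,
    dur_ms: float = 200.0,
    ramp_ms: float = RAMP_MS,
    fs: int = SAMPLE_RATE_HZ,
) -> np.ndarray:
    """Pure tone with raised-cosine on/off ramps."""
    if f_hz <= 0 or f_hz >= fs / 2:
        raise ValueError(f"tone frequency {f_hz} Hz out of range for fs={fs}")
    n = int(round(dur_ms * fs / 1000.0))
    t = np.arange(n) / fs
    env = _raised_cosine_envelope(n, int(round(ramp_ms * fs / 1000.0)))
    return _level_to_amplitude(level_db) * env * np.sin(2 * np.pi * f_hz * t)


def make_click_train(
    rate_hz: float,
    dur_ms: float = 200.0,
    pulse_ms: float = 2.0,
    fs: int = SAMPLE_RATE_HZ,
    amplitude: float = 0.5,
) -> np.ndarray:
    """Monophasic positive click train; pulse count = floor(rate x duration)."""
    if rate_hz <= 0:
        raise ValueError("click rate must be positive")
    if 1000.0 / rate_hz < pulse_ms:
        raise ValueError("pulses would overlap at this rate")
    n = int(round(dur_ms * fs / 1000.0))
    n_pulse = int(round(pulse_ms * fs / 1000.0))
    n_clicks = int(np.floor(rate_hz * dur_ms / 1000.0))
    x = np.zeros(n)
    for k in range(n_clicks):
        start = int(round(k * fs / rate_hz))
        x[start : start + n_pulse] = amplitude
    return x


def make_white_noise(
    dur_ms: float = 200.0,
    rng: np.random.Generator | int | None = None,
    fs: int = SAMPLE_RATE_HZ,
    rms: float = 0.05,
) -> np.ndarray:
    """Gaussian white-noise burst scaled to a fixed RMS."""
    rng = np.random.default_rng(rng)
    x = rng.standard_normal(int(round(dur_ms * fs / 1000.0)))
    return x * (rms / np.sqrt(np.mean(x**2)))
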