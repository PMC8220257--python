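"""Ground-truth-parameterized synthetic recording sessions.

Each site is a rate model whose 1-kHz "MUA envelope" has the statistical
structure the analysis pipeline assumes:

* chord-locked 20-Hz modulation during SFG stimulation (a raised-cosine
  kernel per 50-ms chord),
* log-frequency Gaussian tuning, driven per chord by the element closest to
  the site's best frequency (max over the 15 elements),
* a multiplicative figure-evoked gain that ramps up linearly over 100 ms,
  starting a fixed latency (~2 chords) after figure onset, and is sustained
  for the rest of the figure,
* a small motor transient (raised-cosine bump over the 150 ms before touch
  bar release),
* multiplicative noise: a fast AR(1) component (tau = 5 ms, mimicking the
  200-Hz-low-passed envelope) plus a slow AR(1) excitability drift
  (tau = 200 ms) that carries trial-to-trial variability.

Behavioral outcomes follow a planted observer: hit probability and a shifted
lognormal reaction-time distribution per coherence, plus a constant
false-alarm probability on control trials.  Outcomes are produced by the
same scoring rules the behavior module applies, so trial tables are
self-consistent by construction.

A session bundle holds the trial table, one envelope trace per (site, trial)
covering 400 ms pre-onset baseline + 3000 ms stimulus + 500 ms tail, the
ground-truth site parameters, and the session's stimulus set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import behavior as beh
from .stimulus import (
    CHORD_DUR_MS,
    SFGStimulus,
    build_frequency_pool,
    make_session_stimulus_set,
    tone_battery_frequencies,
    TONE_LEVELS_DB,
    CLICK_RATES_HZ,
)

STIM_DUR_MS = 3000
PRE_MS = 400
POST_MS = 500
CHORD_MS = int(CHORD_DUR_MS)


@dataclass
class GroundTruthSite:
    """Planted parameters of one synthetic recording site."""

    site_id: int
    grid_x: float
    grid_y: float  # anteroposterior coordinate, mm; larger = more rostral
    field_label: str  # "anterior" | "posterior"
    bf_hz: float
    tuning_bw_oct: float = 1.0
    base_rate: float = 1.0
    chord_gain: float = 0.6
    drive_floor: float = 0.3
    onset_latency_ms: float = 20.0
    fig_gain_coh8: float = 1.0
    fig_gain_coh12: float = 1.0
    fig_latency_ms: float = 110.0
    fig_ramp_ms: float = 100.0
    motor_gain: float = 0.02
    phase_lock: bool = False
    is_modulated: bool = False
    noise_fast_sd: float = 0.4
    noise_fast_tau_ms: float = 5.0
    noise_slow_sd: float = 0.2
    noise_slow_tau_ms: float = 200.0

    def fig_gain(self, condition: str) -> float:
        return {"coh8": self.fig_gain_coh8, "coh12": self.fig_gain_coh12, "control": 1.0}[
            condition
        ]

    def __post_init__(self) -> None:
        if self.is_modulated:
            if self.field_label == "anterior":
                if not (self.fig_gain_coh12 >= self.fig_gain_coh8 >= 1.0):
                    raise ValueError("anterior modulated site needs g12 >= g8 >= 1")
            else:
                if not (self.fig_gain_coh12 == self.fig_gain_coh8 > 1.0):
                    raise ValueError("posterior modulated site needs g12 = g8 > 1")
        elif not (self.fig_gain_coh8 == self.fig_gain_coh12 == 1.0):
            raise ValueError("non-modulated site must have unit figure gains")


@dataclass
class BehaviorParams:
    """Planted go/no-go observer."""

    p_hit_coh8: float = 0.85
    p_hit_coh12: float = 0.95
    fa_rate: float = 0.08
    rt_mean_coh8_ms: float = 600.0
    rt_mean_coh12_ms: float = 450.0
    rt_shift_ms: float = 150.0
    rt_sigma: float = 0.35
    response_window_ms: float = beh.RESPONSE_WINDOW_MS

    def rt_mean(self, condition: str) -> float:
        return {"coh8": self.rt_mean_coh8_ms, "coh12": self.rt_mean_coh12_ms}[condition]

    def p_hit(self, condition: str) -> float:
        return {"coh8": self.p_hit_coh8, "coh12": self.p_hit_coh12}[condition]


@dataclass
class SessionConfig:
    """Session-level composition of sites, trials and planted effects."""

    n_sites: int = 30
    frac_modulated: float = 0.3
    frac_anterior: float = 0.5
    n_reps: int = 10  # repetitions per stimulus (x20 stimuli = trials)
    fig_gain_coh8_anterior: float = 1.15
    fig_gain_coh12_anterior: float = 1.30
    fig_gain_posterior: float = 1.20  # both coherences (no coherence effect)
    fig_latency_ms: float = 110.0
    fig_ramp_ms: float = 100.0
    tuning_bw_oct: float = 1.0
    chord_gain: float = 0.6
    noise_fast_sd: float = 0.4
    noise_slow_sd: float = 0.2
    motor_gain: float = 0.02
    grid_nx: int = 5
    grid_ny: int = 10
    behavior: BehaviorParams = field(default_factory=BehaviorParams)


@dataclass
class SessionBundle:
    """Trial table + per-trial envelope traces + ground truth + stimuli."""

    trials: pd.DataFrame
    traces: np.ndarray  # (n_sites, n_trials, T) float32, 1 kHz
    t0_ms: float
    sites: list[GroundTruthSite]
    stimuli: list[SFGStimulus]
    seed: int
    kind: str = "sfg"
    config: Optional[SessionConfig] = None


# ---------------------------------------------------------------------------
# Rate model
# ---------------------------------------------------------------------------

def _chord_kernel() -> np.ndarray:
    """Raised-cosine kernel over one 50-ms chord (peak 1, mean 1/2); tiling it
    across chords yields the 20-Hz chord-locked modulation."""
    tau = np.arange(CHORD_MS)
    return 0.5 * (1.0 - np.cos(2 * np.pi * tau / CHORD_MS))


def chord_drives(site: GroundTruthSite, stim: SFGStimulus) -> np.ndarray:
    """Per-chord tuning drive in (0, 1]: Gaussian in log2 frequency, a chord
    driving via its element closest to the site's BF (max over elements),
    floored so off-BF chords still evoke activity."""
    freqs = stim.pool.frequencies_hz[stim.chord_elements]
    d_oct = np.log2(freqs / site.bf_hz)
    g = np.exp(-0.5 * (d_oct / site.tuning_bw_oct) ** 2).max(axis=1)
    return site.drive_floor + (1.0 - site.drive_floor) * g


def _fig_multiplier(site: GroundTruthSite, stim: SFGStimulus, T_stim: int) -> np.ndarray:
    """Figure-evoked gain over the stimulus period: linear ramp from 1 to the
    condition gain over ``fig_ramp_ms`` starting ``fig_latency_ms`` after
    figure onset, sustained to figure offset, symmetric ramp-down after."""
    f = np.ones(T_stim)
    gain = site.fig_gain(stim.condition)
    if not stim.is_figure or gain == 1.0:
        return f
    onset = stim.figure_onset_ms + site.fig_latency_ms
    offset = stim.figure_onset_ms + stim.figure_len_chords * CHORD_DUR_MS
    t = np.arange(T_stim, dtype=float)
    ramp_up = np.clip((t - onset) / site.fig_ramp_ms, 0.0, 1.0)
    ramp_down = np.clip((t - offset) / site.fig_ramp_ms, 0.0, 1.0)
    return 1.0 + (gain - 1.0) * (ramp_up - ramp_up * ramp_down)


def simulate_rate(
    site: GroundTruthSite,
    stim: SFGStimulus,
    release_time_ms: Optional[float] = None,
    pre_ms: int = PRE_MS,
    post_ms: int = POST_MS,
) -> np.ndarray:
    """Noise-free envelope rate at 1-ms resolution for one (site, stimulus)
    pairing; covers ``[-pre_ms, stim_dur + post_ms)`` relative sound onset."""
    T_stim = int(stim.duration_ms)
    rate = np.ones(pre_ms + T_stim + post_ms)
    k = np.tile(_chord_kernel(), stim.n_chords)
    d = np.repeat(chord_drives(site, stim), CHORD_MS)
    rate[pre_ms : pre_ms + T_stim] = d * (1.0 + site.chord_gain * k)
    rate[pre_ms : pre_ms + T_stim] *= _fig_multiplier(site, stim, T_stim)
    rate *= site.base_rate
    if release_time_ms is not None and np.isfinite(release_time_ms):
        _apply_motor_bump(rate[None, :], np.array([release_time_ms]), site.motor_gain, -pre_ms)
    return rate


_MOTOR_BUMP_MS = 150


def _motor_bump_shape() -> np.ndarray:
    tau = np.arange(_MOTOR_BUMP_MS + 1)
    return 0.5 * (1.0 - np.cos(2 * np.pi * tau / _MOTOR_BUMP_MS))


def _apply_motor_bump(
    rates: np.ndarray, release_ms: np.ndarray, motor_gain: float, t0_ms: float
) -> None:
    """Multiply each row's rate by (1 + m * bump) over [release-150, release]."""
    if motor_gain == 0:
        return
    bump = _motor_bump_shape()
    T = rates.shape[-1]
    for i, rel in enumerate(release_ms):
        if not np.isfinite(rel):
            continue
        i1 = int(round(rel - t0_ms)) + 1
        i0 = i1 - len(bump)
        b0, b1 = max(0, -i0), len(bump) - max(0, i1 - T)
        i0, i1 = max(i0, 0), min(i1, T)
        if i0 < i1:
            rates[i, i0:i1] *= 1.0 + motor_gain * bump[b0:b1]


# ---------------------------------------------------------------------------
# Noise and spiking
# ---------------------------------------------------------------------------

def _ar1(rng: np.random.Generator, shape: tuple[int, ...], tau_ms: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with correlation time ``tau_ms`` and SD ``sd``
    along the last axis (1-ms steps)."""
    rho = np.exp(-1.0 / tau_ms)
    w = rng.standard_normal(shape) * np.sqrt(1.0 - rho**2)
    zi = rho * rng.standard_normal(shape[:-1] + (1,))
    x, _ = sps.lfilter([1.0], [1.0, -rho], w, axis=-1, zi=zi)
    return sd * x


def simulate_envelope(
    rates: np.ndarray, site: GroundTruthSite, rng: np.random.Generator
) -> np.ndarray:
    """Turn noise-free rates (n_trials, T) into noisy envelope traces:
    ``rate * (1 + e_fast + e_slow)``, clipped at zero."""
    e = _ar1(rng, rates.shape, site.noise_fast_tau_ms, site.noise_fast_sd)
    if site.noise_slow_sd > 0:
        e += _ar1(rng, rates.shape, site.noise_slow_tau_ms, site.noise_slow_sd)
    return np.maximum(rates * (1.0 + e), 0.0)


def draw_spikes(
    rate_hz: np.ndarray, rng: np.random.Generator, t0_ms: float = 0.0, dt_ms: float = 1.0
) -> np.ndarray:
    """Inhomogeneous Poisson spike times (ms) from a rate trace in spikes/s."""
    rate_hz = np.asarray(rate_hz, dtype=float)
    if np.any(rate_hz < 0):
        raise ValueError("rate must be non-negative")
    counts = rng.poisson(rate_hz * dt_ms / 1000.0)
    bins = np.repeat(np.arange(len(rate_hz)), counts)
    times = t0_ms + (bins + rng.uniform(size=len(bins))) * dt_ms
    return np.sort(times)


def synth_raw(
    spike_times_ms: np.ndarray,
    dur_ms: float,
    rng: np.random.Generator,
    fs: int = 32000,
    spike_amplitude: float = 1.0,
    noise_sd: float = 0.05,
) -> np.ndarray:
    """Synthesize a wideband (32 kHz) trace: a stereotyped 1-ms biphasic
    waveform per spike plus Gaussian noise shaped into the 600-9000 Hz band."""
    n = int(round(dur_ms * fs / 1000.0))
    n_wave = int(round(fs / 1000.0))  # 1 ms
    wave = spike_amplitude * np.sin(2 * np.pi * np.arange(n_wave) / n_wave)
    x = np.zeros(n + n_wave)
    idx = np.round(np.asarray(spike_times_ms) * fs / 1000.0).astype(int)
    for i in idx[(idx >= 0) & (idx < n)]:
        x[i : i + n_wave] += wave
    x = x[:n]
    if noise_sd > 0:
        sos = sps.butter(4, (600.0, 9000.0), btype="bandpass", fs=fs, output="sos")
        x = x + noise_sd * sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x


# ---------------------------------------------------------------------------
# Behavior and session assembly
# ---------------------------------------------------------------------------

def simulate_behavior(
    condition: str,
    figure_onset_ms: Optional[float],
    params: BehaviorParams,
    rng: np.random.Generator,
) -> tuple[str, Optional[float], Optional[float]]:
    """Simulate one trial's behavioral outcome.

    Figure trials: with probability ``p_hit`` draw a shifted-lognormal RT
    (resampled into the 900-ms window) -> hit; otherwise no release -> miss.
    Control trials: with probability ``fa_rate`` release at a uniform time
    during the stimulus -> FA; otherwise correct rejection.

    Returns ``(outcome, release_time_ms, reaction_time_ms)`` with the outcome
    produced by :func:`figground.behavior.score_trial` for consistency.
    """
    release: Optional[float] = None
    if condition == "control":
        if rng.uniform() < params.fa_rate:
            release = float(rng.uniform(300.0, beh.STIM_DUR_MS))
        outcome, rt = beh.score_trial(False, None, release)
        return outcome, release, rt
    if figure_onset_ms is None:
        raise ValueError("figure condition requires an onset time")
    if rng.uniform() < params.p_hit(condition):
        mu = np.log(params.rt_mean(condition) - params.rt_shift_ms) - params.rt_sigma**2 / 2
        for _ in range(100):
            rt = params.rt_shift_ms + float(rng.lognormal(mu, params.rt_sigma))
            if rt < params.response_window_ms:
                break
        release = figure_onset_ms + rt
    outcome, rt = beh.score_trial(True, figure_onset_ms, release)
    return outcome, release, rt


def simulate_trial_table(
    stimuli: Sequence[SFGStimulus],
    n_reps: int,
    params: BehaviorParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Shuffled trial table: each stimulus repeated ``n_reps`` times with
    simulated behavioral outcomes."""
    stim_idx = rng.permutation(np.repeat(np.arange(len(stimuli)), n_reps))
    rows = []
    for trial_id, si in enumerate(stim_idx):
        stim = stimuli[si]
        outcome, release, rt = simulate_behavior(
            stim.condition, stim.figure_onset_ms, params, rng
        )
        rows.append(
            dict(
                trial_id=trial_id,
                stimulus_id=stim.stimulus_id,
                stimulus_index=int(si),
                condition=stim.condition,
                figure_onset_ms=np.nan if stim.figure_onset_ms is None else stim.figure_onset_ms,
                release_time_ms=np.nan if release is None else release,
                outcome=outcome,
                reaction_time_ms=np.nan if rt is None else rt,
            )
        )
    return pd.DataFrame(rows)


def simulate_site_traces(
    site: GroundTruthSite,
    stimuli: Sequence[SFGStimulus],
    trials: pd.DataFrame,
    rng: np.random.Generator,
    pre_ms: int = PRE_MS,
    post_ms: int = POST_MS,
    dtype=np.float32,
) -> np.ndarray:
    """Envelope traces (n_trials, T) for one site across a trial table."""
    stim_rates = np.stack(
        [simulate_rate(site, s, None, pre_ms, post_ms) for s in stimuli]
    )
    rates = stim_rates[trials["stimulus_index"].to_numpy()]
    _apply_motor_bump(rates, trials["release_time_ms"].to_numpy(float), site.motor_gain, -pre_ms)
    return simulate_envelope(rates, site, rng).astype(dtype)


def _bf_profile_oct(y: float, boundary_y: float = 4.5, low_bf_hz: float = 300.0,
                    slope_oct_per_mm: float = 0.35) -> float:
    """Planted tonotopy: mirror-symmetric high->low->high best-frequency
    gradient with its low-frequency reversal at ``boundary_y``."""
    return np.log2(low_bf_hz) + slope_oct_per_mm * abs(y - boundary_y)


def make_sites(config: SessionConfig, rng: np.random.Generator) -> list[GroundTruthSite]:
    """Draw ground-truth sites: grid positions, V-shaped BF gradient with the
    reversal between rows 4 and 5, field-dependent figure gains."""
    n_ant = int(round(config.frac_anterior * config.n_sites))
    n_mod = int(round(config.frac_modulated * config.n_sites))
    modulated = np.zeros(config.n_sites, dtype=bool)
    modulated[rng.permutation(config.n_sites)[:n_mod]] = True
    sites = []
    for i in range(config.n_sites):
        anterior = i < n_ant
        y_cells = np.arange(5, config.grid_ny) if anterior else np.arange(0, 5)
        y = float(rng.choice(y_cells)) + float(rng.uniform(-0.4, 0.4))
        x = float(rng.integers(0, config.grid_nx)) + float(rng.uniform(-0.4, 0.4))
        bf = 2.0 ** (_bf_profile_oct(round(y)) + rng.normal(0.0, 0.15))
        if modulated[i]:
            g8, g12 = (
                (config.fig_gain_coh8_anterior, config.fig_gain_coh12_anterior)
                if anterior
                else (config.fig_gain_posterior, config.fig_gain_posterior)
            )
        else:
            g8 = g12 = 1.0
        sites.append(
            GroundTruthSite(
                site_id=i,
                grid_x=x,
                grid_y=y,
                field_label="anterior" if anterior else "posterior",
                bf_hz=float(bf),
                tuning_bw_oct=config.tuning_bw_oct,
                chord_gain=config.chord_gain,
                fig_gain_coh8=g8,
                fig_gain_coh12=g12,
                fig_latency_ms=config.fig_latency_ms,
                fig_ramp_ms=config.fig_ramp_ms,
                motor_gain=config.motor_gain,
                is_modulated=bool(modulated[i]),
                noise_fast_sd=config.noise_fast_sd,
                noise_slow_sd=config.noise_slow_sd,
                onset_latency_ms=float(rng.uniform(15.0, 35.0)),
            )
        )
    return sites


def generate_session(config: Optional[SessionConfig] = None, seed: int = 0) -> SessionBundle:
    """Generate a self-consistent figure-detection session bundle."""
    config = config or SessionConfig()
    ss = np.random.SeedSequence(seed)
    ss_stim, ss_beh, ss_sites, ss_noise = ss.spawn(4)
    stimuli = make_session_stimulus_set(ss_stim)
    trials = simulate_trial_table(stimuli, config.n_reps, config.behavior,
                                  np.random.default_rng(ss_beh))
    sites = make_sites(config, np.random.default_rng(ss_sites))
    noise_streams = ss_noise.spawn(len(sites))
    traces = np.empty((len(sites), len(trials), PRE_MS + STIM_DUR_MS + POST_MS), np.float32)
    for i, (site, child) in enumerate(zip(sites, noise_streams)):
        traces[i] = simulate_site_traces(site, stimuli, trials, np.random.default_rng(child))
    return SessionBundle(
        trials=trials, traces=traces, t0_ms=-PRE_MS, sites=sites,
        stimuli=stimuli, seed=seed, kind="sfg", config=config,
    )


def generate_bar_release_session(
    n_sites: int = 3,
    n_releases: int = 100,
    seed: int = 0,
    motor_gain: float = 0.02,
    pre_ms: int = 800,
    post_ms: int = 200,
) -> SessionBundle:
    """Silent bar-release control session: no auditory drive, only baseline
    rate plus the pre-release motor transient.  Traces are release-aligned
    (release at t = 0)."""
    ss = np.random.SeedSequence(seed)
    ss_sites, ss_noise = ss.spawn(2)
    rng = np.random.default_rng(ss_sites)
    sites = [
        GroundTruthSite(
            site_id=i, grid_x=float(i), grid_y=float(i), field_label="posterior",
            bf_hz=1000.0, motor_gain=motor_gain,
        )
        for i in range(n_sites)
    ]
    trials = pd.DataFrame(
        dict(
            trial_id=np.arange(n_releases),
            stimulus_id="silence",
            stimulus_index=-1,
            condition="bar_release",
            figure_onset_ms=np.nan,
            release_time_ms=0.0,
            outcome="release",
            reaction_time_ms=np.nan,
        )
    )
    T = pre_ms + post_ms
    traces = np.empty((n_sites, n_releases, T), np.float32)
    for i, (site, child) in enumerate(zip(sites, ss_noise.spawn(n_sites))):
        rates = np.full((n_releases, T), site.base_rate)
        _apply_motor_bump(rates, np.zeros(n_releases), site.motor_gain, -pre_ms)
        traces[i] = simulate_envelope(rates, site, np.random.default_rng(child))
    return SessionBundle(
        trials=trials, traces=traces, t0_ms=-pre_ms, sites=sites,
        stimuli=[], seed=seed, kind="bar_release",
    )


# ---------------------------------------------------------------------------
# Tone-battery and click-train responses (site characterization inputs)
# ---------------------------------------------------------------------------

TONE_PRE_MS = 300
TONE_DUR_MS = 200
TONE_POST_MS = 100


def _tone_kernel(latency_ms: float, dur_ms: int = TONE_DUR_MS) -> np.ndarray:
    """Tone-evoked kernel: Gaussian onset transient peaking at the site's
    latency (SD 15 ms) riding on a small sustained component."""
    t = np.arange(dur_ms, dtype=float)
    onset = np.exp(-0.5 * ((t - latency_ms) / 15.0) ** 2)
    sustained = 0.25 * (t >= 10)
    return onset + sustained


def simulate_tone_trials(
    site: GroundTruthSite,
    rng: np.random.Generator,
    n_reps: int = 10,
    frequencies_hz: Optional[np.ndarray] = None,
    levels_db: Sequence[float] = TONE_LEVELS_DB,
    tone_gain: float = 1.5,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Envelope responses to the pure-tone battery.

    Returns ``(traces, table)``: traces ``(n_trials, T)`` covering 300 ms
    baseline + 200 ms tone + 100 ms tail, and a table with ``frequency_hz``
    and ``level_db`` per trial.  Response amplitude is Gaussian in log2
    frequency around the site's BF and grows linearly with level.
    """
    freqs = tone_battery_frequencies() if frequencies_hz is None else np.asarray(frequencies_hz)
    kernel = _tone_kernel(site.onset_latency_ms)
    combos = [(f, l) for f in freqs for l in levels_db]
    rows, rates = [], []
    T = TONE_PRE_MS + TONE_DUR_MS + TONE_POST_MS
    for f, level in combos:
        drive = np.exp(-0.5 * (np.log2(f / site.bf_hz) / site.tuning_bw_oct) ** 2)
        level_gain = (level - 40.0) / 30.0
        rate = np.ones(T)
        rate[TONE_PRE_MS : TONE_PRE_MS + TONE_DUR_MS] += tone_gain * drive * level_gain * kernel
        rate *= site.base_rate
        for _ in range(n_reps):
            rows.append(dict(frequency_hz=f, level_db=level))
            rates.append(rate)
    rates = np.stack(rates)
    order = rng.permutation(len(rates))
    traces = simulate_envelope(rates[order], site, rng)
    return traces, pd.DataFrame([rows[i] for i in order]).reset_index(drop=True)


CLICK_PRE_MS = 200
CLICK_DUR_MS = 200


def simulate_click_trials(
    site: GroundTruthSite,
    rng: np.random.Generator,
    n_reps: int = 10,
    rates_hz: Sequence[float] = CLICK_RATES_HZ,
    locked_rates_hz: Optional[Sequence[float]] = None,
    lock_depth: float = 0.8,
) -> dict[float, tuple[np.ndarray, np.ndarray]]:
    """Click-train responses per rate: ``{rate: (stim_traces, baseline_traces)}``
    each ``(n_reps, 200)`` at 1 kHz.  Sites phase-lock (sinusoidal modulation
    at the click rate) at ``locked_rates_hz`` (default: all rates if the site's
    ``phase_lock`` flag is set, none otherwise)."""
    if locked_rates_hz is None:
        locked_rates_hz = list(rates_hz) if site.phase_lock else []
    out = {}
    for rate_hz in rates_hz:
        t = np.arange(CLICK_DUR_MS) / 1000.0
        stim_rate = np.ones(CLICK_DUR_MS)
        if rate_hz in locked_rates_hz:
            stim_rate = stim_rate + lock_depth * 0.5 * (1 - np.cos(2 * np.pi * rate_hz * t))
        rates = np.concatenate(
            [np.ones((n_reps, CLICK_PRE_MS)), np.tile(stim_rate, (n_reps, 1))], axis=1
        ) * site.base_rate
        env = simulate_envelope(rates, site, rng)
        out[rate_hz] = (env[:, CLICK_PRE_MS:], env[:, :CLICK_PRE_MS])
    return out
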