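"""Raw-trace conditioning: MUA envelopes, spike density, normalization, windows.

The multi-unit activity (MUA) envelope is the absolute value of the 600-9000 Hz
band-passed extracellular signal, low-passed at 200 Hz (3rd-order Butterworth)
and decimated to 1 kHz.  Filtering is zero-phase (forward-backward) so the
envelope carries no filter-induced latency; the acquisition hardware's causal
filters would add a small constant delay, which the latency tolerances absorb.

Analysis windows are half-open ``[start, end)`` at 1-ms resolution throughout.
The printed window bounds are honored literally: the figure-onset window
201-400 ms and the response window -300 to -100 ms span 200 samples, while the
motor-control windows (-301..-100 and -501..-300 ms) span 201 samples each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

ENVELOPE_FS_HZ = 1000


@dataclass(frozen=True)
class AnalysisWindow:
    """A time window relative to an alignment event (half-open, ms)."""

    kind: str
    start_ms: int
    end_ms: int

    @property
    def n_samples(self) -> int:
        return self.end_ms - self.start_ms


#: Figure-onset-aligned window, chords 5-8 after figure onset.
ONSET_WINDOW = AnalysisWindow("onset", 201, 401)
#: Response-aligned window before touch-bar release.
RESPONSE_WINDOW = AnalysisWindow("response", -300, -100)
#: Miss trials: last 200 ms of the figure presentation (relative figure onset).
MISS_REFERENCE_WINDOW = AnalysisWindow("miss_reference", 800, 1000)
#: Control trials: same logic applied at a pseudo figure onset.
CONTROL_RANDOM_WINDOW = AnalysisWindow("control_random", 800, 1000)
#: Bar-release control experiment windows (relative to release).
MOTOR_RESPONSE_WINDOW = AnalysisWindow("motor_response", -301, -100)
MOTOR_BASELINE_WINDOW = AnalysisWindow("motor_baseline", -501, -300)

WINDOWS = {
    w.kind: w
    for w in (
        ONSET_WINDOW,
        RESPONSE_WINDOW,
        MISS_REFERENCE_WINDOW,
        CONTROL_RANDOM_WINDOW,
        MOTOR_RESPONSE_WINDOW,
        MOTOR_BASELINE_WINDOW,
    )
}


def mua_envelope(
    raw: np.ndarray,
    fs: float,
    band_hz: tuple[float, float] = (600.0, 9000.0),
    band_order: int = 4,
    lp_cutoff_hz: float = 200.0,
    lp_order: int = 3,
    out_fs: int = ENVELOPE_FS_HZ,
) -> np.ndarray:
    """Extract the 1-kHz MUA envelope from a wideband trace.

    Band-pass 600-9000 Hz -> rectify -> 3rd-order Butterworth low-pass at
    200 Hz -> decimate to 1 kHz.  ``fs`` must exceed twice the upper band
    edge and be an integer multiple of ``out_fs``.
    """
    raw = np.asarray(raw, dtype=float)
    if fs <= 2 * band_hz[1]:
        raise ValueError(f"sampling rate {fs} too low for band edge {band_hz[1]} Hz")
    step = fs / out_fs
    if abs(step - round(step)) > 1e-9:
        raise ValueError(f"fs={fs} is not an integer multiple of out_fs={out_fs}")
    sos_bp = sps.butter(band_order, band_hz, btype="bandpass", fs=fs, output="sos")
    x = np.abs(sps.sosfiltfilt(sos_bp, raw, axis=-1))
    sos_lp = sps.butter(lp_order, lp_cutoff_hz, btype="lowpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos_lp, x, axis=-1)
    return x[..., :: int(round(step))]


def saturated_trials(
    raw: np.ndarray,
    fs: float,
    full_scale: float,
    max_saturated_ms: float = 1.0,
) -> np.ndarray:
    """Flag trials with movement/saturation artifacts.

    A trial is flagged when its raw trace touches +-``full_scale`` for more
    than ``max_saturated_ms`` in total; flagged trials are dropped upstream.
    Returns a boolean mask over the leading (trial) axis.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    n_max = int(round(max_saturated_ms * fs / 1000.0))
    saturated = np.abs(raw) >= full_scale
    return saturated.sum(axis=-1) > n_max


def spike_density(
    spike_times_ms: np.ndarray,
    n_trials: int,
    t_start_ms: float,
    t_stop_ms: float,
    sd_ms: float = 5.0,
    dt_ms: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Spike-density function: unit-area Gaussians (SD 5 ms) per spike, summed
    and divided by the trial count.

    Returns ``(t_ms, rate_hz)``.  The time integral of the rate equals the
    mean spike count per trial (spikes well inside the trace bounds).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    spikes = np.asarray(spike_times_ms, dtype=float).ravel()
    t = np.arange(t_start_ms, t_stop_ms, dt_ms)
    dens = np.zeros_like(t)
    norm = 1.0 / (sd_ms * np.sqrt(2 * np.pi))
    for chunk in np.array_split(spikes, max(1, len(spikes) // 2000)):
        if len(chunk) == 0:
            continue
        d = (t[None, :] - chunk[:, None]) / sd_ms
        dens += norm * np.exp(-0.5 * d**2).sum(axis=0)
    rate_hz = dens * 1000.0 / n_trials  # per-ms density -> spikes/s
    return t, rate_hz


def baseline_normalize(
    x: np.ndarray,
    t0_ms: float,
    baseline_ms: float = 400.0,
    sound_onset_ms: float = 0.0,
) -> np.ndarray:
    """Baseline-normalize envelope traces: ``(x - mu_b) / mu_b`` with ``mu_b``
    the mean over the ``baseline_ms`` window before sound onset.

    ``x`` has time on the last axis at 1 kHz; ``t0_ms`` is the time of the
    first sample relative to sound onset (negative).  Raises if any baseline
    mean is non-positive or non-finite.
    """
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(float)
    i_on = int(round(sound_onset_ms - t0_ms))
    i_lo = i_on - int(round(baseline_ms))
    if i_lo < 0:
        raise ValueError("trace does not cover the full baseline window")
    mu = x[..., i_lo:i_on].mean(axis=-1, keepdims=True)
    if not np.all(np.isfinite(mu)) or np.any(mu <= 0):
        raise ValueError("degenerate baseline (non-positive or non-finite mean)")
    return (x - mu) / mu


def extract_window(
    trace: np.ndarray,
    t0_ms: float,
    event_time_ms: float,
    window: AnalysisWindow,
) -> float:
    """Mean of the trace over ``window`` aligned to ``event_time_ms``.

    ``t0_ms`` is the time of the first sample; indexing is half-open
    ``[event + start, event + end)`` at 1 ms.
    """
    i0 = int(round(event_time_ms + window.start_ms - t0_ms))
    i1 = i0 + window.n_samples
    if i0 < 0 or i1 > trace.shape[-1]:
        raise ValueError(
            f"window [{window.start_ms}, {window.end_ms}) at event "
            f"{event_time_ms} ms out of trace bounds"
        )
    val = np.mean(trace[..., i0:i1], axis=-1)
    return float(val) if np.ndim(val) == 0 else val


def window_means(
    traces: np.ndarray,
    t0_ms: float,
    event_times_ms: np.ndarray,
    window: AnalysisWindow,
) -> np.ndarray:
    """Vectorized :func:`extract_window` over trials.

    ``traces`` is ``(..., n_trials, T)``; ``event_times_ms`` has one event per
    trial (NaN yields NaN).  Returns window means with shape ``(..., n_trials)``.
    """
    traces = np.asarray(traces)
    events = np.asarray(event_times_ms, dtype=float)
    n_trials, T = traces.shape[-2], traces.shape[-1]
    out_shape = traces.shape[:-1]
    out = np.full(out_shape, np.nan)
    valid = np.isfinite(events)
    if not valid.any():
        return out
    starts = np.round(events[valid] + window.start_ms - t0_ms).astype(int)
    if starts.min() < 0 or (starts + window.n_samples).max() > T:
        raise ValueError("window out of trace bounds for at least one trial")
    idx = starts[:, None] + np.arange(window.n_samples)[None, :]
    sl = np.take_along_axis(
        traces[..., valid, :], idx[(None,) * (traces.ndim - 2) + (...,)], axis=-1
    )
    out[..., valid] = sl.mean(axis=-1)
    return out
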