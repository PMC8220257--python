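"""Canned simulation studies: planted-parameter recovery at desk scale.

Each study plants known effects with the synthetic session generator, runs
the analysis pipeline end to end and reports how well the planted values are
recovered.  Problem sizes are chosen so every study completes in minutes on
one core; the methods note records the sizes used.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps, stats

from . import behavior as beh
from . import figure_ground as fg
from . import pipeline, tonotopy
from .session import (
    BehaviorParams,
    SessionConfig,
    generate_session,
    make_sites,
    simulate_site_traces,
    simulate_trial_table,
    PRE_MS,
    STIM_DUR_MS,
)
from .stimulus import make_session_stimulus_set


def chord_locking_peak(seed: int = 0, n_trials: int = 50) -> dict:
    """Dominant spectral peak (above 5 Hz) of the trial-averaged envelope of a
    chord-locked site during SFG control stimulation.

    Simulates ``n_trials`` control-condition trials for one synthetic site,
    averages the envelopes, computes the periodogram of the stimulus period
    and returns the frequency of the largest peak above 5 Hz (expected: the
    20-Hz chord rate).
    """
    config = SessionConfig(n_sites=1, frac_modulated=0.0, n_reps=1)
    ss = np.random.SeedSequence(seed)
    ss_stim, ss_sites, ss_noise = ss.spawn(3)
    stimuli = [s for s in make_session_stimulus_set(ss_stim) if not s.is_figure]
    site = make_sites(config, np.random.default_rng(ss_sites))[0]
    reps = int(np.ceil(n_trials / len(stimuli)))
    trials = pd.DataFrame(
        {
            "stimulus_index": np.tile(np.arange(len(stimuli)), reps)[:n_trials],
            "release_time_ms": np.nan,
        }
    )
    env = simulate_site_traces(site, stimuli, trials, np.random.default_rng(ss_noise))
    mean_env = env.mean(axis=0)
    f, p = sps.periodogram(mean_env[PRE_MS : PRE_MS + STIM_DUR_MS], fs=1000.0,
                           detrend="constant")
    keep = f > 5.0
    peak_hz = float(f[keep][np.argmax(p[keep])])
    return {"peak_hz": peak_hz, "n_trials": n_trials}


def latency_recovery_study(
    seed: int = 0,
    n_sites: int = 20,
    planted_latency_ms: float = 110.0,
    n_boot: int = 5000,
    sites_per_session: int = 10,
) -> pd.DataFrame:
    """Recover a planted modulation-onset latency at high SNR.

    Simulates ``n_sites`` strongly modulated sites (figure gain 2 at both
    coherences, reduced envelope noise, broad tuning), runs the
    96-difference-curve bootstrap estimator on each and returns planted vs
    recovered latencies.
    """
    config = SessionConfig(
        n_sites=sites_per_session,
        frac_modulated=1.0,
        frac_anterior=0.0,
        fig_gain_posterior=2.0,
        fig_latency_ms=planted_latency_ms,
        noise_fast_sd=0.3,
        noise_slow_sd=0.1,
        tuning_bw_oct=3.0,  # broadly tuned sites: chord-content variability small
        n_reps=10,
    )
    rows = []
    rng = np.random.default_rng(seed + 12345)
    n_sessions = int(np.ceil(n_sites / sites_per_session))
    for s in range(n_sessions):
        bundle = generate_session(config, seed=seed + s)
        for i in range(len(bundle.sites)):
            if len(rows) >= n_sites:
                break
            figc, ctrc, t = pipeline.stimulus_trial_curves(bundle, i, seed=seed + s)
            res = fg.modulation_latency(figc, ctrc, t, n_boot=n_boot, rng=rng)
            rows.append(
                dict(
                    session=s,
                    site=bundle.sites[i].site_id,
                    planted_ms=planted_latency_ms,
                    recovered_ms=res.latency_ms,
                )
            )
    df = pd.DataFrame(rows)
    err = (df["recovered_ms"] - df["planted_ms"]).abs()
    df["within_30ms"] = err.le(30.0) & df["recovered_ms"].notna()
    return df


def classifier_calibration_study(
    seed: int = 0,
    n_sites: int = 500,
    n_reps: int = 10,
    alpha: float = 0.01,
    sites_per_batch: int = 50,
) -> dict:
    """Type-I error of the modulation classifier on null sites.

    Simulates sessions of non-modulated (unit figure gain) sites, runs the
    response-aligned t-test classification on each and reports the fraction
    flagged at ``alpha`` together with the central binomial 95% interval
    around ``alpha`` for ``n_sites`` draws.
    """
    n_flagged = 0
    n_done = 0
    batch_seed = 0
    while n_done < n_sites:
        n_batch = min(sites_per_batch, n_sites - n_done)
        config = SessionConfig(n_sites=n_batch, frac_modulated=0.0, n_reps=n_reps)
        bundle = generate_session(config, seed=seed * 10000 + batch_seed)
        results = pipeline.analyze_session(bundle, alpha=alpha, seed=batch_seed)
        n_flagged += int(results["is_modulated"].sum())
        n_done += n_batch
        batch_seed += 1
    lo = int(stats.binom.ppf(0.025, n_sites, alpha))
    hi = int(stats.binom.ppf(0.975, n_sites, alpha))
    return {
        "n_sites": n_sites,
        "n_flagged": n_flagged,
        "fraction": n_flagged / n_sites,
        "binomial_ci_counts": (lo, hi),
        "within_ci": lo <= n_flagged <= hi,
    }


def behavior_ordering_study(
    seed: int = 0,
    n_sessions: int = 100,
    n_reps: int = 20,
    params: BehaviorParams | None = None,
) -> dict:
    """Recovery of the planted behavioral orderings across meta-simulations.

    Each simulated session uses the default planted observer (hit rates
    0.85/0.95, reaction-time means 600/450 ms for Coh8/Coh12).  Returns the
    fraction of sessions recovering d'(Coh12) > d'(Coh8) and
    RT(Coh12) < RT(Coh8).
    """
    params = params or BehaviorParams()
    ss = np.random.SeedSequence(seed)
    d_ok = rt_ok = 0
    summaries = []
    for i, child in enumerate(ss.spawn(n_sessions)):
        rng = np.random.default_rng(child)
        stimuli = make_session_stimulus_set(child.spawn(1)[0])
        trials = simulate_trial_table(stimuli, n_reps, params, rng)
        summary = beh.session_behavior(trials)
        summary["session"] = i
        summaries.append(summary)
        d8 = summary.loc[summary["coherence"] == "coh8", "dprime"].iloc[0]
        d12 = summary.loc[summary["coherence"] == "coh12", "dprime"].iloc[0]
        rt8 = summary.loc[summary["coherence"] == "coh8", "mean_rt_ms"].iloc[0]
        rt12 = summary.loc[summary["coherence"] == "coh12", "mean_rt_ms"].iloc[0]
        d_ok += int(d12 > d8)
        rt_ok += int(rt12 < rt8)
    return {
        "n_sessions": n_sessions,
        "frac_dprime_ordered": d_ok / n_sessions,
        "frac_rt_ordered": rt_ok / n_sessions,
        "sessions": pd.concat(summaries, ignore_index=True),
    }


def regional_coherence_study(
    seed: int = 0,
    n_sites: int = 60,
    n_reps: int = 10,
) -> dict:
    """Anterior-only coherence sensitivity.

    Simulates a session whose anterior modulated sites have g12 > g8 while
    posterior modulated sites have g12 = g8, and reports the median
    Coh12-vs-Coh8 neurometric d' per field (onset-aligned windows).
    """
    config = SessionConfig(n_sites=n_sites, frac_modulated=1.0, frac_anterior=0.5,
                           n_reps=n_reps)
    bundle = generate_session(config, seed=seed)
    results = pipeline.analyze_session(bundle, seed=seed)
    ant = results.loc[results["field"] == "anterior", "dprime_coh"].dropna()
    pos = results.loc[results["field"] == "posterior", "dprime_coh"].dropna()
    return {
        "median_dprime_coh_anterior": float(ant.median()),
        "median_dprime_coh_posterior": float(pos.median()),
        "n_anterior": len(ant),
        "n_posterior": len(pos),
        "results": results,
    }


def tonotopy_recovery_study(
    seed: int = 0,
    sites_per_cell: int = 2,
    n_reps: int = 10,
    grid_nx: int = 4,
    grid_ny: int = 10,
) -> dict:
    """Planted tonotopic gradient: BF recovery and boundary placement.

    Plants a high->low->high best-frequency gradient with the reversal
    between anteroposterior rows 4 and 5, simulates tone-battery responses,
    recovers per-site BFs, builds and smooths the map and reports the
    gradient-reversal boundary plus BF recovery errors (octaves).
    """
    config = SessionConfig(n_sites=grid_nx * grid_ny * sites_per_cell,
                           frac_anterior=0.5, grid_nx=grid_nx, grid_ny=grid_ny)
    ss = np.random.SeedSequence(seed)
    ss_sites, ss_tones = ss.spawn(2)
    sites = make_sites(config, np.random.default_rng(ss_sites))
    rows = []
    for site, child in zip(sites, ss_tones.spawn(len(sites))):
        traces, table = simulate_tone_trials_for(site, child, n_reps)
        char = tonotopy.characterize_site(traces, table, t0_ms=-300.0,
                                          site_id=site.site_id)
        if char.included:
            rows.append(
                dict(
                    site=site.site_id, x=site.grid_x, y=site.grid_y,
                    bf_true_hz=site.bf_hz, bf_est_hz=char.bf_hz,
                    err_oct=abs(np.log2(char.bf_hz / site.bf_hz)),
                )
            )
    df = pd.DataFrame(rows)
    map_ = tonotopy.build_map(df["x"], df["y"], np.log2(df["bf_est_hz"]))
    smoothed = tonotopy.smooth_map(map_)
    boundary = tonotopy.reversal_boundary(smoothed)
    return {
        "boundary": boundary.position,
        "monotone_warning": boundary.monotone_warning,
        "median_bf_error_oct": float(df["err_oct"].median()),
        "n_included": len(df),
        "n_sites": len(sites),
        "sites": df,
    }


def simulate_tone_trials_for(site, seed, n_reps: int = 10):
    from .session import simulate_tone_trials

    return simulate_tone_trials(site, np.random.default_rng(seed), n_reps=n_reps)
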