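"""Session-level analysis pipeline: window scalars -> per-site results.

Ties the modules together for one session bundle:

1. baseline-normalize every envelope trace using the 400 ms before sound
   onset;
2. reduce each trial to onset-aligned and response-aligned window means
   (control trials get a pseudo figure onset drawn once per session from the
   real onset distribution, with a fixed seed);
3. per site: sound responsiveness, modulation classification, neurometric
   d-primes, AUROC contrasts, and (optionally) the bootstrap modulation-onset
   latency from per-stimulus mean curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import figure_ground as fg
from . import tonotopy
from .signal import (
    CONTROL_RANDOM_WINDOW,
    MISS_REFERENCE_WINDOW,
    ONSET_WINDOW,
    RESPONSE_WINDOW,
    baseline_normalize,
    window_means,
)
from .stimulus import CHORD_DUR_MS, ONSET_MAX_CHORD, ONSET_MIN_CHORD

#: Contrasts computed per alignment for every site.
CONTRASTS = ("fig_vs_ctr", "coh12_vs_coh8", "hit_vs_miss", "miss_vs_cr")
ALIGNMENTS = ("onset", "response")


def draw_pseudo_onsets(n: int, rng: np.random.Generator | int | None) -> np.ndarray:
    """Pseudo figure onsets for control trials, drawn from the real onset
    distribution (uniform over chords 6..40, i.e. 300-2000 ms)."""
    rng = np.random.default_rng(rng)
    return CHORD_DUR_MS * rng.integers(ONSET_MIN_CHORD, ONSET_MAX_CHORD + 1, size=n)


def trial_events(trials: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Per-trial alignment events for the onset and response windows.

    Returns a copy of the trial table with ``pseudo_onset_ms`` (controls),
    ``onset_event_ms``/``onset_window`` and ``response_event_ms``/
    ``response_window`` columns.  False-alarm trials get no response window.
    """
    out = trials.copy()
    is_ctr = (out["condition"] == "control").to_numpy()
    pseudo = np.full(len(out), np.nan)
    pseudo[is_ctr] = draw_pseudo_onsets(int(is_ctr.sum()), seed)
    out["pseudo_onset_ms"] = pseudo

    onset_event = np.where(is_ctr, pseudo, out["figure_onset_ms"].to_numpy(float))
    out["onset_event_ms"] = onset_event

    resp_event = np.full(len(out), np.nan)
    resp_window = np.array([""] * len(out), dtype=object)
    for i, row in enumerate(out.itertuples()):
        if row.outcome == "hit":
            resp_event[i] = row.release_time_ms
            resp_window[i] = RESPONSE_WINDOW.kind
        elif row.outcome == "miss":
            resp_event[i] = row.figure_onset_ms
            resp_window[i] = MISS_REFERENCE_WINDOW.kind
        elif row.outcome == "CR":
            resp_event[i] = row.pseudo_onset_ms
            resp_window[i] = CONTROL_RANDOM_WINDOW.kind
    out["response_event_ms"] = resp_event
    out["response_window"] = resp_window
    return out


def session_window_scalars(bundle, seed: int = 0) -> pd.DataFrame:
    """Long-format window-scalar table keyed by (site, trial, window kind).

    Values are means of the baseline-normalized envelope over the onset
    window (201-400 ms after the real or pseudo figure onset) and over the
    response window (release-aligned for hits, last 200 ms of the figure for
    misses, pseudo-onset logic for correct rejections).
    """
    events = trial_events(bundle.trials, seed=seed)
    norm = baseline_normalize(np.asarray(bundle.traces, dtype=float), bundle.t0_ms)
    onset_vals = window_means(norm, bundle.t0_ms, events["onset_event_ms"].to_numpy(),
                              ONSET_WINDOW)
    frames = []
    n_sites, n_trials = norm.shape[:2]
    site_ids = np.array([s.site_id for s in bundle.sites])
    for kind_name, window in (
        ("response", RESPONSE_WINDOW),
        ("miss_reference", MISS_REFERENCE_WINDOW),
        ("control_random", CONTROL_RANDOM_WINDOW),
    ):
        sel = (events["response_window"] == window.kind).to_numpy()
        if not sel.any():
            continue
        vals = window_means(
            norm[:, sel, :], bundle.t0_ms,
            events.loc[sel, "response_event_ms"].to_numpy(), window,
        )
        frames.append(
            pd.DataFrame(
                {
                    "site": np.repeat(site_ids, sel.sum()),
                    "trial": np.tile(events.loc[sel, "trial_id"].to_numpy(), n_sites),
                    "kind": "response",
                    "value": vals.ravel(),
                }
            )
        )
    frames.append(
        pd.DataFrame(
            {
                "site": np.repeat(site_ids, n_trials),
                "trial": np.tile(events["trial_id"].to_numpy(), n_sites),
                "kind": "onset",
                "value": onset_vals.ravel(),
            }
        )
    )
    scalars = pd.concat(frames, ignore_index=True)
    meta = events[["trial_id", "condition", "outcome"]].rename(columns={"trial_id": "trial"})
    return scalars.merge(meta, on="trial", how="left")


@dataclass
class ModulationResult:
    """Per-site figure-ground modulation summary."""

    site_id: int
    p_ttest: float
    sound_responsive: bool
    is_modulated: bool
    dprime_fig_ctr: float
    dprime_coh: Optional[float]
    auroc: dict
    latency_ms: Optional[float]
    n_miss: int


def _groups(scalars: pd.DataFrame, kind: str):
    s = scalars[scalars["kind"] == kind]
    hit = s.loc[s["outcome"] == "hit", "value"].to_numpy()
    miss = s.loc[s["outcome"] == "miss", "value"].to_numpy()
    cr = s.loc[s["outcome"] == "CR", "value"].to_numpy()
    hit8 = s.loc[(s["outcome"] == "hit") & (s["condition"] == "coh8"), "value"].to_numpy()
    hit12 = s.loc[(s["outcome"] == "hit") & (s["condition"] == "coh12"), "value"].to_numpy()
    return hit, miss, cr, hit8, hit12


def stimulus_trial_curves(
    bundle, site_index: int, seed: int = 0,
    t_lo_ms: float = -200.0, t_hi_ms: float = 1100.0,
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Per-stimulus trial curves (baseline-normalized envelopes) on a
    figure-onset-aligned time base, the input of the latency estimator.

    Figure stimuli are aligned at their true figure onset; control stimuli at
    session pseudo onsets (one per control stimulus, drawn once with a fixed
    seed from the real onset distribution).

    Returns ``(figure_sets, control_sets, t_ms)`` where each element of the
    lists is an ``(n_trials, T)`` array for one stimulus.
    """
    norm = baseline_normalize(np.asarray(bundle.traces[site_index], dtype=float),
                              bundle.t0_ms)
    trials = bundle.trials
    rng = np.random.default_rng(seed)
    t = np.arange(t_lo_ms, t_hi_ms)
    fig_sets, ctr_sets = [], []
    for si, stim in enumerate(bundle.stimuli):
        sel = (trials["stimulus_index"] == si).to_numpy()
        if not sel.any():
            continue
        onset = (
            stim.figure_onset_ms
            if stim.is_figure
            else float(draw_pseudo_onsets(1, rng)[0])
        )
        i0 = int(round(onset + t_lo_ms - bundle.t0_ms))
        seg = norm[sel, i0 : i0 + len(t)]
        (fig_sets if stim.is_figure else ctr_sets).append(seg)
    return fig_sets, ctr_sets, t


def stimulus_mean_curves(
    bundle, site_index: int, seed: int = 0,
    t_lo_ms: float = -200.0, t_hi_ms: float = 1100.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-stimulus mean curves (trial averages of
    :func:`stimulus_trial_curves`)."""
    fig_sets, ctr_sets, t = stimulus_trial_curves(bundle, site_index, seed,
                                                  t_lo_ms, t_hi_ms)
    return (
        np.stack([c.mean(axis=0) for c in fig_sets]),
        np.stack([c.mean(axis=0) for c in ctr_sets]),
        t,
    )


def analyze_site(
    scalars: pd.DataFrame,
    responsive: bool,
    site_id: int,
    alpha: float = 0.01,
    equal_var: bool = True,
    min_miss_trials: int = 20,
) -> ModulationResult:
    """Classification, d-primes and AUROC contrasts from one site's scalars."""
    hit_r, miss_r, cr_r, hit8_r, hit12_r = _groups(scalars, "response")
    hit_o, miss_o, cr_o, hit8_o, hit12_o = _groups(scalars, "onset")
    p, modulated = fg.classify_modulated(hit_r, cr_r, responsive, alpha=alpha,
                                         equal_var=equal_var)
    n_miss = len(miss_r)
    groups = {
        "onset": dict(hit=hit_o, miss=miss_o, cr=cr_o, h8=hit8_o, h12=hit12_o),
        "response": dict(hit=hit_r, miss=miss_r, cr=cr_r, h8=hit8_r, h12=hit12_r),
    }
    aurocs = {}
    for align, g in groups.items():
        aurocs[("fig_vs_ctr", align)] = fg.auroc(g["hit"], g["cr"])
        aurocs[("coh12_vs_coh8", align)] = fg.auroc(g["h12"], g["h8"])
        if n_miss >= min_miss_trials:
            aurocs[("hit_vs_miss", align)] = fg.auroc(g["hit"], g["miss"])
            aurocs[("miss_vs_cr", align)] = fg.auroc(g["miss"], g["cr"])
    dprime_coh = (
        fg.neurometric_dprime(hit12_o, hit8_o) if len(hit8_o) > 1 and len(hit12_o) > 1 else None
    )
    return ModulationResult(
        site_id=site_id,
        p_ttest=p,
        sound_responsive=responsive,
        is_modulated=modulated,
        dprime_fig_ctr=fg.neurometric_dprime(hit_o, cr_o),
        dprime_coh=dprime_coh,
        auroc=aurocs,
        latency_ms=None,
        n_miss=n_miss,
    )


def analyze_session(
    bundle,
    alpha: float = 0.01,
    seed: int = 0,
    compute_latency: bool = False,
    n_boot: int = 5000,
    equal_var: bool = True,
    min_miss_trials: int = 20,
) -> pd.DataFrame:
    """Full per-site figure-ground analysis of a session bundle.

    Returns one row per site (classification, d-primes, AUROCs, latency).
    """
    scalars = session_window_scalars(bundle, seed=seed)
    is_ctr = (bundle.trials["condition"] == "control").to_numpy()
    rows = []
    rng = np.random.default_rng(seed + 1)
    for i, site in enumerate(bundle.sites):
        responsive = tonotopy.sound_responsive(
            np.asarray(bundle.traces[i, is_ctr], dtype=float), bundle.t0_ms
        )
        res = analyze_site(
            scalars[scalars["site"] == site.site_id], responsive, site.site_id,
            alpha=alpha, equal_var=equal_var, min_miss_trials=min_miss_trials,
        )
        if compute_latency and res.is_modulated:
            figc, ctrc, t = stimulus_trial_curves(bundle, i, seed=seed)
            lat = fg.modulation_latency(figc, ctrc, t, n_boot=n_boot, rng=rng)
            res.latency_ms = lat.latency_ms
        row = {
            "site": site.site_id,
            "field": site.field_label,
            "p_ttest": res.p_ttest,
            "sound_responsive": res.sound_responsive,
            "is_modulated": res.is_modulated,
            "dprime_fig_ctr": res.dprime_fig_ctr,
            "dprime_coh": res.dprime_coh,
            "latency_ms": res.latency_ms,
            "n_miss": res.n_miss,
        }
        for (contrast, align), val in res.auroc.items():
            row[f"auroc_{contrast}_{align}"] = val
        rows.append(row)
    return pd.DataFrame(rows)
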