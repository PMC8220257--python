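"""Go/no-go trial scoring and behavioral metrics (d', reaction time, CV).

Trials are scored from figure-onset and touch-bar-release times: a release
within the 900-ms window after figure onset is a hit, a figure trial without
such a release is a miss; on control trials any release before stimulus end
is a false alarm, otherwise a correct rejection.  Reaction time runs from
figure onset to release.  Session sensitivity is d' = Z(hit) - Z(FA) with
1/(2n) clamping of extreme rates so Z stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

RESPONSE_WINDOW_MS = 900.0
STIM_DUR_MS = 3000.0

OUTCOMES = ("hit", "miss", "CR", "FA")


def score_trial(
    is_figure: bool,
    figure_onset_ms: Optional[float],
    release_time_ms: Optional[float],
    stim_dur_ms: float = STIM_DUR_MS,
    response_window_ms: float = RESPONSE_WINDOW_MS,
) -> tuple[str, Optional[float]]:
    """Score one trial; returns ``(outcome, reaction_time_ms)``.

    Reaction time is defined (hits only) from figure onset to release.
    Raises for releases before sound onset (invalid trial, excluded upstream).
    """
    rel = release_time_ms
    if rel is not None and not np.isfinite(rel):
        rel = None
    if rel is not None and rel < 0:
        raise ValueError("release before sound onset: invalid trial")
    if is_figure:
        if figure_onset_ms is None:
            raise ValueError("figure trial without figure onset")
        if rel is not None and figure_onset_ms <= rel <= figure_onset_ms + response_window_ms:
            return "hit", rel - figure_onset_ms
        return "miss", None
    if rel is not None and rel < stim_dur_ms:
        return "FA", None
    return "CR", None


def score_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Vector version of :func:`score_trial` over a trial table with columns
    ``condition`` (coh8|coh12|control), ``figure_onset_ms``, ``release_time_ms``."""
    out = trials.copy()
    outcomes, rts = [], []
    for _, row in trials.iterrows():
        is_fig = row["condition"] != "control"
        onset = row["figure_onset_ms"] if is_fig else None
        rel = row["release_time_ms"]
        rel = None if pd.isna(rel) else float(rel)
        outcome, rt = score_trial(is_fig, onset, rel)
        outcomes.append(outcome)
        rts.append(np.nan if rt is None else rt)
    out["outcome"] = outcomes
    out["reaction_time_ms"] = rts
    return out


def _clamp_rate(k: int, n: int) -> float:
    if n <= 0:
        raise ValueError("rate correction needs n > 0")
    lo, hi = 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)
    return float(np.clip(k / n, lo, hi))


def session_dprime(hit_rate: float, fa_rate: float, n_signal: int, n_noise: int) -> float:
    """Session d' = Z(hit rate) - Z(FA rate), rates clamped to
    [1/(2n), 1 - 1/(2n)] before the inverse-normal transform."""
    if n_signal <= 0 or n_noise <= 0:
        raise ValueError("n_signal and n_noise must be positive")
    h = float(np.clip(hit_rate, 1.0 / (2 * n_signal), 1.0 - 1.0 / (2 * n_signal)))
    f = float(np.clip(fa_rate, 1.0 / (2 * n_noise), 1.0 - 1.0 / (2 * n_noise)))
    return float(stats.norm.ppf(h) - stats.norm.ppf(f))


def rt_stats(rts_ms: Iterable[float]) -> tuple[float, float]:
    """Mean reaction time and coefficient of variation (sample SD / mean)."""
    rts = np.asarray(list(rts_ms), dtype=float)
    if len(rts) < 2:
        raise ValueError("need at least 2 hits for RT statistics")
    mean = float(rts.mean())
    return mean, float(rts.std(ddof=1) / mean)


@dataclass
class SessionBehavior:
    """Per-coherence behavioral summary of one session."""

    coherence: str
    n_trials: int
    n_figure: int
    n_control: int
    hit_rate: float
    fa_rate: float
    dprime: float
    mean_rt_ms: float
    cv_rt: float
    response_window_ms: float = RESPONSE_WINDOW_MS


def session_behavior(trials: pd.DataFrame) -> pd.DataFrame:
    """Summarize a scored trial table per coherence level.

    Control trials (and thus the FA rate) are shared between coherences.
    Returns one row per coherence with columns matching
    :class:`SessionBehavior`.
    """
    ctr = trials[trials["condition"] == "control"]
    n_noise = len(ctr)
    n_fa = int((ctr["outcome"] == "FA").sum())
    fa_rate = n_fa / n_noise if n_noise else np.nan
    rows = []
    for coh in ("coh8", "coh12"):
        sub = trials[trials["condition"] == coh]
        n_sig = len(sub)
        n_hit = int((sub["outcome"] == "hit").sum())
        hit_rate = n_hit / n_sig if n_sig else np.nan
        d = session_dprime(hit_rate, fa_rate, n_sig, n_noise)
        rts = sub.loc[sub["outcome"] == "hit", "reaction_time_ms"].dropna()
        if len(rts) >= 2:
            mean_rt, cv = rt_stats(rts)
        else:
            mean_rt, cv = np.nan, np.nan
        rows.append(
            dict(
                coherence=coh,
                n_trials=len(trials),
                n_figure=n_sig,
                n_control=n_noise,
                hit_rate=hit_rate,
                fa_rate=fa_rate,
                dprime=d,
                mean_rt_ms=mean_rt,
                cv_rt=cv,
            )
        )
    return pd.DataFrame(rows)


def smd(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference (pooled-SD form, same as neurometric d')."""
    from .figure_ground import neurometric_dprime

    return neurometric_dprime(a, b)


def compare_coherence(sessions: pd.DataFrame, min_trials: int = 200) -> pd.DataFrame:
    """Across-session Coh12-vs-Coh8 comparison of d', mean RT and CV.

    ``sessions`` stacks :func:`session_behavior` outputs with a ``session``
    column.  Sessions with ``n_trials <= min_trials`` are excluded (the
    "more than 200 trials" session filter).  Returns per-metric SMD and a
    two-sided Wilcoxon rank-sum p value.
    """
    kept = sessions[sessions["n_trials"] > min_trials]
    if kept["session"].nunique() < 2:
        raise ValueError("need at least 2 sessions after the trial-count filter")
    rows = []
    for metric in ("dprime", "mean_rt_ms", "cv_rt"):
        a = kept.loc[kept["coherence"] == "coh12", metric].dropna().to_numpy()
        b = kept.loc[kept["coherence"] == "coh8", metric].dropna().to_numpy()
        stat, p = stats.ranksums(a, b)
        rows.append(dict(metric=metric, smd=smd(a, b), z=stat, p=p,
                         n_sessions=kept["session"].nunique()))
    return pd.DataFrame(rows)
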