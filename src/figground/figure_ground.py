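"""Figure-ground modulation: classification, neurometric d', AUROC, latency.

A site is "modulated" when the response-aligned window means of correctly
performed figure trials differ from the pseudo-randomly windowed control
trials (two-sample t test, p < 0.01) and the site is 20-Hz sound responsive.
Modulation magnitude is the neurometric d' (standardized mean difference,
pooled SD) and the non-parametric AUROC.  The modulation-onset latency pools
the per-stimulus figure-minus-control difference curves (12 x 8 = 96 for a
standard session), bootstraps the per-bin pooled mean (5000 resamples) and
takes the first post-onset bin with two-sided percentile p < 0.01 that is
followed by at least four more consecutively significant bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats


def neurometric_dprime(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """d_AB = (m_A - m_B) / s with s the pooled standard deviation.

    Antisymmetric under swapping A and B.  Raises on zero pooled SD.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    na, nb = len(a), len(b)
    s2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if s2 <= 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / np.sqrt(s2))


#: Standardized mean difference: identical formula, for non-neural contrasts.
smd = neurometric_dprime


def auroc(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Area under the ROC: P(random A > random B), ties counted 1/2
    (Mann-Whitney U divided by n_A * n_B)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    u = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
    return float(u / (len(a) * len(b)))


def classify_modulated(
    figure_values: np.ndarray,
    control_values: np.ndarray,
    sound_responsive: bool = True,
    alpha: float = 0.01,
    equal_var: bool = True,
) -> tuple[float, bool]:
    """Two-sample t test of response-aligned figure-trial window means against
    pseudo-windowed control-trial means; modulated iff p < alpha AND the site
    is sound responsive.  ``equal_var=False`` switches to Welch's t."""
    a = np.asarray(figure_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 trials per group")
    p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
    return p, bool(p < alpha and sound_responsive)


# ---------------------------------------------------------------------------
# Modulation-onset latency
# ---------------------------------------------------------------------------

@dataclass
class DifferenceCurveSet:
    """All pairwise figure-minus-control mean-difference curves on a common
    figure-onset-aligned time base."""

    curves: np.ndarray  # (n_fig * n_ctr, T)
    t_ms: np.ndarray
    n_figure: int
    n_control: int


@dataclass
class LatencyResult:
    latency_ms: Optional[float]
    p_per_bin: np.ndarray
    t_ms: np.ndarray
    n_curves: int


def difference_curves(
    figure_curves: np.ndarray, control_curves: np.ndarray, t_ms: np.ndarray
) -> DifferenceCurveSet:
    """Fig_x - Ctr_y for every (figure stimulus, control stimulus) pair."""
    f = np.asarray(figure_curves, dtype=float)
    c = np.asarray(control_curves, dtype=float)
    if f.ndim != 2 or c.ndim != 2 or f.shape[1] != c.shape[1]:
        raise ValueError("curves must be 2-D with a shared time base")
    if len(f) < 2 or len(c) < 2:
        raise ValueError("need >= 2 stimuli per class")
    d = (f[:, None, :] - c[None, :, :]).reshape(-1, f.shape[1])
    return DifferenceCurveSet(curves=d, t_ms=np.asarray(t_ms), n_figure=len(f),
                              n_control=len(c))


def _stim_means(curve_sets: Sequence[np.ndarray]) -> np.ndarray:
    return np.stack([np.asarray(c, dtype=float).mean(axis=0) for c in curve_sets])


def _boot_class_mean(
    curve_sets: Sequence[np.ndarray], n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Bootstrap the across-stimulus mean curve of one class by resampling
    trials with replacement within each stimulus."""
    acc = None
    for c in curve_sets:
        c = np.asarray(c, dtype=float)
        n = c.shape[0]
        w = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot) / n
        m = w @ c
        acc = m if acc is None else acc + m
    return acc / len(curve_sets)


def modulation_latency(
    figure_curves: Sequence[np.ndarray] | np.ndarray,
    control_curves: Sequence[np.ndarray] | np.ndarray,
    t_ms: np.ndarray,
    n_boot: int = 5000,
    alpha: float = 0.01,
    min_run: int = 5,
    rng: np.random.Generator | int | None = None,
    resample: str = "trials",
) -> LatencyResult:
    """Bootstrap modulation-onset latency.

    The per-bin statistic is the mean of the pooled figure-minus-control
    difference curves (equivalently, mean figure curve minus mean control
    curve).  Its distribution is bootstrapped with 5000 resamples; each
    bin's two-sided percentile p value is
    ``2 * min(P(mean* <= 0), P(mean* >= 0))``, and the latency is the first
    bin after figure onset (t > 0) opening a run of >= ``min_run``
    consecutively significant bins (``None`` if no such run exists).

    ``resample`` selects the bootstrap unit:

    * ``"trials"`` (default): per-stimulus trial curves are required
      (sequences of ``(n_trials, T)`` arrays); trials are resampled within
      each stimulus and the pooled mean recomputed.  This respects the
      dependence structure of the 96 difference curves (each figure curve
      enters 8 of them) and yields calibrated per-bin p values.
    * ``"curves"``: resample the pooled difference curves themselves.  This
      treats the 96 curves as exchangeable, underestimates the sampling
      variability of the pooled mean (the curves share only 20 underlying
      stimulus responses) and is anti-conservative; provided for
      completeness.
    """
    fig_sets = [np.atleast_2d(np.asarray(c, dtype=float)) for c in figure_curves]
    ctr_sets = [np.atleast_2d(np.asarray(c, dtype=float)) for c in control_curves]
    fig_means = _stim_means(fig_sets)
    ctr_means = _stim_means(ctr_sets)
    dcs = difference_curves(fig_means, ctr_means, t_ms)
    rng = np.random.default_rng(rng)
    if resample == "trials":
        boot_means = _boot_class_mean(fig_sets, n_boot, rng) - _boot_class_mean(
            ctr_sets, n_boot, rng
        )
    elif resample == "curves":
        n = dcs.curves.shape[0]
        counts = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot)
        boot_means = counts @ dcs.curves / n
    else:
        raise ValueError("resample must be 'trials' or 'curves'")
    p_le = (boot_means <= 0).mean(axis=0)
    p_ge = (boot_means >= 0).mean(axis=0)
    p = np.minimum(2.0 * np.minimum(p_le, p_ge), 1.0)
    sig = p < alpha
    t = dcs.t_ms
    latency = None
    if len(sig) >= min_run:
        runs = np.all(
            np.lib.stride_tricks.sliding_window_view(sig, min_run), axis=1
        )
        candidates = np.flatnonzero(runs & (t[: len(runs)] > 0))
        if len(candidates):
            latency = float(t[candidates[0]])
    return LatencyResult(latency_ms=latency, p_per_bin=p, t_ms=t,
                         n_curves=dcs.curves.shape[0])


# ---------------------------------------------------------------------------
# Population summaries and helpers
# ---------------------------------------------------------------------------

def fdr_correct(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR: returns (reject, adjusted p)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def wilcoxon_ranksum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (unpaired); returns (z, p)."""
    res = stats.ranksums(a, b)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signrank(a: np.ndarray, b: Optional[np.ndarray] = None) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank (paired, or one-sample against 0)."""
    res = stats.wilcoxon(a) if b is None else stats.wilcoxon(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass
class PopulationTimecourse:
    t_ms: np.ndarray
    mean_figure: np.ndarray
    sem_figure: np.ndarray
    mean_control: np.ndarray
    sem_control: np.ndarray
    p_per_bin: np.ndarray
    significant: np.ndarray  # after FDR


def population_timecourse(
    figure_site_curves: np.ndarray,
    control_site_curves: np.ndarray,
    t_ms: np.ndarray,
    q: float = 0.05,
) -> PopulationTimecourse:
    """Across-site mean +- SEM per bin with per-bin two-sided rank-sum tests
    (figure vs control across sites), Benjamini-Hochberg corrected at q."""
    f = np.asarray(figure_site_curves, dtype=float)
    c = np.asarray(control_site_curves, dtype=float)
    if f.shape[0] < 2 or c.shape[0] < 2:
        raise ValueError("need >= 2 sites")
    sem_f = f.std(axis=0, ddof=1) / np.sqrt(f.shape[0])
    sem_c = c.std(axis=0, ddof=1) / np.sqrt(c.shape[0])
    p = np.array([stats.ranksums(f[:, i], c[:, i]).pvalue for i in range(f.shape[1])])
    reject, _ = fdr_correct(p, q=q)
    return PopulationTimecourse(
        t_ms=np.asarray(t_ms), mean_figure=f.mean(axis=0), sem_figure=sem_f,
        mean_control=c.mean(axis=0), sem_control=sem_c, p_per_bin=p,
        significant=reject,
    )


def motor_control_analysis(bundle) -> dict:
    """Bar-release control: per-site difference between the response-aligned
    window (-301 to -100 ms before release) and the baseline window (-501 to
    -300 ms), plus an across-site signed-rank test against zero.

    Traces are normalized per trial by their mean over a neutral reference
    period (-800 to -501 ms before release) so the difference is expressed as
    a fraction of ongoing activity.
    """
    from .signal import MOTOR_BASELINE_WINDOW, MOTOR_RESPONSE_WINDOW, window_means

    if bundle.kind != "bar_release":
        raise ValueError("expected a bar-release session bundle")
    traces = np.asarray(bundle.traces, dtype=float)
    t0 = bundle.t0_ms
    i_ref0, i_ref1 = int(round(-800 - t0)), int(round(-501 - t0))
    ref = traces[..., i_ref0:i_ref1].mean(axis=-1, keepdims=True)
    norm = traces / ref
    events = np.zeros(traces.shape[1])  # release at t = 0 in these bundles
    resp = window_means(norm, t0, events, MOTOR_RESPONSE_WINDOW)
    base = window_means(norm, t0, events, MOTOR_BASELINE_WINDOW)
    per_site = (resp - base).mean(axis=-1)
    stat, p = wilcoxon_signrank(per_site)
    return {
        "per_site_difference": per_site,
        "mean_difference": float(per_site.mean()),
        "sem_difference": float(per_site.std(ddof=1) / np.sqrt(len(per_site)))
        if len(per_site) > 1
        else np.nan,
        "signrank_stat": stat,
        "p": p,
    }
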