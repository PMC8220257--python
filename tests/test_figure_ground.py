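"""Neurometric d', AUROC, classifier, latency and population statistics."""

import numpy as np
import pytest
from scipy import stats

from figground import figure_ground as fg
from figground import session as ses


class TestDprime:
    def test_identical_samples_zero(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert fg.neurometric_dprime(a, a.copy()) == 0.0

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            fg.neurometric_dprime([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])

    def test_gaussian_oracle(self, rng):
        n = 10**4
        a = rng.normal(0.5, 1.0, n)
        b = rng.normal(0.0, 1.0, n)
        se = np.sqrt(2.0 / n)  # large-sample SE of d at small d
        assert abs(fg.neurometric_dprime(a, b) - 0.5) < 3 * se

    def test_antisymmetry(self, rng):
        a, b = rng.normal(0, 1, 50), rng.normal(1, 2, 60)
        assert fg.neurometric_dprime(a, b) == pytest.approx(-fg.neurometric_dprime(b, a))


class TestAuroc:
    def test_separated_groups(self):
        assert fg.auroc([10.0, 11.0], [1.0, 2.0]) == 1.0
        assert fg.auroc([1.0, 2.0], [10.0, 11.0]) == 0.0

    def test_identical_distributions_half(self, rng):
        a, b = rng.normal(0, 1, 3000), rng.normal(0, 1, 3000)
        assert abs(fg.auroc(a, b) - 0.5) < 0.03

    def test_ties_counted_half_brute_force(self):
        a = np.array([1.0, 2.0, 2.0, 3.0])
        b = np.array([2.0, 2.0, 0.0])
        wins = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        assert fg.auroc(a, b) == pytest.approx(wins / (len(a) * len(b)))

    def test_gaussian_shift_closed_form(self, rng):
        # equal-variance SDT: AUROC = Phi(d / sqrt(2)); d = 1 -> 0.7602
        a = rng.normal(1.0, 1.0, 10**4)
        b = rng.normal(0.0, 1.0, 10**4)
        assert abs(fg.auroc(a, b) - stats.norm.cdf(1 / np.sqrt(2))) < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fg.auroc([], [1.0])


class TestClassifier:
    def test_identical_groups_not_modulated(self):
        vals = np.array([1.0, 1.1, 0.9, 1.0, 1.05])
        p, mod = fg.classify_modulated(vals, vals.copy())
        assert p > 0.95 and not mod

    def test_not_sound_responsive_never_modulated(self, rng):
        a, b = rng.normal(1, 0.1, 40), rng.normal(0, 0.1, 40)
        p, mod = fg.classify_modulated(a, b, sound_responsive=False)
        assert p < 0.01 and not mod

    def test_power_matches_noncentral_t_oracle(self, rng):
        # planted standardized effect 0.8, 40 + 40 trials, alpha 0.01:
        # exact power from the noncentral t distribution
        d, n, alpha, n_sim = 0.8, 40, 0.01, 200
        ncp = d * np.sqrt(n / 2)
        tcrit = stats.t.ppf(1 - alpha / 2, 2 * n - 2)
        power = 1 - stats.nct.cdf(tcrit, 2 * n - 2, ncp) + stats.nct.cdf(-tcrit, 2 * n - 2, ncp)
        hits = 0
        for _ in range(n_sim):
            a = rng.normal(d, 1.0, n)
            b = rng.normal(0.0, 1.0, n)
            _, mod = fg.classify_modulated(a, b, alpha=alpha)
            hits += mod
        se = np.sqrt(power * (1 - power) / n_sim)
        assert abs(hits / n_sim - power) < 3.5 * se

    def test_welch_flag(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0, 5, 200)
        p_pooled, _ = fg.classify_modulated(a, b, equal_var=True)
        p_welch, _ = fg.classify_modulated(a, b, equal_var=False)
        assert p_pooled != p_welch


class TestLatency:
    def _curves(self, rng, n_fig=12, n_ctr=8, n_reps=10, T=700, t0=-200,
                effect=0.0, onset_ms=110.0, ramp_ms=100.0, noise=0.1):
        t = np.arange(t0, T + t0, dtype=float)
        step = effect * np.clip((t - onset_ms) / ramp_ms, 0, 1)
        fig = [step + noise * rng.standard_normal((n_reps, T)) for _ in range(n_fig)]
        ctr = [noise * rng.standard_normal((n_reps, T)) for _ in range(n_ctr)]
        return fig, ctr, t

    def test_96_difference_curves(self, rng):
        fig, ctr, t = self._curves(rng)
        dcs = fg.difference_curves(np.stack([c.mean(0) for c in fig]),
                                   np.stack([c.mean(0) for c in ctr]), t)
        assert dcs.curves.shape[0] == 96 == dcs.n_figure * dcs.n_control

    def test_planted_step_recovered(self, rng):
        hits = 0
        for _ in range(5):
            fig, ctr, t = self._curves(rng, effect=0.5)
            res = fg.modulation_latency(fig, ctr, t, n_boot=2000, rng=rng)
            hits += res.latency_ms is not None and 90 <= res.latency_ms <= 140
        assert hits >= 4

    def test_trial_resampling_null_matches_direct_oracle(self, rng):
        # brute-force oracle: the per-bin statistic is mean(fig) - mean(ctr)
        # of per-stimulus trial means; under trial resampling the per-bin p
        # is approximately uniform, so the false-run rate over white-noise
        # bins is tiny (alpha * P(4 more consecutive) per bin).
        n_false = 0
        n_sim = 20
        for _ in range(n_sim):
            fig, ctr, t = self._curves(rng, effect=0.0, T=500)
            res = fg.modulation_latency(fig, ctr, t, n_boot=1000, rng=rng)
            n_false += res.latency_ms is not None
        # oracle: ~300 post-onset bins * 0.01 * 0.01^4 expected runs ~ 0
        assert n_false <= 1

    def test_curve_resampling_is_anticonservative(self, rng):
        # documented limitation of the curve-level bootstrap: the 96 pooled
        # curves share 20 underlying stimulus responses, so resampling them
        # as exchangeable units yields false onsets under the null
        n_false = 0
        for _ in range(5):
            fig, ctr, t = self._curves(rng, effect=0.0, T=500)
            res = fg.modulation_latency(fig, ctr, t, n_boot=1000, rng=rng,
                                        resample="curves")
            n_false += res.latency_ms is not None
        assert n_false >= 3

    def test_degrades_with_effect_size(self, rng):
        # recovery scatter grows as the planted effect shrinks
        spreads = []
        for effect in (1.0, 0.25):
            lats = []
            for _ in range(8):
                fig, ctr, t = self._curves(rng, effect=effect)
                res = fg.modulation_latency(fig, ctr, t, n_boot=1000, rng=rng)
                if res.latency_ms is not None:
                    lats.append(res.latency_ms)
            spreads.append(np.std(lats) if len(lats) > 1 else np.inf)
        assert spreads[1] >= spreads[0]

    def test_too_few_stimuli_rejected(self, rng):
        fig, ctr, t = self._curves(rng, n_fig=1)
        with pytest.raises(ValueError):
            fg.modulation_latency(fig, ctr, t, n_boot=100, rng=rng)


class TestFdr:
    def test_brute_force_example(self):
        # sorted p vs q*i/m: 0.01<=0.0125, 0.02<=0.025, 0.03<=0.0375, 0.9>0.05
        reject, _ = fg.fdr_correct([0.01, 0.02, 0.03, 0.9], q=0.05)
        assert reject.tolist() == [True, True, True, False]

    def test_all_ones_none_rejected(self):
        reject, _ = fg.fdr_correct(np.ones(10))
        assert not reject.any()

    def test_single_p_reduces_to_threshold(self):
        assert fg.fdr_correct([0.04], q=0.05)[0][0]
        assert not fg.fdr_correct([0.06], q=0.05)[0][0]

    def test_matches_brute_force_step_up(self, rng):
        p = rng.uniform(size=25)
        reject, _ = fg.fdr_correct(p, q=0.1)
        order = np.argsort(p)
        ps = p[order]
        thresh = 0.1 * np.arange(1, 26) / 25
        below = np.flatnonzero(ps <= thresh)
        expected = np.zeros(25, bool)
        if len(below):
            expected[order[: below[-1] + 1]] = True
        assert np.array_equal(reject, expected)


class TestPopulationTimecourse:
    def test_identical_sites_zero_sem(self):
        f = np.tile(np.linspace(0, 1, 50), (4, 1))
        c = np.zeros((4, 50))
        out = fg.population_timecourse(f, c + 1e-9 * np.arange(4)[:, None], np.arange(50))
        assert np.allclose(out.sem_figure, 0.0)

    def test_planted_effect_onset_detected(self, rng):
        t = np.arange(-100, 500)
        effect = 0.5 * (t >= 200)
        f = effect + 0.1 * rng.standard_normal((12, len(t)))
        c = 0.1 * rng.standard_normal((12, len(t)))
        out = fg.population_timecourse(f, c, t)
        # dense significance from the planted onset, sparse before (isolated
        # pre-onset rejections can occur: a strong effect loosens the
        # adaptive step-up threshold)
        assert out.significant[t >= 220].mean() > 0.9
        assert out.significant[t < 180].mean() < 0.2
        runs = np.convolve(out.significant.astype(float), np.ones(20) / 20, "valid")
        first_dense = t[np.argmax(runs >= 1.0)]
        assert 150 <= first_dense <= 260

    def test_permuted_labels_control_fdr(self, rng):
        x = rng.standard_normal((20, 300))
        out = fg.population_timecourse(x[:10], x[10:], np.arange(300))
        assert out.significant.mean() <= 0.05


class TestMotorAnalysis:
    def test_bump_after_release_invisible(self):
        # windows are pre-release; a bump after release must not register
        bundle = ses.generate_bar_release_session(n_sites=4, n_releases=80, seed=1,
                                                  motor_gain=0.0)
        # inject a post-release bump directly
        bundle.traces[:, :, 820:] *= 1.5
        res = fg.motor_control_analysis(bundle)
        assert abs(res["mean_difference"]) < 3 * res["sem_difference"] + 1e-4

    def test_sfg_bundle_rejected(self):
        cfg = ses.SessionConfig(n_sites=2, n_reps=2)
        bundle = ses.generate_session(cfg, seed=0)
        with pytest.raises(ValueError):
            fg.motor_control_analysis(bundle)
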